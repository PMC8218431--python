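"""File formats: PLINK bed/bim/fam, LDSC-style TSV tables, run manifests.

All tabular output is tab-delimited with a header line and ``NA`` for
missing values; SNP joins downstream are by id, never by position (synthetic
positions are artificial: chromosome 1, bp = SNP index * 1000).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .ldscore import LDScoreTable
from .scan import InteractionSummaryStats
from .simulate import GenotypeMatrix, SimulationConfig

__all__ = [
    "read_plink",
    "write_plink",
    "read_sumstats",
    "write_sumstats",
    "read_ldscores",
    "write_ldscores",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_config",
    "write_config",
    "RunManifest",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 bed
# 2-bit codes -> dosage of the A1 allele; 1 (0b01) is the missing code
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}


def write_plink(prefix: Union[str, Path], X: GenotypeMatrix, iids=None) -> None:
    """Write a bed/bim/fam triple (chromosome 1, bp = index*1000, alleles A/C)."""
    prefix = Path(prefix)
    n, m = X.n, X.m
    if iids is None:
        iids = [f"id{i + 1}" for i in range(n)]
    with open(Path(str(prefix) + ".fam"), "w") as fh:
        for iid in iids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    with open(Path(str(prefix) + ".bim"), "w") as fh:
        for j, snp in enumerate(X.snp_ids):
            fh.write(f"1\t{snp}\t0\t{(j + 1) * 1000}\tA\tC\n")

    dos = X.dosages.astype(np.int8)
    if X.missing_mask is not None:
        dos = np.where(X.missing_mask, np.int8(-1), dos)
    codes = np.empty_like(dos, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[dos == d] = c
    n_bytes = (n + 3) // 4
    with open(Path(str(prefix) + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros((m, n_bytes), dtype=np.uint8)
        for k in range(4):
            idx = np.arange(k, n, 4)
            buf[:, : len(idx)] |= codes[idx, :].T.astype(np.uint8) << (2 * k)
        fh.write(buf.tobytes())


def read_plink(prefix: Union[str, Path]) -> GenotypeMatrix:
    """Read a bed/bim/fam triple into a GenotypeMatrix.

    Missing genotypes are surfaced in ``missing_mask`` (and mean-imputed per
    SNP in the standardized view); duplicate SNP ids are an error.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not Path(str(prefix) + ext).exists():
            raise FileNotFoundError(f"missing {prefix}{ext}")
    try:
        fam = pd.read_csv(Path(str(prefix) + ".fam"), sep=r"\s+", header=None)
    except pd.errors.EmptyDataError:
        raise ValueError("fam file lists 0 individuals") from None
    bim = pd.read_csv(Path(str(prefix) + ".bim"), sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    if n == 0:
        raise ValueError("fam file lists 0 individuals")
    snp_ids = bim[1].astype(str).to_numpy()
    dup = pd.Series(snp_ids)[pd.Series(snp_ids).duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate SNP ids: {list(dup[:10])}")

    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("bad bed magic bytes (expected SNP-major PLINK 1 file)")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise ValueError("truncated or oversized bed file")
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # (n, m)

    missing = dosages == -1
    if missing.any():
        dosages = np.where(missing, np.int8(0), dosages)
        mask = missing
    else:
        mask = None
    with np.errstate(invalid="ignore"):
        counts = np.where(mask, np.nan, dosages) if mask is not None else dosages
        freq = np.nanmean(counts, axis=0) / 2.0
    return GenotypeMatrix(
        dosages.astype(np.int8),
        snp_ids,
        np.zeros(m, dtype=int),
        np.clip(freq, 1e-9, 1 - 1e-9),
        missing_mask=mask,
    )


# ---- tabular formats -------------------------------------------------------


def write_sumstats(path: Union[str, Path], ss: InteractionSummaryStats) -> None:
    """Write `SNP N BETA1 SE1 CHISQ Z` (tab-delimited, NA for missing)."""
    ss.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: Union[str, Path]) -> pd.DataFrame:
    """Read a sumstats TSV; requires SNP and N plus CHISQ or Z."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if "SNP" not in df.columns or "N" not in df.columns:
        raise ValueError("sumstats file needs SNP and N columns")
    if "CHISQ" not in df.columns:
        if "Z" not in df.columns:
            raise ValueError("sumstats file needs a CHISQ or Z column")
        df["CHISQ"] = df["Z"] ** 2
    return df


def write_ldscores(path: Union[str, Path], table: LDScoreTable) -> None:
    """Write `CHR SNP BP L2` (LDSC .l2.ldscore-compatible)."""
    pd.DataFrame(
        {
            "CHR": 1,
            "SNP": table.snp_ids,
            "BP": (np.arange(table.m) + 1) * 1000,
            "L2": table.l2,
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ldscores(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if "SNP" not in df.columns or "L2" not in df.columns:
        raise ValueError("LD score file needs SNP and L2 columns")
    return df


def write_phenotype_table(
    path: Union[str, Path], values: np.ndarray, iids=None, name: str = "VALUE"
) -> None:
    """FID IID VALUE, tab-delimited."""
    n = len(values)
    if iids is None:
        iids = [f"id{i + 1}" for i in range(n)]
    pd.DataFrame({"FID": iids, "IID": iids, name: values}).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_phenotype_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if df.columns[:2].tolist() != ["FID", "IID"]:
        raise ValueError("phenotype table must start with FID and IID columns")
    return df


def read_config(path: Union[str, Path]) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "maf_bounds" in raw:
        raw["maf_bounds"] = tuple(raw["maf_bounds"])
    return SimulationConfig(**raw)


def write_config(path: Union[str, Path], config: SimulationConfig) -> None:
    d = {k: v for k, v in config.__dict__.items()}
    d["maf_bounds"] = list(d["maf_bounds"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# ---- reproducibility harness ----------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """What was run: command line, seeds, input checksums, version, time."""

    command: str
    seed: Optional[int] = None
    inputs: dict = field(default_factory=dict)
    version: str = ""
    started: float = field(default_factory=time.time)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.command:
            self.command = " ".join(sys.argv)

    def add_input(self, path: Union[str, Path]) -> None:
        p = Path(path)
        if p.exists():
            self.inputs[str(p)] = _sha256(p)

    def write(self, path: Union[str, Path]) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "inputs": self.inputs,
            "version": self.version,
            "started": self.started,
            "finished": time.time(),
            **({"extra": self.extra} if self.extra else {}),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
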