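"""Readers and writers for the plain-text formats used by the pipeline.

Genotypes: (a) delimited matrix — header of SNP ids, first column the animal
id, entries 0/1/2/NA, tab or comma separated; (b) PLINK RAW dialect — header
``FID IID PAT MAT SEX PHENOTYPE`` followed by per-SNP allele-count columns,
IID used as the animal id.  The canonical output dialect is tab-separated.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, Grm
from .evaluation import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_grm",
    "write_gebv",
    "read_gebv",
    "write_snp_table",
    "write_run_summary",
]

_NA_TOKENS = {"NA", "NaN", "nan", ""}
_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sniff_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _parse_counts(raw: pd.DataFrame, path) -> np.ndarray:
    counts = np.empty(raw.shape, dtype=np.float64)
    for j, col in enumerate(raw.columns):
        vals = raw[col].astype(str).str.strip()
        is_na = vals.isin(_NA_TOKENS)
        numeric = pd.to_numeric(vals.where(~is_na), errors="coerce")
        bad = (~is_na) & (numeric.isna() | ~numeric.isin([0, 1, 2]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: unparseable genotype token {vals.iloc[row]!r} at "
                f"data row {row + 1}, column {col!r} (expected 0/1/2/NA)"
            )
        counts[:, j] = numeric.to_numpy(dtype=float)
    return counts


def read_genotype_matrix(path, format_hint: str | None = None) -> GenotypeMatrix:
    """Parse a genotype file, auto-detecting the PLINK RAW dialect from its
    ``FID IID ...`` header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = _sniff_delimiter(header)
    first_tokens = header.split(None, 2) if sep == r"\s+" else header.split(sep, 2)
    is_raw = format_hint == "plink-raw" or (
        format_hint is None and len(first_tokens) >= 2
        and first_tokens[0] == "FID" and first_tokens[1] == "IID"
    )

    df = pd.read_csv(path, sep=sep, dtype=str, engine="python", keep_default_na=False)
    # with keep_default_na off, genuine NaN can only come from short (ragged) rows
    if df.isna().any().any():
        row = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
        raise ValueError(f"{path}: ragged data row {row + 1}")
    if is_raw:
        missing = [c for c in _PLINK_META if c not in df.columns[:6].tolist()]
        if missing:
            raise ValueError(f"{path}: PLINK RAW header missing columns {missing}")
        animal_ids = df["IID"].to_numpy(dtype=object)
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        # strip the appended counted-allele suffix (e.g. "rs42_A" -> "rs42")
        snp_ids = [
            c.rsplit("_", 1)[0]
            if "_" in c and c.rsplit("_", 1)[1] in {"A", "C", "G", "T", "0"}
            else c
            for c in snp_cols
        ]
        counts = _parse_counts(df[snp_cols], path)
    else:
        animal_ids = df.iloc[:, 0].to_numpy(dtype=object)
        snp_ids = list(df.columns[1:])
        counts = _parse_counts(df.iloc[:, 1:], path)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=np.array(snp_ids, dtype=object),
        counts=counts,
    )


def write_genotype_matrix(geno: GenotypeMatrix, path) -> None:
    """Canonical tab-separated dialect; missing entries as NA."""
    with _atomic_open(path) as fh:
        fh.write("animal_id\t" + "\t".join(map(str, geno.snp_ids)) + "\n")
        for i, aid in enumerate(geno.animal_ids):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.counts[i]
            ]
            fh.write(str(aid) + "\t" + "\t".join(row) + "\n")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    required = {"animal_id", "dyd", "de"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: phenotype table must have columns {sorted(required)}; "
            f"found {list(df.columns)}"
        )
    extra = [c for c in df.columns if c not in required and c != "reliability"]
    if extra:
        logger.info("%s: ignoring extra phenotype columns %s", path, extra)
    return PhenotypeTable(
        animal_id=df["animal_id"].astype(str).to_numpy(dtype=object),
        dyd=df["dyd"].to_numpy(dtype=float),
        d_e=df["de"].to_numpy(dtype=float),
        reliability=df["reliability"].to_numpy(dtype=float)
        if "reliability" in df.columns
        else None,
    )


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    df = pheno.to_frame()
    with _atomic_open(path) as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_grm(grm: Grm, path, lower_triangle: bool = False) -> None:
    with _atomic_open(path) as fh:
        fh.write("animal_id\t" + "\t".join(map(str, grm.animal_ids)) + "\n")
        for i, aid in enumerate(grm.animal_ids):
            end = i + 1 if lower_triangle else grm.n_animals
            vals = "\t".join(f"{v:.6g}" for v in grm.values[i, :end])
            fh.write(f"{aid}\t{vals}\n")


def write_gebv(path, animal_ids, gebv) -> None:
    with _atomic_open(path) as fh:
        fh.write("animal_id\tgebv\n")
        for aid, v in zip(animal_ids, gebv):
            fh.write(f"{aid}\t{v:.6g}\n")


def read_gebv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"animal_id", "gebv"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns animal_id, gebv")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def write_snp_table(path, snp_ids, q_hat, postprob) -> None:
    """Per-SNP effect summary: (snp_id, q_hat, postprob-or-inclusion-freq)."""
    with _atomic_open(path) as fh:
        fh.write("snp_id\tq_hat\tpostprob\n")
        for sid, q, p in zip(snp_ids, q_hat, postprob):
            fh.write(f"{sid}\t{q:.6g}\t{p:.6g}\n")


def write_run_summary(path, summary: dict) -> None:
    summary = dict(summary)
    summary.setdefault("written_at", time.strftime("%Y-%m-%dT%H:%M:%S"))
    with _atomic_open(path) as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


class _atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self.tmp = tempfile.mkstemp(
            dir=self.path.parent, prefix=self.path.name + ".", suffix=".tmp"
        )
        self.fh = os.fdopen(fd, "w")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False
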