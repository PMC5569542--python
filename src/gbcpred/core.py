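"""Genotype containers, allele frequencies, MAF filtering, centering, and the
genomic relationship matrix (GRM).

The GRM follows the classic "method 1" construction: centre allele counts by
twice the allele frequency and divide the cross-product by ``2 * sum p_j (1 - p_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CenteredGenotypes",
    "Grm",
    "RelatednessSummary",
    "allele_frequencies",
    "filter_by_maf",
    "center_genotypes",
    "build_grm",
    "relatedness_summary",
]


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class GenotypeMatrix:
    """Raw allele-count matrix (animals x SNPs).

    ``counts`` holds alternative-allele counts in {0, 1, 2}; missing calls are
    ``NaN``.  Row/column order matches ``animal_ids`` / ``snp_ids``.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        n, m = self.counts.shape
        if len(self.animal_ids) != n:
            raise ValueError(f"{len(self.animal_ids)} animal ids for {n} rows")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {m} columns")
        _check_unique(self.animal_ids, "animal ids")
        _check_unique(self.snp_ids, "SNP ids")
        vals = self.counts[~np.isnan(self.counts)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise ValueError(f"genotype entries must be 0/1/2/missing; found {bad[:5]}")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            animal_ids=self.animal_ids,
            snp_ids=self.snp_ids[index],
            counts=self.counts[:, index],
            chrom=None if self.chrom is None else np.asarray(self.chrom)[index],
            pos=None if self.pos is None else np.asarray(self.pos)[index],
        )


@dataclass
class CenteredGenotypes:
    """Centred design matrix ``M`` with ``M_ij = x_ij - 2 p_j`` and the scaling
    constant ``scale_c = 2 * sum p_j (1 - p_j)``."""

    M: np.ndarray
    freqs: np.ndarray
    scale_c: float
    animal_ids: np.ndarray
    snp_ids: np.ndarray

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    def rows(self, index: np.ndarray) -> "CenteredGenotypes":
        """Row subset sharing the frequencies and scaling of the parent."""
        index = np.asarray(index)
        return CenteredGenotypes(
            M=self.M[index],
            freqs=self.freqs,
            scale_c=self.scale_c,
            animal_ids=self.animal_ids[index],
            snp_ids=self.snp_ids,
        )

    def rows_for(self, ids) -> "CenteredGenotypes":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            index = np.array([lookup[a] for a in ids])
        except KeyError as e:
            raise KeyError(f"animal id {e.args[0]!r} not in genotype matrix") from None
        return self.rows(index)


@dataclass
class Grm:
    """Genomic relationship matrix with aligned animal identifiers."""

    values: np.ndarray
    animal_ids: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("GRM must be square")
        if len(self.animal_ids) != self.values.shape[0]:
            raise ValueError("animal id count does not match GRM dimension")
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    def indices_for(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[a] for a in ids])
        except KeyError as e:
            raise KeyError(f"animal id {e.args[0]!r} not in GRM") from None

    def block(self, row_ids, col_ids) -> np.ndarray:
        r = self.indices_for(row_ids)
        c = self.indices_for(col_ids)
        return self.values[np.ix_(r, c)]

    def subset(self, ids) -> "Grm":
        idx = self.indices_for(ids)
        return Grm(values=self.values[np.ix_(idx, idx)], animal_ids=self.animal_ids[idx])


@dataclass
class RelatednessSummary:
    """Per-validation-animal relatedness to a reference set.

    ``table`` has columns animal_id, mean_rel, rel_max, rel5, rel10.  ``rel_max``
    is the signed maximum relationship; ``rel5``/``rel10`` average the 5/10
    largest absolute relationships.
    """

    table: pd.DataFrame
    group_mean: pd.Series
    group_sd: pd.Series
    truncated: bool = False


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Alternative-allele frequency per SNP from non-missing calls.

    ``p_j = (sum of non-missing counts) / (2 * number of non-missing calls)``.
    """
    n_obs = np.sum(~np.isnan(geno.counts), axis=0)
    if (n_obs == 0).any():
        bad = geno.snp_ids[n_obs == 0]
        raise ValueError(f"SNP(s) with no non-missing calls: {list(bad[:5])}")
    return np.nansum(geno.counts, axis=0) / (2.0 * n_obs)


def filter_by_maf(geno: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop SNPs whose minor allele frequency is below ``threshold``.

    SNPs with MAF exactly equal to the threshold are retained; animal set and
    column order are preserved.
    """
    if not 0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5); got {threshold}")
    p = allele_frequencies(geno)
    keep = np.minimum(p, 1.0 - p) >= threshold
    if not keep.any():
        raise ValueError(
            f"no SNP passes MAF >= {threshold}; reduce the threshold"
        )
    return geno.take_snps(np.flatnonzero(keep))


def center_genotypes(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> CenteredGenotypes:
    """Centre counts to ``M_ij = x_ij - 2 p_j``; missing entries become 0
    (i.e. the mean ``2 p_j`` before centring)."""
    p = allele_frequencies(geno) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (geno.n_snps,):
        raise ValueError(
            f"frequency vector length {p.shape} does not match {geno.n_snps} SNPs"
        )
    fixed = (p <= 0.0) | (p >= 1.0)
    if fixed.any():
        bad = geno.snp_ids[fixed]
        raise ValueError(
            f"degenerate allele frequency (0 or 1) for SNP(s) {list(bad[:5])}; "
            "apply a MAF filter first"
        )
    M = geno.counts - 2.0 * p
    M[np.isnan(M)] = 0.0
    scale_c = float(2.0 * np.sum(p * (1.0 - p)))
    return CenteredGenotypes(
        M=M, freqs=p, scale_c=scale_c,
        animal_ids=geno.animal_ids, snp_ids=geno.snp_ids,
    )


def build_grm(cg: CenteredGenotypes) -> Grm:
    """``G = M M' / scale_c``, symmetrised against round-off."""
    if cg.scale_c <= 0:
        raise ValueError(f"scaling constant must be positive; got {cg.scale_c}")
    G = cg.M @ cg.M.T / cg.scale_c
    G = (G + G.T) / 2.0
    return Grm(values=G, animal_ids=cg.animal_ids)


def relatedness_summary(
    grm: Grm, validation_ids, reference_ids
) -> RelatednessSummary:
    """Summarise each validation animal's genomic relationships to the
    reference set: mean, signed maximum, and the means of the 5 and 10 largest
    absolute relationships."""
    validation_ids = list(validation_ids)
    reference_ids = list(reference_ids)
    if not validation_ids or not reference_ids:
        raise ValueError("validation and reference sets must both be non-empty")
    overlap = set(validation_ids) & set(reference_ids)
    if overlap:
        raise ValueError(f"validation and reference sets overlap: {sorted(overlap)[:5]}")
    vi = grm.indices_for(validation_ids)
    ri = grm.indices_for(reference_ids)
    truncated = len(ri) < 10
    rows = []
    for i, v in enumerate(vi):
        rel = grm.values[v, ri]
        arel = np.sort(np.abs(rel))[::-1]
        rows.append(
            dict(
                animal_id=validation_ids[i],
                mean_rel=float(rel.mean()),
                rel_max=float(rel.max()),
                rel5=float(arel[: min(5, len(arel))].mean()),
                rel10=float(arel[: min(10, len(arel))].mean()),
            )
        )
    table = pd.DataFrame(rows)
    stats = table[["mean_rel", "rel_max", "rel5", "rel10"]]
    return RelatednessSummary(
        table=table,
        group_mean=stats.mean(),
        group_sd=stats.std(ddof=1) if len(table) > 1 else stats.mul(0.0).iloc[0],
        truncated=truncated,
    )
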