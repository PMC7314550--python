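"""Per-individual variant burden by MAF bin and effect category.

The burden of an individual is the number of qualifying variant sites at
which they carry at least one alternate allele (site-count mode; an
allele-dosage mode counting homozygotes twice is available).  Ultra-rare PTV
burden — the count of truncating variants with MAF < 1e-4 — is the exposure
of interest throughout the survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variants import (
    EffectCategory,
    MAF_BIN_EDGES,
    PTV_CATEGORIES,
    VariantRecord,
)

__all__ = ["BurdenMatrix", "compute_burden", "stratify_by_burden", "BURDEN_GROUP_EDGES"]

#: Burden-group boundaries: 0–3, 4–5, 6–7, 8–9, >=10 ultra-rare PTVs.
BURDEN_GROUP_EDGES = (4, 6, 8, 10)


@dataclass
class BurdenMatrix:
    """Individuals x (MAF bin, effect category) integer count matrix.

    ``counts`` is a DataFrame indexed by individual id with a two-level
    column index (bin, category).  ``mode`` records whether sites or alleles
    were counted.
    """

    counts: pd.DataFrame
    mode: str = "site"

    def ultra_rare_ptv(self) -> pd.Series:
        """Ultra-rare (bin 1) PTV count per individual."""
        cols = [
            (1, cat.value)
            for cat in PTV_CATEGORIES
            if (1, cat.value) in self.counts.columns
        ]
        if not cols:
            return pd.Series(0, index=self.counts.index, name="ultra_rare_ptv")
        return self.counts[cols].sum(axis=1).rename("ultra_rare_ptv")

    def by_bin(self, category_filter: set | None = PTV_CATEGORIES) -> pd.DataFrame:
        """Counts per MAF bin, summed over the given categories."""
        cats = (
            {c.value for c in category_filter}
            if category_filter is not None
            else {c[1] for c in self.counts.columns}
        )
        keep = [c for c in self.counts.columns if c[1] in cats]
        return self.counts[keep].T.groupby(level=0).sum().T

    def to_tsv(self, path) -> None:
        long = (
            self.counts.stack([0, 1], future_stack=True)
            .rename("count")
            .reset_index()
        )
        long.columns = ["id", "bin", "category", "count"]
        long.to_csv(path, sep="\t", index=False)


def compute_burden(
    records: Iterable[VariantRecord],
    individuals: Sequence[str],
    categories: set | None = None,
    bins: set | None = None,
    mode: str = "site",
) -> BurdenMatrix:
    """Tally qualifying variant carriage per individual, bin and category.

    Parameters
    ----------
    records : filtered, classified variant records with carrier sets.
    individuals : cohort ids; every carrier must be among them.
    categories : effect categories to keep (default: all).
    bins : 1-based MAF bin indices to keep (default: all four).
    mode : ``"site"`` counts each carried site once; ``"dosage"`` counts
        homozygous carriers twice.
    """
    if mode not in ("site", "dosage"):
        raise ValueError("mode must be 'site' or 'dosage'")
    individuals = list(individuals)
    idx = {ind: i for i, ind in enumerate(individuals)}
    n_bins = len(MAF_BIN_EDGES) - 1
    keep_bins = set(range(1, n_bins + 1)) if bins is None else set(bins)
    keep_cats = (
        {c.value for c in EffectCategory} if categories is None
        else {c.value if isinstance(c, EffectCategory) else str(c) for c in categories}
    )
    columns = [
        (b, c.value)
        for b in sorted(keep_bins)
        for c in EffectCategory
        if c.value in keep_cats
    ]
    col_idx = {c: j for j, c in enumerate(columns)}
    mat = np.zeros((len(individuals), len(columns)), dtype=np.int64)
    for rec in records:
        # truncating annotations only count on the canonical transcript
        if rec.category in PTV_CATEGORIES and not rec.is_ptv:
            continue
        key = (rec.maf_bin, rec.category.value)
        if key not in col_idx:
            continue
        j = col_idx[key]
        for carrier in rec.carriers:
            if carrier not in idx:
                raise KeyError(
                    f"carrier {carrier!r} at {rec.chrom}:{rec.pos} not in cohort"
                )
            mat[idx[carrier], j] += 1
            if mode == "dosage" and carrier in rec.hom_carriers:
                mat[idx[carrier], j] += 1
    counts = pd.DataFrame(
        mat,
        index=pd.Index(individuals, name="id"),
        columns=pd.MultiIndex.from_tuples(columns, names=["bin", "category"]),
    )
    return BurdenMatrix(counts=counts, mode=mode)


def stratify_by_burden(counts: Sequence[int]) -> np.ndarray:
    """Burden-group label (1..5) for each ultra-rare PTV count.

    Groups: 1 = 0–3 PTVs, 2 = 4–5, 3 = 6–7, 4 = 8–9, 5 = 10 or more.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise ValueError("burden counts must be non-negative")
    return np.digitize(c, BURDEN_GROUP_EDGES) + 1
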