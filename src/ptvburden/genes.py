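"""Gene-level constraint and burden statistics.

Covers: the per-gene PTV-versus-synonymous constraint test (2x2 Fisher with
Bonferroni correction, labelling genes as *prone* to or *intolerant* of
ultra-rare truncating variants), the split-cohort gene burden test against
lifespan/healthspan (Fisher with Benjamini-Hochberg FDR), identification of
iPTV genes (genes with no observed ultra-rare PTV), the 50-bp rule for
nonsense-mediated decay, expression breadth from a tissue TPM matrix, and
generic group comparisons of gene annotation metrics (rank-sum, t, Fisher).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variants import PTV_CATEGORIES, EffectCategory, VariantRecord

__all__ = [
    "GeneCounts",
    "GeneAnnotation",
    "TranscriptModel",
    "gene_counts_from_records",
    "constraint_test",
    "gene_burden_test",
    "nmd_predict",
    "expression_breadth",
    "iptv_genes",
    "compare_gene_groups",
]

#: spliced-transcript distance from the premature stop to the last
#: exon-exon junction beyond which NMD is predicted to fire
NMD_RULE_NT = 50

#: TPM threshold above which a gene counts as expressed in a tissue
TPM_EXPRESSED = 10.0


@dataclass(frozen=True)
class GeneCounts:
    """Ultra-rare truncating and synonymous variant tallies for one gene.

    ``n_ptv`` counts ultra-rare stop gains and frameshifts only — splice-site
    variants are excluded because their number per gene scales with intron
    count rather than coding constraint.  ``n_syn`` counts synonymous
    variants at all frequencies (the coverage-normalising neutral read-out).
    """

    gene: str
    n_ptv: int
    n_syn: int

    def __post_init__(self):
        if self.n_ptv < 0 or self.n_syn < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GeneAnnotation:
    """External per-gene deleteriousness/essentiality metrics."""

    gene: str
    oe: float | None = None
    pli: float | None = None
    ghis: float | None = None
    indispensability: float | None = None
    dn_ds: float | None = None
    expression_breadth: float | None = None

    def __post_init__(self):
        if self.oe is not None and self.oe < 0:
            raise ValueError("oe must be non-negative")
        for name in ("pli", "ghis", "expression_breadth"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript in spliced (cDNA) coordinates.

    ``exon_lengths`` are ordered 5'->3'; ``cds_start``/``cds_end`` are
    0-based half-open positions in the spliced transcript.
    """

    gene: str
    transcript: str
    strand: str
    exon_lengths: tuple
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        total = sum(self.exon_lengths)
        if not 0 <= self.cds_start < self.cds_end <= total:
            raise ValueError("CDS must lie within the spliced transcript")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    @property
    def last_junction(self) -> int | None:
        """Spliced-coordinate position of the last exon-exon junction."""
        if self.n_exons < 2:
            return None
        return int(sum(self.exon_lengths[:-1]))


def nmd_predict(stop_position: int, transcript: TranscriptModel,
                rule_nt: int = NMD_RULE_NT) -> bool:
    """50-bp rule: does a premature stop trigger nonsense-mediated decay?

    True iff the stop lies strictly more than ``rule_nt`` nucleotides
    upstream of the last exon-exon junction in spliced-transcript
    coordinates.  Stops in the last exon, or within ``rule_nt`` nt of the
    final junction, escape NMD.  Single-exon transcripts never trigger it.
    """
    if not transcript.cds_start <= stop_position < transcript.cds_end:
        raise ValueError(
            f"stop position {stop_position} outside CDS "
            f"[{transcript.cds_start}, {transcript.cds_end})"
        )
    junction = transcript.last_junction
    if junction is None:
        return False
    return junction - stop_position > rule_nt


def expression_breadth(tpm: Sequence[float], threshold: float = TPM_EXPRESSED) -> float:
    """Fraction of tissues in which the gene is expressed (TPM > threshold)."""
    v = np.asarray(tpm, dtype=float)
    if v.size == 0:
        raise ValueError("empty TPM vector")
    if np.any(v < 0):
        raise ValueError("TPM values must be non-negative")
    return float(np.mean(v > threshold))


def iptv_genes(records: Iterable[VariantRecord], universe: Iterable[str]) -> set:
    """Genes with zero observed ultra-rare PTVs (PTV-intolerant set).

    The complement, within ``universe``, of genes harbouring at least one
    ultra-rare (MAF bin 1) protein-truncating variant.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hit = {
        r.gene
        for r in records
        if r.is_ptv and r.maf_bin == 1
    }
    return universe - hit


def gene_counts_from_records(records: Iterable[VariantRecord]) -> list[GeneCounts]:
    """Tally per-gene ultra-rare stop-gain/frameshift and synonymous counts.

    Splice-site variants are excluded from the PTV tally (their per-gene
    count tracks intron number); synonymous variants are counted at all
    frequencies.
    """
    ptv = {}
    syn = {}
    genes = set()
    coding_ptv = {EffectCategory.STOP_GAINED, EffectCategory.FRAMESHIFT}
    for r in records:
        genes.add(r.gene)
        cat = r.category
        if cat in coding_ptv and r.canonical and r.maf_bin == 1:
            ptv[r.gene] = ptv.get(r.gene, 0) + 1
        elif cat is EffectCategory.SYNONYMOUS:
            syn[r.gene] = syn.get(r.gene, 0) + 1
    return [
        GeneCounts(gene=g, n_ptv=ptv.get(g, 0), n_syn=syn.get(g, 0))
        for g in sorted(genes)
    ]


def constraint_test(
    counts: Sequence[GeneCounts],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene PTV/synonymous constraint scan with Bonferroni correction.

    For each gene, a 2x2 table compares its ultra-rare PTV and synonymous
    counts with those in the rest of the gene set; a two-sided Fisher exact
    test yields an odds ratio and p-value.  After Bonferroni adjustment over
    all tested genes, genes with OR > 1 and adjusted p < alpha are labelled
    ``prone`` (harbouring disproportionately many rare PTVs), genes with
    OR < 1 ``intolerant``, all others ``neutral``.
    """
    counts = list(counts)
    total_ptv = sum(c.n_ptv for c in counts)
    total_syn = sum(c.n_syn for c in counts)
    if total_syn == 0:
        raise ValueError("zero synonymous variants in total; cannot normalise")
    rows = []
    for c in counts:
        table = [
            [c.n_ptv, total_ptv - c.n_ptv],
            [c.n_syn, total_syn - c.n_syn],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene": c.gene, "n_ptv": c.n_ptv, "n_syn": c.n_syn,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    label = np.where(
        (df["p_bonferroni"] < alpha) & (df["odds_ratio"] > 1), "prone",
        np.where((df["p_bonferroni"] < alpha) & (df["odds_ratio"] < 1),
                 "intolerant", "neutral"),
    )
    df["label"] = label
    return df.set_index("gene")


def split_cohort(phenotype: pd.Series) -> tuple[set, set]:
    """Split individuals into two equal halves by ordered phenotype.

    Sorting is by (phenotype value, id) so the split is deterministic; with
    an odd cohort the lower half receives the extra individual.
    """
    df = phenotype.rename("value").rename_axis("id").reset_index()
    df = df.sort_values(by=["value", "id"], kind="stable")
    half = (len(df) + 1) // 2
    return set(df["id"].iloc[:half]), set(df["id"].iloc[half:])


def gene_burden_test(
    carriers_by_gene: Mapping[str, Iterable[str]],
    phenotype: pd.Series,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Split-cohort gene burden scan against a lifespan-like phenotype.

    The cohort is split into two equal halves by ordered phenotype; for each
    gene the number of *unique* carrier individuals in each half is compared
    to the total carriers in that half (all genes pooled) by a two-sided
    Fisher exact test, with Benjamini-Hochberg FDR over the tested genes.
    Genes with no carriers are skipped.
    """
    low, high = split_cohort(phenotype)
    cohort = set(phenotype.index)
    per_gene = {}
    for gene, carr in carriers_by_gene.items():
        uniq = set(carr)
        stray = uniq - cohort
        if stray:
            raise KeyError(f"carriers {sorted(stray)[:3]} of {gene} not in cohort")
        a, b = len(uniq & low), len(uniq & high)
        if a + b:
            per_gene[gene] = (a, b)
    if not per_gene:
        raise ValueError("no gene has any carrier")
    tot_low = sum(a for a, _ in per_gene.values())
    tot_high = sum(b for _, b in per_gene.values())
    rows = []
    for gene, (a, b) in sorted(per_gene.items()):
        table = [[a, b], [tot_low - a, tot_high - b]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"gene": gene, "carriers_low": a, "carriers_high": b,
                     "odds_ratio": odds, "p": p})
    df = pd.DataFrame(rows).set_index("gene")
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["q"] < fdr_alpha
    return df


def compare_gene_groups(
    annotations: pd.DataFrame,
    group_labels: pd.Series,
    metric: str,
    test: str = "wilcoxon",
):
    """Two-sided comparison of a gene metric between two groups.

    ``test`` selects Wilcoxon rank-sum (Mann-Whitney), Student t, or Fisher
    exact (for binary metrics, on the 2x2 count table).  Returns
    ``(statistic, pvalue)``.
    """
    if metric not in annotations.columns:
        raise KeyError(f"metric {metric!r} not in annotation table")
    labels = pd.unique(group_labels)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    vals = annotations[metric]
    x = vals[group_labels == labels[0]].dropna().to_numpy()
    y = vals[group_labels == labels[1]].dropna().to_numpy()
    if test == "fisher":
        table = [
            [int((x > 0).sum()), int((x <= 0).sum())],
            [int((y > 0).sum()), int((y <= 0).sum())],
        ]
        return stats.fisher_exact(table, alternative="two-sided")
    if min(x.size, y.size) < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "wilcoxon":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        res = stats.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValueError("test must be one of 'wilcoxon', 't', 'fisher'")
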