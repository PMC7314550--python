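"""Reading, filtering and classifying annotated exome variants.

A *protein-truncating variant* (PTV) is a stop gain, frameshift, or canonical
splice donor/acceptor disruption observed on a gene's canonical transcript.
This module parses annotated variants from VCF (SnpEff/VEP-style ``ANN`` INFO
field) or a simple TSV dialect, computes and folds minor allele frequencies,
applies the site-level filters used throughout the analysis (autosomes only,
missing rate < 10%, MAF < 0.2, polymorphic), classifies functional effect
terms into categories, and assigns each variant to one of four MAF bins:

    bin 1 (ultra-rare)  [0, 1e-4)
    bin 2               [1e-4, 1e-3)
    bin 3               [1e-3, 1e-2)
    bin 4               [1e-2, 0.2)

Intervals are half-open so the bins partition [0, 0.2) with boundaries
belonging to the upper bin.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectCategory",
    "VariantRecord",
    "PTV_CATEGORIES",
    "PTV_TERMS",
    "MAF_BIN_EDGES",
    "ULTRA_RARE_MAF",
    "MAX_MAF",
    "read_variants",
    "write_variants_tsv",
    "write_vcf",
    "compute_maf",
    "classify_effect",
    "assign_maf_bin",
    "filter_variants",
]


class EffectCategory(str, enum.Enum):
    """Functional consequence categories used in the burden analysis."""

    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    SPLICE_DONOR = "splice_donor"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SYNONYMOUS = "synonymous"
    UTR3 = "utr3"
    UTR5 = "utr5"
    TF_BINDING = "tf_binding"
    STRUCTURAL_INTERACTION = "structural_interaction"
    OTHER = "other"


#: Categories whose members disrupt the open reading frame.
PTV_CATEGORIES = frozenset(
    {
        EffectCategory.STOP_GAINED,
        EffectCategory.FRAMESHIFT,
        EffectCategory.SPLICE_DONOR,
        EffectCategory.SPLICE_ACCEPTOR,
    }
)

# Annotation-term vocabulary (Sequence Ontology, as emitted by SnpEff/VEP)
# mapped onto categories.  Terms not listed fall through to OTHER.
_TERM_TO_CATEGORY = {
    "stop_gained": EffectCategory.STOP_GAINED,
    "frameshift_variant": EffectCategory.FRAMESHIFT,
    "splice_donor_variant": EffectCategory.SPLICE_DONOR,
    "splice_acceptor_variant": EffectCategory.SPLICE_ACCEPTOR,
    "synonymous_variant": EffectCategory.SYNONYMOUS,
    "stop_retained_variant": EffectCategory.SYNONYMOUS,
    "3_prime_UTR_variant": EffectCategory.UTR3,
    "5_prime_UTR_variant": EffectCategory.UTR5,
    "TF_binding_site_variant": EffectCategory.TF_BINDING,
    "structural_interaction_variant": EffectCategory.STRUCTURAL_INTERACTION,
}

#: Effect terms that make a variant protein-truncating.
PTV_TERMS = frozenset(
    t for t, c in _TERM_TO_CATEGORY.items() if c in PTV_CATEGORIES
)

#: Half-open MAF bin edges; bin i (1-based) is [edges[i-1], edges[i]).
MAF_BIN_EDGES = (0.0, 1e-4, 1e-3, 1e-2, 0.2)
ULTRA_RARE_MAF = 1e-4
MAX_MAF = 0.2

_AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass
class VariantRecord:
    """One annotated variant site on one alternate allele.

    ``carriers`` holds the ids of individuals carrying at least one copy of
    the alternate allele; ``hom_carriers`` the subset homozygous for it.
    ``stop_position`` is the premature-stop position in spliced-transcript
    coordinates (stop gains only), used for nonsense-mediated-decay
    prediction.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    canonical: bool
    effect_terms: frozenset
    maf: float
    missing_rate: float = 0.0
    carriers: frozenset = field(default_factory=frozenset)
    hom_carriers: frozenset = field(default_factory=frozenset)
    stop_position: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF must lie in [0, 0.5], got {self.maf}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing rate must lie in [0, 1]")
        if not self.effect_terms:
            raise ValueError("effect_terms must be nonempty")

    @property
    def category(self) -> EffectCategory:
        return classify_effect(self.effect_terms, self.canonical)[0]

    @property
    def is_ptv(self) -> bool:
        return classify_effect(self.effect_terms, self.canonical)[1]

    @property
    def maf_bin(self) -> int:
        return assign_maf_bin(self.maf)

    @property
    def is_autosomal(self) -> bool:
        return self.chrom.removeprefix("chr") in _AUTOSOMES


def compute_maf(genotypes: Sequence[float]) -> float:
    """Minor allele frequency from a 0/1/2 genotype vector.

    Missing genotypes are NaN (or negative).  The frequency is the alternate
    allele count over twice the number of non-missing individuals, folded to
    the minor allele (values above 0.5 are reflected).
    """
    g = np.asarray(genotypes, dtype=float)
    mask = np.isfinite(g) & (g >= 0)
    if not mask.any():
        raise ValueError("all genotypes are missing")
    g = g[mask]
    if np.any(g > 2):
        raise ValueError("genotypes must be 0, 1 or 2")
    af = g.sum() / (2.0 * g.size)
    return float(min(af, 1.0 - af))


def classify_effect(
    effect_terms: Iterable[str], canonical: bool = True
) -> tuple[EffectCategory, bool]:
    """Map annotation terms to an :class:`EffectCategory` and a PTV flag.

    The PTV flag is true iff any of the four truncating terms is present and
    the annotation is on the canonical transcript.  When several terms are
    present the most severe category wins (truncating > synonymous > UTR/TF >
    other).  Synonymous variants serve as the neutral control category.
    """
    terms = set(effect_terms)
    if not terms:
        raise ValueError("empty effect term set")
    ptv_hit = bool(terms & PTV_TERMS)
    order = [
        EffectCategory.STOP_GAINED,
        EffectCategory.FRAMESHIFT,
        EffectCategory.SPLICE_DONOR,
        EffectCategory.SPLICE_ACCEPTOR,
        EffectCategory.SYNONYMOUS,
        EffectCategory.UTR3,
        EffectCategory.UTR5,
        EffectCategory.TF_BINDING,
        EffectCategory.STRUCTURAL_INTERACTION,
    ]
    mapped = {_TERM_TO_CATEGORY[t] for t in terms if t in _TERM_TO_CATEGORY}
    category = next((c for c in order if c in mapped), EffectCategory.OTHER)
    return category, ptv_hit and canonical


def assign_maf_bin(maf: float) -> int:
    """1-based MAF bin index over the half-open partition of [0, 0.2)."""
    if not 0.0 <= maf < MAX_MAF:
        raise ValueError(
            f"MAF {maf} outside [0, {MAX_MAF}); such sites should have been filtered"
        )
    # right edge belongs to the upper bin
    return int(np.searchsorted(MAF_BIN_EDGES[1:-1], maf, side="right")) + 1


def filter_variants(
    records: Iterable[VariantRecord],
    max_maf: float = MAX_MAF,
    max_missing: float = 0.10,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply site filters; return retained records and an exclusion log.

    Sites are dropped when monomorphic (MAF 0), when the genotype missing
    rate is >= ``max_missing``, when MAF >= ``max_maf``, or when not on an
    autosome.  Each record is excluded for the first matching reason; the log
    tabulates counts per reason, so filtering is order-independent and
    idempotent (criteria depend only on the record itself).
    """
    retained: list[VariantRecord] = []
    reasons: list[dict] = []
    for rec in records:
        if not rec.is_autosomal:
            reason = "non_autosomal"
        elif rec.maf == 0.0:
            reason = "monomorphic"
        elif rec.missing_rate >= max_missing:
            reason = "high_missing_rate"
        elif rec.maf >= max_maf:
            reason = "high_maf"
        else:
            retained.append(rec)
            continue
        reasons.append(
            {"chrom": rec.chrom, "pos": rec.pos, "alt": rec.alt, "reason": reason}
        )
    log = pd.DataFrame(reasons, columns=["chrom", "pos", "alt", "reason"])
    return retained, log


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "canonical",
    "effect",
    "maf",
    "missing_rate",
    "carriers",
    "hom_carriers",
    "stop_position",
]


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the package's TSV dialect (lossless round-trip)."""
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "transcript": r.transcript,
                "canonical": int(r.canonical),
                "effect": "&".join(sorted(r.effect_terms)),
                "maf": repr(r.maf),
                "missing_rate": repr(r.missing_rate),
                "carriers": ",".join(sorted(r.carriers)),
                "hom_carriers": ",".join(sorted(r.hom_carriers)),
                "stop_position": "" if r.stop_position is None else r.stop_position,
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_tsv_row(row: pd.Series) -> VariantRecord:
    stop = row["stop_position"]
    stop_position = None if pd.isna(stop) or stop == "" else int(float(stop))
    carriers = frozenset(str(row["carriers"]).split(",")) if row["carriers"] else frozenset()
    homs = frozenset(str(row["hom_carriers"]).split(",")) if row["hom_carriers"] else frozenset()
    return VariantRecord(
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row["gene"]),
        transcript=str(row["transcript"]),
        canonical=bool(int(row["canonical"])),
        effect_terms=frozenset(str(row["effect"]).split("&")),
        maf=float(row["maf"]),
        missing_rate=float(row["missing_rate"]),
        carriers=carriers,
        hom_carriers=homs,
        stop_position=stop_position,
    )


def _read_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(_TSV_COLUMNS[:10]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"TSV missing required columns: {sorted(missing_cols)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(_parse_tsv_row(row))
        except (ValueError, KeyError) as exc:
            # header is line 1, so data row i sits on line i + 2
            warnings.warn(f"{path}: skipping malformed row at line {i + 2}: {exc}")
    return records


# ---------------------------------------------------------------------------
# VCF 4.2 with an ANN-style annotation field
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Gene_Name | Feature_ID | Canonical'">
##INFO=<ID=STOPPOS,Number=1,Type=Integer,Description="Premature stop position in spliced-transcript coordinates">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(
    records: Sequence[VariantRecord],
    individuals: Sequence[str],
    path: str | Path,
) -> None:
    """Write a minimal VCF 4.2 with genotypes and an ANN annotation field.

    One VCF line per record; multi-allelic sites are kept decomposed (one alt
    per line), which is the normalisation the readers assume.
    """
    individuals = list(individuals)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted({r.chrom for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for r in sorted(records, key=lambda v: (v.chrom, v.pos, v.alt)):
            ann = "{}|{}|{}|{}|{}".format(
                r.alt,
                "&".join(sorted(r.effect_terms)),
                r.gene,
                r.transcript,
                "YES" if r.canonical else "NO",
            )
            info = f"ANN={ann}"
            if r.stop_position is not None:
                info += f";STOPPOS={r.stop_position}"
            gts = []
            for ind in individuals:
                if ind in r.hom_carriers:
                    gts.append("1/1")
                elif ind in r.carriers:
                    gts.append("0/1")
                else:
                    gts.append("0/0")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def _read_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        ann = var.INFO.get("ANN")
        if ann is None:
            warnings.warn(f"{path}: {var.CHROM}:{var.POS} has no ANN field; skipped")
            continue
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown/missing, 3 hom-alt
        gt = np.asarray(var.gt_types)
        missing = gt == 2
        carriers = frozenset(
            s for s, t in zip(samples, gt) if t in (1, 3)
        )
        homs = frozenset(s for s, t in zip(samples, gt) if t == 3)
        dosage = np.where(missing, np.nan, np.where(gt == 3, 2, np.where(gt == 1, 1, 0)))
        maf = compute_maf(dosage) if np.isfinite(dosage).any() else 0.0
        stop = var.INFO.get("STOPPOS")
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 5:
                warnings.warn(f"{path}: malformed ANN entry at {var.CHROM}:{var.POS}")
                continue
            allele, terms, gene, transcript, canonical = fields[:5]
            records.append(
                VariantRecord(
                    chrom=str(var.CHROM),
                    pos=int(var.POS),
                    ref=var.REF,
                    alt=allele,
                    gene=gene,
                    transcript=transcript,
                    canonical=canonical.upper() == "YES",
                    effect_terms=frozenset(terms.split("&")),
                    maf=maf,
                    missing_rate=float(missing.mean()),
                    carriers=carriers,
                    hom_carriers=homs,
                    stop_position=None if stop is None else int(stop),
                )
            )
    return records


def read_variants(path: str | Path, format: str = "auto") -> list[VariantRecord]:
    """Read annotated variants from a VCF (ANN field) or the TSV dialect.

    ``format`` is ``"vcf"``, ``"tsv"`` or ``"auto"`` (by file extension).
    Malformed rows are reported as warnings with their location and skipped.
    """
    path = Path(path)
    if format == "auto":
        suffixes = {s.lower() for s in path.suffixes}
        if ".vcf" in suffixes:
            format = "vcf"
        elif ".tsv" in suffixes or ".txt" in suffixes:
            format = "tsv"
        else:
            raise ValueError(f"cannot infer format from {path.name}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown variant format: {format!r}")


def with_external_maf(
    records: Iterable[VariantRecord],
    reference_maf: dict,
    drop_absent: bool = True,
) -> list[VariantRecord]:
    """Replace internal MAFs with frequencies from an external reference panel.

    Keys of ``reference_maf`` are ``(chrom, pos, alt)`` tuples.  Variants
    absent from the reference are dropped when ``drop_absent`` (reference
    mode for small cohorts, where absence from a large panel flags a likely
    calling artefact); otherwise the internal MAF is kept.
    """
    out = []
    for rec in records:
        key = (rec.chrom, rec.pos, rec.alt)
        if key in reference_maf:
            out.append(replace(rec, maf=float(reference_maf[key])))
        elif not drop_absent:
            out.append(rec)
    return out
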