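"""Synthetic cohorts with the statistical structure of an exome-sequenced
biobank lifespan study.

The generator emulates, with no data download:

* per-individual ultra-rare PTV burdens — negative binomial with mean 6 and
  SD 2.6 per genome (variance/mean ratio ~1.13);
* Gompertz mortality and morbidity, ``h(t) = h0 exp(Gamma t + beta n +
  beta_sex s)`` with log-hazard slope Gamma = 0.09 /yr, burden effects
  beta = 0.046 (lifespan) and 0.014 (healthspan) per mutation, and a male
  excess log-hazard;
* an enrolment + 11-year follow-up censoring scheme with assessment ages
  uniform on 40-70 and enrolment conditional on being alive at assessment;
* a variant-level table whose ultra-rare PTV carriages aggregate exactly to
  the simulated burdens, with a synonymous background per gene, a site
  frequency spectrum spanning the four MAF bins, and stop-gain positions on
  simulated transcripts for NMD prediction.

Event ages are drawn by inverse-transform sampling of the Gompertz-PH
survival function; ``T = (1/Gamma) ln(1 - Gamma ln U / (h0 e^{x beta}))``.
At ``Gamma = 0`` the exponential limit ``T = -ln U / (h0 e^{x beta})`` is
used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import TranscriptModel
from .variants import ULTRA_RARE_MAF, VariantRecord, write_variants_tsv, write_vcf

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_burdens",
    "simulate_event_ages",
    "simulate_followup",
    "simulate_variant_table",
    "simulate_cohort",
    "empirical_log_hazard_slope",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the generative conditions assumed throughout: burden
    mean 6 with SD 2.6, Gompertz slope 0.09 /yr, burden log-hazard 0.046
    (lifespan) and 0.014 (healthspan) per mutation, uniform 40-70 assessment
    ages, 11 years of follow-up.  ``baseline_hazard`` (mortality, 4.5e-6 /yr)
    is calibrated so the expected share of deaths within follow-up is ~2.8%
    (averaging the burden and sex multipliers over the cohort);
    ``morbidity_baseline_hazard`` (1.1e-4 /yr) puts the median disease-free
    age near 70.
    """

    n_individuals: int = 20_000
    burden_mean: float = 6.0
    burden_dispersion: float = 2.6**2 / 6.0  # variance/mean; SD 2.6 at mean 6
    other_bin_means: tuple = (3.0, 5.0, 12.0)  # MAF bins 2-4; not data-driven
    gompertz_slope: float = 0.09
    baseline_hazard: float = 4.5e-6
    beta_burden: float = 0.046
    beta_sex: float = 0.47
    morbidity_baseline_hazard: float = 1.1e-4
    beta_burden_healthspan: float = 0.014
    beta_sex_healthspan: float = 0.16
    male_fraction: float = 0.54
    assessment_age_range: tuple = (40.0, 70.0)
    followup_years: float = 11.0
    parental_transmission: float = 0.5
    parental_baseline_hazard: float = 4e-5
    parental_age_gap: float = 28.0
    n_genes: int = 200
    n_variants: int = 2_000
    iptv_fraction: float = 0.11
    synonymous_fraction: float = 0.5
    n_principal_components: int = 4
    n_centers: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.burden_mean < 0 or any(m < 0 for m in self.other_bin_means):
            raise ValueError("burden means must be non-negative")
        if self.burden_dispersion < 1.0:
            raise ValueError(
                "burden_dispersion is a variance/mean ratio and must be >= 1 "
                "(1 gives a Poisson)"
            )
        if self.gompertz_slope < 0:
            raise ValueError("gompertz_slope must be non-negative (0 = exponential)")
        for name in ("baseline_hazard", "morbidity_baseline_hazard",
                     "parental_baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be positive")
        lo, hi = self.assessment_age_range
        if not 0 < lo < hi:
            raise ValueError("assessment_age_range must be an increasing positive pair")
        if not 0.0 <= self.iptv_fraction < 1.0:
            raise ValueError("iptv_fraction must lie in [0, 1)")
        if not 0.0 <= self.synonymous_fraction <= 1.0:
            raise ValueError("synonymous_fraction must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def bin_means(self) -> tuple:
        return (self.burden_mean, *self.other_bin_means)


@dataclass
class SyntheticCohort:
    """A generated cohort: phenotypes, burden table, variant table, transcripts."""

    config: SimulationConfig
    phenotypes: pd.DataFrame
    burden: pd.DataFrame
    variants: list
    transcripts: list
    iptv_truth: set = field(default_factory=set)

    def validate(self) -> None:
        """Check the structural invariants linking the three tables."""
        ids = set(self.phenotypes["id"])
        counts = {i: 0 for i in ids}
        for rec in self.variants:
            stray = set(rec.carriers) - ids
            if stray:
                raise AssertionError(f"carriers {sorted(stray)[:3]} not in cohort")
            if rec.is_ptv and rec.maf_bin == 1:
                for c in rec.carriers:
                    counts[c] += 1
        agg = pd.Series(counts).sort_index()
        table = self.burden.set_index("id")["bin1"].sort_index()
        if not (agg == table).all():
            raise AssertionError("ultra-rare PTV aggregation mismatch")


# ---------------------------------------------------------------------------
# burdens
# ---------------------------------------------------------------------------


def _draw_counts(rng, mean: float, dispersion: float, n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n, dtype=np.int64)
    if dispersion == 1.0:
        return rng.poisson(mean, size=n).astype(np.int64)
    r = mean / (dispersion - 1.0)  # NB size so that var = dispersion * mean
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(np.int64)


def simulate_burdens(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Per-individual PTV counts per MAF bin (columns bin1..bin4).

    Counts are negative binomial with the configured mean and variance/mean
    ratio (Poisson at ratio 1).  Bin 1 is the ultra-rare bin driving the
    survival effects; the other bins default to values that merely span the
    frequency spectrum.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_individuals
    data = {"id": _ids(n)}
    for b, mean in enumerate(config.bin_means, start=1):
        data[f"bin{b}"] = _draw_counts(rng, mean, config.burden_dispersion, n)
    return pd.DataFrame(data)


def _ids(n: int) -> list:
    width = len(str(n))
    return [f"I{str(i).zfill(width)}" for i in range(n)]


# ---------------------------------------------------------------------------
# event ages and follow-up
# ---------------------------------------------------------------------------


def _linear_predictor(config, burdens, sexes, endpoint: str) -> np.ndarray:
    n = np.asarray(burdens, dtype=float)
    s = np.asarray(sexes, dtype=float)
    if endpoint == "mortality":
        return config.beta_burden * n + config.beta_sex * s
    if endpoint == "morbidity":
        return config.beta_burden_healthspan * n + config.beta_sex_healthspan * s
    raise ValueError("endpoint must be 'mortality' or 'morbidity'")


def _baseline(config, endpoint: str) -> float:
    return (
        config.baseline_hazard if endpoint == "mortality"
        else config.morbidity_baseline_hazard
    )


def _sample_gompertz(rng, h0, gamma, lp, min_age=None) -> np.ndarray:
    """Inverse-transform sample of Gompertz-PH event ages.

    With ``min_age`` given, samples from the distribution conditional on
    surviving past ``min_age`` (exact left-truncation sampling, equivalent in
    law to rejection-resampling individuals who die before enrolment).
    """
    lp = np.asarray(lp, dtype=float)
    u = rng.uniform(size=lp.shape)
    rate = h0 * np.exp(lp)
    if gamma == 0.0:
        base = 0.0 if min_age is None else np.asarray(min_age, dtype=float)
        return base - np.log(u) / rate
    start = 1.0 if min_age is None else np.exp(gamma * np.asarray(min_age, dtype=float))
    return np.log(start - gamma * np.log(u) / rate) / gamma


def simulate_event_ages(
    config: SimulationConfig,
    burdens,
    sexes,
    rng=None,
    endpoint: str = "mortality",
    min_age=None,
) -> np.ndarray:
    """Event (death or first-disease) age per individual.

    The hazard is ``h(t) = h0 exp(Gamma t + beta n + beta_sex s)``; ages are
    drawn by inverting the survival function.  ``Gamma = 0`` falls back to
    the exponential limit.  ``min_age`` conditions on survival to that age.
    """
    rng = config.rng() if rng is None else rng
    lp = _linear_predictor(config, burdens, sexes, endpoint)
    ages = _sample_gompertz(rng, _baseline(config, endpoint),
                            config.gompertz_slope, lp, min_age=min_age)
    if not np.all(np.isfinite(ages) & (ages > 0)):
        raise RuntimeError("non-finite or non-positive simulated ages")
    return ages


def simulate_followup(
    config: SimulationConfig,
    event_ages,
    rng=None,
    linear_predictors=None,
) -> pd.DataFrame:
    """Enrolment and follow-up censoring.

    Assessment ages are uniform on the configured range.  Individuals whose
    simulated event precedes assessment are redrawn conditional on being
    alive at assessment (enrolment requires survival to assessment), using
    their own hazard via ``linear_predictors`` (zeros if omitted).  The
    observed time is ``min(event age - assessment age, followup)`` and the
    event flag is 1 iff the event falls inside the follow-up window.
    """
    event_ages = np.asarray(event_ages, dtype=float)
    n = event_ages.size
    if n == 0:
        raise ValueError("empty cohort")
    rng = config.rng() if rng is None else rng
    lp = (np.zeros(n) if linear_predictors is None
          else np.asarray(linear_predictors, dtype=float))
    lo, hi = config.assessment_age_range
    assess = rng.uniform(lo, hi, size=n)
    dead_before = event_ages <= assess
    if dead_before.any():
        event_ages = event_ages.copy()
        event_ages[dead_before] = _sample_gompertz(
            rng, config.baseline_hazard, config.gompertz_slope,
            lp[dead_before], min_age=assess[dead_before],
        )
    event_flag = (event_ages <= assess + config.followup_years).astype(int)
    observed = np.minimum(event_ages - assess, config.followup_years)
    return pd.DataFrame(
        {
            "age_assessment": assess,
            "time": observed,
            "event": event_flag,
            "event_age": event_ages,
        }
    )


# ---------------------------------------------------------------------------
# variant table and transcripts
# ---------------------------------------------------------------------------

_PTV_TERMS_SPECTRUM = [
    ("stop_gained", 0.40),
    ("frameshift_variant", 0.40),
    ("splice_donor_variant", 0.10),
    ("splice_acceptor_variant", 0.10),
]

_BIN_EDGES = (1e-6, 1e-4, 1e-3, 1e-2, 0.2)


def _loguniform(rng, lo, hi, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _simulate_transcripts(config, rng) -> list:
    transcripts = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(1, 9))
        lengths = tuple(int(x) for x in rng.integers(80, 300, size=n_exons))
        total = sum(lengths)
        cds_start = int(rng.integers(0, min(60, total - 10)))
        cds_end = total - int(rng.integers(0, min(60, total - cds_start - 9)))
        strand = "+" if rng.uniform() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(
                gene=f"G{g:04d}",
                transcript=f"T{g:04d}.1",
                strand=strand,
                exon_lengths=lengths,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return transcripts


def _site_position(rng, gene_idx) -> tuple:
    chrom = str(gene_idx % 22 + 1)
    pos = int(1_000_000 * (gene_idx // 22 + 1) + rng.integers(1, 900_000))
    return chrom, pos

_BASES = ("A", "C", "G", "T")


def _alleles(rng, frameshift=False):
    ref = _BASES[rng.integers(4)]
    if frameshift:
        return ref + _BASES[rng.integers(4)], ref  # 1-bp deletion
    alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
    return ref, alt


def simulate_variant_table(
    config: SimulationConfig,
    burdens: pd.DataFrame | None = None,
    rng=None,
    ensure_per_gene: bool = True,
) -> tuple[list, list, set]:
    """Variant records plus transcript models.

    Ultra-rare PTV sites are constructed so their carriages aggregate
    exactly to the bin-1 burden draws: each individual's ``bin1`` count is
    scattered over distinct singleton-scale sites.  Background sites (the
    synonymous neutral control and PTVs in MAF bins 2-4) get frequencies
    drawn log-uniformly within their bin and carriers sampled binomially
    (expected allele count = 2N x MAF).  A configurable fraction of genes is
    held out of ultra-rare PTV assignment, providing a ground-truth set of
    PTV-intolerant genes.  Stop-gain sites carry a spliced-transcript stop
    position for NMD prediction.
    """
    rng = config.rng() if rng is None else rng
    if ensure_per_gene and config.n_variants < config.n_genes:
        raise ValueError(
            "n_variants < n_genes while one variant per gene is requested"
        )
    if burdens is None:
        burdens = simulate_burdens(config, rng)
    ids = list(burdens["id"])
    n = len(ids)
    transcripts = _simulate_transcripts(config, rng)
    tx_by_gene = {t.gene: t for t in transcripts}
    genes = [t.gene for t in transcripts]
    n_iptv = int(round(config.iptv_fraction * config.n_genes))
    # hold the *last* genes out of ultra-rare PTV assignment
    tolerant = genes[: config.n_genes - n_iptv] if n_iptv else genes
    iptv_truth = set(genes) - set(tolerant)

    records: list[VariantRecord] = []

    # --- ultra-rare PTV sites matching the burden table exactly ------------
    counts = burdens["bin1"].to_numpy()
    total = int(counts.sum())
    if total:
        n_sites = max(int(counts.max()), int(round(total / 1.2)))
        site_carriers: dict[int, set] = {}
        for ind, c in zip(ids, counts):
            if c:
                for s in rng.choice(n_sites, size=int(c), replace=False):
                    site_carriers.setdefault(int(s), set()).add(ind)
        term_names = [t for t, _ in _PTV_TERMS_SPECTRUM]
        term_p = np.array([p for _, p in _PTV_TERMS_SPECTRUM])
        for s, carriers in sorted(site_carriers.items()):
            gene = tolerant[int(rng.integers(len(tolerant)))]
            term = term_names[int(rng.choice(len(term_names), p=term_p))]
            internal = len(carriers) / (2.0 * n)
            maf = internal if internal < ULTRA_RARE_MAF else float(
                _loguniform(rng, 1e-6, ULTRA_RARE_MAF)
            )
            tx = tx_by_gene[gene]
            stop = None
            if term == "stop_gained":
                stop = int(rng.integers(tx.cds_start, tx.cds_end))
            chrom, pos = _site_position(rng, genes.index(gene))
            ref, alt = _alleles(rng, frameshift=(term == "frameshift_variant"))
            records.append(
                VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    gene=gene, transcript=tx.transcript, canonical=True,
                    effect_terms=frozenset({term}), maf=maf,
                    missing_rate=0.0, carriers=frozenset(carriers),
                    hom_carriers=frozenset(), stop_position=stop,
                )
            )

    # --- background: synonymous everywhere, PTVs in the commoner bins ------
    for v in range(config.n_variants):
        gene = genes[v % config.n_genes] if ensure_per_gene else genes[
            int(rng.integers(len(genes)))
        ]
        tx = tx_by_gene[gene]
        if rng.uniform() < config.synonymous_fraction:
            term = "synonymous_variant"
            maf = float(_loguniform(rng, 1e-6, 0.2))
        else:
            term = _PTV_TERMS_SPECTRUM[
                int(rng.choice(4, p=[p for _, p in _PTV_TERMS_SPECTRUM]))
            ][0]
            b = int(rng.integers(1, 4))  # bins 2-4
            maf = float(_loguniform(rng, _BIN_EDGES[b], _BIN_EDGES[b + 1]))
        ac = int(rng.binomial(2 * n, maf))
        picks = rng.choice(n, size=min(ac, 2 * n), replace=True)
        uniq, cnt = np.unique(picks, return_counts=True)
        carriers = frozenset(ids[i] for i in uniq)
        homs = frozenset(ids[i] for i, c in zip(uniq, cnt) if c >= 2)
        stop = None
        if term == "stop_gained":
            stop = int(rng.integers(tx.cds_start, tx.cds_end))
        chrom, pos = _site_position(rng, genes.index(gene))
        ref, alt = _alleles(rng, frameshift=(term == "frameshift_variant"))
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref=ref, alt=alt,
                gene=gene, transcript=tx.transcript, canonical=True,
                effect_terms=frozenset({term}), maf=maf,
                missing_rate=0.0, carriers=carriers, hom_carriers=homs,
                stop_position=stop,
            )
        )
    return records, transcripts, iptv_truth


# ---------------------------------------------------------------------------
# whole cohort
# ---------------------------------------------------------------------------


def _simulate_parents(config, rng, child_burden: np.ndarray, assess: np.ndarray):
    """Parental ages at death via a shared-burden Gompertz stand-in.

    Each parent inherits a binomially-thinned share of the child's ultra-rare
    burden (Mendelian transmission in reverse) topped up with an independent
    draw, then dies by the same Gompertz law with a population-scale baseline;
    the parent is censored at the child's assessment age plus the generation
    gap if still alive then.
    """
    out = {}
    for parent, sex in (("mother", 0.0), ("father", 1.0)):
        w = config.parental_transmission
        shared = rng.binomial(child_burden, w)
        own = _draw_counts(rng, config.burden_mean * (1 - w),
                           config.burden_dispersion, child_burden.size)
        burden = shared + own
        lp = config.beta_burden * burden + config.beta_sex * sex
        u = rng.uniform(size=burden.size)
        gam = config.gompertz_slope
        rate = config.parental_baseline_hazard * np.exp(lp)
        if gam == 0:
            death = -np.log(u) / rate
        else:
            death = np.log(1.0 - gam * np.log(u) / rate) / gam
        current = assess + config.parental_age_gap
        dead = (death <= current).astype(int)
        out[f"{parent}_age"] = np.minimum(death, current)
        out[f"{parent}_event"] = dead
        out[f"{parent}_burden"] = burden
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort: phenotypes, burden table, variants, transcripts.

    Deterministic under ``config.seed``; the ultra-rare PTV carriages in the
    variant table aggregate exactly to the burden table's bin-1 column.
    """
    rng = config.rng()
    n = config.n_individuals
    ids = _ids(n)
    burdens = simulate_burdens(config, rng)
    ultra = burdens["bin1"].to_numpy()
    sexes = (rng.uniform(size=n) < config.male_fraction).astype(int)

    death_lp = _linear_predictor(config, ultra, sexes, "mortality")
    death_ages = simulate_event_ages(config, ultra, sexes, rng, "mortality")
    fup = simulate_followup(config, death_ages, rng, linear_predictors=death_lp)

    disease_ages = simulate_event_ages(config, ultra, sexes, rng, "morbidity")
    horizon = fup["age_assessment"].to_numpy() + config.followup_years
    hs_event = (disease_ages <= horizon).astype(int)
    hs_age = np.minimum(disease_ages, horizon)

    parents = _simulate_parents(config, rng, ultra, fup["age_assessment"].to_numpy())

    pheno = pd.DataFrame({
        "id": ids,
        "sex": sexes,
        "age_assessment": fup["age_assessment"],
        "time": fup["time"],
        "event": fup["event"],
        "event_age": fup["event_age"],
        "healthspan_age": hs_age,
        "healthspan_event": hs_event,
        "mother_age": parents["mother_age"],
        "mother_event": parents["mother_event"],
        "father_age": parents["father_age"],
        "father_event": parents["father_event"],
    })
    for k in range(config.n_principal_components):
        pheno[f"pc{k + 1}"] = rng.standard_normal(n)
    pheno["center"] = rng.integers(config.n_centers, size=n)

    variants, transcripts, iptv_truth = simulate_variant_table(config, burdens, rng)
    return SyntheticCohort(
        config=config,
        phenotypes=pheno,
        burden=burdens,
        variants=variants,
        transcripts=transcripts,
        iptv_truth=iptv_truth,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def empirical_log_hazard_slope(
    event_ages,
    bin_width: float = 2.0,
    min_events: int = 25,
    quantile_range: tuple = (0.02, 0.98),
) -> float:
    """Gompertz slope recovered from raw event ages.

    The hazard is estimated per age bin as events / person-years at risk and
    the log-hazard is regressed on bin midpoints, weighting by event counts.
    On uncensored Gompertz samples this recovers the generating slope.
    """
    t = np.sort(np.asarray(event_ages, dtype=float))
    lo, hi = np.quantile(t, quantile_range)
    edges = np.arange(lo, hi + bin_width, bin_width)
    mids, loghaz, weights = [], [], []
    for a, b in zip(edges[:-1], edges[1:]):
        d = int(np.sum((t >= a) & (t < b)))
        exposure = np.sum(np.clip(np.minimum(t, b) - a, 0.0, None))
        if d >= min_events and exposure > 0:
            mids.append((a + b) / 2.0)
            loghaz.append(math.log(d / exposure))
            weights.append(d)
    if len(mids) < 3:
        raise ValueError("too few populated age bins to estimate a slope")
    w = np.asarray(weights, dtype=float)
    x = np.asarray(mids)
    y = np.asarray(loghaz)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    return float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _transcript_to_bed12(tx: TranscriptModel, gene_idx: int) -> str:
    intron = 500
    chrom = str(gene_idx % 22 + 1)
    start = 1_000_000 * (gene_idx // 22 + 1)
    sizes = list(tx.exon_lengths)
    starts = []
    off = 0
    for s in sizes:
        starts.append(off)
        off += s + intron
    end = start + starts[-1] + sizes[-1]

    def spliced_to_genomic(sp: int) -> int:
        acc = 0
        for st, sz in zip(starts, sizes):
            if sp < acc + sz:
                return start + st + (sp - acc)
            acc += sz
        return end

    thick_start = spliced_to_genomic(tx.cds_start)
    thick_end = spliced_to_genomic(tx.cds_end - 1) + 1
    return "\t".join(
        str(x)
        for x in (
            chrom, start, end, tx.transcript, 0, tx.strand,
            thick_start, thick_end, "0,0,0", len(sizes),
            ",".join(map(str, sizes)) + ",",
            ",".join(map(str, starts)) + ",",
        )
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write phenotype/burden TSVs, the variant TSV and VCF, and BED12 transcripts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "burden": outdir / "burden.tsv",
        "variants_tsv": outdir / "variants.tsv",
        "variants_vcf": outdir / "variants.vcf",
        "transcripts": outdir / "transcripts.bed",
    }
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    cohort.burden.to_csv(paths["burden"], sep="\t", index=False)
    write_variants_tsv(cohort.variants, paths["variants_tsv"])
    write_vcf(cohort.variants, list(cohort.phenotypes["id"]), paths["variants_vcf"])
    genes = [t.gene for t in cohort.transcripts]
    with open(paths["transcripts"], "w") as fh:
        for tx in cohort.transcripts:
            fh.write(_transcript_to_bed12(tx, genes.index(tx.gene)) + "\n")
    return paths
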