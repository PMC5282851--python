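"""Seeded synthetic cohort generator.

Emulates the statistical structure of an FFPE amplicon-panel cohort so the
whole post-processing pipeline can be exercised, with ground truth, and
with no external data:

* per-sample artifact burden with mean ``lambda(c) = exp(a - b*log c)``,
  decreasing in the pre-normalization library concentration ``c`` (a proxy
  for DNA integrity), drawn negative-binomially (FFPE cohorts are heavily
  overdispersed sample-to-sample);
* a C:G>T:A-dominated substitution spectrum concentrated at 0-10% allele
  frequency (cytosine-deamination artifacts);
* an additional high-prevalence (9-20% AF) artifact regime that appears
  only in degraded samples, i.e. those below a concentration trigger;
* planted somatic and germline variants, recurrent artifact hotspots,
  read-backed compound (phased) variant pairs, and gene amplifications in
  the amplicon coverage matrix.

All randomness flows from a single seeded :class:`numpy.random.Generator`,
so identical config + seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Amplicon, PanelDefinition

#: The 12 raw single-nucleotide substitution classes.
SUBSTITUTIONS = [
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
]

# Cohort-level defaults. lambda(c) = exp(a - b*log c) with (a, b) chosen so
# that the default 26-sample concentration ladder yields ~3300 calls in
# total with a strong negative rank correlation against concentration;
# spectrum places 0.44 mass on C>T/G>A jointly (deaminated cytosines on
# either strand), the remainder uniform over the other 10 classes.
DEFAULT_CT_WEIGHT = 0.44
DEFAULT_ARTIFACT_SLOPE = 1.0
DEFAULT_ARTIFACT_DISPERSION = 3.5
DEFAULT_HIGH_AF_TRIGGER = 1.5  # ng/ul
DEFAULT_TOTAL_ARTIFACTS = 3180.0  # expected low-AF artifact calls, cohort-wide


def default_spectrum_weights(ct_weight: float = DEFAULT_CT_WEIGHT) -> dict[str, float]:
    """C>T and G>A share ``ct_weight`` equally; the rest is uniform."""
    other = (1.0 - ct_weight) / 10.0
    w = {s: other for s in SUBSTITUTIONS}
    w["C>T"] = ct_weight / 2.0
    w["G>A"] = ct_weight / 2.0
    return w


def default_concentrations(n_samples: int = 26) -> list[float]:
    """Paper-like concentration ladder: four degraded libraries at 1.0-1.3
    ng/ul, the rest log-spaced from 1.9 upward."""
    if n_samples < 5:
        return list(np.geomspace(1.0, 12.0, n_samples))
    rest = np.geomspace(1.9, 12.0, n_samples - 4)
    return [1.0, 1.0, 1.3, 1.3] + [round(float(c), 2) for c in rest]


@dataclass(frozen=True)
class TrueVariant:
    """A planted non-artifact variant with known origin."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    samples: tuple[str, ...]
    origin: str  # "somatic" | "germline"
    pop_freq: float = 0.0
    cosmic: bool = False
    dbsnp: bool = False


@dataclass(frozen=True)
class RecurrentArtifact:
    """A planted recurrent artifact hotspot (blacklist material)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_fraction: float = 0.5
    mean_af: float = 0.03


@dataclass(frozen=True)
class CompoundEvent:
    """Two variants co-occurring on reads in one sample."""

    sample: str
    chrom: str
    pos_a: int
    ref_a: str
    alt_a: str
    pos_b: int
    ref_b: str
    alt_b: str
    shared_fraction: float = 1.0
    n_mut_reads: int = 200
    depth: int = 2000


@dataclass(frozen=True)
class CNVEvent:
    sample: str
    gene: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError(f"CNV fold must be positive, got {self.fold}")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_samples: int = 26
    concentrations: Sequence[float] | None = None
    artifact_slope: float = DEFAULT_ARTIFACT_SLOPE  # b in exp(a - b*log c)
    artifact_intercept: float | None = None  # a; None -> set from total_artifacts
    total_artifacts: float = DEFAULT_TOTAL_ARTIFACTS
    artifact_dispersion: float = DEFAULT_ARTIFACT_DISPERSION  # NB size
    spectrum_weights: dict[str, float] = field(default_factory=default_spectrum_weights)
    low_af_beta: tuple[float, float] = (1.2, 30.0)  # truncated to (0, 0.10]
    low_af_max: float = 0.10
    high_af_trigger: float = DEFAULT_HIGH_AF_TRIGGER  # ng/ul
    high_af_beta: tuple[float, float] = (2.0, 2.0)  # rescaled onto af range
    high_af_range: tuple[float, float] = (0.09, 0.20)
    high_af_mean_count: float = 30.0
    high_af_dispersion: float = 4.0
    true_variants: list[TrueVariant] | None = None  # None -> default set
    recurrent_artifacts: list[RecurrentArtifact] | None = None
    compound_events: list[CompoundEvent] | None = None
    cnv_events: list[CNVEvent] | None = None
    coverage_mean_depth: float = 2000.0
    coverage_bias_sigma: float = 0.1  # per-amplicon lognormal bias
    coverage_sample_sigma: float = 0.1  # per-sample library-size factor
    coverage_noise_sigma: float = 0.1  # per-cell lognormal noise
    dropout_prob: float = 0.005
    variant_mean_depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples (correlation stage)")
        if self.concentrations is None:
            self.concentrations = default_concentrations(self.n_samples)
        self.concentrations = [float(c) for c in self.concentrations]
        if len(self.concentrations) != self.n_samples:
            raise ValueError("concentrations length != n_samples")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        total_w = sum(self.spectrum_weights.values())
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"spectrum weights sum to {total_w}, not 1")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    def intercept(self) -> float:
        """``a`` such that the expected cohort-wide low-AF artifact count
        equals ``total_artifacts`` (unless set explicitly)."""
        if self.artifact_intercept is not None:
            return self.artifact_intercept
        c = np.asarray(self.concentrations, dtype=float)
        return float(np.log(self.total_artifacts / np.sum(c ** -self.artifact_slope)))

    def artifact_mean(self, conc: float | np.ndarray) -> np.ndarray:
        """Expected artifact count lambda(c) = exp(a - b*log c)."""
        return np.exp(self.intercept() - self.artifact_slope * np.log(conc))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key, klass in (
            ("true_variants", TrueVariant),
            ("recurrent_artifacts", RecurrentArtifact),
            ("compound_events", CompoundEvent),
            ("cnv_events", CNVEvent),
        ):
            if raw.get(key) is not None:
                raw[key] = [
                    klass(**{**d, "samples": tuple(d["samples"])})
                    if klass is TrueVariant
                    else klass(**d)
                    for d in raw[key]
                ]
        for key in ("low_af_beta", "high_af_beta", "high_af_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulatedCohort:
    """A generated cohort with ground truth attached."""

    variants: pd.DataFrame  # sample_id chrom pos ref alt gene af depth fwd_alt rev_alt truth
    sample_sheet: pd.DataFrame  # sample_id pre_norm_conc_ng_ul total_reads
    coverage: pd.DataFrame  # samples x amplicon names
    read_evidence: pd.DataFrame  # variant_a variant_b n_both n_a_only n_b_only n_neither
    db: pd.DataFrame  # chrom pos ref alt pop_freq dbsnp cosmic
    panel: PanelDefinition
    config: SimulationConfig


# ---------------------------------------------------------------------------
# demo panel


def demo_panel() -> PanelDefinition:
    """A 212-amplicon, 48-gene synthetic panel on a mini-genome.

    Gene/chromosome assignments come from the bundled panel table; EGFR
    gets 8 amplicons and MET 5 (the amplification scenarios need them),
    the other genes 4 or 5 so the total is 212. Coordinates are synthetic:
    genes sit at 1 Mb offsets, amplicons tile at 200 bp with 175 bp
    products and 24 bp primers.
    """
    table = pd.read_csv(
        importlib.resources.files("panelpost.data") / "gene_panel.tsv", sep="\t"
    )
    genes = list(table["gene"])
    chrom_of = dict(zip(table["gene"], table["chrom"]))
    counts = {"EGFR": 8, "MET": 5}
    others = sorted(g for g in genes if g not in counts)
    for i, g in enumerate(others):
        counts[g] = 5 if i < 15 else 4
    assert sum(counts.values()) == 212

    per_chrom_index: dict[str, int] = {}
    amplicons = []
    for gene in genes:
        chrom = chrom_of[gene]
        gi = per_chrom_index.setdefault(chrom, 0)
        per_chrom_index[chrom] += 1
        base = 1_000_000 * (gi + 1)
        for k in range(counts[gene]):
            start = base + 200 * k + 1
            amplicons.append(
                Amplicon(
                    name=f"{gene}_amp{k + 1}",
                    chrom=chrom,
                    start=start,
                    end=start + 174,
                    fwd_primer_len=24,
                    rev_primer_len=24,
                    gene=gene,
                    strand="+",
                )
            )
    return PanelDefinition(amplicons)


def _insert_mid(panel: PanelDefinition, gene: str, amp_index: int = 0, offset: int = 0) -> tuple[str, int]:
    a = panel.amplicons_of_gene(gene)[amp_index]
    lo, hi = a.insert_start, a.insert_end
    return a.chrom, (lo + hi) // 2 + offset


def default_true_variants(panel: PanelDefinition) -> list[TrueVariant]:
    """A Table-1-like planted set: somatic singletons across target genes
    (one low-prevalence hotspot at 4% AF) plus shared germline variants."""
    mk = _insert_mid
    somatic = [
        ("TP53", 0, "C", "T", 0.44, ("S05",)),
        ("TP53", 1, "G", "A", 0.31, ("S09",)),
        ("TP53", 2, "A", "G", 0.17, ("S12",)),
        ("KRAS", 0, "G", "T", 0.31, ("S07",)),
        ("KRAS", 1, "G", "A", 0.30, ("S15",)),
        ("HRAS", 0, "G", "T", 0.82, ("S20",)),
        ("PIK3CA", 0, "G", "A", 0.15, ("S21",)),
        ("CTNNB1", 0, "C", "T", 0.11, ("S11",)),
        ("AKT1", 0, "G", "A", 0.04, ("S03",)),  # hotspot below 10% AF
        ("MLH1", 0, "G", "A", 0.15, ("S12",)),
        ("VHL", 0, "A", "G", 0.18, ("S18",)),
        ("ATM", 1, "A", "T", 0.10, ("S16",)),
    ]
    germline = [
        ("KDR", 0, "A", "T", 0.25, 0.52),
        ("KIT", 0, "T", "A", 0.11, 0.48),
        ("TP53", 3, "G", "C", 0.62, 0.51),
        ("HNF1A", 0, "C", "G", 0.09, 0.49),
    ]
    out: list[TrueVariant] = []
    for gene, idx, ref, alt, af, sam in somatic:
        chrom, pos = mk(panel, gene, idx)
        out.append(
            TrueVariant(gene, chrom, pos, ref, alt, af, tuple(sam), "somatic",
                        pop_freq=0.0, cosmic=True, dbsnp=False)
        )
    n = 26
    for j, (gene, idx, ref, alt, pop, af) in enumerate(germline):
        chrom, pos = mk(panel, gene, idx, offset=3)
        carriers = tuple(f"S{i + 1:02d}" for i in range(n) if (i + j) % 3 != 0)
        out.append(
            TrueVariant(gene, chrom, pos, ref, alt, af, carriers, "germline",
                        pop_freq=pop, cosmic=False, dbsnp=True)
        )
    return out


def default_recurrent_artifacts(panel: PanelDefinition) -> list[RecurrentArtifact]:
    sites = [("APC", 0), ("RET", 0), ("FLT3", 0), ("GNAS", 0), ("SMAD4", 0)]
    out = []
    for gene, idx in sites:
        chrom, pos = _insert_mid(panel, gene, idx, offset=-5)
        out.append(RecurrentArtifact(chrom, pos, "C", "T", 0.55, 0.03))
    return out


def default_compound_events(panel: PanelDefinition) -> list[CompoundEvent]:
    """One fully phased pair: a frameshift deletion immediately upstream of
    a missense SNV on the same amplicon (the expressed-protein trap).
    Alleles are consistent with the synthetic mini-genome reference."""
    from .panel import synthetic_reference

    a = panel.amplicons_of_gene("EGFR")[0]
    pos_fs = a.insert_start + 30
    pos_mis = pos_fs + 4
    window = synthetic_reference(a.chrom, pos_fs, pos_mis)
    ref_fs = window[0:2]
    ref_mis = window[-1]
    alt_mis = "T" if ref_mis != "T" else "A"
    return [
        CompoundEvent(
            sample="S06", chrom=a.chrom,
            pos_a=pos_fs, ref_a=ref_fs, alt_a=ref_fs[0],
            pos_b=pos_mis, ref_b=ref_mis, alt_b=alt_mis,
            shared_fraction=1.0, n_mut_reads=200, depth=2000,
        )
    ]


def default_cnv_events() -> list[CNVEvent]:
    """The amplification scenarios: two EGFR amplifications (5.7x, 17.6x)
    and one mild MET gain (1.65x)."""
    return [
        CNVEvent("S04", "EGFR", 5.7),
        CNVEvent("S08", "EGFR", 17.6),
        CNVEvent("S10", "MET", 1.65),
    ]


# ---------------------------------------------------------------------------
# draws


def _truncated_beta_rvs(
    rng: np.random.Generator, a: float, b: float, upper: float, size: int
) -> np.ndarray:
    """Beta(a, b) truncated to (0, upper] via inverse-CDF sampling."""
    cap = stats.beta.cdf(upper, a, b)
    u = rng.uniform(0.0, cap, size=size)
    return stats.beta.ppf(u, a, b)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _read_support(
    rng: np.random.Generator, af: np.ndarray, mean_depth: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Depth, realized AF and per-strand alt counts for drawn AFs."""
    n = len(af)
    depth = np.maximum(rng.poisson(mean_depth, size=n), 50)
    alt = np.maximum(rng.binomial(depth, af), 1)
    fwd = rng.binomial(alt, 0.5)
    rev = alt - fwd
    return depth, alt / depth, fwd, rev


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(
    config: SimulationConfig, panel: PanelDefinition | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort (variants, evidence, coverage,
    sample sheet, offline database) with truth labels."""
    panel = panel or demo_panel()
    rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    conc = np.asarray(config.concentrations, dtype=float)

    classes = np.array(list(config.spectrum_weights))
    weights = np.array([config.spectrum_weights[c] for c in classes])
    inserts = [(a.chrom, a.insert_start, a.insert_end, a.gene) for a in panel]

    rows: list[dict] = []

    # low-AF deamination artifacts, burden ~ NB(lambda(conc))
    lam = config.artifact_mean(conc)
    counts = _nb_counts(rng, lam, config.artifact_dispersion)
    for sid, n_art in zip(samples, counts):
        if n_art == 0:
            continue
        cls = rng.choice(classes, p=weights, size=n_art)
        amp_idx = rng.integers(0, len(inserts), size=n_art)
        af = _truncated_beta_rvs(rng, *config.low_af_beta, config.low_af_max, n_art)
        depth, af_obs, fwd, rev = _read_support(rng, af, config.variant_mean_depth)
        for j in range(n_art):
            chrom, lo, hi, gene = inserts[amp_idx[j]]
            ref, alt = cls[j].split(">")
            rows.append(
                dict(sample_id=sid, chrom=chrom, pos=int(rng.integers(lo, hi + 1)),
                     ref=ref, alt=alt, gene=gene, af=float(af_obs[j]),
                     depth=int(depth[j]), fwd_alt=int(fwd[j]), rev_alt=int(rev[j]),
                     truth="artifact")
            )

    # high-AF artifact regime, only below the concentration trigger
    lo_af, hi_af = config.high_af_range
    for sid, c in zip(samples, conc):
        if c >= config.high_af_trigger:
            continue
        n_hi = int(_nb_counts(rng, np.array(config.high_af_mean_count),
                              config.high_af_dispersion))
        if n_hi == 0:
            continue
        cls = rng.choice(classes, p=weights, size=n_hi)
        amp_idx = rng.integers(0, len(inserts), size=n_hi)
        af = lo_af + (hi_af - lo_af) * rng.beta(*config.high_af_beta, size=n_hi)
        depth, af_obs, fwd, rev = _read_support(rng, af, config.variant_mean_depth)
        for j in range(n_hi):
            chrom, lo, hi, gene = inserts[amp_idx[j]]
            ref, alt = cls[j].split(">")
            rows.append(
                dict(sample_id=sid, chrom=chrom, pos=int(rng.integers(lo, hi + 1)),
                     ref=ref, alt=alt, gene=gene, af=float(af_obs[j]),
                     depth=int(depth[j]), fwd_alt=int(fwd[j]), rev_alt=int(rev[j]),
                     truth="artifact")
            )

    # recurrent artifact hotspots
    rec = config.recurrent_artifacts
    if rec is None:
        rec = default_recurrent_artifacts(panel)
    for site in rec:
        n_carriers = max(2, round(site.sample_fraction * len(samples)))
        carriers = rng.choice(samples, size=n_carriers, replace=False)
        af = np.clip(rng.normal(site.mean_af, site.mean_af / 4, size=n_carriers),
                     0.005, config.low_af_max)
        depth, af_obs, fwd, rev = _read_support(rng, af, config.variant_mean_depth)
        gene = next(
            (a.gene for a in panel if a.contains(site.chrom, site.pos)), "off-target"
        )
        for j, sid in enumerate(carriers):
            rows.append(
                dict(sample_id=str(sid), chrom=site.chrom, pos=site.pos,
                     ref=site.ref, alt=site.alt, gene=gene, af=float(af_obs[j]),
                     depth=int(depth[j]), fwd_alt=int(fwd[j]), rev_alt=int(rev[j]),
                     truth="artifact")
            )

    # planted true variants
    tv = config.true_variants
    if tv is None:
        tv = default_true_variants(panel)
    db_rows = []
    for v in tv:
        db_rows.append(dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                            pop_freq=v.pop_freq, dbsnp=int(v.dbsnp),
                            cosmic=int(v.cosmic)))
        present = [s for s in v.samples if s in samples]
        if not present:
            continue
        af = np.full(len(present), v.af)
        depth, af_obs, fwd, rev = _read_support(rng, af, config.variant_mean_depth)
        for j, sid in enumerate(present):
            rows.append(
                dict(sample_id=sid, chrom=v.chrom, pos=v.pos, ref=v.ref,
                     alt=v.alt, gene=v.gene, af=float(af_obs[j]),
                     depth=int(depth[j]), fwd_alt=int(fwd[j]), rev_alt=int(rev[j]),
                     truth=v.origin)
            )

    variants = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "gene", "af",
                 "depth", "fwd_alt", "rev_alt", "truth"],
    )
    variants = variants.sort_values(
        ["sample_id", "chrom", "pos", "ref", "alt"], kind="mergesort"
    ).reset_index(drop=True)

    # sample sheet: degraded libraries also sequence less efficiently
    total_reads = (500_000 * rng.lognormal(0.0, 0.15, size=len(samples))).astype(int)
    total_reads = np.where(conc < config.high_af_trigger,
                           (total_reads * 0.6).astype(int), total_reads)
    sample_sheet = pd.DataFrame(
        {"sample_id": samples, "pre_norm_conc_ng_ul": conc,
         "total_reads": total_reads}
    )

    coverage = simulate_coverage(config, panel, rng=rng)

    cohort = SimulatedCohort(
        variants=variants,
        sample_sheet=sample_sheet,
        coverage=coverage,
        read_evidence=pd.DataFrame(
            columns=["sample_id", "variant_a", "variant_b", "n_both",
                     "n_a_only", "n_b_only", "n_neither"]
        ),
        db=pd.DataFrame(
            db_rows, columns=["chrom", "pos", "ref", "alt", "pop_freq",
                              "dbsnp", "cosmic"]
        ),
        panel=panel,
        config=config,
    )

    events = config.compound_events
    if events is None:
        events = default_compound_events(panel)
    for ev in events:
        cohort = inject_compound_variant(cohort, ev, rng=rng)
    return cohort


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


def inject_compound_variant(
    cohort: SimulatedCohort,
    event: CompoundEvent,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Add a phased variant pair plus its per-read co-occurrence evidence.

    ``n_both`` is binomial(``n_mut_reads``, ``shared_fraction``); the
    remaining mutant reads split evenly between the two single-variant
    strata. ``shared_fraction = 1`` is the fully phased case.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    panel = cohort.panel
    hosts = [
        a for a in panel
        if a.in_insert(event.chrom, event.pos_a) and a.in_insert(event.chrom, event.pos_b)
    ]
    if not hosts:
        raise ValueError(
            "compound variants must fall within a single amplicon's insert "
            f"({event.chrom}:{event.pos_a} / {event.chrom}:{event.pos_b})"
        )
    if not 0.0 <= event.shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")

    n_both = int(rng.binomial(event.n_mut_reads, event.shared_fraction))
    remainder = event.n_mut_reads - n_both
    n_a_only = int(rng.binomial(remainder, 0.5))
    n_b_only = remainder - n_a_only
    n_neither = max(event.depth - event.n_mut_reads, 0)

    key_a = variant_key(event.chrom, event.pos_a, event.ref_a, event.alt_a)
    key_b = variant_key(event.chrom, event.pos_b, event.ref_b, event.alt_b)
    evidence = pd.concat(
        [
            cohort.read_evidence,
            pd.DataFrame(
                [dict(sample_id=event.sample, variant_a=key_a, variant_b=key_b,
                      n_both=n_both, n_a_only=n_a_only, n_b_only=n_b_only,
                      n_neither=n_neither)]
            ),
        ],
        ignore_index=True,
    )

    gene = hosts[0].gene
    new_rows = []
    for pos, ref, alt, n_carry in (
        (event.pos_a, event.ref_a, event.alt_a, n_both + n_a_only),
        (event.pos_b, event.ref_b, event.alt_b, n_both + n_b_only),
    ):
        mask = (
            (cohort.variants["sample_id"] == event.sample)
            & (cohort.variants["chrom"] == event.chrom)
            & (cohort.variants["pos"] == pos)
            & (cohort.variants["ref"] == ref)
            & (cohort.variants["alt"] == alt)
        )
        if not mask.any():
            fwd = int(rng.binomial(n_carry, 0.5))
            new_rows.append(
                dict(sample_id=event.sample, chrom=event.chrom, pos=pos,
                     ref=ref, alt=alt, gene=gene,
                     af=n_carry / event.depth, depth=event.depth,
                     fwd_alt=fwd, rev_alt=n_carry - fwd, truth="somatic")
            )
    variants = cohort.variants
    if new_rows:
        variants = pd.concat([variants, pd.DataFrame(new_rows)], ignore_index=True)
        variants = variants.sort_values(
            ["sample_id", "chrom", "pos", "ref", "alt"], kind="mergesort"
        ).reset_index(drop=True)
    return replace(cohort, variants=variants, read_evidence=evidence)


def simulate_coverage(
    config: SimulationConfig,
    panel: PanelDefinition,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Samples x amplicons integer depth matrix.

    depth = round(mean_depth * sample_factor * amplicon_bias * fold * noise),
    with lognormal factors and configured dropout zeroing single cells.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    amp_names = [a.name for a in panel]
    n_s, n_a = len(samples), len(amp_names)

    sample_factor = rng.lognormal(0.0, config.coverage_sample_sigma, size=(n_s, 1))
    amp_bias = rng.lognormal(0.0, config.coverage_bias_sigma, size=(1, n_a))
    noise = rng.lognormal(0.0, config.coverage_noise_sigma, size=(n_s, n_a))

    fold = np.ones((n_s, n_a))
    events = config.cnv_events
    if events is None:
        events = default_cnv_events()
    amp_gene = np.array([a.gene for a in panel])
    for ev in events:
        if ev.gene not in panel.genes:
            raise ValueError(f"CNV event gene {ev.gene!r} not in panel")
        if ev.sample in samples:
            fold[samples.index(ev.sample), amp_gene == ev.gene] = ev.fold

    depth = np.rint(config.coverage_mean_depth * sample_factor * amp_bias
                    * fold * noise).astype(int)
    if config.dropout_prob > 0:
        depth[rng.random((n_s, n_a)) < config.dropout_prob] = 0
    return pd.DataFrame(depth, index=samples, columns=amp_names)
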