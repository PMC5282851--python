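"""Artifact-spectrum QC for FFPE amplicon cohorts.

Formalin fixation deaminates cytosine, so FFPE libraries carry excess
C:G>T:A calls concentrated below 10% allele frequency; heavily degraded
libraries (recognizable by low pre-normalization concentration) add a
second artifact regime at 9-20% AF that a fixed AF threshold cannot
remove. This module characterizes each sample's mutation spectrum by AF
bin, tests per-class enrichment between bins, correlates artifact burden
with library concentration, flags degraded samples, and converts the
fitted concentration->burden relationship into per-sample reporting
cutoffs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import SUBSTITUTIONS

#: Map of raw substitution class -> strand-symmetric (pyrimidine-anchored) class.
COLLAPSED = {
    "C>T": "C:G>T:A", "G>A": "C:G>T:A",
    "C>A": "C:G>A:T", "G>T": "C:G>A:T",
    "C>G": "C:G>G:C", "G>C": "C:G>G:C",
    "T>A": "T:A>A:T", "A>T": "T:A>A:T",
    "T>C": "T:A>C:G", "A>G": "T:A>C:G",
    "T>G": "T:A>G:C", "A>C": "T:A>G:C",
}

SPECTRUM_CLASSES = SUBSTITUTIONS + ["indel", "mnv"]

#: Clinical reporting floors: variants tied to therapy response vs resistance.
CLINICAL_FLOORS = {"response": 0.05, "resistance": 0.025}

DEFAULT_BIN_EDGES = (0.0, 0.10, 1.0)
FINE_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.025), 3))


@dataclass
class VariantCall:
    """One called variant with read-level support."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    depth: int
    fwd_alt: int = 0
    rev_alt: int = 0
    gene: str = ""
    filter_flags: set = field(default_factory=set)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"AF {self.af} outside [0, 1]")
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.fwd_alt + self.rev_alt > self.depth:
            raise ValueError("strand alt counts exceed depth")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass
class SampleMeta:
    """Per-sample library metadata and derived QC state."""

    sample_id: str
    pre_norm_conc: float  # ng/ul before pooling normalization
    total_reads: int = 0
    degraded: bool = False
    af_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.pre_norm_conc <= 0:
            raise ValueError("pre-normalization concentration must be positive")


def classify_substitution(ref: str, alt: str) -> str:
    """One of the 12 raw SNV classes, or ``indel``/``mnv``."""
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError("ref == alt is not a variant")
    if len(ref) == 1 == len(alt):
        return f"{ref.upper()}>{alt.upper()}"
    if len(ref) == len(alt):
        return "mnv"
    return "indel"


def collapse_class(raw: str) -> str:
    """Strand-symmetric view: C>T and G>A both become C:G>T:A, etc."""
    return COLLAPSED.get(raw, raw)


def _as_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        return variants
    return pd.DataFrame(
        [dict(sample_id=v.sample_id, chrom=v.chrom, pos=v.pos, ref=v.ref,
              alt=v.alt, af=v.af, depth=v.depth) for v in variants],
        columns=["sample_id", "chrom", "pos", "ref", "alt", "af", "depth"],
    )


@dataclass
class SpectrumTable:
    """Counts cross-classified by substitution class and AF bin."""

    bin_edges: tuple[float, ...]
    counts: pd.DataFrame  # rows SPECTRUM_CLASSES, columns bin labels
    pooled: bool = True

    @property
    def bin_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def class_proportion(self, raw_classes: Sequence[str], bin_label: str) -> float:
        col = self.counts[bin_label]
        tot = col.sum()
        return float(col.loc[list(raw_classes)].sum() / tot) if tot else float("nan")


def bin_labels(edges: Sequence[float]) -> list[str]:
    return [f"({lo:g},{hi:g}]" for lo, hi in zip(edges[:-1], edges[1:])]


def spectrum_by_af(
    variants, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> SpectrumTable:
    """Count variants into (low, high] AF bins per substitution class.

    Every variant lands in exactly one half-open bin; totals are conserved
    for any edge set. AF outside (0, 1] is rejected.
    """
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    df = _as_frame(variants)
    labels = bin_labels(edges)
    counts = pd.DataFrame(0, index=SPECTRUM_CLASSES, columns=labels, dtype=int)
    if len(df):
        af = df["af"].to_numpy(dtype=float)
        if np.any((af <= edges[0]) | (af > edges[-1])):
            bad = af[(af <= edges[0]) | (af > edges[-1])]
            raise ValueError(f"AF outside ({edges[0]:g}, {edges[-1]:g}]: {bad[:5]}")
        idx = np.searchsorted(edges, af, side="left") - 1
        cls = [classify_substitution(r, a) for r, a in zip(df["ref"], df["alt"])]
        for c, i in zip(cls, idx):
            counts.loc[c, labels[i]] += 1
    return SpectrumTable(bin_edges=edges, counts=counts)


def concentration_correlation(
    concentrations: Sequence[float], counts: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation of per-sample variant counts against
    pre-normalization concentration.

    Rho uses average ranks for ties. The two-sided p-value is the
    t-approximation for n >= 10 and an exact permutation p (all n!
    orderings) for smaller cohorts.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 aligned (concentration, count) pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: rank correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    n = len(x)
    if n >= 10:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            hits += 1
        total += 1
    return rho_obs, hits / total


def flag_degraded(
    samples: pd.DataFrame,
    variants,
    high_af_threshold: float = 0.10,
    k_mad: float = 3.0,
    count_floor: int = 5,
    conc_trigger: float = 1.5,
) -> pd.DataFrame:
    """Flag degraded samples by high-AF variant burden or low concentration.

    A sample is degraded when its count of variants above
    ``high_af_threshold`` exceeds the cohort median by more than
    ``max(k_mad * MAD, count_floor)``, or when its pre-normalization
    concentration is below ``conc_trigger`` ng/ul. The absolute floor keeps
    a tight cohort (MAD ~ 0) from flagging ordinary somatic carriers.
    """
    df = _as_frame(variants)
    out = samples.copy()
    high = df[df["af"] > high_af_threshold]
    counts = (
        high.groupby("sample_id").size().reindex(out["sample_id"], fill_value=0)
    )
    med = float(np.median(counts))
    mad = float(np.median(np.abs(counts - med)))
    threshold = med + max(k_mad * mad, count_floor)
    out["high_af_count"] = counts.to_numpy()
    by_count = out["high_af_count"] > threshold
    by_conc = out["pre_norm_conc_ng_ul"] < conc_trigger
    out["degraded"] = (by_count | by_conc).to_numpy()
    out["degraded_reason"] = [
        "+".join(filter(None, ["high_af_burden" if c else "", "low_concentration" if k else ""]))
        for c, k in zip(by_count, by_conc)
    ]
    return out


def enrichment_test(
    spectrum: SpectrumTable, low_bin: str | None = None, high_bin: str | None = None
) -> pd.DataFrame:
    """Per-class Fisher's exact test of low-bin vs high-bin membership.

    For each of the 12 substitution classes, the 2x2 table is
    [class vs all other classes] x [low bin vs high bin]; two-sided p by
    hypergeometric summation, q by Benjamini-Hochberg across the classes.
    An odds ratio > 1 means the class is overrepresented in the low-AF bin
    (i.e. behaves like an FFPE artifact class).
    """
    labels = spectrum.bin_labels
    if low_bin is None or high_bin is None:
        if len(labels) != 2:
            raise ValueError("designate low_bin and high_bin explicitly")
        low_bin, high_bin = labels
    counts = spectrum.counts
    rows = []
    for cls in SUBSTITUTIONS:
        a = int(counts.loc[cls, low_bin])
        b = int(counts.loc[cls, high_bin])
        c = int(counts[low_bin].loc[SUBSTITUTIONS].sum()) - a
        d = int(counts[high_bin].loc[SUBSTITUTIONS].sum()) - b
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            rows.append(dict(substitution=cls, a=a, b=b, c=c, d=d,
                             odds_ratio=float("nan"), p=1.0))
            continue
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(dict(substitution=cls, a=a, b=b, c=c, d=d,
                         odds_ratio=float(orr), p=float(p)))
    res = pd.DataFrame(rows)
    res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


@dataclass
class LambdaFit:
    """Fitted artifact-burden model lambda(c) = exp(a + b*log c)."""

    intercept: float
    slope: float
    constant: bool = False

    def predict(self, conc: float | np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return np.exp(self.intercept + self.slope * np.log(conc))


def fit_artifact_rate(
    concentrations: Sequence[float], counts: Sequence[int]
) -> LambdaFit:
    """Poisson regression of artifact counts on log concentration.

    Falls back to a cohort-constant rate (with a warning) when the
    concentrations are degenerate or fewer than 3 samples are available.
    """
    import statsmodels.api as sm

    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(x) < 3 or np.allclose(x, x[0]):
        warnings.warn(
            "degenerate concentrations: falling back to cohort-constant rate",
            stacklevel=2,
        )
        return LambdaFit(intercept=float(np.log(max(y.mean(), 1e-9))), slope=0.0,
                         constant=True)
    X = sm.add_constant(np.log(x))
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return LambdaFit(intercept=float(fit.params[0]), slope=float(fit.params[1]))


@dataclass
class ArtifactAFModel:
    """Truncated-Beta model of artifact allele frequencies on (0, af_max]."""

    a: float = 1.2
    b: float = 30.0
    af_max: float = 0.10

    @property
    def _cap(self) -> float:
        return float(stats.beta.cdf(self.af_max, self.a, self.b))

    def sf(self, f: float | np.ndarray) -> np.ndarray:
        """P(artifact AF >= f) under the truncated Beta."""
        f = np.clip(np.asarray(f, dtype=float), 0.0, self.af_max)
        return (self._cap - stats.beta.cdf(f, self.a, self.b)) / self._cap

    def isf(self, q: float) -> float:
        """Smallest f with sf(f) <= q."""
        q = min(max(q, 0.0), 1.0)
        return float(stats.beta.ppf(self._cap * (1.0 - q), self.a, self.b))


def estimate_cutoff(
    sample: SampleMeta,
    cohort_fit: LambdaFit,
    af_model: ArtifactAFModel | None = None,
    alpha: float = 1.0,
    category: str = "resistance",
    floors: dict[str, float] | None = None,
) -> float:
    """Concentration-informed per-sample AF reporting cutoff.

    The cutoff is the smallest AF ``f`` such that the expected number of
    artifact calls at or above ``f`` - ``lambda(conc) * P(AF >= f)`` -
    does not exceed ``alpha`` (default: one expected artifact), but never
    below the clinical floor for the variant category (5% for
    response-associated, 2.5% for resistance-associated variants). The
    cutoff is monotone non-increasing in concentration because the fitted
    burden is decreasing.
    """
    af_model = af_model or ArtifactAFModel()
    floors = floors or CLINICAL_FLOORS
    floor = floors[category]
    lam = float(cohort_fit.predict(sample.pre_norm_conc))
    if lam <= alpha:
        return floor
    return max(floor, af_model.isf(alpha / lam))


def qc_report(
    variants,
    sample_sheet: pd.DataFrame,
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
    af_model: ArtifactAFModel | None = None,
    alpha: float = 1.0,
    conc_trigger: float = 1.5,
) -> dict:
    """Run the full QC stage: spectrum, correlation, flags, cutoffs.

    Returns a JSON-serializable report; the pooled spectrum table is under
    ``spectrum`` and per-sample rows under ``samples``.
    """
    df = _as_frame(variants)
    flagged = flag_degraded(sample_sheet, df, conc_trigger=conc_trigger)
    counts = (
        df.groupby("sample_id").size()
        .reindex(flagged["sample_id"], fill_value=0)
        .to_numpy()
    )
    rho, p = concentration_correlation(
        flagged["pre_norm_conc_ng_ul"].to_numpy(), counts
    )
    good = ~flagged["degraded"].to_numpy()
    if good.sum() >= 3:
        fit = fit_artifact_rate(
            flagged.loc[good, "pre_norm_conc_ng_ul"].to_numpy(), counts[good]
        )
    else:
        fit = fit_artifact_rate(
            flagged["pre_norm_conc_ng_ul"].to_numpy(), counts
        )
    spectrum = spectrum_by_af(df, bin_edges)
    low_label = spectrum.bin_labels[0]

    sample_rows = []
    for rec, n in zip(flagged.itertuples(index=False), counts):
        meta = SampleMeta(
            sample_id=rec.sample_id,
            pre_norm_conc=rec.pre_norm_conc_ng_ul,
            total_reads=int(getattr(rec, "total_reads", 0)),
            degraded=bool(rec.degraded),
        )
        cutoff = estimate_cutoff(meta, fit, af_model=af_model, alpha=alpha)
        sub = df[df["sample_id"] == rec.sample_id]
        ct = float(
            (sub[["ref", "alt"]]
             .apply(lambda r: collapse_class(classify_substitution(r.ref, r.alt)), axis=1)
             == "C:G>T:A").mean()
        ) if len(sub) else float("nan")
        sample_rows.append(
            dict(sample_id=rec.sample_id,
                 pre_norm_conc_ng_ul=float(rec.pre_norm_conc_ng_ul),
                 n_variants=int(n),
                 high_af_count=int(rec.high_af_count),
                 cgt_ta_proportion=ct,
                 degraded=bool(rec.degraded),
                 degraded_reason=rec.degraded_reason,
                 af_cutoff=float(cutoff))
        )
    return dict(
        n_samples=int(len(flagged)),
        n_variants=int(len(df)),
        spearman_rho=rho,
        spearman_p=p,
        lambda_fit=dict(intercept=fit.intercept, slope=fit.slope,
                        constant=fit.constant),
        pooled_cgt_ta_low_bin=spectrum.class_proportion(["C>T", "G>A"], low_label),
        spectrum={
            b: spectrum.counts[b].to_dict() for b in spectrum.bin_labels
        },
        samples=sample_rows,
    )
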