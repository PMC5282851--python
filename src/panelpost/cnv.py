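"""Gene-level copy-number estimation from amplicon coverage, without
matched normals.

The baseline for each test sample is a bootstrap pseudo-control: the
other samples of the run are resampled with replacement B times, and the
gene fold is the test sample's mean depth over the gene's amplicons
relative to each resampled background. Percentile bounds of the bootstrap
fold distribution give the confidence interval. A within-chromosome
normalization against user-chosen reference genes separates focal gene
amplification from whole-chromosome or sample-wide effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelDefinition


@dataclass
class CoverageMatrix:
    """Samples x amplicons depths plus gene/chromosome bookkeeping."""

    depths: pd.DataFrame  # index samples, columns amplicon names
    gene_of: dict[str, str]  # amplicon -> gene
    chrom_of_gene: dict[str, str]

    def __post_init__(self) -> None:
        zero_rows = self.depths.index[(self.depths.sum(axis=1) == 0)]
        if len(zero_rows):
            raise ValueError(f"all-zero coverage for samples: {list(zero_rows)}")
        unknown = set(self.depths.columns) - set(self.gene_of)
        if unknown:
            raise ValueError(f"amplicons without gene assignment: {sorted(unknown)}")

    @classmethod
    def from_frame(cls, depths: pd.DataFrame, panel: PanelDefinition) -> "CoverageMatrix":
        return cls(
            depths=depths,
            gene_of={a.name: a.gene for a in panel},
            chrom_of_gene=dict(panel.chromosome_of),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, panel: PanelDefinition) -> "CoverageMatrix":
        depths = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(depths, panel)

    def amplicons_of(self, gene: str) -> list[str]:
        return [a for a in self.depths.columns if self.gene_of[a] == gene]

    @property
    def genes(self) -> set[str]:
        return {self.gene_of[a] for a in self.depths.columns}


@dataclass
class CNVCall:
    """Per-gene fold-change estimate with bootstrap confidence interval."""

    sample_id: str
    gene: str
    fold: float
    ci_low: float
    ci_high: float
    significant: bool
    normalized_fold: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.fold <= self.ci_high:
            raise ValueError("fold estimate outside its own CI")


def normalize_matrix(m: CoverageMatrix) -> CoverageMatrix:
    """Library-size and amplicon-efficiency normalization.

    Each sample row is scaled by its median amplicon depth (a library-size
    factor robust to focal amplifications, which would corrupt a total-
    count factor: a strongly amplified gene inflates the sample total and
    spuriously deflates every other gene), then each amplicon column is
    divided by its across-sample median (PCR efficiency bias), leaving
    per-amplicon median 1. All-zero amplicon columns (complete drop-out)
    are removed with a warning.
    """
    depths = m.depths.astype(float)
    dead = depths.columns[(depths == 0).all(axis=0)]
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} amplicon(s) with complete drop-out: "
            f"{list(dead)[:5]}",
            stacklevel=2,
        )
        depths = depths.drop(columns=dead)
    row_med = depths.median(axis=1)
    depths = depths.div(row_med, axis=0) * row_med.mean()
    med = depths.median(axis=0)
    med = med.replace(0, np.nan)
    depths = depths.div(med, axis=1).fillna(0.0)
    return CoverageMatrix(
        depths=depths,
        gene_of={a: m.gene_of[a] for a in depths.columns},
        chrom_of_gene=m.chrom_of_gene,
    )


def bootstrap_gene_fold(
    m: CoverageMatrix,
    sample: str,
    gene: str,
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
    min_fold: float = 1.5,
) -> CNVCall:
    """Bootstrap pseudo-control fold estimate for one gene in one sample.

    For each of B replicates the other samples are resampled with
    replacement; the replicate fold is the mean over the gene's amplicons
    of (sample depth / resampled background center). The background
    center is the per-amplicon *median* of the resampled samples: a mean
    would let an amplified sample elsewhere in the cohort contaminate the
    pseudo-control, deflating every normal sample's fold for that gene
    and compressing true folds. The reported fold is the median of the
    bootstrap distribution, the CI its percentile bounds. A call is
    significant when the CI excludes 1 *and* the fold lies beyond
    ``min_fold`` in either direction (clinical-significance gate,
    configurable).
    """
    if gene not in m.genes:
        raise ValueError(f"gene {gene!r} not in coverage matrix")
    amps = m.amplicons_of(gene)
    if len(amps) < 2:
        raise ValueError(f"gene {gene}: need >= 2 amplicons, have {len(amps)}")
    others = [s for s in m.depths.index if s != sample]
    if len(others) < 4:
        raise ValueError("need >= 4 background samples")
    if B < 100:
        warnings.warn(f"B={B} is small; CI will be unstable", stacklevel=2)

    rng = np.random.default_rng(seed)
    target = m.depths.loc[sample, amps].to_numpy(dtype=float)  # (n_amp,)
    background = m.depths.loc[others, amps].to_numpy(dtype=float)  # (n_other, n_amp)
    idx = rng.integers(0, len(others), size=(B, len(others)))
    bg_center = np.median(background[idx], axis=1)  # (B, n_amp)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = np.nanmean(np.where(bg_center > 0, target / bg_center, np.nan), axis=1)
    folds = folds[np.isfinite(folds)]
    fold = float(np.median(folds))
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    ci_low = float(np.quantile(folds, lo_q))
    ci_high = float(np.quantile(folds, hi_q))
    excludes_one = ci_low > 1.0 or ci_high < 1.0
    beyond = fold >= min_fold or fold <= 1.0 / min_fold
    return CNVCall(
        sample_id=sample,
        gene=gene,
        fold=fold,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=bool(excludes_one and beyond),
    )


def within_chromosome_fold(
    m: CoverageMatrix,
    sample: str,
    target_gene: str,
    reference_genes: set[str],
    flagged_amplified: set[str] = frozenset(),
) -> float:
    """Target-gene fold normalized against same-chromosome reference genes.

    The statistic is (target mean depth / pooled reference mean depth) in
    the sample, divided by the across-other-samples median of the same
    ratio. A uniform whole-chromosome (or whole-sample) change cancels;
    only focal amplification of the target survives.
    """
    if not reference_genes:
        raise ValueError("reference_genes must be non-empty")
    if target_gene in reference_genes:
        raise ValueError("reference set must not contain the target gene")
    chrom = m.chrom_of_gene.get(target_gene)
    for g in reference_genes:
        if m.chrom_of_gene.get(g) != chrom:
            raise ValueError(
                f"reference gene {g} not on the target's chromosome {chrom}"
            )
    contaminated = reference_genes & set(flagged_amplified)
    if contaminated:
        warnings.warn(
            f"reference gene(s) {sorted(contaminated)} flagged amplified in "
            f"{sample}: baseline may be contaminated",
            stacklevel=2,
        )
    t_amps = m.amplicons_of(target_gene)
    r_amps = [a for g in sorted(reference_genes) for a in m.amplicons_of(g)]
    if not t_amps or not r_amps:
        raise ValueError("target or reference genes have no amplicons")
    ratio = (
        m.depths[t_amps].mean(axis=1) / m.depths[r_amps].mean(axis=1)
    )
    others = [s for s in m.depths.index if s != sample]
    return float(ratio.loc[sample] / ratio.loc[others].median())


def cnv_report(
    m: CoverageMatrix,
    B: int = 1000,
    seed: int = 0,
    genes: list[str] | None = None,
    normalize_chrom: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Run bootstrap calls for every (sample, gene) pair; one row each.

    ``normalize_chrom`` maps target gene -> same-chromosome reference
    genes for the optional within-chromosome fold column.
    """
    norm = normalize_matrix(m)
    genes = genes or sorted(g for g in norm.genes if len(norm.amplicons_of(g)) >= 2)
    rows = []
    for i, sample in enumerate(norm.depths.index):
        for j, gene in enumerate(genes):
            call = bootstrap_gene_fold(
                norm, sample, gene, B=B, seed=seed + 7919 * i + 104729 * j
            )
            nf = None
            if normalize_chrom and gene in normalize_chrom:
                nf = within_chromosome_fold(m, sample, gene, normalize_chrom[gene])
            rows.append(
                dict(sample_id=sample, gene=gene, fold=call.fold,
                     ci_low=call.ci_low, ci_high=call.ci_high,
                     significant=call.significant, normalized_fold=nf)
            )
    return pd.DataFrame(rows)
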