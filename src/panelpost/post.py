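"""Variant post-processing: primer exclusion, recurrent-artifact
blacklisting, germline discrimination, read-backed phasing with complex
variant reconstruction, strand-bias rescue, and final report filtering.

Stage order (each stage feeds the next): primer exclusion -> blacklist ->
germline call -> phasing/merge -> protein annotation -> per-sample AF
thresholds. The order matters: the blacklist must not learn from
primer-only calls, and thresholds apply to merged (not parent) records.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Amplicon, PanelDefinition
from .qc import VariantCall, _as_frame


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Per-read joint observation counts for a variant pair."""

    variant_a: str
    variant_b: str
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int = 0

    def __post_init__(self) -> None:
        if min(self.n_both, self.n_a_only, self.n_b_only, self.n_neither) < 0:
            raise ValueError("negative read counts")


def phase_fraction(
    c: CooccurrenceCounts, threshold: float = 0.9
) -> tuple[float, bool]:
    """Fraction of mutant-carrying reads that carry both variants.

    Returns ``(fraction, phased)``; ``phased`` means the pair behaves as
    one haplotype (fraction >= threshold, default 0.9 — the textbook fully
    phased case is fraction 1.0). With no mutant reads the fraction is
    undefined (NaN) and the pair is not phased.
    """
    denom = c.n_both + c.n_a_only + c.n_b_only
    if denom == 0:
        return float("nan"), False
    frac = c.n_both / denom
    return frac, frac >= threshold


# ---------------------------------------------------------------------------
# primer exclusion


def exclude_primer_evidence(
    variants, panel: PanelDefinition
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split calls into (kept, primer-only, off-target).

    A variant is kept when its position falls inside the primer-free
    insert of at least one covering amplicon; positions covered only by
    primer footprints carry no independent evidence (the base was copied
    from the oligo) and are removed. Positions on no amplicon at all go to
    the off-target log rather than raising.
    """
    df = _as_frame(variants)
    status = []
    for rec in df.itertuples(index=False):
        covering = panel.covering(rec.chrom, rec.pos)
        if not covering:
            status.append("off_target")
        elif any(a.in_insert(rec.chrom, rec.pos) for a in covering):
            status.append("kept")
        else:
            status.append("primer_only")
    status = np.asarray(status)
    return (
        df[status == "kept"].reset_index(drop=True),
        df[status == "primer_only"].reset_index(drop=True),
        df[status == "off_target"].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# recurrent-artifact blacklist


@dataclass
class Blacklist:
    """Recurrent low-AF sites treated as panel-specific artifacts."""

    entries: set  # of (chrom, pos, ref, alt)
    provenance: pd.DataFrame  # chrom pos ref alt n_samples median_af
    germline_candidates: set = field(default_factory=set)

    def __contains__(self, key: tuple) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def build_blacklist(
    variants,
    n_samples: int | None = None,
    min_sample_fraction: float = 0.4,
    max_median_af: float = 0.10,
) -> Blacklist:
    """Sites recurring in >= ``min_sample_fraction`` of samples at low AF.

    Recurrence at a consistently low allele fraction across unrelated
    samples is the signature of a panel-specific artifact (context-driven
    polymerase or deamination error), not of shared biology. Recurrent
    sites with *high* median AF are excluded from the blacklist and routed
    to germline discrimination instead (candidate common polymorphisms).
    Membership is invariant to sample and record order.
    """
    df = _as_frame(variants)
    if n_samples is None:
        n_samples = df["sample_id"].nunique()
    if n_samples < 3:
        raise ValueError("blacklist needs a cohort of >= 3 samples")
    grouped = (
        df.groupby(["chrom", "pos", "ref", "alt"])
        .agg(n_samples_seen=("sample_id", "nunique"), median_af=("af", "median"))
        .reset_index()
    )
    # recurrence threshold rounds to the nearest sample count (0.4 of 26
    # samples means 10 carriers), but never below 2
    min_seen = max(2, round(min_sample_fraction * n_samples))
    recurrent = grouped[grouped["n_samples_seen"] >= min_seen]
    low = recurrent[recurrent["median_af"] < max_median_af]
    high = recurrent[recurrent["median_af"] >= max_median_af]
    key = lambda r: (r.chrom, int(r.pos), r.ref, r.alt)
    return Blacklist(
        entries={key(r) for r in low.itertuples(index=False)},
        provenance=low.sort_values(["chrom", "pos", "ref", "alt"]).reset_index(drop=True),
        germline_candidates={key(r) for r in high.itertuples(index=False)},
    )


# ---------------------------------------------------------------------------
# germline discrimination


class GermlineDB:
    """Offline lookup of population frequency and dbSNP/COSMIC membership."""

    def __init__(self, table: pd.DataFrame):
        self._map = {
            (r.chrom, int(r.pos), r.ref, r.alt): (
                float(r.pop_freq), bool(r.dbsnp), bool(r.cosmic)
            )
            for r in table.itertuples(index=False)
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GermlineDB":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @classmethod
    def bundled_synthetic(cls) -> "GermlineDB":
        """The small synthetic fixture shipped with the package."""
        path = importlib.resources.files("panelpost.data") / "germline_db_synthetic.tsv"
        return cls.from_tsv(path)

    def lookup(self, chrom: str, pos: int, ref: str, alt: str):
        return self._map.get((chrom, int(pos), ref, alt), (0.0, False, False))


def discriminate_germline(
    v: VariantCall | tuple,
    db: GermlineDB,
    germline_pop_freq: float = 0.01,
    somatic_pop_freq: float = 0.001,
) -> str:
    """Classify origin from population frequency and database membership.

    Common in the population (>= 1%) -> germline; a COSMIC-catalogued
    variant essentially absent from the population (< 0.1%) -> somatic;
    anything in between -> ambiguous (surfaced for human judgment rather
    than auto-resolved). Absent from the database counts as frequency 0.
    """
    if isinstance(v, VariantCall):
        chrom, pos, ref, alt = v.chrom, v.pos, v.ref, v.alt
    else:
        chrom, pos, ref, alt = v
    pop, _dbsnp, cosmic = db.lookup(chrom, pos, ref, alt)
    if pop >= germline_pop_freq:
        return "germline"
    if cosmic and pop < somatic_pop_freq:
        return "somatic"
    return "ambiguous"


# ---------------------------------------------------------------------------
# phased-pair merge


def _left_align(seq: str, seq_start: int, pos: int, ref: str, alt: str):
    """Minimal left-aligned VCF representation over reference ``seq``
    (1-based start ``seq_start``): repeatedly strip a shared trailing base,
    re-anchoring with the preceding reference base when an allele empties,
    then trim the shared leading context."""
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos <= seq_start:
                break  # cannot extend left of the provided reference
            prev = seq[pos - 1 - seq_start]
            ref, alt = prev + ref, prev + alt
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def merge_phased(
    a: VariantCall,
    b: VariantCall | None,
    ref_seq: str,
    ref_start: int,
    max_span: int = 100,
) -> VariantCall:
    """Reconstruct one complex variant from a phased pair.

    Callers routinely emit a complex substitution as two adjacent calls
    (e.g. two frameshifts that together are one inframe delins). Both
    edits are applied to the reference over the spanning interval and the
    minimal single REF/ALT pair is derived (common prefix/suffix trimmed,
    indels left-aligned). AF of the merged record is the more conservative
    (minimum) of the parents; parent identities are kept for audit.

    ``ref_seq`` is the reference sequence starting at 1-based ``ref_start``.
    """
    if b is None:
        return a
    if a.sample_id != b.sample_id:
        raise ValueError("phased variants must come from one sample")
    first, second = sorted((a, b), key=lambda v: v.pos)
    span = second.pos + len(second.ref) - first.pos
    if span > max_span:
        raise ValueError(f"spanning interval {span} bp exceeds max_span={max_span}")
    if first.pos + len(first.ref) > second.pos:
        raise ValueError(
            f"conflicting overlapping edits: {first.key} and {second.key}"
        )
    lo = first.pos
    hi = second.pos + len(second.ref) - 1
    if lo < ref_start or hi - ref_start + 1 > len(ref_seq):
        raise ValueError("ref_seq does not cover the spanning interval")
    region = ref_seq[lo - ref_start : hi - ref_start + 1]
    for v in (first, second):
        off = v.pos - lo
        if region[off : off + len(v.ref)] != v.ref.upper():
            raise ValueError(f"reference mismatch at {v.key}")
    # apply right-to-left so offsets stay valid
    edited = region
    for v in (second, first):
        off = v.pos - lo
        edited = edited[:off] + v.alt.upper() + edited[off + len(v.ref) :]
    pos, ref, alt = _left_align(ref_seq, ref_start, lo, region, edited)
    return VariantCall(
        sample_id=a.sample_id,
        chrom=a.chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        af=min(a.af, b.af),
        depth=min(a.depth, b.depth),
        fwd_alt=min(a.fwd_alt, b.fwd_alt),
        rev_alt=min(a.rev_alt, b.rev_alt),
        gene=a.gene or b.gene,
        info={"parents": (a.key, b.key)},
    )


# ---------------------------------------------------------------------------
# strand-bias rescue


def strand_bias_rescue(
    v: VariantCall,
    a: Amplicon,
    read_length: int = 150,
    margin: int = 20,
) -> bool:
    """Flag indels whose strand bias is a geometric artifact.

    Near an amplicon end, reads from one orientation terminate *inside*
    a long insertion/deletion: those reads misalign, all support collapses
    onto the other strand, and a naive strand-bias filter kills a real
    call. The flag is raised when, for either end, the variant lies within
    one read length of the end (``dist < read_length``) and the read would
    end within the variant (``dist + len(variant) > read_length - margin``).
    Flagged calls are exempted from strand-bias filtering and marked for
    realignment instead.
    """
    if len(v.ref) == len(v.alt):
        return False
    var_len = abs(len(v.alt) - len(v.ref))
    for dist in (v.pos - a.start, a.end - v.pos):
        if dist < 0:
            continue
        if dist < read_length and dist + var_len > read_length - margin:
            return True
    return False


# ---------------------------------------------------------------------------
# report filtering


def load_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a curated-report-style TSV (gene, hgvs_p, patient, histology,
    af_percent, impact) into the internal variant frame convention."""
    df = pd.read_csv(path, sep="\t", dtype={"patient": str})
    out = pd.DataFrame(
        {
            "sample_id": df["patient"],
            "gene": df["gene"],
            "hgvs_p": df["hgvs_p"],
            "histology": df.get("histology", ""),
            "af": df["af_percent"].astype(float) / 100.0,
            "impact": df.get("impact", ""),
        }
    )
    return out


def bundled_curated_table() -> pd.DataFrame:
    """The 25-row curated variant table shipped as a fixture."""
    path = importlib.resources.files("panelpost.data") / "curated_variant_table.tsv"
    return load_variant_table(path)


def filter_report(
    variants,
    samples: pd.DataFrame,
    blacklist: Blacklist | None = None,
    non_target_af_floor: float = 0.10,
    target_genes: set | None = None,
) -> pd.DataFrame:
    """Assemble the curated variant report.

    Keeps a variant when its gene is targeted for therapy decisions and
    its AF clears the sample-specific cutoff, or — for every other panel
    gene, where only major clones matter — when AF >= the 10% floor.
    Drops blacklist members, synonymous/non-coding calls, records flagged
    not-expressed-suppressing-nothing (kept but labelled), and
    non-recurrent calls seen only in degraded samples. Idempotent: running
    it on its own output changes nothing.

    ``samples`` must carry ``af_cutoff`` (and optionally ``degraded``)
    from the QC stage.
    """
    df = _as_frame(variants).copy()
    if "af_cutoff" not in samples.columns:
        raise ValueError(
            "sample sheet has no af_cutoff column: run the QC stage first"
        )
    cutoffs = samples.set_index("sample_id")["af_cutoff"]
    missing = set(df["sample_id"]) - set(cutoffs.index)
    if missing:
        raise ValueError(
            f"samples without QC cutoffs: {sorted(missing)}; run QC first"
        )
    if len(df) == 0:
        return df

    keep = np.ones(len(df), dtype=bool)

    if blacklist is not None and {"chrom", "pos"} <= set(df.columns):
        keys = list(zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"]))
        keep &= np.array([k not in blacklist for k in keys])

    if "effect" in df.columns:
        keep &= ~df["effect"].isin(["synonymous", "non_coding"]).to_numpy()

    # germline calls are logged by the discrimination stage, not reported
    # among somatic findings
    if "origin" in df.columns:
        keep &= ~(df["origin"] == "germline").to_numpy()

    # non-recurrent calls confined to degraded samples are presumed artifacts
    if "degraded" in samples.columns and {"chrom", "pos"} <= set(df.columns):
        degraded = set(samples.loc[samples["degraded"], "sample_id"])
        if degraded:
            grp = df.groupby(["chrom", "pos", "ref", "alt"])["sample_id"]
            n_seen = grp.transform("nunique").to_numpy()
            only_degraded = (
                grp.transform(lambda s: s.isin(degraded).all()).to_numpy()
            )
            keep &= ~((n_seen < 2) & only_degraded)

    af = df["af"].to_numpy(dtype=float)
    sample_cutoff = cutoffs.reindex(df["sample_id"]).to_numpy(dtype=float)
    if target_genes is None:
        in_target = np.ones(len(df), dtype=bool)
    else:
        in_target = df["gene"].isin(target_genes).to_numpy()
    keep &= np.where(in_target, af >= sample_cutoff, af >= non_target_af_floor)

    out = df[keep].copy()
    for col, default in (("origin", "ambiguous"), ("expressed", True),
                         ("rescue", False)):
        if col not in out.columns:
            out[col] = default
    sort_cols = [c for c in ("gene", "pos", "sample_id") if c in out.columns]
    return out.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
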