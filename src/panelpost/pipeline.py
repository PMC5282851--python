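"""End-to-end orchestration: simulate -> qc -> postprocess -> cnv.

Each stage writes its outputs under the run directory and the next stage
reads them back, so the pipeline exercises the on-disk interfaces rather
than passing objects around. All randomness derives from the single run
seed; reports contain no timestamps, so identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_protein
from .cnv import CoverageMatrix, cnv_report
from .io import read_vcf_dir, write_cohort
from .panel import PanelDefinition, TranscriptModel, load_panel, synthetic_reference
from .post import (
    CooccurrenceCounts,
    GermlineDB,
    build_blacklist,
    discriminate_germline,
    exclude_primer_evidence,
    filter_report,
    phase_fraction,
    merge_phased,
    strand_bias_rescue,
)
from .qc import VariantCall, qc_report
from .simulate import SimulationConfig, demo_panel, simulate_cohort

log = logging.getLogger("panelpost")

DEFAULT_TARGET_GENES = frozenset({"EGFR"})
DEFAULT_CHROM_REFERENCES = {"MET": {"EGFR", "BRAF", "SMO"}}


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    outdir: Path
    seed: int = 0
    sim_config: Path | None = None  # JSON; None -> defaults
    bootstrap_B: int = 1000
    target_genes: frozenset = DEFAULT_TARGET_GENES
    non_target_af_floor: float = 0.10
    chrom_references: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_REFERENCES))

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.sim_config is not None and not Path(self.sim_config).exists():
            raise FileNotFoundError(f"sim config not found: {self.sim_config}")


def _key_parts(key: str) -> tuple[str, int, str, str]:
    chrom, pos, change = key.split(":")
    ref, alt = change.split(">")
    return chrom, int(pos), ref, alt


def _toy_transcript(amplicon) -> TranscriptModel:
    """An in-frame CDS over the amplicon insert of the synthetic genome
    (partial model: no start codon is required)."""
    lo, hi = amplicon.insert_start, amplicon.insert_end
    length = ((hi - lo + 1) // 3) * 3
    hi = lo + length - 1
    seq = synthetic_reference(amplicon.chrom, lo, hi)
    return TranscriptModel(
        gene=amplicon.gene, chrom=amplicon.chrom, strand="+",
        cds_intervals=[(lo, hi)], sequence=seq, partial=True,
    )


def _row_to_call(row, gene: str = "") -> VariantCall:
    return VariantCall(
        sample_id=row.sample_id, chrom=row.chrom, pos=int(row.pos),
        ref=row.ref, alt=row.alt, af=float(row.af), depth=int(row.depth),
        fwd_alt=int(row.fwd_alt), rev_alt=int(row.rev_alt),
        gene=gene or getattr(row, "gene", ""),
    )


def postprocess_variants(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    panel: PanelDefinition,
    evidence: pd.DataFrame,
    db: GermlineDB,
    target_genes: frozenset = DEFAULT_TARGET_GENES,
    non_target_af_floor: float = 0.10,
) -> dict:
    """Run the whole post-processing chain on a cohort's variant calls.

    Order: primer exclusion -> blacklist -> germline call -> phasing and
    complex-variant reconstruction -> annotation flags -> per-sample AF
    thresholds. Returns the curated report plus the intermediate logs.
    """
    kept, primer_only, off_target = exclude_primer_evidence(variants, panel)
    blacklist = build_blacklist(kept)

    kept = kept.copy()
    if "gene" not in kept.columns:
        kept["gene"] = [
            (panel.covering(r.chrom, r.pos) or [None])[0].gene
            if panel.covering(r.chrom, r.pos) else ""
            for r in kept.itertuples(index=False)
        ]
    kept["origin"] = [
        discriminate_germline((r.chrom, int(r.pos), r.ref, r.alt), db)
        for r in kept.itertuples(index=False)
    ]
    kept["expressed"] = True
    kept["effect"] = None
    kept["rescue"] = False
    kept["hgvs_p"] = None

    # read-backed phasing and complex-variant reconstruction
    drop_idx: list[int] = []
    merged_rows: list[dict] = []
    for ev in evidence.itertuples(index=False):
        counts = CooccurrenceCounts(
            variant_a=ev.variant_a, variant_b=ev.variant_b,
            n_both=int(ev.n_both), n_a_only=int(ev.n_a_only),
            n_b_only=int(ev.n_b_only), n_neither=int(ev.n_neither),
        )
        frac, phased = phase_fraction(counts)
        if not phased:
            continue
        sample_id = getattr(ev, "sample_id", None)
        pair = []
        for key in (ev.variant_a, ev.variant_b):
            chrom, pos, ref, alt = _key_parts(key)
            mask = (
                (kept["chrom"] == chrom) & (kept["pos"] == pos)
                & (kept["ref"] == ref) & (kept["alt"] == alt)
            )
            if sample_id is not None:
                mask &= kept["sample_id"] == sample_id
            hit = kept[mask]
            if len(hit):
                pair.append(hit.index[0])
        if len(pair) != 2:
            continue
        row_a, row_b = kept.loc[pair[0]], kept.loc[pair[1]]
        call_a, call_b = _row_to_call(row_a), _row_to_call(row_b)
        hosts = [
            a for a in panel
            if a.in_insert(call_a.chrom, call_a.pos)
            and a.in_insert(call_b.chrom, call_b.pos)
        ]
        if not hosts:
            continue
        amp = hosts[0]
        transcript = _toy_transcript(amp)
        window = synthetic_reference(amp.chrom, amp.start, amp.end)
        try:
            merged = merge_phased(call_a, call_b, window, amp.start)
        except ValueError:
            merged = None
        merged_ann = None
        if merged is not None:
            try:
                merged_ann = annotate_protein(merged, transcript)
            except ValueError:
                merged_ann = None
        if merged_ann is not None and merged_ann.effect.startswith("inframe"):
            # the pair is really one complex variant: replace both parents
            drop_idx.extend(pair)
            merged_rows.append(
                dict(sample_id=merged.sample_id, chrom=merged.chrom,
                     pos=merged.pos, ref=merged.ref, alt=merged.alt,
                     gene=amp.gene, af=merged.af, depth=merged.depth,
                     fwd_alt=merged.fwd_alt, rev_alt=merged.rev_alt,
                     origin="somatic", expressed=True,
                     effect=merged_ann.effect, rescue=False,
                     hgvs_p=merged_ann.hgvs_p,
                     parents=f"{call_a.key}|{call_b.key}")
            )
        else:
            # distinct events on one haplotype: an upstream frameshift
            # silences the downstream call at the protein level
            for idx, call in ((pair[0], call_a), (pair[1], call_b)):
                other = call_b if call is call_a else call_a
                try:
                    ann = annotate_protein(call, transcript, phased_context=[other])
                except ValueError:
                    continue
                kept.loc[idx, "effect"] = ann.effect
                kept.loc[idx, "hgvs_p"] = ann.hgvs_p
                kept.loc[idx, "expressed"] = ann.expressed

    if drop_idx:
        kept = kept.drop(index=drop_idx)
    if merged_rows:
        kept = pd.concat([kept, pd.DataFrame(merged_rows)], ignore_index=True)
    kept = kept.reset_index(drop=True)

    # strand-bias rescue flags for indels near amplicon ends
    for i, rec in enumerate(kept.itertuples(index=False)):
        if len(rec.ref) == len(rec.alt):
            continue
        call = _row_to_call(rec)
        for amp in panel.covering(rec.chrom, rec.pos):
            if strand_bias_rescue(call, amp):
                kept.iloc[i, kept.columns.get_loc("rescue")] = True
                break

    report = filter_report(
        kept, samples, blacklist,
        non_target_af_floor=non_target_af_floor,
        target_genes=set(target_genes) | set(),
    )
    return dict(
        report=report,
        blacklist=blacklist,
        primer_only=primer_only,
        off_target=off_target,
        n_input=len(variants),
        n_kept_pre_threshold=len(kept),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in order, writing artifacts under ``config.outdir``.

    A stage failure leaves a ``<stage>.failed`` marker next to the partial
    outputs and re-raises. Returns the artifact paths.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.sim_config is not None:
            sim_cfg = SimulationConfig.from_json(config.sim_config)
            sim_cfg.seed = config.seed
        else:
            sim_cfg = SimulationConfig(seed=config.seed)
        panel = demo_panel()
        cohort = simulate_cohort(sim_cfg, panel)
        paths = write_cohort(cohort, outdir / "sim")
        artifacts.update(paths)
        log.info("stage=simulate records=%d wall=%.2fs",
                 len(cohort.variants), time.perf_counter() - t0)

        stage = "qc"
        t0 = time.perf_counter()
        variants = read_vcf_dir(paths["vcf_dir"])
        sample_sheet = pd.read_csv(paths["sample_sheet"], sep="\t")
        report = qc_report(variants, sample_sheet)
        qc_path = outdir / "qc_report.json"
        qc_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["qc_report"] = qc_path
        log.info("stage=qc records=%d wall=%.2fs",
                 report["n_variants"], time.perf_counter() - t0)

        stage = "postprocess"
        t0 = time.perf_counter()
        qc_samples = pd.DataFrame(report["samples"])
        evidence = pd.read_csv(paths["evidence"], sep="\t")
        db = GermlineDB.from_tsv(paths["db"])
        loaded_panel = load_panel(paths["panel_bed"], paths["panel_manifest"])
        result = postprocess_variants(
            variants, qc_samples, loaded_panel, evidence, db,
            target_genes=config.target_genes,
            non_target_af_floor=config.non_target_af_floor,
        )
        report_path = outdir / "curated_variants.tsv"
        result["report"].to_csv(report_path, sep="\t", index=False)
        blacklist_path = outdir / "blacklist.tsv"
        result["blacklist"].provenance.to_csv(blacklist_path, sep="\t", index=False)
        artifacts["curated_variants"] = report_path
        artifacts["blacklist"] = blacklist_path
        log.info("stage=postprocess records=%d wall=%.2fs",
                 len(result["report"]), time.perf_counter() - t0)

        stage = "cnv"
        t0 = time.perf_counter()
        cov = CoverageMatrix.from_tsv(paths["coverage"], loaded_panel)
        cnv = cnv_report(
            cov, B=config.bootstrap_B, seed=config.seed,
            normalize_chrom=config.chrom_references,
        )
        cnv_path = outdir / "cnv_report.tsv"
        cnv.to_csv(cnv_path, sep="\t", index=False)
        artifacts["cnv_report"] = cnv_path
        log.info("stage=cnv records=%d wall=%.2fs", len(cnv),
                 time.perf_counter() - t0)

        stage = "manifest"
        manifest = dict(
            version=__version__,
            seed=config.seed,
            bootstrap_B=config.bootstrap_B,
            target_genes=sorted(config.target_genes),
            non_target_af_floor=config.non_target_af_floor,
            inputs={
                name: _sha256(p)
                for name, p in sorted(paths.items())
                if isinstance(p, Path) and p.is_file()
            },
        )
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        artifacts["manifest"] = manifest_path
    except Exception:
        (outdir / f"{stage}.failed").touch()
        raise
    summary_path = outdir / "summary.txt"
    summary_path.write_text(render_report(outdir))
    artifacts["summary"] = summary_path
    return artifacts


def render_report(outdir: str | Path) -> str:
    """Human-readable cohort summary from the stage outputs on disk."""
    outdir = Path(outdir)
    lines: list[str] = ["# Cohort summary", ""]

    qc_path = outdir / "qc_report.json"
    if qc_path.exists():
        qc = json.loads(qc_path.read_text())
        lines += [
            "## Per-sample QC",
            f"samples: {qc['n_samples']}  variant calls: {qc['n_variants']}",
            f"Spearman rho (counts vs concentration): {qc['spearman_rho']:.3f} "
            f"(p = {qc['spearman_p']:.3g})",
            "",
            "sample\tconc(ng/ul)\tn_variants\thigh_af\tC:G>T:A\tdegraded\tcutoff",
        ]
        for s in qc["samples"]:
            lines.append(
                f"{s['sample_id']}\t{s['pre_norm_conc_ng_ul']:g}\t"
                f"{s['n_variants']}\t{s['high_af_count']}\t"
                f"{s['cgt_ta_proportion']:.2f}\t"
                f"{'yes' if s['degraded'] else 'no'}\t{s['af_cutoff']:.3f}"
            )
        lines.append("")

    var_path = outdir / "curated_variants.tsv"
    if var_path.exists():
        report = pd.read_csv(var_path, sep="\t")
        lines.append("## Curated variants")
        if len(report) == 0:
            lines.append("no reportable variants")
        else:
            cols = [c for c in ("gene", "hgvs_p", "sample_id", "af", "origin",
                                "expressed", "rescue") if c in report.columns]
            by_gene = report.groupby("gene").size().sort_values(ascending=False)
            lines.append(
                "genes: " + ", ".join(f"{g} ({n})" for g, n in by_gene.items())
            )
            shown = report[cols].fillna("-")
            if "af" in cols:
                shown["af"] = report["af"].map(lambda x: f"{x:.3f}")
            for rec in shown.itertuples(index=False):
                lines.append("\t".join(str(x) for x in rec))
        lines.append("")

    cnv_path = outdir / "cnv_report.tsv"
    if cnv_path.exists():
        cnv = pd.read_csv(cnv_path, sep="\t")
        hits = cnv[cnv["significant"]]
        lines.append("## Copy-number calls")
        if len(hits) == 0:
            lines.append("no significant copy-number changes")
        else:
            for rec in hits.itertuples(index=False):
                nf = (f"  within-chrom {rec.normalized_fold:.2f}x"
                      if pd.notna(rec.normalized_fold) else "")
                lines.append(
                    f"{rec.sample_id}\t{rec.gene}\t{rec.fold:.2f}x "
                    f"[{rec.ci_low:.2f}, {rec.ci_high:.2f}]{nf}"
                )
        lines.append("")
    return "\n".join(lines) + "\n"
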