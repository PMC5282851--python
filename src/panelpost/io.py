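"""On-disk formats: per-sample VCFs, sample sheet, coverage matrix,
read-evidence and truth-label TSVs, plus a deterministic synthetic
reference for the mini-genome.

Truth labels are written to a sidecar TSV, never into the VCFs, so the
pipeline under test cannot see them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .panel import PanelDefinition
from .simulate import SimulatedCohort


def _contig_lengths(panel: PanelDefinition) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for a in panel:
        lengths[a.chrom] = max(lengths.get(a.chrom, 0), a.end + 1000)
    return lengths


def write_sample_vcf(
    variants: pd.DataFrame, sample_id: str, panel: PanelDefinition, path: Path
) -> None:
    """One uncompressed VCF 4.2 per sample; AF and per-strand alt depths
    travel as FORMAT fields."""
    header = pysam.VariantHeader()
    header.add_meta("source", "panelpost-simulate")
    for chrom, length in sorted(_contig_lengths(panel).items()):
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Covering reads")
    header.formats.add("AF", 1, "Float", "Variant allele fraction")
    header.formats.add("FAD", 1, "Integer", "Forward-strand alt reads")
    header.formats.add("RAD", 1, "Integer", "Reverse-strand alt reads")
    header.add_sample(sample_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        sub = variants[variants["sample_id"] == sample_id]
        sub = sub.sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort")
        for rec in sub.itertuples(index=False):
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(rec.ref, rec.alt),
            )
            sample = row.samples[sample_id]
            sample["GT"] = (0, 1)
            sample["DP"] = int(rec.depth)
            sample["AF"] = float(rec.af)
            sample["FAD"] = int(rec.fwd_alt)
            sample["RAD"] = int(rec.rev_alt)
            out.write(row)


def read_vcf_dir(vcf_dir: str | Path) -> pd.DataFrame:
    """Read every ``*.vcf`` in a directory into the internal variant frame.

    Multi-allelic records are split into biallelic rows at ingestion.
    """
    rows = []
    for path in sorted(Path(vcf_dir).glob("*.vcf")):
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for sample_id in rec.samples:
                    fmt = rec.samples[sample_id]
                    for alt in rec.alts or ():
                        rows.append(
                            dict(
                                sample_id=sample_id,
                                chrom=rec.chrom,
                                pos=rec.pos,
                                ref=rec.ref,
                                alt=alt,
                                af=float(fmt.get("AF", 0.0)),
                                depth=int(fmt.get("DP", 0)),
                                fwd_alt=int(fmt.get("FAD", 0) or 0),
                                rev_alt=int(fmt.get("RAD", 0) or 0),
                            )
                        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "af", "depth",
                 "fwd_alt", "rev_alt"],
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort to disk; returns the paths written."""
    outdir = Path(outdir)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    for sample_id in cohort.config.sample_ids:
        write_sample_vcf(
            cohort.variants, sample_id, cohort.panel, vcf_dir / f"{sample_id}.vcf"
        )
    paths = {
        "vcf_dir": vcf_dir,
        "sample_sheet": outdir / "sample_sheet.tsv",
        "coverage": outdir / "coverage.tsv",
        "truth": outdir / "truth_labels.tsv",
        "evidence": outdir / "read_evidence.tsv",
        "db": outdir / "germline_db.tsv",
        "panel_bed": outdir / "panel.bed",
        "panel_manifest": outdir / "panel_manifest.tsv",
    }
    cohort.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    cohort.coverage.to_csv(paths["coverage"], sep="\t")
    cohort.variants[
        ["sample_id", "chrom", "pos", "ref", "alt", "truth"]
    ].to_csv(paths["truth"], sep="\t", index=False)
    cohort.read_evidence.to_csv(paths["evidence"], sep="\t", index=False)
    cohort.db.to_csv(paths["db"], sep="\t", index=False)
    from .panel import write_panel

    write_panel(cohort.panel, paths["panel_bed"], paths["panel_manifest"])
    return paths
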