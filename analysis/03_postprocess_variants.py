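#!/usr/bin/env python
"""Variant post-processing of the simulated cohort.

Applies, in order: primer-footprint exclusion, recurrent-artifact
blacklisting, germline/somatic discrimination against the offline
database, read-backed phasing with complex-variant reconstruction (and
frameshift-masking of downstream calls on the same haplotype),
strand-bias rescue flags, and the per-sample AF thresholds from the QC
stage. Writes results/curated_variants.tsv and results/blacklist.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from panelpost.io import read_vcf_dir
from panelpost.panel import load_panel
from panelpost.pipeline import postprocess_variants
from panelpost.post import GermlineDB


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohort", type=Path, default=Path("results") / "cohort")
    parser.add_argument("--qc", type=Path,
                        default=Path("results") / "qc_report.json")
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    variants = read_vcf_dir(args.cohort / "vcf")
    qc = json.loads(args.qc.read_text())
    samples = pd.DataFrame(qc["samples"])
    panel = load_panel(args.cohort / "panel.bed",
                       args.cohort / "panel_manifest.tsv")
    evidence = pd.read_csv(args.cohort / "read_evidence.tsv", sep="\t")
    db = GermlineDB.from_tsv(args.cohort / "germline_db.tsv")

    result = postprocess_variants(variants, samples, panel, evidence, db)
    report = result["report"]
    report.to_csv(args.outdir / "curated_variants.tsv", sep="\t", index=False)
    result["blacklist"].provenance.to_csv(args.outdir / "blacklist.tsv",
                                          sep="\t", index=False)

    print(f"input calls: {result['n_input']}")
    print(f"  primer-only removed: {len(result['primer_only'])}, "
          f"off-target: {len(result['off_target'])}")
    print(f"  blacklist sites: {len(result['blacklist'])}")
    print(f"curated report: {len(report)} records")
    by_origin = report["origin"].value_counts().to_dict()
    print(f"  by origin: {by_origin}")
    masked = report[~report["expressed"].astype(bool)]
    if len(masked):
        print(f"  calls silenced by upstream phased frameshift: "
              f"{len(masked)} ({masked['gene'].tolist()})")
    top = report.groupby("gene").size().sort_values(ascending=False).head(5)
    print("  most-affected genes: "
          + ", ".join(f"{g} ({n})" for g, n in top.items()))


if __name__ == "__main__":
    main()
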