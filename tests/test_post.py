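"""Primer exclusion, blacklist, germline discrimination, phasing,
strand-bias rescue and report filtering."""

import numpy as np
import pandas as pd
import pytest

from panelpost.panel import Amplicon, PanelDefinition
from panelpost.post import (
    Blacklist,
    CooccurrenceCounts,
    GermlineDB,
    build_blacklist,
    bundled_curated_table,
    discriminate_germline,
    exclude_primer_evidence,
    filter_report,
    phase_fraction,
    strand_bias_rescue,
)
from panelpost.qc import VariantCall


def _variant_frame(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "af", "depth"]
    )


class TestPhaseFraction:
    @pytest.mark.parametrize(
        "counts,expected_frac,expected_phased",
        [
            ((200, 0, 0), 1.0, True),
            ((0, 100, 100), 0.0, False),
            ((85, 10, 5), 0.85, False),  # below the 0.9 threshold
            ((95, 3, 2), 0.95, True),
        ],
    )
    def test_examples(self, counts, expected_frac, expected_phased):
        c = CooccurrenceCounts("a", "b", *counts)
        frac, phased = phase_fraction(c)
        assert frac == pytest.approx(expected_frac)
        assert phased is expected_phased

    def test_no_mutant_reads_is_undefined(self):
        frac, phased = phase_fraction(CooccurrenceCounts("a", "b", 0, 0, 0, 500))
        assert np.isnan(frac) and not phased

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            CooccurrenceCounts("a", "b", -1, 0, 0)


class TestPrimerExclusion:
    @pytest.fixture
    def two_amp_panel(self):
        # amplicon 2 overlaps amplicon 1's 3' primer region
        return PanelDefinition([
            Amplicon("A1", "chr1", 100, 250, 25, 25, "G1"),
            Amplicon("A2", "chr1", 220, 370, 25, 25, "G1"),
        ])

    def test_primer_only_position_removed(self, two_amp_panel):
        df = _variant_frame([("S", "chr1", 110, "C", "T", 0.1, 100)])
        kept, primer_only, off = exclude_primer_evidence(df, two_amp_panel)
        assert len(kept) == 0 and len(primer_only) == 1

    def test_mid_insert_retained(self, two_amp_panel):
        df = _variant_frame([("S", "chr1", 180, "C", "T", 0.1, 100)])
        kept, primer_only, off = exclude_primer_evidence(df, two_amp_panel)
        assert len(kept) == 1

    def test_primer_of_one_amplicon_but_insert_of_another_retained(
        self, two_amp_panel
    ):
        # 245 is in A1's reverse primer (226-250) but inside A2's insert
        df = _variant_frame([("S", "chr1", 245, "C", "T", 0.1, 100)])
        kept, primer_only, off = exclude_primer_evidence(df, two_amp_panel)
        assert len(kept) == 1

    def test_off_target_logged_not_raised(self, two_amp_panel):
        df = _variant_frame([("S", "chr9", 5, "C", "T", 0.1, 100)])
        kept, primer_only, off = exclude_primer_evidence(df, two_amp_panel)
        assert len(off) == 1 and len(kept) == 0


class TestBlacklist:
    @staticmethod
    def _cohort(site_carriers, af=0.03, n_samples=26):
        rows = []
        for i in range(site_carriers):
            rows.append((f"S{i:02d}", "chr1", 500, "C", "T", af, 1000))
        # background singleton so every sample id exists
        for i in range(n_samples):
            rows.append((f"S{i:02d}", "chr2", 100 + i, "G", "A", 0.02, 1000))
        return _variant_frame(rows)

    def test_recurrent_low_af_site_blacklisted(self):
        bl = build_blacklist(self._cohort(10), n_samples=26)
        assert ("chr1", 500, "C", "T") in bl

    def test_singleton_not_blacklisted(self):
        bl = build_blacklist(self._cohort(1), n_samples=26)
        assert ("chr1", 500, "C", "T") not in bl

    def test_recurrent_high_af_routed_to_germline_candidates(self):
        bl = build_blacklist(self._cohort(20, af=0.45), n_samples=26)
        assert ("chr1", 500, "C", "T") not in bl
        assert ("chr1", 500, "C", "T") in bl.germline_candidates

    def test_membership_invariant_to_record_order(self):
        df = self._cohort(12)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert build_blacklist(df, n_samples=26).entries == build_blacklist(
            shuffled, n_samples=26
        ).entries

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            build_blacklist(self._cohort(2, n_samples=2), n_samples=2)


class TestGermlineDiscrimination:
    @pytest.fixture
    def db(self):
        return GermlineDB.bundled_synthetic()

    def test_common_population_variant_is_germline(self, db):
        assert discriminate_germline(("chr4", 2000150, "A", "T"), db) == "germline"

    def test_cosmic_hotspot_absent_from_population_is_somatic(self, db):
        assert discriminate_germline(("chr12", 2000160, "G", "T"), db) == "somatic"

    def test_rare_non_cosmic_variant_is_ambiguous(self, db):
        # 0.5% population frequency, dbSNP only: surfaced, not auto-resolved
        assert discriminate_germline(("chr11", 2000140, "T", "C"), db) == "ambiguous"

    def test_absent_from_db_treated_as_frequency_zero(self, db):
        assert discriminate_germline(("chrZ", 1, "A", "C"), db) == "ambiguous"


class TestStrandBiasRescue:
    @pytest.fixture
    def amplicon(self):
        return Amplicon("A", "chr7", 1000, 1400, 24, 24, "EGFR")

    def _ins(self, pos, length):
        return VariantCall(sample_id="S", chrom="chr7", pos=pos, ref="A",
                           alt="A" + "T" * length, af=0.2, depth=500)

    def test_long_insertion_near_amplicon_end_rescued(self, amplicon):
        # 18 bp insertion 138 bp from the 3' end; 150 bp reads end inside it
        v = self._ins(amplicon.end - 138, 18)
        assert strand_bias_rescue(v, amplicon, read_length=150) is True

    def test_snv_never_rescued(self, amplicon):
        v = VariantCall(sample_id="S", chrom="chr7", pos=1200, ref="C",
                        alt="T", af=0.2, depth=500, fwd_alt=50, rev_alt=48)
        assert strand_bias_rescue(v, amplicon) is False

    def test_insertion_far_inside_read_not_rescued(self, amplicon):
        # 10 bp from the end: reads clear the insertion in early cycles
        # (10 + 18 = 28 < 150 - 20, the geometric rule says no rescue)
        v = self._ins(amplicon.end - 10, 18)
        assert strand_bias_rescue(v, amplicon, read_length=150) is False


class TestFilterReport:
    @staticmethod
    def _samples(sample_ids, cutoff=0.025, degraded=False):
        return pd.DataFrame(
            dict(sample_id=list(sample_ids), af_cutoff=cutoff,
                 degraded=degraded)
        )

    def test_curated_table_fixture_passthrough(self):
        table = bundled_curated_table()
        samples = self._samples(table["sample_id"].unique())
        report = filter_report(table, samples, target_genes=set(table["gene"]))
        assert len(report) == len(table) == 25
        assert (report["gene"] == "TP53").sum() == 11
        assert report["af"].max() == pytest.approx(0.82)
        assert report["af"].min() == pytest.approx(0.04)

    def test_idempotent_on_own_output(self):
        table = bundled_curated_table()
        samples = self._samples(table["sample_id"].unique())
        once = filter_report(table, samples, target_genes=set(table["gene"]))
        twice = filter_report(once, samples, target_genes=set(table["gene"]))
        pd.testing.assert_frame_equal(once, twice)

    def test_threshold_logic_per_sample_cutoff(self):
        df = _variant_frame([("S1", "chr1", 10, "G", "A", 0.04, 1000)])
        df["gene"] = "AKT1"
        kept = filter_report(df, self._samples(["S1"], cutoff=0.025),
                             target_genes={"AKT1"})
        dropped = filter_report(df, self._samples(["S1"], cutoff=0.05),
                                target_genes={"AKT1"})
        assert len(kept) == 1 and len(dropped) == 0

    def test_non_target_gene_uses_ten_percent_floor(self):
        df = _variant_frame([
            ("S1", "chr1", 10, "G", "A", 0.04, 1000),
            ("S1", "chr1", 20, "G", "A", 0.12, 1000),
        ])
        df["gene"] = "GNAS"
        report = filter_report(df, self._samples(["S1"]), target_genes={"EGFR"})
        assert report["pos"].tolist() == [20]

    def test_blacklisted_site_dropped(self):
        df = _variant_frame([("S1", "chr1", 10, "C", "T", 0.3, 1000)])
        df["gene"] = "EGFR"
        bl = Blacklist(entries={("chr1", 10, "C", "T")},
                       provenance=pd.DataFrame())
        report = filter_report(df, self._samples(["S1"]), blacklist=bl,
                               target_genes={"EGFR"})
        assert len(report) == 0

    def test_non_recurrent_call_only_in_degraded_sample_dropped(self):
        df = _variant_frame([
            ("S1", "chr1", 10, "C", "T", 0.15, 1000),
            ("S2", "chr1", 99, "G", "A", 0.15, 1000),
        ])
        df["gene"] = "EGFR"
        samples = pd.DataFrame(
            dict(sample_id=["S1", "S2"], af_cutoff=0.025,
                 degraded=[True, False])
        )
        report = filter_report(df, samples, target_genes={"EGFR"})
        assert report["sample_id"].tolist() == ["S2"]

    def test_empty_input_gives_empty_report(self):
        report = filter_report(_variant_frame([]), self._samples(["S1"]))
        assert len(report) == 0

    def test_missing_cutoff_directs_to_qc(self):
        df = _variant_frame([("S1", "chr1", 10, "C", "T", 0.3, 1000)])
        with pytest.raises(ValueError, match="QC"):
            filter_report(df, pd.DataFrame(dict(sample_id=["S1"])))
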