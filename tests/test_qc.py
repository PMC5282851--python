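"""Spectrum QC, rank correlation, Fisher enrichment and AF cutoffs,
checked against independent brute-force oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from panelpost.qc import (
    SPECTRUM_CLASSES,
    ArtifactAFModel,
    LambdaFit,
    SampleMeta,
    SpectrumTable,
    classify_substitution,
    collapse_class,
    concentration_correlation,
    enrichment_test,
    estimate_cutoff,
    fit_artifact_rate,
    flag_degraded,
    spectrum_by_af,
)

# ---------------------------------------------------------------------------
# oracles


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by enumerating every 2x2 table with the
    observed margins, summing the probabilities of tables no more likely
    than the observed one (integer arithmetic, no scipy)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = table_prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def spearman_exact_oracle(x, y):
    """Rho via the classic 1 - 6*sum(d^2)/(n(n^2-1)) formula (distinct
    values only) and a two-sided p from the full permutation null."""
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    rho = 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
    hits = 0
    perms = list(itertools.permutations(ry))
    for perm in perms:
        r = 1 - 6 * np.sum((rx - np.array(perm)) ** 2) / (n * (n**2 - 1))
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / len(perms)


# ---------------------------------------------------------------------------


class TestClassification:
    @pytest.mark.parametrize(
        "ref,alt,raw,collapsed",
        [
            ("C", "T", "C>T", "C:G>T:A"),
            ("G", "A", "G>A", "C:G>T:A"),
            ("A", "C", "A>C", "T:A>G:C"),
            ("AT", "A", "indel", "indel"),
            ("AT", "GC", "mnv", "mnv"),
        ],
    )
    def test_examples(self, ref, alt, raw, collapsed):
        assert classify_substitution(ref, alt) == raw
        assert collapse_class(raw) == collapsed

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_substitution("", "A")

    def test_strand_symmetric_collapse_pairs_all_twelve(self):
        from panelpost.qc import COLLAPSED

        assert len(COLLAPSED) == 12
        assert len(set(COLLAPSED.values())) == 6


class TestSpectrum:
    @staticmethod
    def _frame(afs, ref="C", alt="T"):
        return pd.DataFrame(
            dict(sample_id="S", chrom="chr1", pos=range(1, len(afs) + 1),
                 ref=ref, alt=alt, af=afs, depth=1000)
        )

    def test_counting_into_half_open_bins(self):
        table = spectrum_by_af(self._frame([0.02, 0.05, 0.15]), (0, 0.10, 1.0))
        assert table.counts.loc["C>T"].tolist() == [2, 1]
        assert table.total == 3

    def test_boundary_af_lands_in_lower_bin(self):
        table = spectrum_by_af(self._frame([0.10]), (0, 0.10, 1.0))
        assert table.counts.loc["C>T"].tolist() == [1, 0]

    def test_empty_input_gives_zero_table(self):
        table = spectrum_by_af(self._frame([]))
        assert table.total == 0

    def test_af_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="AF outside"):
            spectrum_by_af(self._frame([1.5]))

    def test_pure_low_bin_class_proportion_is_one(self):
        table = spectrum_by_af(self._frame([0.01] * 10))
        assert table.class_proportion(["C>T"], table.bin_labels[0]) == 1.0

    @given(
        afs=st.lists(st.floats(0.001, 1.0), min_size=1, max_size=60),
        edges=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=5, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_totals_conserved_for_any_edges(self, afs, edges):
        all_edges = tuple([0.0] + sorted(edges) + [1.0])
        table = spectrum_by_af(self._frame(afs), all_edges)
        assert table.total == len(afs)


class TestConcentrationCorrelation:
    def test_perfect_monotone_decrease(self):
        rho, p = concentration_correlation([1, 2, 3, 4, 5, 6], [60, 50, 40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_matches_exhaustive_permutation_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [10, 8, 9, 5, 1]
        rho, p = concentration_correlation(x, y)
        rho_o, p_o = spearman_exact_oracle(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_on_random_orderings(self, perm):
        x = list(range(1, 7))
        y = [p + 1 for p in perm]
        if all(a == b for a, b in zip(y, sorted(y))):
            return  # rho exactly 1: both paths trivially agree
        rho, p = concentration_correlation(x, y)
        rho_o, p_o = spearman_exact_oracle(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_constant_input_returns_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = concentration_correlation([2, 2, 2], [1, 2, 3])
        assert math.isnan(rho) and math.isnan(p)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.random(26)
        y = -x + rng.normal(0, 0.2, 26)
        rho, p = concentration_correlation(x, y)
        assert rho < -0.5 and p < 1e-3


class TestFlagDegraded:
    @staticmethod
    def _cohort(high_counts, concs=None):
        n = len(high_counts)
        concs = concs or [3.0] * n
        samples = pd.DataFrame(
            dict(sample_id=[f"S{i:02d}" for i in range(n)],
                 pre_norm_conc_ng_ul=concs)
        )
        rows = []
        for sid, k in zip(samples["sample_id"], high_counts):
            for j in range(k):
                rows.append(dict(sample_id=sid, chrom="chr1", pos=j + 1,
                                 ref="C", alt="T", af=0.15, depth=1000))
        variants = pd.DataFrame(
            rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "af", "depth"]
        )
        return samples, variants

    def test_burden_outliers_flagged_exactly(self):
        counts = [8, 17, 40, 56] + [2, 1, 0, 2, 1, 0, 2, 1, 0, 2, 1, 0, 2, 1,
                                    0, 2, 1, 0, 2, 1, 0, 2]
        samples, variants = self._cohort(counts)
        out = flag_degraded(samples, variants)
        assert out.loc[out["degraded"], "sample_id"].tolist() == [
            "S00", "S01", "S02", "S03"
        ]

    def test_uniform_cohort_unflagged(self):
        samples, variants = self._cohort([3] * 10)
        assert not flag_degraded(samples, variants)["degraded"].any()

    def test_low_concentration_flags_even_without_burden(self):
        samples, variants = self._cohort([0] * 6, concs=[1.4, 3, 3, 3, 3, 3])
        out = flag_degraded(samples, variants)
        assert out["degraded"].tolist() == [True] + [False] * 5
        assert out.loc[0, "degraded_reason"] == "low_concentration"


class TestEnrichment:
    @staticmethod
    def _table(per_class):
        counts = pd.DataFrame(0, index=SPECTRUM_CLASSES, columns=["lo", "hi"],
                              dtype=int)
        for cls, (a, b) in per_class.items():
            counts.loc[cls] = [a, b]
        return SpectrumTable(bin_edges=(0, 0.1, 1.0), counts=counts)

    def test_extreme_table_closed_form(self):
        # one class entirely in the low bin, the rest entirely high:
        # 2x2 is [[10,0],[0,10]], two-sided p = 2/C(20,10)
        spec = self._table({"C>T": (10, 0), "A>C": (0, 10)})
        res = enrichment_test(spec, "lo", "hi").set_index("substitution")
        assert res.loc["C>T", "p"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_table_is_null(self):
        spec = self._table({"C>T": (5, 5), "A>C": (5, 5)})
        res = enrichment_test(spec, "lo", "hi").set_index("substitution")
        assert res.loc["C>T", "odds_ratio"] == pytest.approx(1.0)
        assert res.loc["C>T", "p"] == pytest.approx(1.0)

    def test_empty_margin_gives_p_one(self):
        spec = self._table({"C>T": (3, 0), "A>C": (5, 0)})
        res = enrichment_test(spec, "lo", "hi").set_index("substitution")
        assert res.loc["C>T", "p"] == 1.0
        assert math.isnan(res.loc["C>T", "odds_ratio"])

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8),
        c=st.integers(0, 8), d=st.integers(0, 8),
    )
    @settings(max_examples=80, deadline=None)
    def test_matches_enumeration_oracle_on_small_tables(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        spec = self._table({"C>T": (a, b), "A>C": (c, d)})
        res = enrichment_test(spec, "lo", "hi").set_index("substitution")
        assert res.loc["C>T", "p"] == pytest.approx(
            fisher_two_sided_oracle(a, b, c, d), rel=1e-7
        )

    def test_bh_correction_is_monotone(self):
        spec = self._table(
            {"C>T": (40, 2), "G>A": (30, 5), "A>C": (10, 10), "T>G": (9, 11)}
        )
        res = enrichment_test(spec, "lo", "hi")
        assert (res["q"] >= res["p"] - 1e-12).all()


class TestCutoffs:
    def test_zero_burden_falls_to_clinical_floor(self):
        s = SampleMeta("S1", pre_norm_conc=5.0)
        fit = LambdaFit(intercept=-50.0, slope=0.0)  # lambda ~ 0
        assert estimate_cutoff(s, fit) == 0.025
        assert estimate_cutoff(s, fit, category="response") == 0.05

    def test_cutoff_monotone_in_concentration(self):
        fit = LambdaFit(intercept=5.0, slope=-1.0)
        low = estimate_cutoff(SampleMeta("a", 1.0), fit)
        high = estimate_cutoff(SampleMeta("b", 8.0), fit)
        assert low >= high

    def test_cutoff_equals_numeric_quantile_inversion(self):
        model = ArtifactAFModel()
        fit = LambdaFit(intercept=float(np.log(200.0)), slope=0.0)
        cutoff = estimate_cutoff(SampleMeta("S", 2.0), fit, af_model=model)
        # independent inversion: smallest f with 200 * sf(f) = 1
        f_star = brentq(lambda f: 200 * model.sf(f) - 1.0, 1e-6, 0.1 - 1e-9)
        assert cutoff == pytest.approx(max(0.025, f_star), abs=1e-6)

    def test_degenerate_concentrations_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_artifact_rate([2.0, 2.0, 2.0], [10, 12, 8])
        assert fit.constant
        assert fit.predict(1.0) == pytest.approx(10.0)

    def test_regression_recovers_negative_slope(self):
        rng = np.random.default_rng(1)
        conc = np.geomspace(1, 12, 22)
        lam = np.exp(5.0 - 1.0 * np.log(conc))
        counts = rng.poisson(lam)
        fit = fit_artifact_rate(conc, counts)
        assert fit.slope == pytest.approx(-1.0, abs=0.15)
        assert fit.intercept == pytest.approx(5.0, abs=0.25)
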