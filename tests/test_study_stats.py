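"""Descriptive and nonparametric statistics of the longitudinal feature table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chewtex import (
    DegenerateInputError,
    build_report,
    descriptives,
    friedman,
    mann_whitney,
    report_tables,
    wilcoxon_signed_rank,
)
from chewtex.study_stats import validate_table


class TestDescriptives:
    def test_constant_sample(self):
        d = descriptives([2, 2, 2])
        assert d["mean"] == 2 and d["sd"] == 0 and d["median"] == 2 and d["iqr"] == 0

    def test_symmetric_sample(self):
        d = descriptives([1, 2, 3, 4])
        assert d["mean"] == 2.5 and d["median"] == 2.5

    def test_iqr_linear_interpolation(self):
        assert descriptives([1, 2, 3, 4, 5])["iqr"] == 2.0

    def test_single_value_sd_is_nan(self):
        assert np.isnan(descriptives([7.0])["sd"])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            descriptives([])


class TestFriedman:
    def test_identical_columns_carry_no_information(self):
        r = friedman(np.ones((5, 3)))
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_consistent_ordering_statistic(self):
        r = friedman(np.array([[1, 2, 3], [4, 5, 6], [1, 5, 9]]))
        assert r.statistic == pytest.approx(6.0)

    def test_matches_scipy_on_tie_free_data(self):
        from scipy.stats import friedmanchisquare

        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 4))
        mine = friedman(x)
        ref = friedmanchisquare(*x.T)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mode_matches_enumeration(self, seed, friedman_oracle):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        x[0, 1] = x[0, 0]  # inject a tie
        assert friedman(x, method="exact").p_value == pytest.approx(
            friedman_oracle(x), abs=1e-12
        )

    def test_incomplete_blocks_rejected_with_cells(self):
        x = np.ones((3, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            friedman(x)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            friedman(np.ones((1, 3)))


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        r = wilcoxon_signed_rank([1, 2, 3])
        assert r.statistic == 6.0
        assert r.p_value == pytest.approx(0.25)

    def test_antisymmetric_tied_pair(self):
        assert wilcoxon_signed_rank([-1, 1]).p_value == pytest.approx(1.0)

    def test_zeros_dropped(self):
        r = wilcoxon_signed_rank([0, 0, 1, 2, 3])
        assert r.n == 3 and r.p_value == pytest.approx(0.25)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_exact_matches_enumeration_with_ties(self, seed, wilcoxon_oracle):
        rng = np.random.default_rng(seed)
        d = np.round(rng.normal(0.4, 1.0, size=10), 1)  # rounding creates ties
        d = d[d != 0]
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_oracle(d), abs=1e-12
        )

    def test_exact_matches_scipy_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(15)
        d = rng.normal(0.5, 1.0, size=12)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            scipy_wilcoxon(d, method="exact").pvalue
        )

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(16)
        d = rng.normal(0.3, 1.0, size=60)
        r = wilcoxon_signed_rank(d)
        assert r.method == "wilcoxon-normal"
        assert 0.0 <= r.p_value <= 1.0


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_give_central_u(self):
        a = [1.0, 2.0, 3.0]
        r = mann_whitney(a, a)
        assert r.statistic == pytest.approx(len(a) ** 2 / 2)

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_exact_matches_enumeration(self, seed, mannwhitney_oracle):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(0.8, 1.0, size=5)
        assert mann_whitney(a, b).p_value == pytest.approx(
            mannwhitney_oracle(a, b), abs=1e-12
        )

    def test_ties_switch_to_corrected_normal(self):
        r = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert r.method == "mannwhitney-normal"
        assert 0.0 <= r.p_value <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRankInvariance:
    @given(st.integers(0, 10_000))
    def test_tests_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(6, 3))
        transform = lambda v: np.exp(3 * v) - 1  # strictly increasing

        f1, f2 = friedman(x), friedman(transform(x))
        assert f1.p_value == pytest.approx(f2.p_value, abs=1e-12)

        a, b = rng.normal(size=5), rng.normal(size=6)
        m1, m2 = mann_whitney(a, b), mann_whitney(transform(a), transform(b))
        assert m1.p_value == pytest.approx(m2.p_value, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_wilcoxon_invariant_to_scaling(self, seed):
        # signed ranks depend on |d|, so the invariance is to odd monotone maps
        rng = np.random.default_rng(seed)
        d = rng.normal(0.2, 1.0, size=8)
        d = d[d != 0]
        w1 = wilcoxon_signed_rank(d)
        w2 = wilcoxon_signed_rank(np.sign(d) * np.abs(d) ** 1.7)
        assert w1.p_value == pytest.approx(w2.p_value, abs=1e-12)


def synthetic_table(seed=0, n_subjects=5, effect=0.0) -> pd.DataFrame:
    """Numbers-only feature table: no images involved."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for i, t in enumerate(("T0", "T1", "T2")):
            for side in ("upper", "lower"):
                for rep in (1, 2):
                    base = rng.normal(0, 1) - effect * i
                    rows.append(
                        {
                            "subject": f"S{s}",
                            "time": t,
                            "side": side,
                            "replicate": rep,
                            "uniformity": rng.normal(0.003, 0.0005),
                            "contrast": 2.5 + base,
                            "homogeneity": rng.normal(0.55, 0.02),
                            "entropy": rng.normal(6.2, 0.1),
                            "voh": abs(rng.normal(0.08, 0.03)),
                        }
                    )
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_report_structure_complete(self):
        rep = build_report(synthetic_table())
        assert set(rep["variables"]) == {
            "uniformity",
            "contrast",
            "homogeneity",
            "entropy",
            "voh",
        }
        entry = rep["variables"]["contrast"]["upper"]
        assert set(entry["descriptives"]) == {"T0", "T1", "T2"}
        assert set(entry["pairwise_wilcoxon"]) == {"T0-T1", "T0-T2", "T1-T2"}
        assert set(rep["variables"]["contrast"]["side_comparison"]) == {"T0", "T1", "T2"}

    def test_descriptives_use_replicates_as_rows(self):
        tab = synthetic_table()
        rep = build_report(tab)
        d = rep["variables"]["entropy"]["lower"]["descriptives"]["T1"]
        sel = tab[(tab.side == "lower") & (tab.time == "T1")]["entropy"]
        assert d["n"] == len(sel) == 10  # 5 subjects x 2 replicates
        assert d["mean"] == pytest.approx(sel.mean())

    def test_strong_effect_detected(self):
        rep = build_report(synthetic_table(seed=1, n_subjects=10, effect=1.5))
        e = rep["variables"]["contrast"]["upper"]
        assert e["friedman"]["p_value"] < 0.05
        assert e["pairwise_wilcoxon"]["T0-T2"]["p_value"] < 0.05

    def test_single_subject_rejected(self):
        tab = synthetic_table(n_subjects=1)
        with pytest.raises(ValueError):
            build_report(tab)

    def test_missing_cell_reported_with_context(self):
        tab = synthetic_table()
        tab = tab[~((tab.subject == "S2") & (tab.time == "T1"))]
        with pytest.raises(ValueError, match="S2"):
            build_report(tab)

    def test_tables_flatten_report(self):
        rep = build_report(synthetic_table())
        desc, pairs = report_tables(rep)
        assert len(desc) == 5 * 2 * 3  # variables x sides x times
        assert len(pairs) == 5 * 2 * 3  # variables x sides x time pairs
        assert {"friedman_p", "side_comparison_p"} <= set(desc.columns)

    def test_validate_table_catches_missing_columns_and_duplicates(self):
        tab = synthetic_table()
        with pytest.raises(ValueError, match="voh"):
            validate_table(tab.drop(columns=["voh"]))
        dup = pd.concat([tab, tab.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_table(dup)


class TestSimulatedStudyPower:
    def test_improving_profile_detected_in_most_replicates(self, lowres_spec):
        """An improving chewer cohort should light up Friedman and the
        T0-vs-T2 Wilcoxon on contrast in nearly every simulated study."""
        from chewtex.cli import simulate_feature_table
        from chewtex.synthetic import IMPROVING_PROFILE

        friedman_hits = wilcoxon_hits = 0
        n_rep = 50
        for r in range(n_rep):
            tab = simulate_feature_table(
                8, IMPROVING_PROFILE, seed=7_000 + r, spec=lowres_spec
            )
            rep = build_report(tab)
            e = rep["variables"]["contrast"]["upper"]
            friedman_hits += e["friedman"]["p_value"] < 0.05
            wilcoxon_hits += e["pairwise_wilcoxon"]["T0-T2"]["p_value"] < 0.05
        assert friedman_hits >= 0.8 * n_rep
        assert wilcoxon_hits >= 0.9 * n_rep
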