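"""Variance decomposition, reliability coefficients and subgroup fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdosim.varcomp import (
    VarianceComponents,
    fit_variance_components,
    reliability_coefficients,
    reliability_to_shares,
    simulate_observations,
    subgroup_analysis,
)


def ems_oracle(obs: pd.DataFrame):
    """Closed-form expected-mean-squares solution for a balanced design.

    Independent of the package implementation: plain sums of squares.
    """
    a = obs["lesion_id"].nunique()
    b = obs["reader_id"].nunique()
    n = obs["round"].nunique()
    grand = obs["value"].mean()
    ms_lesion = (
        b * n * ((obs.groupby("lesion_id")["value"].mean() - grand) ** 2).sum() / (a - 1)
    )
    cell = obs.groupby(["lesion_id", "reader_id"])["value"].mean()
    lesion_mean = obs.groupby("lesion_id")["value"].mean()
    ss_r = sum(
        (cell[(l, r)] - lesion_mean[l]) ** 2
        for l in lesion_mean.index
        for r in obs["reader_id"].unique()
    )
    ms_reader = n * ss_r / (a * (b - 1))
    resid = obs["value"] - obs.set_index(["lesion_id", "reader_id"]).index.map(cell)
    ms_err = (resid**2).sum() / (a * b * (n - 1))
    return (
        (ms_lesion - ms_reader) / (b * n),
        (ms_reader - ms_err) / n,
        ms_err,
    )


def balanced_toy():
    """3 lesions x 2 readers x 2 rounds with hand-built values."""
    rows = []
    base = {"L1": 10.0, "L2": 20.0, "L3": 35.0}
    bias = {("L1", "A"): 1.0, ("L1", "B"): -1.0, ("L2", "A"): 2.0,
            ("L2", "B"): 0.5, ("L3", "A"): -1.5, ("L3", "B"): 1.0}
    noise = iter([0.3, -0.3, 0.1, -0.1, 0.5, -0.5, 0.2, -0.2, 0.4, -0.4, 0.6, -0.6])
    for lid in base:
        for reader in ("A", "B"):
            for rnd in (1, 2):
                rows.append(
                    {
                        "lesion_id": lid,
                        "reader_id": reader,
                        "round": rnd,
                        "value": base[lid] + bias[(lid, reader)] + next(noise),
                    }
                )
    return pd.DataFrame(rows)


class TestFitVarianceComponents:
    def test_identical_reads_per_lesion(self):
        obs = pd.DataFrame(
            {
                "lesion_id": ["L1"] * 4 + ["L2"] * 4,
                "reader_id": ["A", "A", "B", "B"] * 2,
                "round": [1, 2, 1, 2] * 2,
                "value": [5.0] * 4 + [9.0] * 4,
            }
        )
        vc = fit_variance_components(obs, method="mom")
        assert vc.sigma2_inter == 0.0
        assert vc.sigma2_intra == 0.0
        assert vc.sigma2_lesion > 0.0

    def test_all_values_identical(self):
        obs = pd.DataFrame(
            {
                "lesion_id": ["L1"] * 4 + ["L2"] * 4,
                "reader_id": ["A", "A", "B", "B"] * 2,
                "round": [1, 2, 1, 2] * 2,
                "value": [7.0] * 8,
            }
        )
        vc = fit_variance_components(obs)
        assert vc.sigma2_total == 0.0

    def test_balanced_toy_matches_ems_oracle(self):
        obs = balanced_toy()
        expect = ems_oracle(obs)
        vc = fit_variance_components(obs, method="mom")
        assert vc.sigma2_lesion == pytest.approx(max(expect[0], 0), abs=1e-10)
        assert vc.sigma2_inter == pytest.approx(max(expect[1], 0), abs=1e-10)
        assert vc.sigma2_intra == pytest.approx(max(expect[2], 0), abs=1e-10)

    def test_reml_close_to_mom_on_balanced_design(self):
        obs = simulate_observations(
            50, {"A": 2, "B": 2, "C": 2}, (100.0, 9.0, 4.0), seed=1
        )
        reml = fit_variance_components(obs, method="reml")
        mom = fit_variance_components(obs, method="mom")
        for attr in ("sigma2_lesion", "sigma2_inter", "sigma2_intra"):
            assert getattr(reml, attr) == pytest.approx(getattr(mom, attr), rel=0.01)

    def test_single_seed_recovery_unbalanced(self):
        obs = simulate_observations(80, {"A": 3, "B": 3, "C": 1}, (100.0, 9.0, 4.0), seed=3)
        vc = fit_variance_components(obs)
        assert vc.sigma2_lesion == pytest.approx(100.0, rel=0.5)
        assert vc.sigma2_inter == pytest.approx(9.0, rel=0.5)
        assert vc.sigma2_intra == pytest.approx(4.0, rel=0.5)

    def test_inter_share_monotone_in_simulated_sigma(self):
        shares = []
        for s2_inter in (1.0, 9.0, 36.0):
            vals = []
            for seed in range(20):
                obs = simulate_observations(
                    40, {"A": 3, "B": 3, "C": 1}, (100.0, s2_inter, 4.0), seed=seed
                )
                rel = reliability_coefficients(fit_variance_components(obs))
                vals.append(rel.inter_share_pct)
            shares.append(np.mean(vals))
        assert shares[0] < shares[1] < shares[2]

    def test_no_repeated_rounds_rejected(self):
        obs = pd.DataFrame(
            {
                "lesion_id": ["L1", "L1", "L2", "L2"],
                "reader_id": ["A", "B", "A", "B"],
                "round": [1, 1, 1, 1],
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="sigma2_intra not estimable"):
            fit_variance_components(obs)

    def test_log_scale(self):
        obs = balanced_toy()
        vc = fit_variance_components(obs, method="mom", log_scale=True)
        assert vc.sigma2_total > 0
        obs.loc[0, "value"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            fit_variance_components(obs, log_scale=True)


class TestReliability:
    def test_arithmetic_example(self):
        rel = reliability_coefficients(VarianceComponents(9.0, 0.5, 0.5))
        assert rel.rho_inter == pytest.approx(0.90)
        assert rel.rho_intra == pytest.approx(0.95)
        assert rel.inter_share_pct == pytest.approx(50.0)
        assert rel.intra_share_pct == pytest.approx(50.0)

    def test_no_observer_variance(self):
        rel = reliability_coefficients(VarianceComponents(4.2, 0.0, 0.0))
        assert rel.rho_inter == 1.0 and rel.rho_intra == 1.0
        assert np.isnan(rel.inter_share_pct)

    @pytest.mark.parametrize(
        "rho_intra, rho_inter, expected",
        [
            (0.992, 0.967, 75.8),  # volume, all lesions
            (0.995, 0.987, 61.5),  # mean dose without RC, all lesions
            (0.818, 0.754, 26.0),  # mean dose with RC, all lesions
        ],
    )
    def test_shares_from_published_icc_pairs(self, rho_intra, rho_inter, expected):
        inter, intra = reliability_to_shares(rho_intra, rho_inter)
        assert inter == pytest.approx(expected, abs=0.05)
        assert inter + intra == pytest.approx(100.0)

    def test_equal_rhos_give_zero_share(self):
        assert reliability_to_shares(0.9, 0.9)[0] == 0.0

    def test_rho_inter_one_rejected(self):
        with pytest.raises(ValueError):
            reliability_to_shares(1.0, 1.0)

    @settings(derandomize=True, deadline=None, max_examples=60)
    @given(
        s2l=st.floats(0.01, 100.0),
        s2b=st.floats(0.001, 50.0),
        s2e=st.floats(0.001, 50.0),
    )
    def test_share_roundtrip_identity(self, s2l, s2b, s2e):
        """reliability_to_shares inverts reliability_coefficients on shares."""
        rel = reliability_coefficients(VarianceComponents(s2l, s2b, s2e))
        inter, intra = reliability_to_shares(rel.rho_intra, rel.rho_inter)
        assert inter == pytest.approx(rel.inter_share_pct, rel=1e-6, abs=1e-6)
        assert rel.rho_intra >= rel.rho_inter


class TestSubgroups:
    def test_all_subset_equals_global(self):
        obs = simulate_observations(10, {"A": 2, "B": 2}, (50.0, 4.0, 2.0), seed=2)
        global_fit = fit_variance_components(obs)
        tab = subgroup_analysis(obs, {"all": [True] * len(obs)})
        assert tab.loc[0, "sigma2_lesion"] == pytest.approx(global_fit.sigma2_lesion)

    def test_partition_covers_all(self):
        obs = simulate_observations(10, {"A": 2, "B": 2}, (50.0, 4.0, 2.0), seed=2)
        small = obs["lesion_id"].isin([f"L{i:03d}" for i in range(1, 6)])
        tab = subgroup_analysis(obs, {"small": small, "large": ~small})
        assert tab["n_obs"].sum() == len(obs)

    def test_outlier_exclusion_flips_share_ordering(self):
        """One erratic reader on one lesion can flip inter vs intra dominance."""
        obs = simulate_observations(12, {"A": 3, "B": 3, "C": 1}, (100.0, 16.0, 1.0), seed=5)
        vc_clean = fit_variance_components(obs)
        rel_clean = reliability_coefficients(vc_clean)
        assert rel_clean.inter_share_pct > 50.0
        # corrupt lesion L001: reader A wildly inconsistent across rounds
        bad = obs.copy()
        sel = (bad["lesion_id"] == "L001") & (bad["reader_id"] == "A")
        bad.loc[sel, "value"] += np.array([-60.0, 0.0, 60.0])
        rel_bad = reliability_coefficients(fit_variance_components(bad))
        assert rel_bad.intra_share_pct > 50.0
        # excluding the constructed outlier restores inter-dominance
        tab = subgroup_analysis(bad, {"excl": bad["lesion_id"] != "L001"})
        assert tab.loc[0, "inter_share_pct"] > 50.0

    def test_degenerate_subset_named(self):
        obs = simulate_observations(4, {"A": 2}, (50.0, 4.0, 2.0), seed=2)
        sel = obs["lesion_id"] == "L001"
        with pytest.raises(ValueError, match="tiny"):
            subgroup_analysis(obs, {"tiny": sel})
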