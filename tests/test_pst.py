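"""P_ST variance components, sensitivity curve and critical ratio."""

import numpy as np
import pandas as pd
import pytest

import invadiv as iv
from invadiv.pst import critical_ratio
from invadiv.simulate import PhenotypeSimConfig, simulate_phenotypes


def balanced_frame(site_values: dict[str, list[float]], covariate=None):
    rows = []
    for site, vals in site_values.items():
        for i, v in enumerate(vals):
            row = dict(individual=f"{site}_{i}", site=site, sex="m", trait=v)
            if covariate is not None:
                row["body_length"] = covariate[site][i]
            rows.append(row)
    return pd.DataFrame(rows)


class TestVarianceComponents:
    def test_effective_group_size_unbalanced(self):
        rng = np.random.default_rng(0)
        frame = balanced_frame(
            {"a": rng.normal(0, 1, 2).tolist(),
             "b": rng.normal(0, 1, 4).tolist(),
             "c": rng.normal(0, 1, 6).tolist()}
        )
        vc = iv.variance_components(frame, "trait", covariate=None)
        assert vc.n0 == pytest.approx((12 - 56 / 12) / 2, abs=1e-3)

    def test_component_extraction_matches_statsmodels(self, rng):
        from oracles import anova_components_statsmodels

        frame = balanced_frame(
            {f"s{i}": (rng.normal(i * 0.5, 1.0, 10)).tolist() for i in range(3)}
        )
        vc = iv.variance_components(frame, "trait", covariate=None)
        among, within = anova_components_statsmodels(
            frame["trait"].to_numpy(), frame["site"].to_numpy()
        )
        assert vc.sigma2_b_raw == pytest.approx(among, abs=1e-10)
        assert vc.sigma2_w == pytest.approx(within, abs=1e-10)

    def test_equal_site_means_truncated_to_zero(self, rng):
        noise = rng.normal(0, 1, 30)
        frame = balanced_frame(
            {f"s{i}": (noise[10 * i:10 * i + 10] - noise[10 * i:10 * i + 10].mean()).tolist()
             for i in range(3)}
        )
        vc = iv.variance_components(frame, "trait", covariate=None)
        assert vc.sigma2_b == 0.0
        assert vc.sigma2_b_raw <= 0.0

    def test_covariate_adjustment_removes_shared_slope(self, rng):
        cov = {f"s{i}": rng.normal(15, 1, 20).tolist() for i in range(4)}
        frame = balanced_frame(
            {f"s{i}": [0.0] * 20 for i in range(4)}, covariate=cov
        )
        frame["trait"] = 3.0 * frame["body_length"] + rng.normal(0, 0.1, len(frame))
        vc = iv.variance_components(frame, "trait", covariate="body_length")
        assert vc.sigma2_w == pytest.approx(0.01, abs=0.01)

    def test_covariate_equal_to_trait_rejected(self):
        frame = balanced_frame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError, match="differ"):
            iv.variance_components(frame, "trait", covariate="trait")


class TestPstValue:
    def test_closed_forms(self):
        vc = iv.VarianceComponents(
            "t", None, 1.0, 1.0, 1.0, 3, [10, 10, 10], 10.0, 12.0, 2.0, 2, 27
        )
        assert iv.pst_value(vc, 1.0) == pytest.approx(1 / 3)
        assert iv.pst_value(vc, 0.0) == 0.0
        vc_nw = iv.VarianceComponents(
            "t", None, 1.0, 0.0, 1.0, 3, [10, 10, 10], 10.0, 12.0, 0.0, 2, 27
        )
        assert iv.pst_value(vc_nw, 0.5) == 1.0

    def test_monotone_in_ratio(self):
        vc = iv.VarianceComponents(
            "t", None, 0.7, 2.0, 0.7, 4, [5] * 4, 5.0, 5.0, 2.0, 3, 16
        )
        vals = [iv.pst_value(vc, r) for r in np.linspace(0, 2, 21)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestCriticalRatio:
    def test_grid_inversion_against_fst_bound(self):
        # lower bound x/(x+2) crosses 0.046 at x = 0.0965 -> grid 0.10
        ratios = np.round(np.arange(0, 2.0001, 0.01), 10)
        lower = ratios / (ratios + 2.0)
        assert critical_ratio(ratios, lower, 0.046) == pytest.approx(0.10)

    def test_absent_when_never_exceeds(self):
        ratios = np.arange(0, 2.01, 0.01)
        assert critical_ratio(ratios, np.zeros_like(ratios), 0.046) is None


class TestPstSensitivity:
    def _pheno(self, seed, sigma2_b=1.0):
        cfg = PhenotypeSimConfig(
            sites=[f"s{i}" for i in range(6)], n_per_site=25, sexes=("m",),
            traits={"tarsus": 19.0}, sigma2_b=sigma2_b, sigma2_w=2.0, seed=seed,
        )
        return simulate_phenotypes(cfg)[0]

    def test_curve_monotone_and_consistent_with_critical(self):
        curve = iv.pst_sensitivity(
            self._pheno(1), "tarsus", sex=None, fst_interval=(0.016, 0.046),
            covariate=None, seed=0,
        )
        assert np.all(np.diff(curve.pst) >= -1e-12)
        above = curve.lower > curve.fst_interval[1]
        if curve.critical_ratio is not None:
            idx = int(np.flatnonzero(curve.ratios == curve.critical_ratio)[0])
            assert above[idx:].all()
            assert not above[:idx].any()

    def test_zero_between_variance_curve_identically_zero(self, rng):
        noise = rng.normal(0, 1, 60)
        frame = balanced_frame(
            {f"s{i}": (noise[20 * i:20 * i + 20]
                       - noise[20 * i:20 * i + 20].mean()).tolist()
             for i in range(3)}
        )
        curve = iv.pst_sensitivity(
            frame, "trait", sex=None, fst_interval=(0.016, 0.046),
            covariate=None, seed=0,
        )
        assert np.all(curve.pst == 0.0)
        assert curve.critical_ratio is None

    def test_scale_invariance(self):
        pheno = self._pheno(3)
        c1 = iv.pst_sensitivity(
            pheno, "tarsus", None, (0.016, 0.046), covariate=None, seed=0
        )
        scaled = pheno.copy()
        scaled["tarsus"] = scaled["tarsus"] * 4.2
        c2 = iv.pst_sensitivity(
            scaled, "tarsus", None, (0.016, 0.046), covariate=None, seed=0
        )
        assert np.allclose(c1.pst, c2.pst, atol=1e-10)

    def test_inflating_between_variance_lowers_critical_ratio(self):
        crits = []
        for s2b in (0.5, 4.0):
            cs = []
            for seed in range(5):
                curve = iv.pst_sensitivity(
                    self._pheno(seed, sigma2_b=s2b), "tarsus", None,
                    (0.016, 0.046), covariate=None, seed=0,
                )
                cs.append(2.5 if curve.critical_ratio is None else curve.critical_ratio)
            crits.append(np.median(cs))
        assert crits[1] <= crits[0]

    def test_bootstrap_method_runs_and_brackets_point(self):
        curve = iv.pst_sensitivity(
            self._pheno(5), "tarsus", None, (0.016, 0.046), covariate=None,
            grid_step=0.5, n_boot=100, seed=2, ci_method="bootstrap",
        )
        assert np.all(curve.lower <= curve.pst + 1e-12)
        assert np.all(curve.upper >= curve.pst - 1e-12)
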