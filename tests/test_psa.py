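"""Probabilistic sensitivity analysis: sampling, CEAC, confidence ellipse."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mibcsim as m
from mibcsim.psa import DEFAULT_WTP_GRID, PsaResult


def synthetic_result(d_qaly, d_cost, wtp=100_000.0):
    samples = pd.DataFrame({"d_qaly": np.asarray(d_qaly, dtype=float),
                            "d_cost": np.asarray(d_cost, dtype=float)})
    return PsaResult(reference="RC", comparator="TMT", samples=samples,
                     parameter_draws=pd.DataFrame(index=samples.index),
                     n=len(samples), seed=0, horizon_years=5.0, wtp=wtp)


@pytest.fixture(scope="module")
def psa_result(models, calibrated):
    return m.run_psa(models, calibrated, n=4_000, seed=20)


class TestRunPsa:
    def test_seeded_bit_reproducibility(self, models, calibrated):
        a = m.run_psa(models, calibrated, n=300, seed=5)
        b = m.run_psa(models, calibrated, n=300, seed=5)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.parameter_draws, b.parameter_draws)
        c = m.run_psa(models, calibrated, n=300, seed=6)
        assert not a.samples.equals(c.samples)

    def test_all_fixed_collapses_to_base_case(self, models, calibrated):
        entries = {k: replace(p, distribution="fixed") for k, p in calibrated.entries.items()}
        ps = replace(calibrated, entries=entries)
        res = m.run_psa(models, ps, n=25, seed=1)
        base_rc = m.evaluate_cohort(models[0], calibrated, want_trace=False)
        assert np.allclose(res.samples["cost_RC"], base_rc.total_cost)
        assert np.allclose(res.samples["qaly_RC"], base_rc.total_qaly)
        assert res.samples.nunique()["d_cost"] == 1

    def test_draws_respect_distribution_supports(self, psa_result, calibrated):
        for key in psa_result.parameter_draws.columns:
            col = psa_result.parameter_draws[key].to_numpy()
            kind = calibrated[key].kind
            if kind in {"probability", "utility", "toll_disutility"}:
                assert ((col >= 0) & (col <= 1)).all()
            else:
                assert (col >= 0).all()

    def test_psa_means_approach_base_case_as_variance_shrinks(self, models, calibrated):
        entries = {}
        for k, p in calibrated.entries.items():
            if p.is_fixed:
                entries[k] = p
            else:
                w = (p.high - p.low) * 0.005
                entries[k] = replace(p, low=max(p.base - w, 0.0), high=p.base + w)
        tight = replace(calibrated, entries=entries)
        res = m.run_psa(models, tight, n=800, seed=2)
        base = m.evaluate_cohort(models[1], calibrated, want_trace=False)
        assert res.samples["cost_TMT"].mean() == pytest.approx(base.total_cost, rel=0.01)
        assert res.samples["qaly_TMT"].mean() == pytest.approx(base.total_qaly, rel=0.01)


class TestCeac:
    def test_fractions_normalised_on_default_grid(self, psa_result):
        curves = m.ceac(psa_result)
        assert len(curves) == len(DEFAULT_WTP_GRID)
        total = curves["RC"] + curves["TMT"]
        assert np.allclose(total, 1.0, atol=1e-12)
        assert ((curves[["RC", "TMT"]] >= 0) & (curves[["RC", "TMT"]] <= 1)).all().all()

    def test_degenerate_dominant_comparator(self):
        res = synthetic_result(d_qaly=[0.5, 0.4, 0.3], d_cost=[-10.0, -5.0, -1.0])
        curves = m.ceac(res, np.array([0.0, 50_000.0]))
        assert (curves["TMT"] == 1.0).all()

    def test_wtp_zero_counts_strictly_cheaper_draws(self, psa_result):
        curves = m.ceac(psa_result, np.array([0.0]))
        d_cost = psa_result.samples["d_cost"]
        expected = (d_cost < 0).mean() + 0.5 * (d_cost == 0).mean()
        assert curves["TMT"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_ties_split_equally(self):
        res = synthetic_result(d_qaly=[0.0, 0.0], d_cost=[0.0, 0.0])
        curves = m.ceac(res, np.array([100_000.0]))
        assert curves["TMT"].iloc[0] == 0.5

    def test_empty_grid_rejected(self, psa_result):
        with pytest.raises(ValueError):
            m.ceac(psa_result, np.array([]))

    def test_matches_scatter_quadrant_tally_at_threshold(self, psa_result):
        """The CEAC value at the WTP threshold equals the NMB tally of the
        scatter draws — the acceptability curve and the plane agree."""
        curves = m.ceac(psa_result, np.array([psa_result.wtp]))
        acc = psa_result.acceptability()
        assert curves["TMT"].iloc[0] == pytest.approx(acc["TMT"], abs=1e-12)

    def test_sampling_error_shrinks_with_n(self, models, calibrated):
        """CEAC at the threshold moves by O(1/sqrt(n)) when n quadruples."""
        small = m.run_psa(models, calibrated, n=2_000, seed=31)
        large = m.run_psa(models, calibrated, n=8_000, seed=32)
        p_small = small.acceptability()["TMT"]
        p_large = large.acceptability()["TMT"]
        p = (p_small + p_large) / 2
        bound = 4 * np.sqrt(p * (1 - p) * (1 / 2_000 + 1 / 8_000))
        assert abs(p_small - p_large) <= bound


class TestConfidenceEllipse:
    def test_identity_covariance_axes(self):
        """Sample covariance whitened to the identity: both semi-axes equal
        sqrt(chi2_{2,0.95}) = sqrt(5.991) ~ 2.448."""
        rng = np.random.default_rng(0)
        xy = rng.normal(size=(4_000, 2))
        xy -= xy.mean(axis=0)
        chol = np.linalg.cholesky(np.cov(xy, rowvar=False))
        xy = xy @ np.linalg.inv(chol).T  # exact identity sample covariance
        res = synthetic_result(xy[:, 0], xy[:, 1])
        ell = m.confidence_ellipse(res, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))
        assert ell.semi_axes[0] == pytest.approx(expected, abs=1e-9)
        assert ell.semi_axes[1] == pytest.approx(expected, abs=1e-9)
        assert not ell.degenerate

    def test_degenerate_point_cloud_flagged(self):
        res = synthetic_result([0.1] * 10, [5.0] * 10)
        ell = m.confidence_ellipse(res)
        assert ell.degenerate
        assert ell.semi_axes == pytest.approx((0.0, 0.0), abs=1e-8)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(scale=3.0, size=2_000)
        y = 0.5 * x + rng.normal(scale=1.0, size=2_000)
        a = m.confidence_ellipse(synthetic_result(x, y))
        b = m.confidence_ellipse(synthetic_result(-y, x))  # rotate 90 degrees
        assert a.semi_axes == pytest.approx(b.semi_axes, rel=1e-9)
        assert (b.angle_deg - a.angle_deg) % 180 == pytest.approx(90.0, abs=1e-6)

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            m.confidence_ellipse(synthetic_result([1.0, 2.0], [1.0, 2.0]))

    def test_centered_on_sample_mean(self, psa_result):
        ell = m.confidence_ellipse(psa_result)
        assert ell.center[0] == pytest.approx(psa_result.samples["d_qaly"].mean())
        assert ell.center[1] == pytest.approx(psa_result.samples["d_cost"].mean())


class TestPlots:
    def test_plot_files_written(self, psa_result, models, calibrated, tmp_path):
        from mibcsim.psa import ceac_plot, scatter_plot
        from mibcsim.sensitivity import tornado, tornado_plot, two_way, two_way_plot

        scatter_plot(psa_result, tmp_path / "scatter.png")
        ceac_plot(m.ceac(psa_result), tmp_path / "ceac.png")
        frame = tornado(models, calibrated, keys=["c_tmt_initial", "c_rc_initial"])
        tornado_plot(frame, tmp_path / "tornado.png")
        res = m.two_way(models, calibrated, "c_tmt_initial", "c_rc_initial", n_x=5, n_y=5)
        two_way_plot(res, tmp_path / "two_way.png")
        for name in ("scatter.png", "ceac.png", "tornado.png", "two_way.png"):
            assert (tmp_path / name).stat().st_size > 0
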