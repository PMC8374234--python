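"""DMR fitting engine: bounds, both steps, averaging and the model-order sweep."""

import numpy as np
import pytest

from ecapdeconv import (
    CDLDParams,
    FitConfig,
    GaussComponent,
    PUBLISHED_HUMAN_UR,
    STEP1_START_UR,
    SyntheticSpec,
    TimeGrid,
    URParams,
    average_urs,
    cdld_param_names,
    fit_step_one,
    fit_step_two,
    forward_ecap,
    model_order_sweep,
    preprocess,
    simulate_batch,
    step_one_bounds,
    step_two_bounds,
)
from ecapdeconv.fitting import UR_PARAM_NAMES
from ecapdeconv.models import _forward_values

GRID = TimeGrid(0.0, 2.2, 0.005)


def make_ecap(cdld: CDLDParams, ur: URParams = PUBLISHED_HUMAN_UR, noise=0.0, seed=0):
    w = forward_ecap(cdld, ur, GRID)
    if noise:
        rng = np.random.default_rng(seed)
        w = w.with_values(
            w.values + rng.normal(0, noise * np.max(np.abs(w.values)), w.n)
        )
    return preprocess(w.with_values(w.values, label="test"))


class TestBoundsTables:
    def test_step_one_printed_domain(self):
        b = step_one_bounds()
        assert b.lower["u_n"] == 0.02 and b.upper["u_n"] == 0.25
        assert b.lower["t0"] == -0.25 and b.upper["t0"] == 0.06
        assert b.lower["mu1"] == 0.04 and b.upper["mu1"] == 1.3
        assert b.start["u_n"] == 0.12 and b.start["sigma_n"] == 0.045
        assert b.start["mu2"] == 0.5 and b.start["sigma2"] == 0.14

    def test_step_two_printed_domain(self):
        b = step_two_bounds(2)
        assert b.lower["mu1"] == 0.15 and b.upper["mu1"] == 1.35
        assert b.upper["alpha2"] == 0.35 and b.upper["sigma2"] == 0.45
        assert b.start["mu1"] == 0.59 and b.start["mu2"] == 0.6

    def test_bounds_replicate_for_higher_k(self):
        b = step_two_bounds(4)
        assert b.lower["mu4"] == 0.15 and b.upper["sigma4"] == 0.45
        assert set(cdld_param_names(4)) == set(b.start)

    def test_start_outside_bounds_rejected(self):
        from ecapdeconv import ParamBounds

        with pytest.raises(ValueError, match="outside"):
            ParamBounds(lower={"a": 0.0}, upper={"a": 1.0}, start={"a": 2.0})


class TestAverageUrs:
    def test_single_ur_is_identity(self):
        assert average_urs([PUBLISHED_HUMAN_UR]) == PUBLISHED_HUMAN_UR

    def test_parameterwise_mean(self):
        a = URParams(0.10, 0.03, 0.02, 0.1, -0.1)
        b = URParams(0.20, 0.05, 0.04, 0.2, -0.2)
        m = average_urs([a, b])
        assert m.u_n == pytest.approx(0.15)
        assert m.sigma_n == pytest.approx(0.04)
        assert m.t0 == pytest.approx(-0.15)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            average_urs([])


class TestStepOne:
    def test_self_consistency_recovery(self):
        """A noiseless eCAP generated at the starting UR with an in-bounds,
        window-contained CDLD is refit nearly perfectly."""
        cdld = CDLDParams(
            [GaussComponent(0.08, 0.38, 0.05), GaussComponent(0.05, 0.65, 0.08)]
        )
        ecap = make_ecap(cdld, ur=STEP1_START_UR)
        res = fit_step_one(ecap)
        assert res.fit_index >= 0.999
        assert res.converged

    def test_flat_input_rejected(self):
        flat = forward_ecap(
            CDLDParams([GaussComponent(0.0, 0.5, 0.1)]), PUBLISHED_HUMAN_UR, GRID
        )
        with pytest.raises(ValueError, match="degenerate eCAP"):
            fit_step_one(flat)

    def test_parameters_within_bounds(self):
        cdld = CDLDParams(
            [GaussComponent(0.1, 0.45, 0.06), GaussComponent(0.07, 0.8, 0.12)]
        )
        res = fit_step_one(make_ecap(cdld, noise=0.02))
        b = step_one_bounds()
        vec = np.concatenate([res.ur.as_array(), res.cdld.as_array()])
        lo, hi, _ = b.arrays(UR_PARAM_NAMES + cdld_param_names(2))
        assert np.all(vec >= lo - 1e-12) and np.all(vec <= hi + 1e-12)


class TestStepTwo:
    def test_noiseless_parameter_recovery(self):
        """Well-separated components with healthy amplitudes are recovered
        to better than 1% each."""
        truth = CDLDParams(
            [GaussComponent(0.12, 0.45, 0.05), GaussComponent(0.08, 0.95, 0.1)]
        )
        res = fit_step_two(make_ecap(truth), PUBLISHED_HUMAN_UR)
        rel = np.abs(res.cdld.as_array() - truth.as_array()) / truth.as_array()
        assert np.all(rel < 0.01)
        assert res.fit_index > 0.999

    def test_fixed_ur_echoed(self):
        truth = CDLDParams(
            [GaussComponent(0.12, 0.45, 0.05), GaussComponent(0.08, 0.95, 0.1)]
        )
        res = fit_step_two(make_ecap(truth), PUBLISHED_HUMAN_UR)
        assert res.ur == PUBLISHED_HUMAN_UR

    def test_components_sorted_and_nonnegative(self):
        truth = CDLDParams(
            [GaussComponent(0.3, 1.0, 0.08), GaussComponent(0.2, 0.35, 0.04)]
        )
        res = fit_step_two(make_ecap(truth, noise=0.01), PUBLISHED_HUMAN_UR)
        mus = [c.mu for c in res.cdld.components]
        assert mus == sorted(mus)
        assert all(c.alpha >= 0 for c in res.cdld.components)

    def test_bound_compliance_on_noise_fuzz(self):
        """Fits of pure-noise-corrupted waveforms stay inside the box."""
        rng = np.random.default_rng(42)
        lo, hi, _ = step_two_bounds(2).arrays(cdld_param_names(2))
        cfg = FitConfig(refine_on_poor_fit=False, max_iterations=60)
        for _ in range(4):
            truth = CDLDParams(
                [
                    GaussComponent(rng.uniform(0.05, 0.35), rng.uniform(0.3, 1.2), rng.uniform(0.02, 0.2)),
                    GaussComponent(rng.uniform(0.05, 0.35), rng.uniform(0.3, 1.2), rng.uniform(0.02, 0.2)),
                ]
            )
            res = fit_step_two(
                make_ecap(truth, noise=0.2, seed=int(rng.integers(1 << 30))),
                PUBLISHED_HUMAN_UR,
                cfg,
            )
            vec = res.cdld.as_array()
            assert np.all(vec >= lo - 1e-12) and np.all(vec <= hi + 1e-12)

    def test_monotone_noise_degradation(self):
        """Median fit index decreases as relative noise SD grows."""
        medians = []
        cfg = FitConfig(refine_on_poor_fit=False)
        for noise in (0.005, 0.05, 0.2):
            spec = SyntheticSpec(seed=11, n_waveforms=6, noise_sd_rel=noise)
            fis = [
                fit_step_two(preprocess(w), spec.ur, cfg).fit_index
                for w, _ in simulate_batch(spec)
            ]
            medians.append(np.median(fis))
        assert medians[0] > medians[1] > medians[2]

    def test_grid_search_equivalence(self):
        """On a single-component problem the DMR optimum matches an
        exhaustive grid search of the same objective within one cell."""
        truth = CDLDParams([GaussComponent(0.12, 0.52, 0.09)])
        ecap = make_ecap(truth)
        grid = TimeGrid.of(ecap)
        alphas = np.linspace(0.02, 0.35, 12)
        mus = np.linspace(0.15, 1.35, 25)
        sigmas = np.linspace(0.02, 0.45, 22)
        best, best_cost = None, np.inf
        for a in alphas:
            for m in mus:
                for s in sigmas:
                    r = _forward_values(np.array([a, m, s]), PUBLISHED_HUMAN_UR, grid) - ecap.values
                    c = float(r @ r)
                    if c < best_cost:
                        best, best_cost = (a, m, s), c
        res = fit_step_two(ecap, PUBLISHED_HUMAN_UR, k=1)
        fitted = res.cdld.as_array()
        cell = np.array([np.diff(alphas)[0], np.diff(mus)[0], np.diff(sigmas)[0]])
        assert np.all(np.abs(fitted - np.array(best)) <= cell)


class TestModelOrderSweep:
    truth = CDLDParams(
        [GaussComponent(0.15, 0.4, 0.05), GaussComponent(0.1, 0.95, 0.09)]
    )

    def test_residual_non_increasing_in_k(self):
        ecap = make_ecap(self.truth, noise=0.01)
        sweep = model_order_sweep(ecap, PUBLISHED_HUMAN_UR, k_range=range(1, 7))
        r = [sweep[k].residual_norm for k in sorted(sweep)]
        assert all(r[i + 1] <= r[i] * (1 + 1e-9) + 1e-12 for i in range(len(r) - 1))

    def test_bimodal_gain_from_second_component(self):
        """On a clearly bimodal noiseless eCAP the K=1 -> K=2 relative
        residual reduction exceeds 50%."""
        ecap = make_ecap(self.truth)
        sweep = model_order_sweep(ecap, PUBLISHED_HUMAN_UR, k_range=[1, 2])
        red = 1 - sweep[2].residual_norm / sweep[1].residual_norm
        assert red > 0.5

    def test_empty_k_range_rejected(self):
        ecap = make_ecap(self.truth)
        with pytest.raises(ValueError):
            model_order_sweep(ecap, PUBLISHED_HUMAN_UR, k_range=[])
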