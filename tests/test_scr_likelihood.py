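import math

import numpy as np
import pytest

import packscr as p
from packscr.scr_likelihood import _suffstats
from conftest import make_traps


# ---------------------------------------------------------------------------
# Independent brute-force oracle: plain-Python enumeration over mask points
# ---------------------------------------------------------------------------


def brute_kernel(d, sigma, detfn):
    return math.exp(-d * d / (2 * sigma * sigma)) if detfn == "HN" else math.exp(-d / sigma)


def brute_prob(d, level, sigma, detfn, param):
    # -expm1(-x), not 1-exp(-x): the identity is exact and avoids
    # cancellation for the tiny encounter rates at distant mask points
    k = brute_kernel(d, sigma, detfn)
    return level * k if param == "direct" else -math.expm1(-level * k)


def brute_history_prob(y_i, s, traps_xy, act, sigma, base, post, detfn, param, response):
    prob = 1.0
    for j, (tx, ty) in enumerate(traps_xy):
        d = math.hypot(s[0] - tx, s[1] - ty)
        seen = False
        for k in range(act.shape[1]):
            if act[j, k] == 0:
                continue
            level = post if (seen and response) else base
            pp = brute_prob(d, level, sigma, detfn, param)
            prob *= pp if y_i[j, k] else 1.0 - pp
            if y_i[j, k]:
                seen = True
    return prob


def brute_marginal_loglik(y, traps_xy, act, mask_pts, cell_km2, sigma, base, post,
                          detfn, param, response, D):
    P = len(mask_pts)
    n = len(y)
    pdots = []
    for s in mask_pts:
        p0 = 1.0
        for j, (tx, ty) in enumerate(traps_xy):
            d = math.hypot(s[0] - tx, s[1] - ty)
            pp = brute_prob(d, base, sigma, detfn, param)
            p0 *= (1.0 - pp) ** int(act[j].sum())
        pdots.append(1.0 - p0)
    pbar = sum(pdots) / P
    A = P * cell_km2
    mu = D * A / 100.0 * pbar
    ll = n * math.log(mu) - mu - math.lgamma(n + 1)
    for i in range(n):
        marg = sum(
            brute_history_prob(y[i], s, traps_xy, act, sigma, base, post,
                               detfn, param, response)
            for s in mask_pts
        ) / P
        ll += math.log(marg) - math.log(pbar)
    return ll


def random_instance(rng, response):
    """Random tiny SCR instance: <=3 traps, <=3 occasions, <=6 mask points."""
    J = int(rng.integers(1, 4))
    K = int(rng.integers(1, 4))
    P = int(rng.integers(2, 7))
    n = int(rng.integers(1, 4))
    traps_xy = rng.normal(0, 2000, size=(J, 2))
    mask_pts = rng.normal(0, 3000, size=(P, 2))
    act = (rng.random((J, K)) < 0.8).astype(np.int8)
    act[rng.integers(0, J), :] = 1  # at least one fully active trap
    for j in range(J):
        if act[j].sum() == 0:
            act[j, rng.integers(0, K)] = 1
    y = (rng.random((n, J, K)) < 0.4).astype(np.int8) * act[None, :, :]
    for i in range(n):  # every animal needs >=1 capture at an active slot
        if y[i].sum() == 0:
            j = int(rng.integers(0, J))
            k = int(np.flatnonzero(act[j])[0])
            y[i, j, k] = 1
    sigma = float(rng.uniform(800, 4000))
    base = float(rng.uniform(0.05, 0.6))
    post = float(rng.uniform(0.05, 0.6)) if response else None
    D = float(rng.uniform(0.5, 5.0))
    return y, traps_xy, act, mask_pts, sigma, base, post, D


class TestKernel:
    def test_closed_forms(self):
        assert p.kernel(2400.0, 2400.0, "HN") == pytest.approx(math.exp(-0.5))
        assert p.kernel(2400.0, 2400.0, "NE") == pytest.approx(math.exp(-1.0))
        assert p.kernel(0.0, 1000.0, "HN") == 1.0
        assert p.kernel(0.0, 1000.0, "NE") == 1.0

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20000, 50)
        for detfn in ("HN", "NE"):
            k = p.kernel(d, 2400.0, detfn)
            assert (np.diff(k) < 0).all()

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            p.kernel(-1.0, 1000.0, "HN")


class TestEncounterProb:
    def test_direct_at_zero_is_g0(self):
        spec = p.ModelSpec("HN", None, "direct")
        params = p.DetectionParams(sigma=2428.0, g0=0.1162)
        assert p.encounter_prob(0.0, params, spec) == pytest.approx(0.1162)

    def test_cloglog_at_zero(self):
        spec = p.ModelSpec("HN", None, "cloglog")
        params = p.DetectionParams(sigma=2424.0, lambda0=0.1220)
        expected = 1.0 - math.exp(-0.1220)
        assert p.encounter_prob(0.0, params, spec) == pytest.approx(expected)
        assert round(float(p.encounter_prob(0.0, params, spec)), 4) == 0.1149

    def test_vanishes_at_infinity(self):
        spec = p.ModelSpec("NE", None, "cloglog")
        params = p.DetectionParams(sigma=2400.0, lambda0=0.5)
        assert p.encounter_prob(1e9, params, spec) == pytest.approx(0.0, abs=1e-12)

    def test_cloglog_bounded_by_linear(self):
        """1 - exp(-x) <= x: cloglog probability never exceeds lambda0*kernel."""
        d = np.linspace(0, 10000, 200)
        spec = p.ModelSpec("HN", None, "cloglog")
        for lam in (0.01, 0.12, 1.5):
            params = p.DetectionParams(sigma=2400.0, lambda0=lam)
            pc = p.encounter_prob(d, params, spec)
            assert (pc <= lam * p.kernel(d, 2400.0, "HN") + 1e-12).all()

    def test_parameterizations_agree_to_first_order(self):
        d = np.linspace(0, 8000, 50)
        lam = 1e-4
        pc = p.encounter_prob(d, p.DetectionParams(sigma=2400.0, lambda0=lam),
                              p.ModelSpec("HN", None, "cloglog"))
        pd_ = p.encounter_prob(d, p.DetectionParams(sigma=2400.0, g0=lam),
                               p.ModelSpec("HN", None, "direct"))
        np.testing.assert_allclose(pc, pd_, rtol=1e-3)


class TestHistoryProb:
    def test_all_zero_and_single_capture(self):
        spec = p.ModelSpec("HN", None, "direct")
        # p = 0.5 at distance 0 with g0 = 0.5
        params = p.DetectionParams(sigma=1000.0, g0=0.5)
        y = np.zeros((1, 2), dtype=np.int8)
        prob = p.history_prob(y, np.array([0.0, 0.0]), np.array([[0.0, 0.0]]),
                              params, spec)
        assert prob == pytest.approx(0.25)
        y1 = np.array([[1]], dtype=np.int8)
        params2 = p.DetectionParams(sigma=1000.0, g0=0.3)
        assert p.history_prob(y1, np.array([0.0, 0.0]), np.array([[0.0, 0.0]]),
                              params2, spec) == pytest.approx(0.3)

    @pytest.mark.parametrize("response", [None, "TRAP"])
    @pytest.mark.parametrize("param", ["direct", "cloglog"])
    def test_matches_hand_enumeration(self, response, param):
        rng = np.random.default_rng(99)
        for _ in range(5):
            y, traps_xy, act, mask_pts, sigma, base, post, _ = random_instance(
                rng, response
            )
            spec = p.ModelSpec("HN", response, param)
            if param == "direct":
                params = p.DetectionParams(sigma=sigma, g0=base, g0_post=post)
            else:
                params = p.DetectionParams(sigma=sigma, lambda0=base, lambda0_post=post)
            s = mask_pts[0]
            got = p.history_prob(y[0], s, traps_xy, params, spec, act)
            want = brute_history_prob(y[0], s, traps_xy, act, sigma, base, post,
                                      "HN", param, response is not None)
            assert got == pytest.approx(want, rel=1e-12)


class TestSuffstats:
    def test_counts_reconstruct_totals(self):
        rng = np.random.default_rng(3)
        act = (rng.random((4, 6)) < 0.7).astype(np.int8)
        act[:, 0] = 1
        y = (rng.random((5, 4, 6)) < 0.4).astype(np.int8) * act[None, :, :]
        pre0, first, post1, post0, effort = _suffstats(y, act)
        Y = y.sum(axis=2)
        np.testing.assert_allclose(first + post1, Y)
        np.testing.assert_allclose(pre0 + post0, effort[None, :] - Y)

    def test_rejects_capture_at_inactive_slot(self):
        act = np.zeros((1, 2), dtype=np.int8)
        act[0, 1] = 1
        y = np.zeros((1, 1, 2), dtype=np.int8)
        y[0, 0, 0] = 1
        with pytest.raises(ValueError, match="inactive"):
            _suffstats(y, act)


class TestMarginalLoglik:
    @pytest.mark.parametrize("detfn", ["HN", "NE"])
    @pytest.mark.parametrize("param", ["direct", "cloglog"])
    @pytest.mark.parametrize("response", [None, "TRAP"])
    def test_equals_bruteforce_enumeration(self, detfn, param, response):
        combo = (
            ["HN", "NE"].index(detfn) * 4
            + ["direct", "cloglog"].index(param) * 2
            + int(response is not None)
        )
        rng = np.random.default_rng(7000 + combo)
        for _ in range(4):
            y, traps_xy, act, mask_pts, sigma, base, post, D = random_instance(
                rng, response
            )
            spec = p.ModelSpec(detfn, response, param)
            if param == "direct":
                params = p.DetectionParams(sigma=sigma, g0=base, g0_post=post)
            else:
                params = p.DetectionParams(sigma=sigma, lambda0=base, lambda0_post=post)
            hist = p.CaptureHistory(
                y=y, animal_ids=[f"A{i}" for i in range(len(y))],
                trap_ids=[f"T{j}" for j in range(len(traps_xy))],
            )
            traps = [
                p.TrapDeployment(f"T{j}", *traps_xy[j], act[j])
                for j in range(len(traps_xy))
            ]
            space = p.StateSpace(mask_pts, np.ones(len(mask_pts)), spacing_m=500.0)
            got = p.marginal_loglik(hist, space, traps, params, spec, D)
            want = brute_marginal_loglik(
                y, traps_xy, act, mask_pts, space.area_per_point_km2,
                sigma, base, post, detfn, param, response is not None, D,
            )
            assert got == pytest.approx(want, rel=1e-10)

    def test_inactive_padding_occasions_change_nothing(self):
        rng = np.random.default_rng(8)
        y, traps_xy, act, mask_pts, sigma, base, _, D = random_instance(rng, None)
        spec = p.ModelSpec("HN", None, "cloglog")
        params = p.DetectionParams(sigma=sigma, lambda0=base)
        space = p.StateSpace(mask_pts, np.ones(len(mask_pts)), 500.0)

        def build(yy, aa):
            hist = p.CaptureHistory(
                y=yy, animal_ids=[f"A{i}" for i in range(len(yy))],
                trap_ids=[f"T{j}" for j in range(len(traps_xy))],
            )
            traps = [
                p.TrapDeployment(f"T{j}", *traps_xy[j], aa[j])
                for j in range(len(traps_xy))
            ]
            return p.marginal_loglik(hist, space, traps, params, spec, D)

        ll1 = build(y, act)
        pad_y = np.concatenate([y, np.zeros_like(y)], axis=2)
        pad_act = np.concatenate([act, np.zeros_like(act)], axis=1)
        ll2 = build(pad_y, pad_act)
        assert ll2 == pytest.approx(ll1, rel=1e-12)

    def test_truth_beats_perturbed_sigma_on_simulated_data(self, design_2015_coarse):
        design, traps, mask = design_2015_coarse
        spec = p.ModelSpec("HN", None, "cloglog")
        wins = 0
        for seed in range(8):
            sc = p.study_scenario(seed=100 + seed, mask=mask)
            hist, truth = p.simulate(sc)
            at_truth = p.marginal_loglik(
                hist, mask, traps, sc.params, spec, sc.true_density
            )
            bad = p.DetectionParams(sigma=2 * sc.sigma, lambda0=sc.lambda0)
            at_bad = p.marginal_loglik(hist, mask, traps, bad, spec, sc.true_density)
            wins += at_truth > at_bad
        assert wins >= 7


class TestAicc:
    def test_arithmetic(self):
        assert p.aicc(-10.0, 3, 12) == pytest.approx(29.0)
        assert p.aicc(-10.0, 0, 12) == pytest.approx(20.0)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            p.aicc(-10.0, 3, 4)


class TestFitML:
    def test_single_animal_rejected(self, design_2015_coarse):
        design, traps, mask = design_2015_coarse
        y = np.zeros((1, len(traps), design.n_occasions), dtype=np.int8)
        y[0, 0, 0] = 1
        hist = p.CaptureHistory(y=y, animal_ids=["A1"],
                                trap_ids=[t.trap_id for t in traps])
        with pytest.raises(ValueError, match="at least 2"):
            p.fit_ml(hist, mask, traps, p.ModelSpec("HN", None, "cloglog"))

    def test_translation_invariance(self, simulated_2015):
        design, traps, mask, hist, _ = simulated_2015
        spec = p.ModelSpec("HN", None, "cloglog")
        fit1 = p.fit_ml(hist, mask, traps, spec, seed=1)
        shift = np.array([123456.0, -98765.0])
        traps2 = [
            p.TrapDeployment(t.trap_id, t.x + shift[0], t.y + shift[1], t.active)
            for t in traps
        ]
        mask2 = p.StateSpace(mask.points + shift, mask.habitat, mask.spacing_m)
        fit2 = p.fit_ml(hist, mask2, traps2, spec, seed=1)
        assert fit2.D_hat == pytest.approx(fit1.D_hat, rel=1e-4)
        assert fit2.params.sigma == pytest.approx(fit1.params.sigma, rel=1e-4)
        assert fit2.params.lambda0 == pytest.approx(fit1.params.lambda0, rel=1e-4)

    def test_fit_recovers_simulated_truth_roughly(self, simulated_2015):
        design, traps, mask, hist, truth = simulated_2015
        fit = p.fit_ml(hist, mask, traps, p.ModelSpec("HN", None, "cloglog"), seed=1)
        assert fit.converged
        assert 0.5 * truth.density < fit.D_hat < 2.0 * truth.density
        assert 0.7 * 2424 < fit.params.sigma < 1.3 * 2424
        lo, hi = fit.ci95["D"]
        assert lo < fit.D_hat < hi

    def test_hn_preferred_on_hn_data_by_aicc(self, simulated_2015):
        design, traps, mask, hist, _ = simulated_2015
        hn = p.fit_ml(hist, mask, traps, p.ModelSpec("HN", None, "cloglog"), seed=1)
        ne = p.fit_ml(hist, mask, traps, p.ModelSpec("NE", None, "cloglog"), seed=1)
        assert hn.aicc < ne.aicc
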