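"""Residualized lagged regression: oracles, peaks, maps, nulls."""
import numpy as np
import pytest

from tracklag.encoding import (
    TAU_MS,
    CollinearityError,
    EncodingProfile,
    Peak,
    PeakSet,
    TauGrid,
    _design_matrix,
    _local_max_indices,
    _profile_engine,
    build_firing_map,
    detect_peaks,
    match_peaks,
    regress_residuals,
    residualize_firing,
    restrict_inside_target,
    sensitivity,
    shuffle_null,
    temporal_profile,
)
from tracklag.preprocess import KinematicsSeries, RateSeries


from _oracles import brute_two_step as _brute_two_step, make_kin as _kin, make_rate as _rate


def test_tau_grid_shape():
    grid = TauGrid()
    assert len(grid.values) == 51
    assert grid.values[0] == -500 and grid.values[-1] == 500


@pytest.mark.parametrize(
    "pair,expected",
    [((3.0, 4.0), 5.0), ((0.0, 0.0), 0.0), ((-2.0, 2.0), 2.0 * np.sqrt(2.0))],
)
def test_sensitivity_euclidean_norm(pair, expected):
    assert sensitivity(pair) == pytest.approx(expected, abs=1e-12)


class TestResidualization:
    def test_firing_independent_of_nuisance_returns_centered_firing(self, rng):
        kins = [_kin(500, rng)]
        f = rng.normal(0.0, 1.0, 500)
        fr = residualize_firing([_rate(f)], kins, "PE", tau=0)
        # nuisance explains almost nothing: FR ≈ F − mean(F)
        assert np.corrcoef(fr, f - f.mean())[0, 1] > 0.98

    def test_firing_linear_in_nuisance_fully_removed(self, rng):
        kins = [_kin(100, rng)]
        f = 3.0 * kins[0].X - 1.0 * kins[0].VY + 2.0
        fr = residualize_firing([_rate(f)], kins, "PE", tau=0)
        np.testing.assert_allclose(fr, 0.0, atol=1e-10)

    def test_noiseless_target_coupling_recovered_exactly(self, rng):
        kins = [_kin(200, rng)]
        fr = 2.0 * kins[0].XE + 0.0 * kins[0].YE
        r2, betas = regress_residuals(fr, kins, "PE", tau=0)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert betas[0] == pytest.approx(2.0, abs=1e-9)
        assert betas[1] == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_residuals_have_negligible_r2(self, rng):
        kins = [_kin(400, rng)]
        r2, _ = regress_residuals(rng.normal(0, 1, 400), kins, "PE", tau=0)
        assert r2 < 0.05

    @pytest.mark.parametrize("tau", [-500, -220, -20, 0, 40, 500])
    @pytest.mark.parametrize("pair", ["PE", "position", "velocity"])
    def test_engine_matches_brute_force_normal_equations(self, rng, tau, pair):
        """On small multi-trial instances the Gram-based engine and the
        public two-step path both agree with an explicit normal-equations
        solve to 1e-8 relative tolerance."""
        kins = [_kin(60, rng), _kin(45, rng), _kin(80, rng)]
        rates = [_rate(rng.normal(0, 1.0, len(k))) for k in kins]
        fr_b, r2_b, betas_b = _brute_two_step(kins, rates, pair, tau)

        fr = residualize_firing(rates, kins, pair, tau)
        np.testing.assert_allclose(fr, fr_b, rtol=1e-8, atol=1e-10)
        r2, betas = regress_residuals(fr, kins, pair, tau)
        assert r2 == pytest.approx(r2_b, rel=1e-8, abs=1e-12)

        designs = [_design_matrix(k, pair) for k in kins]
        arrays = [r.rate for r in rates]
        i = int(np.where(TAU_MS == tau)[0][0])
        r2_e, b1_e, b2_e = _profile_engine(designs, arrays, pair, range(len(kins)))
        assert r2_e[i] == pytest.approx(r2_b, rel=1e-8, abs=1e-12)
        np.testing.assert_allclose([b1_e[i], b2_e[i]], betas_b, rtol=1e-7, atol=1e-10)

    def test_degenerate_target_variance_raises(self, rng):
        kins = [_kin(50, rng)]
        kins[0].XE[:] = 1.0
        with pytest.raises(CollinearityError, match="XE"):
            regress_residuals(rng.normal(0, 1, 50), kins, "PE", tau=0)

    def test_collinear_nuisance_names_columns(self, rng):
        kins = [_kin(80, rng)]
        kins[0].Y[:] = kins[0].X  # perfectly collinear pair
        rates = [_rate(rng.normal(0, 1, 80))]
        with pytest.raises(CollinearityError, match="X"):
            temporal_profile(rates, kins, "PE")


class TestProfiles:
    def test_r2_bounds_and_sensitivity_identity(self, rng):
        kins = [_kin(150, rng) for _ in range(3)]
        rates = [_rate(rng.normal(0, 1, 150)) for _ in range(3)]
        p = temporal_profile(rates, kins, "PE")
        assert np.all((p.r2 >= 0.0) & (p.r2 <= 1.0))
        np.testing.assert_allclose(
            p.sensitivity**2, p.beta1**2 + p.beta2**2, atol=1e-10
        )

    def test_time_reversal_mirrors_profile(self, rng):
        """Reversing both firing and behavior in time mirrors R²(τ)
        about τ = 0."""
        kins = [_kin(120, rng)]
        f = rng.normal(0, 1, 120) + 0.8 * np.roll(kins[0].XE, 3)
        p_fwd = temporal_profile([_rate(f)], kins, "PE")
        kin_rev = KinematicsSeries(
            t_ms=kins[0].t_ms,
            **{c: kins[0].column(c)[::-1].copy() for c in ("X", "Y", "VX", "VY", "XE", "YE")},
            inside_target=kins[0].inside_target[::-1].copy(),
        )
        p_rev = temporal_profile([_rate(f[::-1].copy())], [kin_rev], "PE")
        np.testing.assert_allclose(p_rev.r2, p_fwd.r2[::-1], atol=1e-10)


class TestShuffleNull:
    def test_deterministic_and_shaped(self, rng):
        kins = [_kin(80, rng) for _ in range(4)]
        rates = [_rate(rng.normal(0, 1, 80)) for _ in range(4)]
        a = shuffle_null(rates, kins, "PE", n_shuffles=20, seed=5)
        b = shuffle_null(rates, kins, "PE", n_shuffles=20, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        nm, nsd, thr = a
        np.testing.assert_allclose(thr, nm + 3 * nsd)
        assert len(nm) == 51

    def test_single_trial_rejected(self, rng):
        kins = [_kin(80, rng)]
        rates = [_rate(rng.normal(0, 1, 80))]
        with pytest.raises(ValueError):
            shuffle_null(rates, kins, "PE", n_shuffles=5, seed=0)


def _profile_with(r2, threshold):
    r2 = np.asarray(r2, float)
    n = len(TAU_MS)
    assert len(r2) == n
    p = EncodingProfile(
        parameter_pair="PE",
        tau_ms=TAU_MS.copy(),
        r2=r2,
        beta1=np.ones(n),
        beta2=np.ones(n),
        sensitivity=np.sqrt(2.0) * np.ones(n),
    )
    return p.attach_null(np.asarray(threshold, float), np.zeros(n))


class TestPeakDetection:
    def test_unimodal_lead_only(self):
        r2 = np.exp(-0.5 * ((TAU_MS + 100) / 60.0) ** 2)
        ps = detect_peaks(_profile_with(r2, np.full(51, 0.1)))
        assert ps.lead is not None and ps.lead.tau_ms == -100
        assert ps.lag is None

    def test_everything_below_threshold_is_empty(self):
        r2 = 0.05 * np.ones(51)
        r2[10] = 0.08
        ps = detect_peaks(_profile_with(r2, np.full(51, 0.5)))
        assert ps.lead is None and ps.lag is None

    def test_bimodal_profile_vs_exhaustive_scan(self, rng):
        """Random rough profiles: detection agrees with an independent
        exhaustive scan of all 51 τ values."""
        for _ in range(50):
            r2 = np.abs(rng.normal(0.1, 0.08, 51))
            thr = np.full(51, rng.uniform(0.05, 0.2))
            ps = detect_peaks(_profile_with(r2, thr))
            # oracle: scan all indices for strict local maxima
            best = {"lead": None, "lag": None}
            for i in range(51):
                left = r2[i - 1] < r2[i] if i > 0 else True
                right = r2[i + 1] < r2[i] if i < 50 else True
                if not (left and right) or TAU_MS[i] == 0 or r2[i] <= thr[i]:
                    continue
                side = "lead" if TAU_MS[i] < 0 else "lag"
                if best[side] is None or r2[i] > best[side][1]:
                    best[side] = (TAU_MS[i], r2[i])
            for side in ("lead", "lag"):
                got = getattr(ps, side)
                if best[side] is None:
                    assert got is None
                else:
                    assert got is not None and got.tau_ms == best[side][0]

    def test_example_bimodal(self):
        r2 = 0.02 * np.ones(51)
        i1 = int(np.where(TAU_MS == -120)[0][0])
        i2 = int(np.where(TAU_MS == 440)[0][0])
        r2[i1], r2[i2] = 0.4, 0.3
        ps = detect_peaks(_profile_with(r2, np.full(51, 0.1)))
        assert ps.lead.tau_ms == -120 and ps.lag.tau_ms == 440

    def test_plateau_broken_toward_smaller_abs_tau(self):
        r2 = np.zeros(51)
        i = int(np.where(TAU_MS == -200)[0][0])
        r2[i : i + 3] = 0.5  # plateau spanning -200, -180, -160
        ps = detect_peaks(_profile_with(r2, np.full(51, 0.1)))
        assert ps.lead.tau_ms == -160

    def test_requires_null(self):
        p = EncodingProfile("PE", TAU_MS.copy(), np.zeros(51), np.zeros(51), np.zeros(51), np.zeros(51))
        with pytest.raises(ValueError):
            detect_peaks(p)


class TestMatching:
    def _peak(self, tau, r2, b):
        return Peak(tau_ms=tau, r2=r2, beta_pair=b)

    def test_same_signs_match_and_report_shift(self):
        base = PeakSet(lead=self._peak(-100, 0.4, (1.0, 2.0)), lag=self._peak(440, 0.3, (0.5, 0.5)))
        manip = PeakSet(lead=self._peak(-280, 0.35, (0.8, 1.5)), lag=self._peak(420, 0.25, (0.4, 0.6)))
        m = match_peaks(base, manip)
        assert m.lead.dtau_ms == -180
        assert m.lag.dtau_ms == -20

    def test_sign_flip_prevents_match(self):
        base = PeakSet(lead=self._peak(-100, 0.4, (1.0, -2.0)))
        manip = PeakSet(lead=self._peak(-280, 0.35, (-0.8, -1.5)))
        assert match_peaks(base, manip).lead is None

    def test_absent_peak_prevents_match(self):
        base = PeakSet(lead=self._peak(-100, 0.4, (1.0, 2.0)))
        assert match_peaks(base, PeakSet()).lead is None


class TestInsideTargetRestriction:
    def test_checkerboard_mask_enumeration(self, rng):
        inside = np.zeros(20, bool)
        inside[::2] = True
        kins = [_kin(20, rng, inside=inside)]
        rates = [_rate(rng.normal(0, 1, 20))]
        _r, _k, masks = restrict_inside_target(rates, kins)
        np.testing.assert_array_equal(masks[0], np.arange(0, 20, 2))

    def test_all_inside_is_identity(self, rng):
        kins = [_kin(30, rng)]
        rates = [_rate(rng.normal(0, 1, 30))]
        _r, _k, masks = restrict_inside_target(rates, kins)
        np.testing.assert_array_equal(masks[0], np.arange(30))

    def test_sparse_mask_warns(self, rng):
        inside = np.zeros(100, bool)
        inside[:5] = True
        kins = [_kin(100, rng, inside=inside)]
        rates = [_rate(rng.normal(0, 1, 100))]
        with pytest.warns(UserWarning):
            restrict_inside_target(rates, kins)


class TestFiringMap:
    def test_constant_mean_subtracted_rate_maps_to_zero(self, rng):
        kins = [_kin(800, rng)]
        rates = [_rate(np.zeros(800))]
        fmap = build_firing_map(rates, kins, "PE", tau=0, min_occupancy=1)
        occupied = fmap.occupancy > 0
        assert occupied.any()
        np.testing.assert_allclose(fmap.grid[occupied], 0.0, atol=1e-12)

    def test_rate_equal_to_xe_increases_along_first_axis(self, rng):
        kins = [_kin(4000, rng)]
        rates = [_rate(kins[0].XE.copy())]
        fmap = build_firing_map(rates, kins, "PE", tau=0, min_occupancy=3)
        col_means = np.nanmean(fmap.grid, axis=1)
        assert np.all(np.diff(col_means) > 0)

    def test_matches_naive_double_loop(self, rng):
        """Per-bin means agree with a direct double loop, including the
        τ shift and the minimum-occupancy rule."""
        kins = [_kin(300, rng), _kin(250, rng)]
        rates = [_rate(rng.normal(0, 1, len(k))) for k in kins]
        tau, min_occ = -60, 2
        fmap = build_firing_map(rates, kins, "PE", tau=tau, min_occupancy=min_occ)
        k = tau // 20
        half, nb = 2.0, 8
        sums = np.zeros((nb, nb))
        counts = np.zeros((nb, nb))
        for kin, r in zip(kins, rates):
            n = len(kin)
            for t in range(max(0, -k), n - max(0, k)):
                u, v = kin.XE[t], kin.YE[t]
                if not (-half <= u <= half and -half <= v <= half):
                    continue
                i = min(int((u + half) / (2 * half / nb)), nb - 1)
                j = min(int((v + half) / (2 * half / nb)), nb - 1)
                sums[i, j] += r.rate[t + k]
                counts[i, j] += 1
        expected = np.where(counts >= min_occ, sums / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(fmap.grid, expected, atol=1e-12, equal_nan=True)
        np.testing.assert_array_equal(fmap.occupancy, counts.astype(int))

    def test_lead_cell_map_gradient_larger_at_lead_tau(self):
        """For a simulated lead-only cell the PE firing-map gradient is
        steeper at the lead τ than at its mirror lag τ."""
        from tracklag.experiments import preprocess_session
        from tracklag.simulate import CellGroundTruth, generate_session
        from tracklag.task import Condition

        def lead_only(rng, seed=0):
            return CellGroundTruth(
                baseline_rate=70.0,
                lead_latency_ms=160.0,
                lag_latency_ms=400.0,
                lead_gain_xy=(28.0, 12.0),
                lag_gain_xy=(0.0, 0.0),
                pos_gain_xy=(0.0, 0.0),
                vel_gain_xy=(0.0, 0.0),
                seed=seed,
            )

        session = generate_session(
            1, 8, Condition.from_label("baseline"), seed=55, truth_factory=lead_only
        )
        pre = preprocess_session(session)[0]
        rates, kins = pre["baseline"]
        truth = session.cells[0].truth
        tau = -int(truth.lead_latency_ms)

        def grad_norm(fmap):
            g = np.nan_to_num(fmap.grid)
            gx, gy = np.gradient(g)
            return float(np.hypot(gx, gy).sum())

        lead_map = build_firing_map(rates, kins, "PE", tau=tau)
        anti_map = build_firing_map(rates, kins, "PE", tau=-tau)
        assert grad_norm(lead_map) > grad_norm(anti_map)
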