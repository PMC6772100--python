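"""tt/tk-GRAPPA: repetition arithmetic, source location, weight solving,
application, and recursion.  The core correctness oracle is a planted linear
model: data generated so every missing sample is an exact fixed linear
combination of its kernel sources must be recovered to machine precision."""

import numpy as np
import pytest

import ringmrsi as rm
from ringmrsi.grappa import (
    GrappaGeometry,
    OverdeterminationError,
    TtkGrappa,
    apply_weights,
    check_overdetermination,
    count_repetitions,
    locate_sources,
    solve_weights,
)
from ringmrsi.kspace import RingKSpace
from ringmrsi.sampling import make_pattern

DWELL = 1.0 / 2778.0


class TestRepetitionArithmetic:
    def test_default_geometry_reproduces_39_by_21(self):
        spatial, total = count_repetitions(GrappaGeometry())
        assert spatial == 39
        assert total == 819

    def test_segment_equals_kernel_gives_one_spatial_repetition(self):
        g = GrappaGeometry(segment_points=3, segment_rings=2, n_time_points=4)
        assert count_repetitions(g) == (1, 4)

    def test_formula_matches_explicit_sliding_enumeration(self):
        g = GrappaGeometry(
            kernel_points=3, kernel_rings=2, segment_points=10,
            segment_rings=3, n_time_points=5,
        )
        count = sum(
            1
            for _dp in range(g.segment_points - g.kernel_points + 1)
            for _dr in range(g.segment_rings - g.kernel_rings + 1)
        )
        assert count_repetitions(g) == (count, count * 5)
        assert count_repetitions(g)[0] == 16

    def test_overdetermination_rule(self):
        # default geometry, 32 coils: 819 >= 6 x 32 = 192
        assert check_overdetermination(GrappaGeometry(), 32)
        # a single repetition cannot determine six weights even for one coil
        g1 = GrappaGeometry(segment_points=3, segment_rings=2, n_time_points=1)
        assert g1.total_repetitions == 1
        assert not check_overdetermination(g1, 1)

    def test_overdetermination_boundary_is_inclusive(self):
        # exactly 192 repetitions vs 6 x 32 = 192 source columns
        g = GrappaGeometry(segment_points=3, segment_rings=2, n_time_points=192)
        assert g.total_repetitions == 192
        assert check_overdetermination(g, 32)
        g191 = GrappaGeometry(segment_points=3, segment_rings=2, n_time_points=191)
        assert not check_overdetermination(g191, 32)


class TestLocateSources:
    def test_interior_target_uses_adjacent_rings(self):
        pat = make_pattern(32, 2, 0)  # measured rings 1, 3, 5, ...
        spec = locate_sources((6, 100), pat, GrappaGeometry(), 540)
        np.testing.assert_array_equal(spec.src_rings, [5, 7])
        np.testing.assert_array_equal(spec.pt_offsets, [-1, 0, 1])
        assert not spec.boundary

    def test_angular_wraparound(self):
        pat = make_pattern(32, 2, 0)
        spec = locate_sources((6, 0), pat, GrappaGeometry(), 540)
        pts = (0 + spec.pt_offsets) % 540
        np.testing.assert_array_equal(pts, [539, 0, 1])

    def test_variable_pattern_core_is_never_a_target(self):
        pat = make_pattern(32, 2, 5)
        assert np.flatnonzero(pat.missing).min() >= 5

    def test_one_sided_fallback_warns(self):
        pat = make_pattern(16, 2, 0)  # ring 0 missing, nothing below
        with pytest.warns(RuntimeWarning, match="one-sided"):
            spec = locate_sources((0, 0), pat, GrappaGeometry(), 128)
        np.testing.assert_array_equal(spec.src_rings, [1, 3])
        assert spec.boundary

    def test_measured_target_rejected(self):
        pat = make_pattern(16, 2, 0)
        with pytest.raises(ValueError, match="measured"):
            locate_sources((1, 0), pat, GrappaGeometry(), 128)


def _planted_dataset(traj, pattern, weight_matrix, kp, seed, n_spec):
    """Random data on measured rings; each missing ring is the exact fixed
    linear combination of its located sources given by ``weight_matrix``."""
    n_coils = weight_matrix.shape[-1]
    p = traj.points_per_ring
    rng = np.random.default_rng(seed)
    data = np.zeros((n_coils, traj.n_rings, p, n_spec), complex)
    meas = pattern.measured
    data[:, meas] = rng.standard_normal(
        (n_coils, int(meas.sum()), p, n_spec)
    ) + 1j * rng.standard_normal((n_coils, int(meas.sum()), p, n_spec))
    offs = np.arange(kp) - kp // 2
    pts = (np.arange(p)[:, None] + offs[None, :]) % p
    geom = GrappaGeometry(kernel_points=kp, kernel_rings=2,
                          segment_points=kp, segment_rings=2, n_time_points=1)
    for r in np.flatnonzero(pattern.missing):
        spec = locate_sources((int(r), 0), pattern, geom, p)
        x = data[:, spec.src_rings][:, :, pts, :]  # (C, 2, P, kp, T)
        xr = x.transpose(2, 4, 0, 1, 3).reshape(p, n_spec, -1)
        data[:, r] = np.einsum("ptk,kc->cpt", xr, weight_matrix)
    return data


class TestPlantedLinearModel:
    @pytest.mark.parametrize(
        "n_coils, kp, seg_pts, n_time",
        [(2, 3, 9, 15), (1, 3, 13, 6), (3, 5, 11, 21)],
    )
    def test_exact_recovery_of_missing_rings(self, n_coils, kp, seg_pts, n_time):
        traj = rm.make_ring_trajectory(8, 32, 16, 200.0)
        pattern = make_pattern(8, 2, 1)
        geom = GrappaGeometry(
            kernel_points=kp, kernel_rings=2, segment_points=seg_pts,
            segment_rings=2, n_time_points=n_time,
        )
        k = n_coils * 2 * kp
        rng = np.random.default_rng(42)
        w_true = rng.standard_normal((k, n_coils)) + 1j * rng.standard_normal(
            (k, n_coils)
        )
        calib = RingKSpace(
            _planted_dataset(traj, pattern, w_true, kp, seed=1, n_spec=n_time),
            traj, DWELL,
        )
        weights = solve_weights(calib, pattern, geom, force=True)
        # apply to an independently generated dataset with the same model
        full = _planted_dataset(traj, pattern, w_true, kp, seed=2, n_spec=4)
        truth = RingKSpace(full.copy(), traj, DWELL)
        under = rm.decimate(truth, pattern)
        rec = apply_weights(under, weights, pattern)
        err = np.linalg.norm(rec.data - full) / np.linalg.norm(full)
        assert err < 1e-8

    def test_duplicated_time_points_leave_weights_unchanged(self):
        """Least-squares weights are invariant under row duplication."""
        traj = rm.make_ring_trajectory(8, 32, 16, 200.0)
        pattern = make_pattern(8, 2, 1)
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 8, 32, 6)) + 1j * rng.standard_normal(
            (2, 8, 32, 6)
        )
        calib = RingKSpace(data, traj, DWELL)
        dup = RingKSpace(np.repeat(data, 2, axis=-1), traj, DWELL)
        geom6 = GrappaGeometry(segment_points=9, segment_rings=2, n_time_points=6)
        geom12 = GrappaGeometry(segment_points=9, segment_rings=2, n_time_points=12)
        w6 = solve_weights(calib, pattern, geom6, force=True)
        w12 = solve_weights(dup, pattern, geom12, force=True)
        for r in w6.rings:
            np.testing.assert_allclose(w6.rings[r].w, w12.rings[r].w, atol=1e-9)


class TestSolveAndApplyContracts:
    def test_overdetermination_refusal_and_force(self, desk_study):
        pat = make_pattern(16, 2, 5)
        geom = GrappaGeometry(segment_points=3, segment_rings=2, n_time_points=1)
        with pytest.raises(OverdeterminationError, match="force"):
            solve_weights(desk_study.calibs["imusical"], pat, geom)

    def test_calibration_must_be_fully_sampled(self, desk_study):
        pat = make_pattern(16, 2, 5)
        partial = rm.decimate(desk_study.calibs["imusical"], pat)
        with pytest.raises(ValueError, match="fully sampled"):
            solve_weights(partial, pat)

    def test_calibration_needs_enough_time_points(self, desk_study):
        pat = make_pattern(16, 2, 5)
        geom = GrappaGeometry(n_time_points=64)
        with pytest.raises(ValueError, match="spectral points"):
            solve_weights(desk_study.calibs["imusical"], pat, geom)

    def test_missing_weight_lookup_identifies_sample(self, desk_study):
        pat = make_pattern(16, 2, 5)
        w = solve_weights(
            desk_study.calibs["imusical"], pat,
            target_rings=np.flatnonzero(pat.missing)[:1],
        )
        under = rm.decimate(desk_study.mrsi, pat)
        with pytest.raises(KeyError, match="ring="):
            apply_weights(under, w, pat)

    def test_time_uniform_application(self, desk_study):
        """Filled samples at spectral index t depend only on measured samples
        at the same t."""
        pat = make_pattern(16, 2, 5)
        under = rm.decimate(desk_study.mrsi, pat)
        w = solve_weights(desk_study.calibs["imusical"], pat)
        full = apply_weights(under, w, pat)
        zeroed = under.copy()
        zeroed.data[..., 1:] = 0  # keep only t=0
        only_t0 = apply_weights(zeroed, w, pat)
        np.testing.assert_allclose(
            only_t0.data[..., 0], full.data[..., 0], rtol=1e-12
        )
        assert not np.any(only_t0.data[:, pat.missing][..., 1:])

    def test_measured_samples_pass_through_unchanged(self, desk_study):
        pat = make_pattern(16, 2, 5)
        under = rm.decimate(desk_study.mrsi, pat)
        w = solve_weights(desk_study.calibs["imusical"], pat)
        full = apply_weights(under, w, pat)
        np.testing.assert_array_equal(
            full.data[:, pat.measured], under.data[:, pat.measured]
        )
        assert full.measured_rings.all()


class TestPhantomReconstruction:
    def test_filled_kspace_error_regression(self, desk_study):
        """R=2 constant-density fill stays below the frozen error band
        (first validated run: 0.090 relative l2 on the filled rings)."""
        pat = make_pattern(16, 2, 0)
        under = rm.decimate(desk_study.mrsi, pat)
        model = TtkGrappa(recursive=False).fit(desk_study.calibs["imusical"], pat)
        filled = model.predict(under)
        miss = pat.missing
        err = np.linalg.norm(
            filled.data[:, miss] - desk_study.mrsi.data[:, miss]
        ) / np.linalg.norm(desk_study.mrsi.data[:, miss])
        assert err < 0.15

    def test_recursive_two_fold_equals_single_pass(self, desk_study):
        pat = make_pattern(16, 2, 5)
        under = rm.decimate(desk_study.mrsi, pat)
        calib = desk_study.calibs["imusical"]
        a = TtkGrappa(recursive=True).fit(calib, pat).predict(under)
        b = TtkGrappa(recursive=False).fit(calib, pat).predict(under)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_eight_fold_recursion_fills_everything_in_three_stages(self, desk_study):
        pat = make_pattern(16, 8, 5)
        under = rm.decimate(desk_study.mrsi, pat)
        model = TtkGrappa(recursive=True).fit(desk_study.calibs["imusical"], pat)
        assert len(model.stage_weights_) == 3
        filled = model.predict(under)
        assert filled.measured_rings.all()
        assert np.all(np.abs(filled.data).sum(axis=(0, 2, 3)) > 0)

    def test_weights_are_computed_from_calibration_only(self, desk_study):
        """Fitting never sees the undersampled data; two different
        undersampled sets share identical weights."""
        pat = make_pattern(16, 2, 5)
        model = TtkGrappa().fit(desk_study.calibs["imusical"], pat)
        w_before = [
            {r: rw.w.copy() for r, rw in stage.rings.items()}
            for stage in model.stage_weights_
        ]
        model.predict(rm.decimate(desk_study.mrsi, pat))
        for stage, snapshot in zip(model.stage_weights_, w_before):
            for r, rw in stage.rings.items():
                np.testing.assert_array_equal(rw.w, snapshot[r])
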