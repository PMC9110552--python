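"""Windowed GP: coverage, operator oracles, reuse without factorization,
and convergence to the full exact GP as the window grows."""

import numpy as np
import pytest

from scangp import (
    KernelSpec,
    ScanGrid,
    build_operators,
    full_gp_interpolate,
    load_operators,
    observation_coords,
    patched_gp_interpolate,
    patched_predict,
    plan_patches,
    save_operators,
)
from scangp.evaluation import decimate, psnr
from scangp.gp import cholesky_call_count, gp_predict, reset_cholesky_counter
from scangp.patched import Patch, PatchPlan
from tests.conftest import gp_frame, random_frame


def small_spec(noise=1e-2):
    return KernelSpec(
        family="matern",
        nu=1.5,
        signal_variance=1.0,
        length_scale_r=3.0,
        length_scale_alpha=1.5,
        noise_variance=noise,
    )


class TestPlanPatches:
    def test_every_target_covered_exactly_once(self, par_grid):
        targets = observation_coords(par_grid)
        plan = plan_patches(par_grid, targets, window_size=8)
        seen = np.concatenate([p.target_idx for p in plan.patches])
        assert np.array_equal(np.sort(seen), np.arange(len(targets)))

    def test_toy_grid_windows_exhaustive(self):
        # 2-beam, 4-sample grid; window of 4 total nearest observations
        g = ScanGrid("parallel", 2, 4, 1.0, 1.0)
        targets = observation_coords(g)
        plan = plan_patches(g, targets, window_size=4, mode="nearest")
        for p in plan.patches:
            assert p.obs_idx.size == 4
        seen = np.concatenate([p.target_idx for p in plan.patches])
        assert np.array_equal(np.sort(seen), np.arange(8))

    def test_window_truncated_with_warning(self, par_grid, caplog):
        targets = observation_coords(par_grid)
        n_obs = par_grid.n_samples * par_grid.n_scanlines
        with caplog.at_level("WARNING"):
            plan = plan_patches(par_grid, targets, window_size=n_obs + 50, mode="nearest")
        assert plan.window_size == n_obs
        assert any("truncat" in r.message for r in caplog.records)

    def test_plan_deterministic(self, div_grid):
        targets = observation_coords(div_grid)
        p1 = plan_patches(div_grid, targets, window_size=9)
        p2 = plan_patches(div_grid, targets, window_size=9)
        assert p1.fingerprint() == p2.fingerprint()

    def test_rejects_tiny_window(self, par_grid):
        with pytest.raises(ValueError):
            plan_patches(par_grid, observation_coords(par_grid), window_size=1)


def single_patch_plan(grid, targets):
    """A one-patch plan whose window is every observation — the degenerate
    case that must reproduce the full exact GP."""
    coords = targets.coords
    n_obs = grid.n_samples * grid.n_scanlines
    patch = Patch(
        target_idx=np.arange(len(coords), dtype=np.int64),
        target_coords=coords,
        obs_idx=np.arange(n_obs, dtype=np.int64),
        centroid=coords.mean(axis=0),
    )
    return PatchPlan(
        patches=(patch,),
        window_size=n_obs,
        mode="nearest",
        n_targets=len(coords),
        n_obs=n_obs,
        grid_fingerprint=grid.fingerprint(),
    )


class TestOperators:
    def test_single_patch_equals_full_gp(self, par_grid, rng):
        frame = random_frame(par_grid, rng)
        targets = observation_coords(par_grid)
        plan = single_patch_plan(par_grid, targets)
        ops = build_operators(plan, targets, small_spec(), par_grid)
        res = patched_predict(ops, frame, plan)
        full = full_gp_interpolate(frame, targets, small_spec())
        np.testing.assert_allclose(res.values, full.values, atol=1e-9)
        np.testing.assert_allclose(res.variance, full.variance, atol=1e-9)

    def test_operator_matches_per_patch_gp_predict(self, div_grid, rng):
        frame = random_frame(div_grid, rng)
        targets = observation_coords(div_grid)
        obs = observation_coords(div_grid)
        spec = small_spec()
        spec = spec.replace(length_scale_alpha=1.5 * div_grid.beam_pitch)
        plan = plan_patches(div_grid, targets, window_size=9, spec=spec)
        ops = build_operators(plan, obs, spec, div_grid)
        res = patched_predict(ops, frame, plan)
        vals = frame.values_flat()
        for patch in plan.patches[:5]:
            post = gp_predict(
                obs.coords[patch.obs_idx],
                vals[patch.obs_idx],
                patch.target_coords,
                spec,
            )
            np.testing.assert_allclose(res.values[patch.target_idx], post.mean, atol=1e-10)

    def test_rebuild_is_bitwise_identical(self, par_grid):
        targets = observation_coords(par_grid)
        plan = plan_patches(par_grid, targets, window_size=7)
        a = build_operators(plan, targets, small_spec(), par_grid)
        b = build_operators(plan, targets, small_spec(), par_grid)
        assert [op.fingerprint for op in a] == [op.fingerprint for op in b]
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)

    def test_reuse_skips_factorizations(self, par_grid, rng):
        targets = observation_coords(par_grid)
        plan = plan_patches(par_grid, targets, window_size=7)
        ops = build_operators(plan, targets, small_spec(), par_grid)
        frame2 = random_frame(par_grid, rng)
        reset_cholesky_counter()
        res = patched_predict(ops, frame2, plan)
        assert cholesky_call_count() == 0  # O(NM) apply path
        assert np.isfinite(res.values).all()

    def test_variance_nonnegative_and_bounded(self, par_grid, rng):
        frame = random_frame(par_grid, rng)
        targets = observation_coords(par_grid)
        res = patched_gp_interpolate(frame, targets, small_spec(), window_size=9)
        assert res.variance.min() >= 0.0
        for op in build_operators(
            plan_patches(par_grid, targets, window_size=9), targets, small_spec(), par_grid
        ):
            assert np.all(op.prior_var - op.cross_var >= -1e-8 * 1.0)

    def test_grid_mismatch_rejected(self, par_grid, div_grid, rng):
        targets = observation_coords(par_grid)
        plan = plan_patches(par_grid, targets, window_size=7)
        ops = build_operators(plan, targets, small_spec(), par_grid)
        wrong = random_frame(div_grid, rng)
        with pytest.raises(ValueError):
            patched_predict(ops, wrong, plan)


class TestConvergenceToFullGP:
    def test_gap_non_increasing_in_window(self):
        # held-out reconstruction error vs the full GP shrinks with window
        grid = ScanGrid("parallel", 16, 48, 1.0, 1.0)
        spec = small_spec(noise=2e-3)
        frame = gp_frame(grid, spec, seed=11, noise_std=np.sqrt(2e-3))
        reduced, held = decimate(frame, 8)
        mask = np.zeros((grid.n_samples, grid.n_scanlines), bool)
        mask[:, held] = True
        targets = observation_coords(grid).coords[mask.ravel(order="F")]
        full = full_gp_interpolate(reduced, targets, spec, compute_variance=False)
        gaps = []
        for w in (5, 9, 15, 21, reduced.grid.n_samples):
            res = patched_gp_interpolate(reduced, targets, spec, window_size=w)
            gaps.append(np.abs(res.values - full.values).max())
        assert all(g2 <= g1 + 1e-9 for g1, g2 in zip(gaps, gaps[1:]))

    def test_growing_window_recovers_full_gp(self):
        # with the window spanning every sample row, the axial patched GP
        # regresses from the same local beams the full GP leans on; the
        # residual PSNR gap at full axial extent is far below the w=5 gap
        grid = ScanGrid("diverging", 16, 64, 1.0, 0.02)
        spec = small_spec(noise=8e-3).replace(length_scale_alpha=1.5 * 0.02)
        frame = gp_frame(grid, spec, seed=3, noise_std=np.sqrt(8e-3))
        reduced, held = decimate(frame, 8)
        mask = np.zeros((grid.n_samples, grid.n_scanlines), bool)
        mask[:, held] = True
        targets = observation_coords(grid).coords[mask.ravel(order="F")]
        truth = frame.intensities[:, held].ravel(order="F")
        full = full_gp_interpolate(reduced, targets, spec, compute_variance=False)
        gap5 = abs(psnr(truth, full.values) - psnr(
            truth, patched_gp_interpolate(reduced, targets, spec, window_size=5).values))
        gap_full = abs(psnr(truth, full.values) - psnr(
            truth, patched_gp_interpolate(reduced, targets, spec, window_size=64).values))
        assert gap_full < gap5


def test_operator_cache_round_trip(tmp_path, par_grid, rng):
    targets = observation_coords(par_grid)
    plan = plan_patches(par_grid, targets, window_size=7)
    ops = build_operators(plan, targets, small_spec(), par_grid)
    path = tmp_path / "ops.npz"
    save_operators(path, ops, plan)
    again = load_operators(path, plan)
    frame = random_frame(par_grid, rng)
    r1 = patched_predict(ops, frame, plan)
    r2 = patched_predict(again, frame, plan)
    np.testing.assert_array_equal(r1.values, r2.values)
    # stale cache rejected
    other = plan_patches(par_grid, targets, window_size=9)
    with pytest.raises(ValueError):
        load_operators(path, other)
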