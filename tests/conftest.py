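"""Shared fixtures: small trajectories and the session-wide desk study.

The desk study (32x32 matrix, 16 rings, 128 points/ring, 8 coils, 64
spectral points, seed 1) is simulated once per session; the expensive
reconstruction regressions reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

import ringmrsi as rm
from ringmrsi.config import preset
from ringmrsi.pipeline import (
    evaluate_reconstruction,
    g_factor_map,
    grappa_model,
    reconstruct_combined,
    simulate_study,
)

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_cfg():
    return preset("desk")


@pytest.fixture(scope="session")
def desk_study(desk_cfg):
    return simulate_study(desk_cfg, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_references(desk_study):
    """Fully sampled reconstructions combined with each calibration set."""
    return {
        "imusical": reconstruct_combined(desk_study, None, "imusical"),
        "static": reconstruct_combined(desk_study, None, "static"),
        "moved": reconstruct_combined(desk_study, None, "moved"),
    }


def _mean_rmse(ev: dict) -> float:
    vals = list(ev["percent_rmse"].values())
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def desk_regressions(desk_study, desk_references):
    """Accelerated reconstructions and their metrics, computed once.

    Keys:
      rmse_by_R          mean %RMSE for variable-density R = 2, 4, 8
      rmse_recursive4 / rmse_direct4   R = 4 variable, both strategies
      calib              per calibration source at R = 2 variable:
                         (mean %RMSE, lipid mean in brain)
      g_mean             mean in-brain g-factor per calibration source
      g_unaccelerated    mean g of the unaccelerated control
    """
    study = desk_study
    out: dict = {}

    ref_for = {
        "imusical": desk_references["imusical"],
        "static": desk_references["static"],
        "moved": desk_references["static"],
    }

    rmse_by_R = {}
    for R in (2, 4, 8):
        pat = rm.make_pattern(16, R, 5)
        rec = reconstruct_combined(study, pat, "imusical")
        rmse_by_R[R] = _mean_rmse(
            evaluate_reconstruction(study, rec, ref_for["imusical"])
        )
    out["rmse_by_R"] = rmse_by_R

    pat4 = rm.make_pattern(16, 4, 5)
    direct = grappa_model(study.config)
    direct.recursive = False
    rec_dir = reconstruct_combined(study, pat4, "imusical", model=direct)
    out["rmse_direct4"] = _mean_rmse(
        evaluate_reconstruction(study, rec_dir, ref_for["imusical"])
    )
    out["rmse_recursive4"] = rmse_by_R[4]

    pat2 = rm.make_pattern(16, 2, 5)
    calib = {}
    for mode in ("imusical", "static", "moved"):
        rec = reconstruct_combined(study, pat2, mode)
        ev = evaluate_reconstruction(study, rec, ref_for[mode])
        calib[mode] = (_mean_rmse(ev), ev["lipid_mean_in_brain"])
    out["calib"] = calib

    mask = study.phantom.brain_mask
    g_mean = {}
    for mode in ("imusical", "moved"):
        gm = g_factor_map(study, pat2, mode, n_replicas=50)
        g_mean[mode] = float(np.nanmean(gm.g[mask]))
    out["g_mean"] = g_mean

    from ringmrsi.evaluate import g_factor, pseudo_replica
    from ringmrsi.pipeline import t0_recon_fn

    fn, data = t0_recon_fn(study, None, "imusical")
    noise_sd = study.config.geometry.noise_sd
    pr_a = pseudo_replica(fn, data, noise_sd, 50, seed=11)
    pr_b = pseudo_replica(fn, data, noise_sd, 50, seed=12)
    g0 = g_factor(pr_a.snr, pr_b.snr, 1.0, mask=mask)
    out["g_unaccelerated"] = float(np.nanmean(g0.g[mask]))
    return out


@pytest.fixture()
def small_traj():
    return rm.make_ring_trajectory(16, 128, 32, 200.0)


@pytest.fixture()
def oracle_traj():
    """Tiny geometry for direct-DFT oracles (8x8 matrix, 4 rings)."""
    return rm.make_ring_trajectory(4, 32, 8, 100.0)
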