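"""Hybrid through-time/through-k-space GRAPPA for concentric-ring k-space.

Missing rings are synthesized point by point as learned linear combinations
of measured neighbors across coils.  Because translational invariance does
not hold globally on a non-Cartesian trajectory, kernel repetitions for the
least-squares weight calibration are harvested from a local k-space segment
(default 15 points-on-ring x 4 rings around each target, kernel 3 x 2, i.e.
six source points -> 13 x 3 = 39 spatial repetitions) and from multiple
calibration time points (default 21), giving 819 repetitions in the default
geometry.  The system is overdetermined when the repetition count reaches
``kernel source points x coils`` (192 for 32 coils).

Weights are solved per missing sample from the calibration data alone and
then applied to every spectral time point of the undersampled FID.  Higher
accelerations can be reconstructed recursively (R=8 -> R=4 -> R=2 -> full)
with the same geometry at every stage.

``TtkGrappa`` is the estimator interface (fit on calibration, predict on
undersampled data); ``solve_weights`` / ``apply_weights`` /
``reconstruct_recursive`` are functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .kspace import RingKSpace
from .sampling import UndersamplingPattern, make_pattern, stage_patterns

__all__ = [
    "GrappaGeometry",
    "GrappaWeights",
    "TtkGrappa",
    "OverdeterminationError",
    "count_repetitions",
    "check_overdetermination",
    "locate_sources",
    "solve_weights",
    "apply_weights",
    "reconstruct_recursive",
]


class OverdeterminationError(RuntimeError):
    """Raised when the geometry yields too few kernel repetitions."""


@dataclass(frozen=True)
class GrappaGeometry:
    """Kernel and segment extents of the tt/tk-GRAPPA calibration.

    ``kernel_points x kernel_rings`` source points predict one target;
    the kernel slides through a ``segment_points x segment_rings`` segment
    of the calibration data and across ``n_time_points`` calibration time
    points to gather repetitions.
    """

    kernel_points: int = 3
    kernel_rings: int = 2
    segment_points: int = 15
    segment_rings: int = 4
    n_time_points: int = 21

    def __post_init__(self) -> None:
        if self.segment_points < self.kernel_points:
            raise ValueError("segment_points must be >= kernel_points")
        if self.segment_rings < self.kernel_rings:
            raise ValueError("segment_rings must be >= kernel_rings")
        if min(self.kernel_points, self.kernel_rings, self.n_time_points) < 1:
            raise ValueError("kernel extents and n_time_points must be >= 1")

    @property
    def n_source_points(self) -> int:
        return self.kernel_points * self.kernel_rings

    @property
    def spatial_repetitions(self) -> int:
        return (self.segment_points - self.kernel_points + 1) * (
            self.segment_rings - self.kernel_rings + 1
        )

    @property
    def total_repetitions(self) -> int:
        return self.spatial_repetitions * self.n_time_points


def count_repetitions(geom: GrappaGeometry) -> tuple[int, int]:
    """(spatial, spatial x temporal) kernel repetitions of a geometry."""
    return geom.spatial_repetitions, geom.total_repetitions


def check_overdetermination(geom: GrappaGeometry, n_coils: int) -> bool:
    """True iff repetitions >= kernel source points x coils (>=, not >)."""
    return geom.total_repetitions >= geom.n_source_points * n_coils


@dataclass
class SourceSpec:
    """Kernel/segment footprint for one target ring."""

    src_rings: np.ndarray  # 2 source ring indices, ascending
    pt_offsets: np.ndarray  # kernel_points angular offsets, centered on target
    ring_shifts: np.ndarray  # segment ring shifts (truncated at boundaries)
    pt_shifts: np.ndarray  # segment angular shifts (circular)
    boundary: bool  # True if one-sided source fallback was used


def locate_sources(
    target: tuple[int, int],
    pattern: UndersamplingPattern,
    geom: GrappaGeometry,
    n_points: int,
) -> SourceSpec:
    """Source constellation and segment footprint for one missing sample.

    Sources are the nearest measured ring below and above the target ring at
    ``kernel_points`` angular indices centered on the target's (circular wrap
    along the ring).  If no measured ring exists on one side, the two nearest
    measured rings on the available side are used and flagged.  The segment
    footprint is centered identically and truncated (never wrapped) at the
    innermost/outermost ring.
    """
    if geom.kernel_rings != 2:
        raise NotImplementedError("source location is defined for kernel_rings == 2")
    r_t, _ = target
    measured = np.flatnonzero(pattern.measured)
    if pattern.measured[r_t]:
        raise ValueError(f"target ring {r_t} is measured, not missing")
    if measured.size < 2:
        raise ValueError("need at least two measured rings to locate sources")
    below = measured[measured < r_t]
    above = measured[measured > r_t]
    boundary = False
    if below.size and above.size:
        src = np.array([below[-1], above[0]])
    elif below.size >= 2:
        src, boundary = np.sort(below[-2:]), True
    elif above.size >= 2:
        src, boundary = np.sort(above[:2]), True
    else:
        raise ValueError(
            f"cannot build a two-ring kernel for target ring {r_t}: only "
            f"{below.size} measured ring(s) below and {above.size} above"
        )
    if boundary:
        warnings.warn(
            f"target ring {r_t}: no measured ring on one side; using one-sided "
            f"sources {src.tolist()}",
            RuntimeWarning,
        )
    offs = np.arange(geom.kernel_points) - geom.kernel_points // 2
    n_sh = geom.segment_rings - geom.kernel_rings + 1
    shifts = np.arange(n_sh) - (n_sh - 1) // 2
    lo = min(int(src[0]), r_t)
    hi = max(int(src[1]), r_t)
    shifts = shifts[(lo + shifts >= 0) & (hi + shifts <= pattern.n_rings - 1)]
    if shifts.size == 0:
        shifts = np.array([0])
    n_ps = geom.segment_points - geom.kernel_points + 1
    pshifts = np.arange(n_ps) - (n_ps - 1) // 2
    return SourceSpec(
        src_rings=src,
        pt_offsets=offs,
        ring_shifts=shifts,
        pt_shifts=pshifts,
        boundary=boundary,
    )


@dataclass
class RingWeights:
    """Per-point weight sets for one missing ring (all points share geometry)."""

    w: np.ndarray  # (points_per_ring, K, n_coils), K = n_coils * 2 * kernel_points
    spec: SourceSpec
    residual: np.ndarray  # relative LS residual per point
    condition: float  # condition estimate of one normal matrix
    rank_deficient: bool


@dataclass
class GrappaWeights:
    """Weights for every missing sample of one reconstruction stage."""

    geom: GrappaGeometry
    n_coils: int
    pattern: UndersamplingPattern
    rings: dict[int, RingWeights] = field(default_factory=dict)

    def weight_tensor(self, ring: int, point: int) -> np.ndarray:
        """Weights for one missing sample as (target coil, source coil, position)."""
        rw = self.rings[ring]
        w = rw.w[point]  # (K, C_t)
        c = self.n_coils
        return np.transpose(w.reshape(c, -1, w.shape[-1]), (2, 0, 1))

    @property
    def max_residual(self) -> float:
        return max((float(rw.residual.max()) for rw in self.rings.values()), default=0.0)


def _solve_ring(
    calib: RingKSpace,
    pattern: UndersamplingPattern,
    geom: GrappaGeometry,
    ring: int,
    lam: float,
    chunk: int = 32,
) -> RingWeights:
    """Least-squares weights for every point on one missing ring."""
    spec = locate_sources((ring, 0), pattern, geom, calib.traj.points_per_ring)
    p_tot = calib.traj.points_per_ring
    c = calib.n_coils
    kp = geom.kernel_points
    k_cols = c * 2 * kp
    tau = np.arange(geom.n_time_points)
    drs, dps, offs = spec.ring_shifts, spec.pt_shifts, spec.pt_offsets
    n_rows = drs.size * dps.size * tau.size

    ci = np.arange(c).reshape(c, 1, 1, 1, 1, 1, 1)
    ri = (spec.src_rings[:, None] + drs[None, :]).reshape(1, 2, drs.size, 1, 1, 1, 1)
    ti = tau.reshape(1, 1, 1, 1, 1, 1, -1)
    ci_t = np.arange(c).reshape(c, 1, 1, 1, 1)
    ri_t = (ring + drs).reshape(1, drs.size, 1, 1, 1)
    ti_t = tau.reshape(1, 1, 1, 1, -1)

    w = np.empty((p_tot, k_cols, c), dtype=complex)
    residual = np.empty(p_tot)
    condition = np.nan
    rank_deficient = False
    for start in range(0, p_tot, chunk):
        pts = np.arange(start, min(start + chunk, p_tot))
        pc = pts.size
        pidx = (pts[:, None, None] + offs[None, :, None] + dps[None, None, :]) % p_tot
        s = calib.data[ci, ri, pidx.reshape(1, 1, 1, pc, kp, dps.size, 1), ti]
        # (C, 2, D, Pc, kp, Q, T) -> (Pc, D, Q, T, C, 2, kp)
        s = s.transpose(3, 2, 5, 6, 0, 1, 4).reshape(pc, n_rows, k_cols)
        p_t = (pts[:, None] + dps[None, :]) % p_tot
        t = calib.data[ci_t, ri_t, p_t.reshape(1, 1, pc, dps.size, 1), ti_t]
        t = t.transpose(2, 1, 3, 4, 0).reshape(pc, n_rows, c)

        sh = s.conj().transpose(0, 2, 1)
        a = sh @ s
        b = sh @ t
        if lam > 0:
            scale = np.trace(a, axis1=1, axis2=2).real / k_cols
            a = a + (lam * scale)[:, None, None] * np.eye(k_cols)[None]
        try:
            wc = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            rank_deficient = True
            wc = np.stack(
                [np.linalg.lstsq(s[i], t[i], rcond=None)[0] for i in range(pc)]
            )
        if start == 0:
            with np.errstate(all="ignore"):
                condition = float(np.linalg.cond(a[0]))
        resid = np.linalg.norm(s @ wc - t, axis=(1, 2))
        tnorm = np.linalg.norm(t, axis=(1, 2))
        residual[pts] = resid / np.where(tnorm > 0, tnorm, 1.0)
        w[pts] = wc
    if n_rows < k_cols:
        rank_deficient = True
    return RingWeights(
        w=w, spec=spec, residual=residual, condition=condition,
        rank_deficient=rank_deficient,
    )


def solve_weights(
    calib: RingKSpace,
    pattern: UndersamplingPattern,
    geom: GrappaGeometry | None = None,
    lam: float = 0.0,
    force: bool = False,
    target_rings: np.ndarray | None = None,
) -> GrappaWeights:
    """Solve tt/tk-GRAPPA weights for every missing sample of ``pattern``.

    For each missing (ring, point), kernel repetitions are harvested from the
    calibration data across the segment's ring/point shifts and the first
    ``n_time_points`` calibration FID points, and the weight matrix is the
    least-squares solution ``argmin ||S W - T||`` (optionally Tikhonov
    regularized with relative strength ``lam``).
    """
    geom = geom or GrappaGeometry()
    if not bool(np.all(calib.measured_rings)):
        raise ValueError("calibration data must be fully sampled")
    if calib.n_spec < geom.n_time_points:
        raise ValueError(
            f"calibration has {calib.n_spec} spectral points but the geometry "
            f"requires {geom.n_time_points}"
        )
    if not check_overdetermination(geom, calib.n_coils) and not force:
        raise OverdeterminationError(
            f"{geom.total_repetitions} kernel repetitions < "
            f"{geom.n_source_points} source points x {calib.n_coils} coils = "
            f"{geom.n_source_points * calib.n_coils}; pass force=True to solve anyway"
        )
    if target_rings is None:
        target_rings = np.flatnonzero(pattern.missing)
    weights = GrappaWeights(geom=geom, n_coils=calib.n_coils, pattern=pattern)
    for ring in target_rings:
        weights.rings[int(ring)] = _solve_ring(calib, pattern, geom, int(ring), lam)
    return weights


def apply_weights(
    under: RingKSpace,
    weights: GrappaWeights,
    pattern: UndersamplingPattern | None = None,
) -> RingKSpace:
    """Fill the rings the weights cover, for all spectral time points.

    The same weights are applied across the whole FID; measured samples pass
    through unchanged.  If ``pattern`` is given, every missing sample of the
    pattern must be covered (error naming the sample otherwise).
    """
    if pattern is not None:
        for ring in np.flatnonzero(pattern.missing):
            if int(ring) not in weights.rings:
                raise KeyError(
                    f"no weights for missing sample (ring={int(ring)}); weights "
                    f"cover rings {sorted(weights.rings)}"
                )
    out = under.copy()
    p_tot = under.traj.points_per_ring
    for ring, rw in sorted(weights.rings.items()):
        pts = (np.arange(p_tot)[:, None] + rw.spec.pt_offsets[None, :]) % p_tot
        x = under.data[:, rw.spec.src_rings][:, :, pts, :]  # (C, 2, P, kp, T)
        x = x.transpose(2, 4, 0, 1, 3).reshape(p_tot, under.n_spec, -1)
        out.data[:, ring] = np.einsum("ptk,pkc->cpt", x, rw.w)
    filled = np.array(sorted(weights.rings), dtype=int)
    out.measured_rings = out.measured_rings.copy()
    out.measured_rings[filled] = True
    return out


def reconstruct_recursive(
    under: RingKSpace,
    calib: RingKSpace,
    pattern: UndersamplingPattern,
    geom: GrappaGeometry | None = None,
    lam: float = 0.0,
) -> RingKSpace:
    """Walk the R=8 -> R=4 -> R=2 -> full ladder with per-stage weight solves."""
    model = TtkGrappa(recursive=True, lam=lam, **_geom_kwargs(geom))
    return model.fit(calib, pattern).predict(under)


def _geom_kwargs(geom: GrappaGeometry | None) -> dict:
    geom = geom or GrappaGeometry()
    return {
        "kernel_points": geom.kernel_points,
        "kernel_rings": geom.kernel_rings,
        "segment_points": geom.segment_points,
        "segment_rings": geom.segment_rings,
        "n_time_points": geom.n_time_points,
    }


class TtkGrappa(BaseEstimator):
    """Through-time/through-k-space GRAPPA reconstructor.

    fit(calib, pattern) solves the per-sample weights from a fully sampled
    calibration acquisition; predict(under) fills the missing rings of a
    matching undersampled acquisition.  With ``recursive=True`` accelerations
    4 and 8 are reconstructed as consecutive two-fold stages, re-solving the
    weights per stage against the same calibration set and geometry.

    Parameters mirror :class:`GrappaGeometry` plus the Tikhonov strength
    ``lam`` (relative to the mean diagonal of the normal matrix; 0 = plain
    least squares) and ``force`` to override the overdetermination refusal.

    Fitted attributes: ``stage_weights_`` (list of :class:`GrappaWeights`,
    one per stage), ``pattern_``, ``n_coils_``.
    """

    def __init__(
        self,
        kernel_points: int = 3,
        kernel_rings: int = 2,
        segment_points: int = 15,
        segment_rings: int = 4,
        n_time_points: int = 21,
        lam: float = 0.0,
        recursive: bool = False,
        force: bool = False,
    ):
        self.kernel_points = kernel_points
        self.kernel_rings = kernel_rings
        self.segment_points = segment_points
        self.segment_rings = segment_rings
        self.n_time_points = n_time_points
        self.lam = lam
        self.recursive = recursive
        self.force = force

    def _geometry(self) -> GrappaGeometry:
        return GrappaGeometry(
            kernel_points=self.kernel_points,
            kernel_rings=self.kernel_rings,
            segment_points=self.segment_points,
            segment_rings=self.segment_rings,
            n_time_points=self.n_time_points,
        )

    def fit(self, calib: RingKSpace, pattern: UndersamplingPattern) -> "TtkGrappa":
        geom = self._geometry()
        if self.recursive and pattern.nominal_R in (4, 8):
            ladder = stage_patterns(pattern)
        else:
            ladder = [make_pattern(pattern.n_rings, 1, 0)]
        current = pattern
        stages = []
        for nxt in ladder:
            # Only the rings this stage promotes to measured get weights;
            # sources are located against the stage's true sampling state.
            fill = np.flatnonzero(nxt.measured & current.missing)
            w = solve_weights(
                calib, current, geom, lam=self.lam, force=self.force,
                target_rings=fill,
            )
            stages.append(w)
            current = nxt
        self.stage_weights_ = stages
        self.pattern_ = pattern
        self.n_coils_ = calib.n_coils
        return self

    def predict(self, under: RingKSpace) -> RingKSpace:
        if not hasattr(self, "stage_weights_"):
            raise RuntimeError("TtkGrappa must be fitted before predict")
        if not np.array_equal(under.measured_rings, self.pattern_.measured):
            raise ValueError(
                "undersampled data's measured rings do not match the fitted pattern"
            )
        out = under
        for w in self.stage_weights_:
            out = apply_weights(out, w)
        return out
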