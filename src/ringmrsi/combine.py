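"""MUSICAL-style coil combination from a water-reference calibration.

The first spectral time point of the water-unsuppressed calibration
acquisition is gridded per coil into an image U_c, which approximates the
complex coil sensitivity times the water density.  The combination weights

    w_c(x) = conj(U_c(x)) / sum_c |U_c(x)|^2

both combine the channels near-optimally (matched filter for identity noise
covariance) and cancel the common phase at t=0, giving an intrinsic 0th-order
prephasing of every combined spectrum.  Voxels whose calibration power falls
below a floor are zeroed and masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .kspace import RingKSpace
from .trajectory import DensityWeights, grid_to_image, pipe_menon_dcf

__all__ = [
    "CombinationWeights",
    "MusicalCoilCombiner",
    "weights_from_calibration",
    "combine",
]


@dataclass
class CombinationWeights:
    """Per-voxel complex coil-combination weights.

    ``norm_mode`` is the normalization rule label ('sumsq' divides by
    sum |U|^2, 'rss' by sqrt(sum |U|^2)); ``source`` records which
    calibration set produced the weights (imusical | static | moved).
    """

    weights: np.ndarray  # (n_coils, N, N) complex
    mask: np.ndarray  # voxels with calibration power above the floor
    norm_mode: str
    source: str = ""


class MusicalCoilCombiner(BaseEstimator):
    """Water-reference coil combiner (fit on calibration, transform images).

    Parameters
    ----------
    norm_mode : {'sumsq', 'rss'}
        Weight normalization; 'sumsq' yields a sensitivity-corrected
        magnitude image, 'rss' a root-sum-of-squares-scaled one.
    floor_frac : float
        Voxels with calibration power below ``floor_frac`` times the image
        maximum are zeroed and excluded from the mask.

    Fitted attributes: ``weights_`` (:class:`CombinationWeights`).
    """

    def __init__(
        self,
        norm_mode: str = "sumsq",
        floor_frac: float = 1e-3,
        oversampling: float = 2.0,
        kb_width: float = 3.0,
    ):
        self.norm_mode = norm_mode
        self.floor_frac = floor_frac
        self.oversampling = oversampling
        self.kb_width = kb_width

    def fit(
        self,
        calib: RingKSpace,
        dcf: DensityWeights | None = None,
        source: str = "",
    ) -> "MusicalCoilCombiner":
        if self.norm_mode not in ("sumsq", "rss"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")
        if not bool(np.all(calib.measured_rings)):
            raise ValueError("calibration data must be fully sampled")
        if not np.any(calib.data):
            raise ValueError("calibration data is identically zero")
        if dcf is None:
            dcf = pipe_menon_dcf(calib.traj)
        u = grid_to_image(
            calib.data[..., 0], calib.traj, dcf,
            oversampling=self.oversampling, kb_width=self.kb_width,
        )  # (C, N, N)
        power = np.sum(np.abs(u) ** 2, axis=0)
        floor = self.floor_frac * float(power.max())
        mask = power > floor
        denom = power if self.norm_mode == "sumsq" else np.sqrt(power)
        w = np.zeros_like(u)
        w[:, mask] = u.conj()[:, mask] / denom[mask]
        self.weights_ = CombinationWeights(
            weights=w, mask=mask, norm_mode=self.norm_mode, source=source
        )
        return self

    def transform(self, coil_images: np.ndarray) -> np.ndarray:
        """Combine per-coil spatial(-spectral) images: s = sum_c w_c m_c."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("MusicalCoilCombiner must be fitted before transform")
        return combine(coil_images, self.weights_)


def weights_from_calibration(
    calib: RingKSpace,
    dcf: DensityWeights | None = None,
    norm_mode: str = "sumsq",
    floor_frac: float = 1e-3,
    source: str = "",
) -> CombinationWeights:
    """Derive combination weights from a water-reference calibration set."""
    return (
        MusicalCoilCombiner(norm_mode=norm_mode, floor_frac=floor_frac)
        .fit(calib, dcf=dcf, source=source)
        .weights_
    )


def combine(coil_images: np.ndarray, weights: CombinationWeights) -> np.ndarray:
    """Linear weighted coil combination.

    ``coil_images`` has shape (n_coils, N, N) or (n_coils, N, N, n_spec);
    the result drops the coil axis.
    """
    coil_images = np.asarray(coil_images)
    w = weights.weights
    if coil_images.shape[: w.ndim] != w.shape:
        raise ValueError(
            f"coil image shape {coil_images.shape} does not match weight shape "
            f"{w.shape}"
        )
    extra = coil_images.ndim - w.ndim
    wb = w.reshape(w.shape + (1,) * extra)
    return np.sum(wb * coil_images, axis=0)
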