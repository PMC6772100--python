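"""Container for multichannel spatial-spectral ring k-space data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import RingTrajectory

__all__ = ["RingKSpace"]


@dataclass
class RingKSpace:
    """Complex ring samples indexed ``(coil, ring, point-on-ring, spectral_time)``.

    ``dwell`` is the spectral dwell time in seconds (1 / spectral bandwidth).
    ``measured_rings`` marks which rings carry data; fully sampled sets have
    all rings measured.  ``flip_scale`` records the relative excitation
    scaling of this acquisition (e.g. a low-flip water-reference calibration).
    """

    data: np.ndarray
    traj: RingTrajectory
    dwell: float
    measured_rings: np.ndarray = field(default=None)  # type: ignore[assignment]
    flip_scale: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"data must be (coil, ring, point, spectral_time), got shape "
                f"{self.data.shape}"
            )
        if self.data.shape[1:3] != (self.traj.n_rings, self.traj.points_per_ring):
            raise ValueError(
                f"data shape {self.data.shape} does not match trajectory "
                f"({self.traj.n_rings} rings x {self.traj.points_per_ring} points)"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space data contains non-finite values")
        if self.dwell <= 0:
            raise ValueError(f"dwell must be positive, got {self.dwell}")
        if self.measured_rings is None:
            self.measured_rings = np.ones(self.traj.n_rings, dtype=bool)
        else:
            self.measured_rings = np.asarray(self.measured_rings, dtype=bool)
            if self.measured_rings.shape != (self.traj.n_rings,):
                raise ValueError(
                    f"measured_rings must have one flag per ring "
                    f"({self.traj.n_rings}), got shape {self.measured_rings.shape}"
                )

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_spec(self) -> int:
        return self.data.shape[-1]

    @property
    def spectral_bandwidth(self) -> float:
        return 1.0 / self.dwell

    def copy(self) -> "RingKSpace":
        return replace(self, data=self.data.copy(), measured_rings=self.measured_rings.copy())
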