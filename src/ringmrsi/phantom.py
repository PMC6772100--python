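"""Digital brain phantom and synthetic multichannel MRSI acquisition.

The phantom stands in for a volunteer's head at 7 T: an elliptical brain
with gray-matter / white-matter / CSF structure, a 2-voxel subcutaneous
lipid rim outside the brain, and per-compartment amplitudes for the named
resonances (tNAA 2.01, tCr 3.02, tCho 3.2 ppm, lipids at 1.3 / 0.9 ppm,
water at the 4.7 ppm carrier).  Each voxel emits a sum-of-Lorentzians FID;
the acquisition evaluates the coil-weighted non-uniform DFT of that cube on
a concentric-ring trajectory and adds i.i.d. complex Gaussian noise.

Water-reference calibration scans are the same acquisition with water
included (no suppression), few spectral points, and a reduced flip scale;
the "moved" prescan rotates the head (`apply_motion`) before acquiring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .kspace import RingKSpace
from .trajectory import RingTrajectory, image_to_rings

__all__ = [
    "DigitalPhantom",
    "CoilProfileSet",
    "make_phantom",
    "make_coil_profiles",
    "simulate_fid_cube",
    "acquire",
    "apply_motion",
    "GYRO_MHZ_7T",
    "CARRIER_PPM",
]

GYRO_MHZ_7T = 297.2  # proton frequency at 7 T, MHz
CARRIER_PPM = 4.7  # water carrier

# ppm positions and Lorentzian T2* (ms) of the simulated resonances.
DEFAULT_SHIFTS = {
    "water": 4.7,
    "tnaa": 2.01,
    "tcr": 3.02,
    "tcho": 3.2,
    "lip13": 1.3,
    "lip09": 0.9,
}
DEFAULT_LINEWIDTHS = {
    "water": 30.0,
    "tnaa": 24.0,
    "tcr": 24.0,
    "tcho": 24.0,
    "lip13": 20.0,
    "lip09": 20.0,
}
# Per-compartment amplitudes (arbitrary units; water ~40x metabolites,
# subcutaneous lipid far above brain metabolite level).
DEFAULT_CONCS = {
    "water": {"gm": 40.0, "wm": 35.0, "csf": 50.0, "lipid": 5.0},
    "tnaa": {"gm": 1.25, "wm": 1.0},
    "tcr": {"gm": 1.0, "wm": 0.8},
    "tcho": {"gm": 0.3, "wm": 0.35},
    "lip13": {"lipid": 40.0},
    "lip09": {"lipid": 20.0},
}


@dataclass
class DigitalPhantom:
    """Tissue-compartment phantom with known metabolite ground truth."""

    matrix_size: int
    fov: float
    tissue_maps: dict[str, np.ndarray]  # occupancy in [0, 1] per compartment
    metabolite_concs: dict[str, dict[str, float]]
    chemical_shifts: dict[str, float]
    linewidths: dict[str, float]  # T2* in ms
    b0_map: np.ndarray  # off-resonance, Hz
    brain_mask: np.ndarray

    @property
    def resonances(self) -> list[str]:
        return list(self.metabolite_concs)

    def amplitude_map(self, name: str) -> np.ndarray:
        """Ground-truth amplitude image of one resonance."""
        if name not in self.metabolite_concs:
            raise KeyError(
                f"unknown resonance {name!r}; known: {sorted(self.metabolite_concs)}"
            )
        out = np.zeros((self.matrix_size, self.matrix_size))
        for comp, amp in self.metabolite_concs[name].items():
            out += amp * self.tissue_maps[comp]
        return out


@dataclass
class CoilProfileSet:
    """Smooth complex receive sensitivities with identity noise covariance."""

    n_coils: int
    sensitivities: np.ndarray  # (n_coils, N, N) complex
    noise_cov: np.ndarray

    @property
    def matrix_size(self) -> int:
        return self.sensitivities.shape[-1]


def _ellipse(n: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    """Radial coordinate of an axis-aligned ellipse on normalized [-1,1] grid."""
    coords = np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    return np.sqrt(((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2)


def make_phantom(matrix_size: int, seed: int = 0, fov: float = 220.0) -> DigitalPhantom:
    """Deterministic ellipsoidal brain phantom with a subcutaneous lipid rim.

    The seed jitters ellipse axes and ventricle placement slightly so that
    different seeds give different but equally plausible anatomies.
    """
    if matrix_size < 16:
        raise ValueError(f"matrix_size must be >= 16, got {matrix_size}")
    rng = np.random.default_rng(seed)
    jit = lambda s: 1.0 + s * rng.uniform(-1.0, 1.0)

    n = matrix_size
    brain = _ellipse(n, 0.0, 0.0, 0.60 * jit(0.03), 0.72 * jit(0.03)) <= 1.0
    wm = _ellipse(n, 0.0, -0.02, 0.40 * jit(0.04), 0.50 * jit(0.04)) <= 1.0
    wm &= brain
    # Two ventricles carved from white matter.
    v_dx = 0.10 * jit(0.1)
    csf = (_ellipse(n, -v_dx, 0.06, 0.07, 0.16) <= 1.0) | (
        _ellipse(n, v_dx, 0.06, 0.07, 0.16) <= 1.0
    )
    csf &= wm
    wm &= ~csf
    gm = brain & ~wm & ~csf

    # Lipid rim: 2 voxels thick, separated from the brain by 1 voxel.
    rim = ndimage.binary_dilation(brain, iterations=3) & ~ndimage.binary_dilation(
        brain, iterations=1
    )

    tissue = {
        "gm": gm.astype(float),
        "wm": wm.astype(float),
        "csf": csf.astype(float),
        "lipid": rim.astype(float),
    }
    return DigitalPhantom(
        matrix_size=n,
        fov=float(fov),
        tissue_maps=tissue,
        metabolite_concs={k: dict(v) for k, v in DEFAULT_CONCS.items()},
        chemical_shifts=dict(DEFAULT_SHIFTS),
        linewidths=dict(DEFAULT_LINEWIDTHS),
        b0_map=np.zeros((n, n)),
        brain_mask=brain,
    )


def make_coil_profiles(
    matrix_size: int, n_coils: int = 8, seed: int = 0
) -> CoilProfileSet:
    """Gaussian-blob receive profiles placed on a circle around the FOV.

    Each coil has a smooth magnitude bump outside the object and a smooth
    (constant + linear) phase; bandlimited by construction.
    """
    rng = np.random.default_rng(seed)
    n = matrix_size
    coords = np.linspace(-1.0, 1.0, n, endpoint=False) + 1.0 / n
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    sens = np.empty((n_coils, n, n), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        cx, cy = 0.85 * np.cos(ang), 0.85 * np.sin(ang)
        mag = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.55**2)))
        gx, gy = rng.uniform(-1.5, 1.5, size=2)
        phase = rng.uniform(0, 2 * np.pi) + gx * xx + gy * yy
        sens[c] = mag * np.exp(1j * phase)
    return CoilProfileSet(
        n_coils=n_coils, sensitivities=sens, noise_cov=np.eye(n_coils)
    )


def simulate_fid_cube(
    phantom: DigitalPhantom,
    n_spec: int,
    dwell: float,
    resonances: list[str] | None = None,
    carrier_ppm: float = CARRIER_PPM,
    field_mhz: float = GYRO_MHZ_7T,
) -> np.ndarray:
    """Per-voxel sum-of-Lorentzians FID cube, shape (N, N, n_spec).

    Each resonance m contributes
    ``A_m(x) exp(2i pi f_m t) exp(-t / T2*_m)`` with ``f_m = (ppm_m -
    carrier_ppm) * field_mhz`` Hz; a per-voxel ``exp(2i pi b0(x) t)`` factor
    applies the off-resonance map.
    """
    if n_spec < 8:
        raise ValueError(f"n_spec must be >= 8, got {n_spec}")
    names = list(phantom.metabolite_concs) if resonances is None else list(resonances)
    unknown = [m for m in names if m not in phantom.metabolite_concs]
    if unknown:
        raise KeyError(
            f"unknown resonance(s) {unknown}; known: {sorted(phantom.metabolite_concs)}"
        )
    t = np.arange(n_spec) * dwell
    n = phantom.matrix_size
    fid = np.zeros((n, n, n_spec), dtype=complex)
    for name in names:
        amp = phantom.amplitude_map(name)
        f_hz = (phantom.chemical_shifts[name] - carrier_ppm) * field_mhz
        t2s = phantom.linewidths[name] * 1e-3
        sig = np.exp((2j * np.pi * f_hz - 1.0 / t2s) * t)
        fid += amp[:, :, None] * sig[None, None, :]
    if np.any(phantom.b0_map):
        fid *= np.exp(2j * np.pi * phantom.b0_map[:, :, None] * t[None, None, :])
    return fid


def metabolite_resonances(phantom: DigitalPhantom) -> list[str]:
    """Resonance names excluding water (a perfectly water-suppressed scan)."""
    return [m for m in phantom.metabolite_concs if m != "water"]


def acquire(
    phantom: DigitalPhantom,
    coils: CoilProfileSet,
    traj: RingTrajectory,
    n_spec: int,
    dwell: float,
    flip_scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    water_suppressed: bool = True,
) -> RingKSpace:
    """Simulate a multichannel concentric-ring spatial-spectral acquisition.

    ``data[c, r, p, t]`` is the NUDFT over space of ``sens_c * fid(., ., t)``
    at ring sample (r, p), scaled by ``flip_scale``, plus i.i.d. complex
    Gaussian noise with per-component standard deviation ``noise_sd``.
    Calibration datasets use the same operation with small ``n_spec``,
    ``water_suppressed=False``, and a reduced ``flip_scale``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if coils.matrix_size != phantom.matrix_size:
        raise ValueError(
            f"coil matrix {coils.matrix_size} != phantom matrix {phantom.matrix_size}"
        )
    resonances = metabolite_resonances(phantom) if water_suppressed else None
    fid = simulate_fid_cube(phantom, n_spec, dwell, resonances=resonances)
    # (C, N, N, T) weighted cubes -> NUDFT in one batched matmul.
    weighted = coils.sensitivities[:, :, :, None] * fid[None]
    samples = image_to_rings(np.moveaxis(weighted, -1, 1), traj)  # (C, T, R, P)
    data = np.moveaxis(samples, 1, -1) * flip_scale
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )
    return RingKSpace(data=data, traj=traj, dwell=dwell, flip_scale=flip_scale)


def apply_motion(obj, rotation_deg: float):
    """Rotate a phantom or coil-profile set in-plane (bilinear interpolation).

    Emulates the subject rotating their head between the MRSI scan and a
    prescan; masks are re-derived by thresholding the rotated occupancies.
    """
    if abs(rotation_deg) > 45:
        raise ValueError(f"|rotation_deg| must be <= 45, got {rotation_deg}")
    if rotation_deg == 0:
        return obj

    def rot(img: np.ndarray) -> np.ndarray:
        if np.iscomplexobj(img):
            return rot(img.real) + 1j * rot(img.imag)
        return ndimage.rotate(img, rotation_deg, reshape=False, order=1)

    if isinstance(obj, DigitalPhantom):
        tissue = {k: np.clip(rot(v), 0.0, 1.0) for k, v in obj.tissue_maps.items()}
        brain = (tissue["gm"] + tissue["wm"] + tissue["csf"]) > 0.5
        return replace(
            obj, tissue_maps=tissue, b0_map=rot(obj.b0_map), brain_mask=brain
        )
    if isinstance(obj, CoilProfileSet):
        sens = np.stack([rot(s) for s in obj.sensitivities])
        return replace(obj, sensitivities=sens)
    raise TypeError(f"cannot rotate object of type {type(obj).__name__}")
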