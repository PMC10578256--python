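"""Shared containers, acquisition parameters, configuration and NIfTI I/O.

The quantities handled throughout the package live on regular 3-D voxel
grids.  A :class:`MultiEchoImage` stacks one volume per echo (complex for
the gradient-echo Dixon acquisition, magnitude for the multi-echo
spin-echo), together with the echo times and voxel geometry needed to
interpret them.  :class:`AcquisitionParams` carries the sequence timing
(echo times, TR, flip angle), the static field strength and the chemical
shift of the fat resonance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "MUSCLES",
    "EYES",
    "AcquisitionParams",
    "MultiEchoImage",
    "fat_frequency_hz",
    "fat_phasor",
    "default_config",
    "load_config",
    "dixon_params_from_config",
    "mse_params_from_config",
    "save_nifti",
    "load_nifti",
]

#: Proton gyromagnetic ratio, MHz/T.
GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577478518

#: The four rectus-muscle ROIs.  The superior rectus is segmented together
#: with the levator palpebrae superioris ("SR_LPS") because the two cannot
#: be separated reliably on orbital images.
MUSCLES = ("LR", "MR", "IR", "SR_LPS")
EYES = ("L", "R")


@dataclass(frozen=True)
class AcquisitionParams:
    """Timing and field parameters of a multi-echo acquisition.

    Parameters
    ----------
    echo_times_ms
        Strictly increasing echo times in milliseconds.
    tr_ms
        Repetition time in milliseconds; must exceed the last echo time.
    nominal_flip_deg
        Nominal excitation flip angle in degrees, in (0, 90].
    voxel_size_mm
        Per-axis voxel edge lengths in millimetres.
    field_strength_t
        Static field strength in tesla.
    fat_shift_ppm
        Signed chemical shift of the (single-peak) fat resonance relative
        to water, in ppm.  Negative: fat resonates below water.
    """

    echo_times_ms: tuple[float, ...]
    tr_ms: float
    nominal_flip_deg: float
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    field_strength_t: float = 7.0
    fat_shift_ppm: float = -3.4

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times_ms must be a non-empty 1-D sequence")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing")
        if self.tr_ms <= te[-1]:
            raise ValueError("tr_ms must exceed the last echo time")
        if not (0.0 < self.nominal_flip_deg <= 90.0):
            raise ValueError("nominal_flip_deg must lie in (0, 90]")
        object.__setattr__(self, "echo_times_ms", tuple(float(t) for t in te))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)


@dataclass
class MultiEchoImage:
    """A stack of 3-D volumes, one per echo.

    ``data`` has shape ``(n_echoes, nx, ny, nz)`` and is complex for Dixon
    echoes and real (magnitude) for spin-echo trains.
    """

    data: np.ndarray
    echo_times_ms: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must have shape (n_echoes, nx, ny, nz)")
        if self.data.shape[0] != len(self.echo_times_ms):
            raise ValueError(
                f"{self.data.shape[0]} echo volumes but "
                f"{len(self.echo_times_ms)} echo times"
            )

    @property
    def n_echoes(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


def fat_frequency_hz(acq: AcquisitionParams) -> float:
    """Fat resonance offset in Hz: ``fat_shift_ppm * gamma * B0``."""
    return (
        acq.fat_shift_ppm * 1e-6
        * GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6
        * acq.field_strength_t
    )


def fat_phasor(
    acq: AcquisitionParams,
    echo_times_ms: Sequence[float] | None = None,
    spectrum: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Complex fat signal phasor c(TE) at each echo time.

    With the default single-peak model ``c(TE) = exp(i 2 pi f_fat TE)``.
    ``spectrum`` may give a multi-peak model as ``(relative_amplitude,
    shift_ppm)`` pairs; amplitudes are normalised to sum to one and the
    phasor is their amplitude-weighted sum.
    """
    te_s = np.asarray(
        acq.echo_times_ms if echo_times_ms is None else echo_times_ms,
        dtype=float,
    ) * 1e-3
    if spectrum is None:
        spectrum = [(1.0, acq.fat_shift_ppm)]
    amps = np.array([a for a, _ in spectrum], dtype=float)
    amps = amps / amps.sum()
    shifts_hz = np.array(
        [s * 1e-6 * GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6 * acq.field_strength_t
         for _, s in spectrum]
    )
    return (amps[None, :] * np.exp(2j * np.pi * shifts_hz[None, :] * te_s[:, None])).sum(axis=1)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "dixon": {
        "te1_ms": 2.4,
        "dte_ms": 0.33,
        "n_echoes": 3,
        "tr_ms": 8.0,
        "flip_deg": 7.0,
        "t1_water_ms": 1400.0,
        "t1_fat_ms": 380.0,
        "fat_shift_ppm": -3.4,
        "field_strength_t": 7.0,
        "voxel_size_mm": [0.8, 0.8, 0.8],
        # IDEAL per-voxel solver
        "psi_tol_hz": 0.01,
        "max_iter": 50,
    },
    "mse": {
        "te1_ms": 9.0,
        "dte_ms": 9.0,
        "n_echoes": 24,
        "n_rf_disabled": 3,
        "tr_ms": 4000.0,
        "flip_deg": 90.0,
        "voxel_size_mm": [1.2, 1.2, 3.0],
        "t1_water_ms": 1400.0,
        "t1_fat_ms": 365.0,
        # dictionary grids
        "t2water_min_ms": 10.0,
        "t2water_max_ms": 60.0,
        "t2water_step_ms": 0.5,
        "t2fat_min_ms": 120.0,
        "t2fat_max_ms": 200.0,
        "t2fat_step_ms": 5.0,
        "b1_min": 0.50,
        "b1_max": 1.00,
        "b1_step": 0.01,
        # slice profile: Hann-windowed sinc, small-tip Fourier approximation
        "slice_profile_bins": 51,
        "slice_time_bandwidth": 4.0,
        # refocusing slice narrower by the gradient-strength ratio
        "refocus_gradient_ratio": 3.15 / 3.78,
        "noise_floor_subtraction": True,
    },
    "segmentation": {
        "band_k_sigma": 2.0,
        "max_voxels": 200000,
        "largest_component_only": False,
    },
    "orthoptics": {
        "cap_abduction_deg": 40.0,
        "cap_adduction_deg": 40.0,
        "cap_elevation_deg": 30.0,
        "cap_depression_deg": 30.0,
        "cap_diagonal_deg": 35.0,
        "hess_cutoff_deg": 5.0,
    },
    "stats": {
        "alpha": 0.05,
        "pool_eyes": True,
        "sd_band_per_eye": True,
    },
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT_CONFIG)


def _deep_update(base: dict, extra: dict) -> dict:
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file (deep-merged)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, user)
    return cfg


def dixon_params_from_config(cfg: dict | None = None) -> AcquisitionParams:
    d = (cfg or default_config())["dixon"]
    te = [d["te1_ms"] + i * d["dte_ms"] for i in range(d["n_echoes"])]
    return AcquisitionParams(
        echo_times_ms=tuple(te),
        tr_ms=d["tr_ms"],
        nominal_flip_deg=d["flip_deg"],
        voxel_size_mm=tuple(d["voxel_size_mm"]),
        field_strength_t=d["field_strength_t"],
        fat_shift_ppm=d["fat_shift_ppm"],
    )


def mse_params_from_config(cfg: dict | None = None) -> AcquisitionParams:
    m = (cfg or default_config())["mse"]
    te = [m["te1_ms"] + i * m["dte_ms"] for i in range(m["n_echoes"])]
    return AcquisitionParams(
        echo_times_ms=tuple(te),
        tr_ms=m["tr_ms"],
        nominal_flip_deg=m["flip_deg"],
        voxel_size_mm=tuple(m["voxel_size_mm"]),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_for(voxel_size_mm: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(
    volume: np.ndarray,
    path: str | Path,
    voxel_size_mm: Sequence[float] = (0.8, 0.8, 0.8),
    affine: np.ndarray | None = None,
) -> None:
    """Write a 3-D (or 4-D echo-stacked) volume as NIfTI.

    Complex volumes are written as a real/imaginary pair along a trailing
    axis, since NIfTI has no native complex dtype guaranteed across
    readers; :func:`load_nifti` reverses this.
    """
    vol = np.asarray(volume)
    if affine is None:
        affine = _affine_for(voxel_size_mm)
    if np.iscomplexobj(vol):
        vol = np.stack([vol.real, vol.imag], axis=-1).astype(np.float32)
        img = nib.Nifti1Image(vol, affine)
        img.header["intent_name"] = b"complex_ri"
    else:
        if vol.dtype.kind in "ui":
            vol = vol.astype(np.int16)
        else:
            vol = vol.astype(np.float32)
        img = nib.Nifti1Image(vol, affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns ``(array, affine)``.

    Volumes written by :func:`save_nifti` with complex data are
    reassembled into a complex array.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    intent = bytes(img.header["intent_name"]).rstrip(b"\x00")
    if intent == b"complex_ri":
        data = data[..., 0] + 1j * data[..., 1]
    return data, img.affine
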