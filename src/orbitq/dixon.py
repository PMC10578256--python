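"""IDEAL water-fat decomposition and T1-bias-corrected fat fractions.

Per voxel the 3-point gradient-echo signal is modelled as

    s(TE_n) = (W + F c(TE_n)) exp(i 2 pi psi TE_n)

with complex water and fat amplitudes W, F, the B0 field-map offset psi
(Hz) and the fat phasor c(TE) of the configured chemical-shift model.
IDEAL alternates a linear least-squares solve for (W, F) given psi with a
linearised joint update of (psi, W, F) until the field map converges.
Each voxel is solved independently: no field-map smoothing, region
growing, or T2* correction is applied.

Because the spoiled gradient-echo steady state saturates water and fat
differently (their T1s differ), the raw fat fraction is T1-biased; it is
corrected by dividing each compartment by its Ernst-equation saturation
factor at the effective (B1-scaled) flip angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParams, MultiEchoImage, fat_phasor

__all__ = [
    "WaterFatMaps",
    "ideal_decompose",
    "ernst_factor",
    "t1_corrected_ff",
    "effective_flip_angle",
]


@dataclass
class WaterFatMaps:
    """Per-voxel water/fat amplitudes, field map and fat fraction.

    ``ff`` is ``fat / (water + fat)`` where the denominator is positive
    and NaN elsewhere (flagged in ``undefined``).  ``converged`` marks
    voxels whose field-map update reached tolerance.
    """

    water: np.ndarray
    fat: np.ndarray
    psi_hz: np.ndarray
    ff: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    undefined: np.ndarray


def ernst_factor(flip_deg: float, tr_ms: float, t1_ms: float) -> float:
    """Spoiled gradient-echo saturation factor sin a (1-E1)/(1 - E1 cos a).

    ``E1 = exp(-TR/T1)``.  A zero flip angle validly yields 0.
    """
    if t1_ms <= 0:
        raise ValueError("T1 must be positive")
    if tr_ms <= 0:
        raise ValueError("TR must be positive")
    if flip_deg < 0:
        raise ValueError("flip angle must be non-negative")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / t1_ms)
    return float(np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a)))


def effective_flip_angle(
    b1_map: np.ndarray,
    roi_mask: np.ndarray,
    nominal_flip_deg: float,
) -> float:
    """ROI-average relative B1 times the nominal flip angle, in degrees.

    The muscle-specific effective flip angle is the arithmetic mean of the
    relative-B1 values over the (typically all-recti) ROI.
    """
    b1_map = np.asarray(b1_map, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if roi_mask.shape != b1_map.shape:
        raise ValueError("ROI mask not congruent with B1 map")
    if not roi_mask.any():
        raise ValueError("ROI is empty")
    return float(b1_map[roi_mask].mean() * nominal_flip_deg)


def _signal_matrix(acq: AcquisitionParams,
                   spectrum=None) -> tuple[np.ndarray, np.ndarray]:
    te_s = np.asarray(acq.echo_times_ms, dtype=float) * 1e-3
    c = fat_phasor(acq, spectrum=spectrum)
    a = np.column_stack([np.ones_like(c), c])  # (n_echoes, 2)
    return te_s, a


def ideal_decompose(
    images: MultiEchoImage,
    acq: AcquisitionParams,
    psi_tol_hz: float = 0.01,
    max_iter: int = 50,
    psi_init_hz: float | np.ndarray = 0.0,
    spectrum=None,
) -> WaterFatMaps:
    """Voxel-wise iterative water-fat decomposition of complex echoes.

    Starting from ``psi_init_hz`` (0 by default), each iteration solves
    the complex linear least squares for (W, F) at the current field map
    and then a linearised real-valued least squares for the joint update
    (d_psi, dW, dF); iteration stops when ``|d_psi| < psi_tol_hz`` or
    after ``max_iter`` sweeps.  Non-converged voxels keep their last
    estimate and are flagged, not zeroed.

    Field-map offsets beyond roughly ``1 / (2 dTE)`` of the initial value
    alias onto the wrong chemical-shift solution (water-fat swaps); no
    spatial information is used to resolve them.
    """
    data = np.asarray(images.data)
    if not np.iscomplexobj(data):
        raise ValueError("IDEAL requires complex echo data")
    n_echoes = data.shape[0]
    if n_echoes < 3:
        raise ValueError("need at least 3 echoes for W, F and psi")
    if n_echoes != acq.n_echoes:
        raise ValueError("echo count of image and acquisition differ")

    te_s, a_mat = _signal_matrix(acq, spectrum)
    # pseudo-inverse for the (W, F) solve is voxel-independent
    a_pinv = np.linalg.pinv(a_mat)  # (2, n_echoes)

    grid_shape = data.shape[1:]
    s = data.reshape(n_echoes, -1).T  # (v, n_echoes)
    n_vox = s.shape[0]
    psi = np.broadcast_to(np.asarray(psi_init_hz, dtype=float),
                          grid_shape).reshape(-1).copy()
    active = np.ones(n_vox, dtype=bool)
    converged = np.zeros(n_vox, dtype=bool)
    x = np.zeros((n_vox, 2), dtype=complex)  # (W, F)

    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        phase = np.exp(-2j * np.pi * psi[idx, None] * te_s[None, :])
        d = s[idx] * phase  # demodulated signal
        x[idx] = d @ a_pinv.T
        s_hat = x[idx] @ a_mat.T  # (v, n_echoes)
        resid = d - s_hat
        # linearised model: resid ~ g d_psi + dW + c dF, g = 2i pi TE s_hat
        g = 2j * np.pi * te_s[None, :] * s_hat
        # stack real system: columns [g, 1, c] over Re/Im, solve 5-par LS
        b = np.empty((idx.size, 2 * n_echoes, 5))
        rhs = np.empty((idx.size, 2 * n_echoes))
        cols = np.broadcast_to(a_mat, (idx.size,) + a_mat.shape)
        b[:, :n_echoes, 0] = g.real
        b[:, n_echoes:, 0] = g.imag
        b[:, :n_echoes, 1] = cols[..., 0].real
        b[:, n_echoes:, 1] = cols[..., 0].imag
        b[:, :n_echoes, 2] = -cols[..., 0].imag
        b[:, n_echoes:, 2] = cols[..., 0].real
        b[:, :n_echoes, 3] = cols[..., 1].real
        b[:, n_echoes:, 3] = cols[..., 1].imag
        b[:, :n_echoes, 4] = -cols[..., 1].imag
        b[:, n_echoes:, 4] = cols[..., 1].real
        rhs[:, :n_echoes] = resid.real
        rhs[:, n_echoes:] = resid.imag
        bt_b = np.einsum("vec,ved->vcd", b, b)
        bt_r = np.einsum("vec,ve->vc", b, rhs)
        # tiny Tikhonov term keeps zero-signal voxels solvable without
        # perturbing well-conditioned systems (relative 1e-12)
        trace = np.einsum("vcc->v", bt_b)
        eps = 1e-12 * np.maximum(trace, 1e-30)
        bt_b[:, np.arange(5), np.arange(5)] += eps[:, None]
        upd = np.linalg.solve(bt_b, bt_r[..., None])[..., 0]
        d_psi = upd[:, 0]
        psi[idx] += d_psi
        done = np.abs(d_psi) < psi_tol_hz
        converged[idx[done]] = True
        active[idx[done]] = False

    # final (W, F) at the converged field map
    phase = np.exp(-2j * np.pi * psi[:, None] * te_s[None, :])
    d = s * phase
    x = d @ a_pinv.T
    resid = d - x @ a_mat.T
    residual = np.linalg.norm(resid, axis=1)

    water = np.abs(x[:, 0])
    fat = np.abs(x[:, 1])
    total = water + fat
    undefined = total <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(undefined, np.nan, fat / np.where(undefined, 1.0, total))

    shape = grid_shape
    return WaterFatMaps(
        water=water.reshape(shape),
        fat=fat.reshape(shape),
        psi_hz=psi.reshape(shape),
        ff=ff.reshape(shape),
        residual=residual.reshape(shape),
        converged=converged.reshape(shape),
        undefined=undefined.reshape(shape),
    )


def t1_corrected_ff(
    maps: WaterFatMaps,
    acq: AcquisitionParams,
    alpha_eff_deg: float,
    t1_water_ms: float = 1400.0,
    t1_fat_ms: float = 380.0,
) -> np.ndarray:
    """Ernst-equation T1-bias correction of the fat-fraction map.

    ``W' = W / E(a_eff, TR, T1water)``, ``F' = F / E(a_eff, TR, T1fat)``,
    ``FF_corr = F' / (W' + F')``.  Voxels with no signal stay NaN.  Equal
    T1s cancel and leave the fat fraction unchanged; FF of exactly 0 or 1
    is a fixed point.
    """
    if not (0.0 < alpha_eff_deg <= 90.0):
        raise ValueError("alpha_eff_deg must lie in (0, 90]")
    ew = ernst_factor(alpha_eff_deg, acq.tr_ms, t1_water_ms)
    ef = ernst_factor(alpha_eff_deg, acq.tr_ms, t1_fat_ms)
    w = maps.water / ew
    f = maps.fat / ef
    total = w + f
    undefined = total <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(undefined, np.nan, f / np.where(undefined, 1.0, total))
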