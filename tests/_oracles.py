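"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own algorithms: the CPMG oracle
rotates explicit isochromat magnetisation vectors, and the water-fat
oracle scans the field map on a dense grid.
"""

from __future__ import annotations

import numpy as np


def bloch_cpmg(
    t2_ms: float,
    t1_ms: float,
    b1: float,
    n_echoes: int = 24,
    dte_ms: float = 9.0,
    n_isochromats: int = 2000,
    exc_deg: float = 90.0,
    ref_deg: float = 180.0,
) -> np.ndarray:
    """CPMG echo magnitudes from a rotation-matrix isochromat simulation.

    Isochromats carry dephasing angles uniformly covering [0, 2pi) per
    half echo spacing; excitation is about +y, refocusing about +x.
    """
    phi = 2.0 * np.pi * (np.arange(n_isochromats) + 0.5) / n_isochromats
    m = np.zeros((3, n_isochromats))
    m[2] = 1.0

    def rot_y(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

    def rot_x(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

    e2 = np.exp(-dte_ms / 2.0 / t2_ms)
    e1 = np.exp(-dte_ms / 2.0 / t1_ms)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    def precess_relax(m):
        mx = m[0] * cos_p - m[1] * sin_p
        my = m[0] * sin_p + m[1] * cos_p
        out = np.empty_like(m)
        out[0] = mx * e2
        out[1] = my * e2
        out[2] = 1.0 + (m[2] - 1.0) * e1
        return out

    m = rot_y(np.deg2rad(exc_deg) * b1) @ m
    refocus = rot_x(np.deg2rad(ref_deg) * b1)
    echoes = np.zeros(n_echoes)
    for n in range(n_echoes):
        m = precess_relax(m)
        m = refocus @ m
        m = precess_relax(m)
        echoes[n] = np.abs(np.mean(m[0] + 1j * m[1]))
    return echoes


def ideal_grid_search(
    signal: np.ndarray,
    echo_times_ms: np.ndarray,
    fat_phasor: np.ndarray,
    psi_range_hz: tuple[float, float] = (-200.0, 200.0),
    coarse_step_hz: float = 1.0,
) -> tuple[float, complex, complex]:
    """Brute-force water-fat solve: scan psi, linear LS per candidate.

    Returns (psi, W, F) minimising the residual; the coarse grid winner
    is refined by golden-section search.
    """
    te_s = np.asarray(echo_times_ms, dtype=float) * 1e-3
    a = np.column_stack([np.ones_like(fat_phasor), fat_phasor])
    a_pinv = np.linalg.pinv(a)

    def residual(psi: float) -> float:
        d = signal * np.exp(-2j * np.pi * psi * te_s)
        x = a_pinv @ d
        return float(np.linalg.norm(d - a @ x))

    grid = np.arange(psi_range_hz[0], psi_range_hz[1] + 1e-9, coarse_step_hz)
    res = [residual(p) for p in grid]
    best = grid[int(np.argmin(res))]

    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(
        residual,
        bracket=(best - coarse_step_hz, best, best + coarse_step_hz),
        method="golden",
        options={"xtol": 1e-10},
    )
    psi = float(opt.x)
    d = signal * np.exp(-2j * np.pi * psi * te_s)
    w, f = a_pinv @ d
    return psi, complex(w), complex(f)


def ellipsoid_volume_mm3(semi_axes_mm) -> float:
    a, b, c = semi_axes_mm
    return 4.0 / 3.0 * np.pi * a * b * c
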