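"""Radiochromic-film calibration and dose-plane conversion.

Film pieces scanned in 16-bit RGB transmission mode are converted to net
optical density from the red channel,

    nod = log10(PV0 / PVexp),

with PV0 the mean pixel value of an unexposed control piece.  The
dose-response is fitted with the two-term calibration

    nod(D) = k1 * D + k2 * D**n,

and dose planes are obtained by median-filtering the scan (5x5), converting
to nod, and inverting the calibration per pixel, in that protocol order.
(A median filter commutes exactly with the monotone nod/dose maps, so the
order is protocol fidelity rather than a numerical necessity; it would
matter for any averaging filter.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "FilmCalibration",
    "net_optical_density",
    "fit_calibration",
    "dose_from_nod",
    "film_to_dose",
    "load_calibration",
    "save_calibration",
    "render_film",
]

#: calibration doses (Gy) used for the packaged synthetic fixture grid
CALIBRATION_DOSES_GY = (0.47, 0.95, 1.90, 3.79, 6.64, 9.48, 14.22, 18.96, 28.44)


@dataclass(frozen=True)
class FilmCalibration:
    """Fitted parameters of the net-optical-density dose response."""

    k1: float  # linear coefficient, nod per Gy
    k2: float  # power-term coefficient
    n_exp: float  # power-term exponent, dimensionless
    dose_max: float  # upper end of the fitted dose range, Gy
    rms: float  # fit residual, nod units

    def nod(self, dose) -> np.ndarray:
        """Forward response nod(D) = k1*D + k2*D^n."""
        d = np.asarray(dose, dtype=float)
        return self.k1 * d + self.k2 * np.sign(d) * np.abs(d) ** self.n_exp

    def is_monotone(self, n_check: int = 512) -> bool:
        d = np.linspace(0.0, self.dose_max, n_check)
        return bool(np.all(np.diff(self.nod(d)) > 0))


def net_optical_density(pv_exp, pv0) -> np.ndarray:
    """nod = log10(pv0 / pv_exp); raises on non-positive pixel values."""
    pv_exp = np.asarray(pv_exp, dtype=float)
    if np.any(pv_exp <= 0) or pv0 <= 0:
        raise ValueError("pixel values must be positive")
    return np.log10(pv0 / pv_exp)


def fit_calibration(doses, nods) -> FilmCalibration:
    """Nonlinear least squares for (k1, k2, n_exp), deterministic.

    The model is linear in (k1, k2) given the exponent, and it carries a
    degeneracy ridge near n_exp = 1 (where the two terms collapse) that
    traps a naive three-parameter descent.  The fit therefore profiles the
    exponent: exact linear least squares for (k1, k2) on a fixed n grid over
    the bounded range (0.2, 3), followed by a bounded three-parameter
    polish from the best grid point.  No randomness is involved.  Raises if
    the fitted response is not monotone on the data range.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(nods, dtype=float)
    if d.size < 5:
        raise ValueError("need at least 5 calibration points")
    if np.any(d < 0) or len(np.unique(d)) != d.size:
        raise ValueError("doses must be non-negative and distinct")
    order = np.argsort(d)
    d, y = d[order], y[order]
    best = None
    for n in np.linspace(0.2, 3.0, 57):
        A = np.column_stack([d, d**n])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        ssr = float(((A @ coef - y) ** 2).sum())
        if coef[0] >= 0 and (best is None or ssr < best[0]):
            best = (ssr, coef[0], coef[1], n)
    if best is None:
        raise RuntimeError("calibration fit found no admissible exponent")
    _, k1_0, k2_0, n_0 = best
    res = least_squares(
        lambda p: p[0] * d + p[1] * d ** p[2] - y,
        [k1_0, k2_0, n_0],
        bounds=([0.0, -np.inf, 0.2], [np.inf, np.inf, 3.0]),
        xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=2000,
    )
    if not (res.success or res.cost <= best[0] + 1e-15):
        raise RuntimeError(f"calibration fit did not converge: {res.message}")
    k1, k2, n_exp = map(float, res.x)
    cal = FilmCalibration(k1=k1, k2=k2, n_exp=n_exp, dose_max=float(d[-1]),
                          rms=float(np.sqrt(np.mean(res.fun**2))))
    if not cal.is_monotone():
        raise RuntimeError("fitted calibration is not monotone on the dose range")
    return cal


def dose_from_nod(cal: FilmCalibration, nod) -> np.ndarray:
    """Invert the calibration by bracketed root finding (monotone response).

    Accepts scalars or arrays; nod values outside [0, nod(dose_max)] raise
    (saturated or negative pixels must be masked upstream).
    """
    nod_arr = np.asarray(nod, dtype=float)
    nod_hi = float(cal.nod(cal.dose_max))
    if np.any(nod_arr < -1e-12) or np.any(nod_arr > nod_hi * (1 + 1e-9)):
        raise ValueError("nod outside the invertible range [0, nod(dose_max)]")
    flat = nod_arr.ravel()
    # fast path: dense inverse lookup, then Newton polish to 1e-9 nod units
    grid_d = np.linspace(0.0, cal.dose_max, 4096)
    grid_n = cal.nod(grid_d)
    dose = np.interp(flat, grid_n, grid_d)
    for _ in range(60):
        f = cal.nod(dose) - flat
        if np.all(np.abs(f) < 1e-10):
            break
        slope = cal.k1 + cal.k2 * cal.n_exp * np.maximum(dose, 1e-12) ** (cal.n_exp - 1)
        dose = np.clip(dose - f / slope, 0.0, cal.dose_max)
    else:  # fall back to brentq on stragglers
        bad = np.abs(cal.nod(dose) - flat) >= 1e-10
        for i in np.nonzero(bad)[0]:
            dose[i] = brentq(lambda x: cal.nod(x) - flat[i], 0.0, cal.dose_max,
                             xtol=1e-12)
    out = dose.reshape(nod_arr.shape)
    return out if out.ndim else float(out)


def film_to_dose(
    image: np.ndarray,
    pv0: float,
    cal: FilmCalibration,
    filter_size: int = 5,
) -> np.ma.MaskedArray:
    """Convert a scanned film image to a dose plane (Gy).

    Pipeline order is fixed: red channel -> ``filter_size`` median filter
    (reflected edges) -> nod -> calibration inversion.  Pixels whose nod
    falls outside the invertible range (saturated or over-ranged) are masked
    rather than converted.
    """
    from scipy.ndimage import median_filter

    img = np.asarray(image)
    if img.ndim == 3:
        red = img[..., 0].astype(float)
    elif img.ndim == 2:
        red = img.astype(float)
    else:
        raise ValueError("expected a 2D grayscale or 3D RGB image")
    red = median_filter(red, size=filter_size, mode="reflect")
    nod = net_optical_density(red, pv0)
    nod_hi = float(cal.nod(cal.dose_max))
    invalid = (nod < 0) | (nod > nod_hi)
    dose = np.zeros_like(nod)
    dose[~invalid] = dose_from_nod(cal, nod[~invalid])
    return np.ma.MaskedArray(dose, mask=invalid)


def render_film(
    dose_plane: np.ndarray,
    cal: FilmCalibration,
    pv0: float = 41000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Forward model: synthesize a 16-bit RGB film scan from a dose plane.

    Inverse of :func:`film_to_dose` (without the median filter): dose -> nod
    -> red pixel value ``pv0 * 10**(-nod)``, with optional Gaussian pixel
    noise of relative standard deviation ``noise_sd``.  Green/blue channels
    carry a flat value; only the red channel encodes dose.
    """
    rng = np.random.default_rng(seed)
    nod = cal.nod(np.asarray(dose_plane, dtype=float))
    red = pv0 * 10.0 ** (-nod)
    if noise_sd > 0:
        red = red * (1.0 + noise_sd * rng.standard_normal(red.shape))
    img = np.empty((*red.shape, 3), dtype=np.uint16)
    img[..., 0] = np.clip(red, 0, 65535).astype(np.uint16)
    img[..., 1] = 30000
    img[..., 2] = 20000
    return img


def save_calibration(cal: FilmCalibration, path) -> None:
    payload = {"k1": cal.k1, "k2": cal.k2, "n_exp": cal.n_exp,
               "dose_max": cal.dose_max, "rms": cal.rms}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration(path) -> FilmCalibration:
    d = json.loads(Path(path).read_text())
    return FilmCalibration(k1=d["k1"], k2=d["k2"], n_exp=d["n_exp"],
                           dose_max=d["dose_max"], rms=d.get("rms", 0.0))
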