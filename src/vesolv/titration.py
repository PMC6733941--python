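"""Ensemble FRET titration analysis: band-ratio efficiencies and Hill fits.

The dose-response model is the interpolating Hill form

    E(c) = A + (B - A) * c^n / (k^n + c^n)

with A the efficiency at zero detergent, B the efficiency at saturating
detergent, k the half-maximal concentration (mM) and n the Hill
coefficient, so that E(0) = A, E(inf) = B and E(k) = (A + B) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["HillFit", "ensemble_fret", "hill_eval", "fit_hill"]

DONOR_BAND_NM = 565.0
ACCEPTOR_BAND_NM = 665.0


@dataclass
class HillFit:
    """Hill dose-response parameters (efficiency endpoints A, B; k in mM)."""

    A: float
    B: float
    k: float
    n: float
    stderr: dict = field(default_factory=dict)
    chi2: float = float("nan")
    converged: bool = True
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n <= 0:
            raise ValueError("n must be positive")


def ensemble_fret(I_donor, I_acceptor):
    """Efficiency from donor (565 nm) and acceptor (665 nm) band intensities."""
    I_donor = np.asarray(I_donor, dtype=float)
    I_acceptor = np.asarray(I_acceptor, dtype=float)
    total = I_donor + I_acceptor
    if np.any(total <= 0):
        raise ValueError("band intensities must sum to a positive total")
    E = I_acceptor / total
    return float(E) if E.ndim == 0 else E


def ensemble_fret_from_spectrum(wavelength_nm, intensity, half_width_nm: float = 5.0):
    """Efficiency from a full emission spectrum.

    Integrates +/- `half_width_nm` bands (trapezoid rule) around the donor
    (565 nm) and acceptor (665 nm) emission maxima.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    I = np.asarray(intensity, dtype=float)

    def band(center):
        m = np.abs(wl - center) <= half_width_nm
        if m.sum() < 2:
            raise ValueError(f"spectrum does not cover the {center} nm band")
        return np.trapezoid(I[m], wl[m])

    return ensemble_fret(band(DONOR_BAND_NM), band(ACCEPTOR_BAND_NM))


def hill_eval(c, fit: HillFit):
    """Evaluate the Hill model at concentration ``c`` (mM)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        cn = np.where(c > 0, c**fit.n, 0.0)
    E = fit.A + (fit.B - fit.A) * cn / (fit.k**fit.n + cn)
    return float(E) if E.ndim == 0 else E


def _hill(c, A, B, k, n):
    cn = np.where(c > 0, c**n, 0.0)
    return A + (B - A) * cn / (k**n + cn)


def fit_hill(concentrations, E, weights=None) -> HillFit:
    """Weighted nonlinear least-squares Hill fit.

    Parameters
    ----------
    concentrations : array-like, mM; should span 0 up to well past k.
    E : array-like, measured efficiencies.
    weights : array-like, optional
        Per-point weights; the fit minimizes ``sum(w * resid^2)``.

    Returns
    -------
    HillFit with parameter standard errors from the covariance; a fit that
    fails to converge or whose covariance is singular is flagged rather
    than raising.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(E, dtype=float)
    if c.size != y.size:
        raise ValueError("concentrations and E must have equal length")
    if c.size < 5:
        raise ValueError("need at least 5 concentrations for a Hill fit")
    if np.all(c == c[0]):
        raise ValueError("concentrations are all identical")

    order = np.argsort(c)
    c, y = c[order], y[order]
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[order]
        sigma = 1.0 / np.sqrt(w)

    A0, B0 = y[0], y[-1]
    k0 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    p0 = [A0, B0, k0, 1.0]
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 50.0])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _hill, c, y, p0=p0, sigma=sigma, bounds=bounds,
                maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        converged = True
    except RuntimeError:
        popt, pcov = p0, np.full((4, 4), np.inf)
        converged = False

    perr = np.sqrt(np.diag(pcov))
    resid = y - _hill(c, *popt)
    chi2 = float(resid @ resid)
    flags = []
    if not np.all(np.isfinite(perr)):
        flags.append("covariance_singular")
    # flat data: n carries no information
    if np.isfinite(perr[3]) and perr[3] > 10 * abs(popt[3]):
        flags.append("n_unidentifiable")
    if np.ptp(y) < 10 * max(np.std(resid), 1e-15):
        flags.append("n_unidentifiable") if "n_unidentifiable" not in flags else None

    return HillFit(
        A=float(popt[0]),
        B=float(popt[1]),
        k=float(max(popt[2], 1e-12)),
        n=float(max(popt[3], 1e-12)),
        stderr={"A": perr[0], "B": perr[1], "k": perr[2], "n": perr[3]},
        chi2=chi2,
        converged=converged and not flags,
        flags=flags,
    )
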