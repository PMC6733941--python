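"""Fluorescence correlation spectroscopy: multi-tau correlation, model
fitting, focal-volume calibration and Stokes-Einstein sizing.

The autocorrelation estimator is the standard normalized form
``G(tau) = <I(t) I(t+tau)> / <I>^2`` (uncorrelated signal -> 1) computed on
a logarithmic multi-tau lag grid with symmetric normalization per lag.
The fit model is 3D free diffusion through a Gaussian focus with an
optional triplet factor:

    G(tau) = 1 + b0 + (1/N) * (1 + tau/tau_D)^-1
             * (1 + tau/(Omega^2 tau_D))^-1/2 * (1 + A_T exp(-tau/tau_T))

where N is the mean focal-volume occupancy, tau_D the diffusion time and
Omega = omega_z / omega_xy the axial/radial structure parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "CorrelationCurve",
    "FcsFitResult",
    "FocalCalibration",
    "SizingResult",
    "multitau_correlate",
    "fcs_model",
    "fit_fcs",
    "calibrate_focus",
    "diffusion_coefficient",
    "hydrodynamic_radius",
    "water_viscosity",
    "correct_to_25C",
    "titration_slope",
    "reject_outlier_curves",
]

#: dynamic viscosity of water at 25 C (Pa s), default solvent assumption
ETA_WATER_25C = 0.890e-3
T_REF = 298.15


@dataclass
class CorrelationCurve:
    """Normalized autocorrelation on a strictly increasing lag grid."""

    lags: np.ndarray  # seconds
    G: np.ndarray
    n_samples: np.ndarray  # pair count contributing to each lag

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.n_samples = np.asarray(self.n_samples)
        if not (len(self.lags) == len(self.G) == len(self.n_samples)):
            raise ValueError("lags/G/n_samples must have equal length")
        if np.any(self.lags <= 0) or not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G contains non-finite values")


@dataclass
class FcsFitResult:
    N: float
    tau_D: float
    Omega: float
    A_T: float = 0.0
    tau_T: float = 1e-6
    b0: float = 0.0
    stderr: dict = field(default_factory=dict)
    chi2_reduced: float = float("nan")
    converged: bool = True
    flags: list = field(default_factory=list)


@dataclass
class FocalCalibration:
    """Focal geometry from a reference dye of known diffusion coefficient."""

    omega_xy: float  # m
    Omega: float
    V: float  # m^3, effective Gaussian volume pi^(3/2) * Omega * omega_xy^3
    D_ref: float  # m^2/s
    fit: FcsFitResult | None = None


@dataclass
class SizingResult:
    D: float  # m^2/s
    R_h: float  # m
    T: float = T_REF
    eta: float = ETA_WATER_25C


# ------------------------------------------------------------- correlator
def multitau_correlate(
    counts, bin_dt: float, m_per_level: int = 16, n_levels: int = 20
) -> CorrelationCurve:
    """Multi-tau autocorrelation with bin-width doubling per level.

    Level 0 computes lags ``1..m_per_level`` at the raw bin width; each
    subsequent level halves the time resolution (averaging adjacent bins)
    and computes lags ``m_per_level/2+1 .. m_per_level`` in coarse bins.
    Symmetric normalization: each lag is divided by the product of the
    means of the two overlapping windows, so an uncorrelated stationary
    signal gives G = 1 exactly in expectation.
    """
    data = np.asarray(counts, dtype=float)
    if data.ndim != 1:
        raise ValueError("counts must be a 1D trace")
    if data.size < 2 * m_per_level:
        raise ValueError("trace too short for the requested lag grid")
    if data.mean() == 0:
        raise ValueError("zero-mean trace: normalization undefined")
    if bin_dt <= 0:
        raise ValueError("bin_dt must be positive")

    lags, G, n_samples = [], [], []
    width = bin_dt
    for level in range(n_levels):
        ks = range(1, m_per_level + 1) if level == 0 else range(m_per_level // 2 + 1, m_per_level + 1)
        for k in ks:
            if data.size <= k:
                break
            left = data[:-k]
            right = data[k:]
            denom = left.mean() * right.mean()
            if denom == 0:
                continue
            lags.append(k * width)
            G.append(float((left * right).mean() / denom))
            n_samples.append(data.size - k)
        # coarsen for next level
        half = data.size // 2
        if half < m_per_level + 1 or level == n_levels - 1:
            break
        data = 0.5 * (data[: 2 * half : 2] + data[1 : 2 * half : 2])
        width *= 2.0

    return CorrelationCurve(np.array(lags), np.array(G), np.array(n_samples))


# ------------------------------------------------------------------ model
def fcs_model(tau, N, tau_D, Omega, A_T=0.0, tau_T=1e-6, b0=0.0):
    """3D diffusion + triplet autocorrelation model (see module docstring)."""
    tau = np.asarray(tau, dtype=float)
    diff = (1.0 + tau / tau_D) ** -1 * (1.0 + tau / (Omega**2 * tau_D)) ** -0.5
    trip = 1.0 + A_T * np.exp(-tau / tau_T) if A_T != 0.0 else 1.0
    return 1.0 + b0 + diff * trip / N


def fit_fcs(
    curve: CorrelationCurve,
    fix_Omega: float | None = None,
    fit_triplet: bool = False,
    fit_baseline: bool = False,
) -> FcsFitResult:
    """Weighted NLS fit of the diffusion(+triplet) model to a curve.

    Weights are ``sqrt(n_samples)`` per lag. Initial guesses: N from the
    short-lag amplitude, tau_D from where the amplitude halves. Omega can
    be fixed (recommended for noisy single curves) or fitted.
    """
    tau = curve.lags
    y = curve.G
    if tau.size < 6:
        raise ValueError("curve has too few lags to fit")
    sigma = 1.0 / np.sqrt(np.asarray(curve.n_samples, dtype=float))

    amp0 = max(y[0] - 1.0, 1e-6)
    N0 = 1.0 / amp0
    half_level = 1.0 + amp0 / 2.0
    below = np.nonzero(y <= half_level)[0]
    tau_D0 = tau[below[0]] if below.size else tau[len(tau) // 2]

    names = ["N", "tau_D"]
    p0 = [N0, tau_D0]
    lo = [1e-9, tau[0] / 10]
    hi = [np.inf, tau[-1] * 100]
    if fix_Omega is None:
        names.append("Omega")
        p0.append(5.0)
        lo.append(1.0)
        hi.append(100.0)
    if fit_triplet:
        names += ["A_T", "tau_T"]
        p0 += [0.1, tau[0]]
        lo += [0.0, tau[0] / 100]
        hi += [10.0, tau[-1]]
    if fit_baseline:
        names.append("b0")
        p0.append(0.0)
        lo.append(-1.0)
        hi.append(1.0)

    def model(t, *params):
        kw = dict(zip(names, params))
        kw.setdefault("Omega", fix_Omega)
        return fcs_model(t, **kw)

    # the triplet time is prone to local minima when it approaches tau_D;
    # multi-start over a few starting scales and keep the best chi^2
    starts = [list(p0)]
    if fit_triplet:
        i_tt = names.index("tau_T")
        for tt0 in (np.sqrt(tau[0] * tau_D0), tau_D0 / 2):
            alt = list(p0)
            alt[i_tt] = float(np.clip(tt0, lo[i_tt], hi[i_tt]))
            starts.append(alt)

    flags: list[str] = []
    best = None
    for start in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt_i, pcov_i = curve_fit(
                    model, tau, y, p0=start, sigma=sigma, bounds=(lo, hi),
                    maxfev=40000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
        except RuntimeError:
            continue
        ssr = float(np.sum(((y - model(tau, *popt_i)) / sigma) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt_i, pcov_i)
    if best is not None:
        _, popt, pcov = best
        converged = True
    else:
        popt, pcov = np.array(p0), np.full((len(p0), len(p0)), np.inf)
        converged = False
        flags.append("no_convergence")

    perr = np.sqrt(np.diag(pcov))
    fitted = dict(zip(names, popt))
    stderr = dict(zip(names, perr))
    resid = (y - model(tau, *popt)) / sigma
    dof = max(tau.size - len(popt), 1)
    chi2_reduced = float(resid @ resid / dof)

    result = FcsFitResult(
        N=float(fitted["N"]),
        tau_D=float(fitted["tau_D"]),
        Omega=float(fitted.get("Omega", fix_Omega if fix_Omega is not None else np.nan)),
        A_T=float(fitted.get("A_T", 0.0)),
        tau_T=float(fitted.get("tau_T", 1e-6)),
        b0=float(fitted.get("b0", 0.0)),
        stderr=stderr,
        chi2_reduced=chi2_reduced,
        converged=converged,
        flags=flags,
    )
    if fit_triplet and result.tau_T >= result.tau_D / 2:
        warnings.warn(
            "fitted triplet time within a factor 2 of the diffusion time: "
            "triplet and diffusion terms may be mixing",
            stacklevel=2,
        )
        result.flags.append("triplet_diffusion_mixing")
    return result


# ------------------------------------------------------------ calibration
def calibrate_focus(
    reference_curve: CorrelationCurve, D_ref: float, fix_Omega: float | None = None,
    fit_triplet: bool = False,
) -> FocalCalibration:
    """Focal geometry from a reference curve of a dye with known D.

    ``omega_xy = sqrt(4 D_ref tau_D_ref)``; the effective Gaussian focal
    volume is ``V = pi^(3/2) * Omega * omega_xy^3``.
    """
    if D_ref <= 0:
        raise ValueError("D_ref must be positive")
    fit = fit_fcs(reference_curve, fix_Omega=fix_Omega, fit_triplet=fit_triplet)
    omega_xy = float(np.sqrt(4.0 * D_ref * fit.tau_D))
    Omega = fit.Omega
    V = float(np.pi ** 1.5 * Omega * omega_xy**3)
    return FocalCalibration(omega_xy=omega_xy, Omega=Omega, V=V, D_ref=D_ref, fit=fit)


def diffusion_coefficient(tau_D: float, omega_xy: float) -> float:
    """``D = omega_xy^2 / (4 tau_D)`` (SI units)."""
    if tau_D <= 0 or omega_xy <= 0:
        raise ValueError("tau_D and omega_xy must be positive")
    return omega_xy**2 / (4.0 * tau_D)


def hydrodynamic_radius(D: float, T: float = T_REF, eta: float = ETA_WATER_25C) -> SizingResult:
    """Stokes-Einstein radius ``R_h = k_B T / (6 pi eta D)``."""
    if D <= 0 or T <= 0 or eta <= 0:
        raise ValueError("D, T and eta must be positive")
    R_h = constants.k * T / (6.0 * np.pi * eta * D)
    return SizingResult(D=D, R_h=R_h, T=T, eta=eta)


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of water (Pa s) at temperature T (K).

    Kestin-type correlation anchored at 1.002 mPa s at 20 C; adequate for
    the 0-40 C range relevant here (0.8904 mPa s at 25 C).
    """
    t = T - 273.15
    if not -5.0 <= t <= 100.0:
        raise ValueError("temperature outside correlation range")
    d = 20.0 - t
    exponent = d * (1.2364 - 1.37e-3 * d + 5.7e-6 * d * d) / (t + 96.0)
    return 1.002e-3 * 10.0**exponent


def correct_to_25C(D_measured: float, T_measured: float) -> float:
    """Report a diffusion coefficient at 25 C via the Stokes-Einstein
    temperature/viscosity scaling ``D_25 = D * (298.15/T) * (eta(T)/eta(25C))``."""
    if D_measured <= 0:
        raise ValueError("D must be positive")
    factor = (T_REF / T_measured) * (water_viscosity(T_measured) / water_viscosity(T_REF))
    return D_measured * factor


# --------------------------------------------------------------- batching
def titration_slope(concentrations_mM, tau_Ds):
    """OLS slope of diffusion time versus detergent concentration.

    Returns ``(slope, stderr, intercept)``; slope units are (tau units)/mM,
    i.e. us/mM when tau_Ds are given in microseconds.
    """
    c = np.asarray(concentrations_mM, dtype=float)
    td = np.asarray(tau_Ds, dtype=float)
    if c.size != td.size or c.size < 2:
        raise ValueError("need >= 2 matched (concentration, tau_D) points")
    res = linregress(c, td)
    return float(res.slope), float(res.stderr), float(res.intercept)


def reject_outlier_curves(
    curves, fix_Omega: float | None = None, chi2_max: float = 5.0, n_mad: float = 3.0
):
    """Drop curves distorted by rare bright transits (aggregates).

    Each curve is fitted; curves whose occupancy N deviates more than
    ``n_mad`` robust MADs from the batch median, or whose reduced chi^2
    exceeds ``chi2_max``, are excluded. Batches of fewer than 3 curves are
    returned unchanged with a warning.

    Returns ``(kept_curves, rejected_indices)``.
    """
    curves = list(curves)
    if len(curves) < 3:
        warnings.warn("fewer than 3 curves: outlier rejection disabled", stacklevel=2)
        return curves, []
    fits = [fit_fcs(c, fix_Omega=fix_Omega) for c in curves]
    Ns = np.array([f.N for f in fits])
    med = np.median(Ns)
    mad = 1.4826 * np.median(np.abs(Ns - med))
    rejected = [
        i
        for i, f in enumerate(fits)
        if (mad > 0 and abs(f.N - med) > n_mad * mad) or f.chi2_reduced > chi2_max
    ]
    kept = [c for i, c in enumerate(curves) if i not in rejected]
    return kept, rejected
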