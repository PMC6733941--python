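"""Synthetic-data generators with the statistical structure the analysis
pipeline assumes.

The forward mechanism for a single surface-immobilized vesicle under
detergent attack is biphasic: a fast swelling step during which the FRET
efficiency relaxes exponentially from ``E0`` to ``E_plateau`` with true
half-life ``t_E`` at near-constant total intensity, followed by a slow
lysis step during which the total intensity decays with half-life ``t_L``
(fraction ``f_loss`` lost at completion) at constant efficiency. Both
half-lives enter as base-2 exponentials ``2**(-(t - t0)/t_half)`` so the
parameters are true half-lives, not e-folding constants. Detection noise
is Poisson shot noise about the expected per-frame counts plus a constant
background.

Every generator draws from a single ``numpy.random.default_rng(seed)`` per
call: identical parameters and seed give identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .qcmd import QcmdTrace
from .titration import HillFit, hill_eval
from .trajectory import VesicleTrajectory

__all__ = [
    "ValidationError",
    "SolubilizationParams",
    "FcsSimParams",
    "QcmdSimParams",
    "generate_trajectory",
    "generate_image_stack",
    "generate_fcs_trace",
    "generate_titration",
    "generate_qcmd_trace",
]


class ValidationError(ValueError):
    """Raised when generator parameters violate their invariants."""


# ------------------------------------------------------------------ params
@dataclass
class SolubilizationParams:
    """Forward-model parameters for one solubilization trajectory."""

    E0: float = 0.46  # pre-injection FRET efficiency
    E_plateau: float = 0.22  # post-swelling efficiency
    t_E: float = 1.2  # swelling half-life, s
    t_L: float = 17.6  # lysis half-life, s
    f_loss: float = 0.5  # fraction of total intensity lost at completion
    I_tot0: float = 1000.0  # pre-injection total intensity, counts/frame
    t0: float = 90.0  # injection time, s
    frame_dt: float = 0.05  # integration time, s
    duration: float = 300.0  # trace length, s
    background: float = 0.0  # mean background, counts/frame
    bleach_rate: float = 0.0  # optional photobleaching rate, 1/s

    def validate(self) -> None:
        if not 0.0 < self.E_plateau < self.E0 < 1.0:
            raise ValidationError("require 0 < E_plateau < E0 < 1")
        if self.t_E <= 0 or self.t_L <= 0:
            raise ValidationError("half-lives must be positive")
        if not 0.0 <= self.f_loss <= 1.0:
            raise ValidationError("f_loss must lie in [0, 1]")
        if self.frame_dt <= 0:
            raise ValidationError("frame_dt must be positive")
        if self.I_tot0 <= 0:
            raise ValidationError("I_tot0 must be positive")
        if not 0.0 <= self.t0 < self.duration:
            raise ValidationError("need 0 <= t0 < duration")
        if self.background < 0 or self.bleach_rate < 0:
            raise ValidationError("background and bleach_rate must be >= 0")


@dataclass
class FcsSimParams:
    """Brownian-dynamics parameters for a confocal photon-count trace."""

    D: float  # diffusion coefficient, m^2/s
    mean_N: float = 1.0  # mean occupancy of the effective focal volume
    omega_xy: float = 0.27e-6  # radial 1/e^2 radius, m
    Omega: float = 5.0  # axial/radial ratio
    brightness: float = 1e5  # counts per particle per second at focus center
    A_T: float = 0.0  # triplet amplitude
    tau_T: float = 1e-6  # triplet correlation time, s
    duration: float = 10.0  # s
    bin_dt: float = 1e-4  # count bin width, s
    box_factor: float = 8.0  # box half-width in units of omega_xy (omega_z axially)

    def validate(self) -> None:
        for name in ("D", "mean_N", "omega_xy", "brightness", "duration", "bin_dt", "tau_T", "box_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.Omega <= 1:
            raise ValidationError("Omega must exceed 1")
        if self.A_T < 0:
            raise ValidationError("A_T must be >= 0")

    @property
    def tau_D(self) -> float:
        return self.omega_xy**2 / (4.0 * self.D)


@dataclass
class QcmdSimParams:
    """Parametric QCM-D solubilization trace at a single overtone.

    The trace sits at ``-f_vesicle`` (vesicle layer), rises in magnitude to
    ``-f_vesicle*(1+gain_frac)`` during the gain phase, holds the peak
    briefly, then relaxes to ``-f_vesicle*(1+gain_frac)*(1-loss_frac)``
    so the detected loss referenced to the peak equals ``loss_frac``
    exactly. Each transition is a saturating exponential normalized to
    reach its endpoint exactly at the segment boundary (so noiseless
    round-trips through phase detection are exact).
    """

    f_vesicle: float = 30.0  # Hz, vesicle-layer |frequency shift| at this overtone
    gain_frac: float = 0.05
    loss_frac: float = 0.63
    tau_gain: float = 5.0  # s
    tau_loss: float = 60.0  # s
    overtone: int = 7
    noise_sd: float = 0.0  # Hz
    dissipation_scale: float = 0.05  # delta_D (1e-6 units) per Hz of -delta_f
    t_inject: float = 100.0  # s
    gain_duration: float = 30.0  # s
    peak_hold: float = 10.0  # s
    loss_duration: float = 300.0  # s
    duration: float = 600.0  # s
    dt: float = 0.5  # s

    def validate(self) -> None:
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ValidationError("overtone must be an odd integer >= 1")
        if self.f_vesicle < 0:
            raise ValidationError("f_vesicle must be >= 0")
        if self.gain_frac < 0:
            raise ValidationError("gain_frac must be >= 0")
        if not 0.0 <= self.loss_frac <= 1.0:
            raise ValidationError("loss_frac must lie in [0, 1]")
        if self.tau_gain <= 0 or self.tau_loss <= 0 or self.dt <= 0:
            raise ValidationError("time constants and dt must be positive")
        end = self.t_inject + self.gain_duration + self.peak_hold + self.loss_duration
        if end >= self.duration:
            raise ValidationError("phases must fit inside the trace duration")


# ------------------------------------------------------------- trajectory
def generate_trajectory(
    params: SolubilizationParams,
    seed: int,
    poisson_noise: bool = True,
    vesicle_id: str = "sim-0",
) -> VesicleTrajectory:
    """Simulate one donor/acceptor trajectory from the biphasic mechanism.

    Expected efficiencies and intensities follow the module docstring;
    expected donor counts are ``(1 - E) * I_tot`` and acceptor counts
    ``E * I_tot``, each plus `background` and (optionally) Poisson-drawn.
    Photobleaching, when enabled, multiplies both channel expectations by
    ``exp(-bleach_rate * t)``.
    """
    params.validate()
    rng = np.random.default_rng(seed)

    n = int(round(params.duration / params.frame_dt))
    t = np.arange(n) * params.frame_dt
    rel = np.clip(t - params.t0, 0.0, None)

    E = params.E_plateau + (params.E0 - params.E_plateau) * 2.0 ** (-rel / params.t_E)
    I_tot = params.I_tot0 * (1.0 - params.f_loss * (1.0 - 2.0 ** (-rel / params.t_L)))
    if params.bleach_rate > 0:
        I_tot = I_tot * np.exp(-params.bleach_rate * t)

    donor_mean = (1.0 - E) * I_tot + params.background
    acceptor_mean = E * I_tot + params.background
    if np.any(donor_mean < 0) or np.any(acceptor_mean < 0):
        raise ValidationError("expected intensities became negative")

    if poisson_noise:
        donor = rng.poisson(donor_mean).astype(float)
        acceptor = rng.poisson(acceptor_mean).astype(float)
    else:
        donor = donor_mean
        acceptor = acceptor_mean

    truth = {
        "E0": params.E0,
        "E_plateau": params.E_plateau,
        "t_E": params.t_E,
        "t_L": params.t_L,
        "f_loss": params.f_loss,
        "I_tot0": params.I_tot0,
        "background": params.background,
        "bleach_rate": params.bleach_rate,
    }
    return VesicleTrajectory(
        time=t,
        donor=donor,
        acceptor=acceptor,
        frame_dt=params.frame_dt,
        t0=params.t0,
        vesicle_id=vesicle_id,
        meta={"truth": truth, "seed": seed},
    )


# ------------------------------------------------------------ image stack
def generate_image_stack(
    trajectories,
    positions,
    psf_sigma: float,
    frame_shape: tuple[int, int],
    seed: int,
    channel_offset: tuple[float, float] = (0.0, 0.0),
    background: float = 0.0,
    poisson_noise: bool = True,
):
    """Render trajectories as diffraction-limited spots in two channels.

    Each vesicle is a 2D Gaussian spot (pixel-integrated, so the full-plane
    integral per frame equals the trajectory value exactly) at a fixed
    position; the acceptor channel shares the geometry shifted by
    `channel_offset` (row, col). Returns ``(donor_stack, acceptor_stack)``
    as float arrays of shape ``(n_frames, *frame_shape)``.
    """
    trajectories = list(trajectories)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(trajectories) != len(positions):
        raise ValidationError("need one position per trajectory")
    H, W = frame_shape
    if np.any(positions[:, 0] < 0) or np.any(positions[:, 0] > H - 1) or np.any(
        positions[:, 1] < 0
    ) or np.any(positions[:, 1] > W - 1):
        raise ValidationError("spot positions must lie within the frame")
    if psf_sigma <= 0:
        raise ValidationError("psf_sigma must be positive")

    if len(positions) > 1:
        from scipy.spatial.distance import pdist

        if np.min(pdist(positions)) < 4.0 * psf_sigma:
            warnings.warn("spots closer than 4*psf_sigma: overlapping PSFs", stacklevel=2)

    n_frames = len(trajectories[0])
    if any(len(tr) != n_frames for tr in trajectories):
        raise ValidationError("all trajectories must have equal length")

    rng = np.random.default_rng(seed)

    def render(channel_values, offset):
        patches = np.stack(
            [_pixel_gaussian(pos + offset, psf_sigma, H, W) for pos in positions]
        )  # (n_vesicles, H, W)
        intens = np.stack(channel_values, axis=1)  # (n_frames, n_vesicles)
        stack = np.tensordot(intens, patches, axes=1) + background
        if poisson_noise:
            stack = rng.poisson(stack).astype(float)
        return stack

    offset = np.asarray(channel_offset, dtype=float)
    donor_stack = render([tr.donor for tr in trajectories], np.zeros(2))
    acceptor_stack = render([tr.acceptor for tr in trajectories], offset)
    return donor_stack, acceptor_stack


def _pixel_gaussian(center, sigma, H, W):
    """Pixel-integrated unit-mass 2D Gaussian (pixel i spans [i-1/2, i+1/2])."""
    s = sigma * np.sqrt(2.0)
    rows = np.arange(H + 1) - 0.5
    cols = np.arange(W + 1) - 0.5
    cr = 0.5 * (erf((rows[1:] - center[0]) / s) - erf((rows[:-1] - center[0]) / s))
    cc = 0.5 * (erf((cols[1:] - center[1]) / s) - erf((cols[:-1] - center[1]) / s))
    return np.outer(cr, cc)


# -------------------------------------------------------------------- FCS
def generate_fcs_trace(params: FcsSimParams, seed: int) -> np.ndarray:
    """Brownian-dynamics photon-count trace through a 3D Gaussian focus.

    Particles random-walk (per-axis step variance ``2 D bin_dt``) in a
    periodic box of half-width ``box_factor * omega_xy`` laterally and
    ``box_factor * omega_z`` axially. The per-bin expected count is
    ``brightness * bin_dt * sum_i exp(-2 r_i^2/omega_xy^2 - 2 z_i^2/omega_z^2)``
    and counts are Poisson. The particle number is chosen so the mean
    occupancy of the effective Gaussian focal volume
    ``V_eff = pi^(3/2) omega_xy^2 omega_z`` equals ``mean_N`` (hence
    ``G(0) - 1 ~ 1/mean_N``). Triplet blinking, when ``A_T > 0``, is a
    two-state telegraph process with dark fraction ``A_T/(1+A_T)`` and
    correlation time ``tau_T``.

    Returns the integer count trace; the bin width is ``params.bin_dt``.
    """
    params.validate()
    if params.bin_dt > params.tau_D / 20.0:
        warnings.warn(
            "bin_dt coarser than tau_D/20: diffusion decay will be under-resolved",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    omega_z = params.Omega * params.omega_xy
    L = params.box_factor * params.omega_xy  # lateral half-width
    Lz = params.box_factor * omega_z
    v_box = (2 * L) * (2 * L) * (2 * Lz)
    v_eff = np.pi**1.5 * params.omega_xy**2 * omega_z
    n_particles = max(1, int(round(params.mean_N * v_box / v_eff)))

    n_bins = int(round(params.duration / params.bin_dt))
    sigma_step = np.sqrt(2.0 * params.D * params.bin_dt)

    half = np.array([L, L, Lz], dtype=np.float32)
    pos = rng.uniform(-half, half, size=(n_particles, 3)).astype(np.float32)

    bright = None
    if params.A_T > 0:
        bright = _telegraph_states(rng, params, n_bins, n_particles)

    inv_wxy2 = np.float32(2.0 / params.omega_xy**2)
    inv_wz2 = np.float32(2.0 / omega_z**2)
    scale = params.brightness * params.bin_dt

    counts = np.empty(n_bins, dtype=np.int64)
    chunk = 8192
    for start in range(0, n_bins, chunk):
        nb = min(chunk, n_bins - start)
        steps = rng.standard_normal((nb, n_particles, 3), dtype=np.float32)
        steps *= np.float32(sigma_step)
        path = pos[None, :, :] + np.cumsum(steps, axis=0)
        path = (path + half) % (2 * half) - half  # periodic wrap
        pos = path[-1]
        w = np.exp(
            -(path[:, :, 0] ** 2 + path[:, :, 1] ** 2) * inv_wxy2
            - path[:, :, 2] ** 2 * inv_wz2
        )
        if bright is not None:
            w = w * bright[start : start + nb]
        lam = scale * w.sum(axis=1, dtype=np.float64)
        counts[start : start + nb] = rng.poisson(lam)
    return counts


def _telegraph_states(rng, params: FcsSimParams, n_bins: int, n_particles: int):
    """Per-bin bright/dark states (sampled at bin centers) for each particle."""
    p_dark = params.A_T / (1.0 + params.A_T)
    mean_bright = params.tau_T / p_dark  # dwell means giving the target
    mean_dark = params.tau_T / (1.0 - p_dark)  # dark fraction and tau_T
    t_centers = (np.arange(n_bins) + 0.5) * params.bin_dt
    states = np.empty((n_bins, n_particles), dtype=np.float32)
    for j in range(n_particles):
        start_bright = rng.random() > p_dark
        # alternate exponential dwells until the trace is covered
        n_guess = int(4 + 2 * params.duration / (mean_bright + mean_dark) * 2)
        switch_times = np.array([], dtype=float)
        total = 0.0
        while total < params.duration:
            n_draw = max(n_guess, 16)
            n_draw += n_draw % 2  # keep parity across batches
            means = np.where(
                (np.arange(n_draw) % 2 == 0) == start_bright, mean_bright, mean_dark
            )
            dwells = rng.exponential(means)
            switch_times = np.concatenate([switch_times, total + np.cumsum(dwells)])
            total = switch_times[-1]
        idx = np.searchsorted(switch_times, t_centers, side="right")
        bright = (idx % 2 == 0) if start_bright else (idx % 2 == 1)
        states[:, j] = bright.astype(np.float32)
    return states


# -------------------------------------------------------------- titration
def generate_titration(
    hill: HillFit,
    concentrations,
    noise_sd: float,
    replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Hill-model titration table with additive Gaussian noise.

    Returns a DataFrame with columns ``conc_mM``, ``E`` and ``replicate``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        E = hill_eval(c, hill)
        if noise_sd > 0:
            E = E + rng.normal(0.0, noise_sd, size=c.shape)
        rows.append(pd.DataFrame({"conc_mM": c, "E": E, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------------ QCM-D
def generate_qcmd_trace(params: QcmdSimParams, seed: int) -> QcmdTrace:
    """Piecewise gain/hold/loss QCM-D frequency trace (see QcmdSimParams)."""
    params.validate()
    rng = np.random.default_rng(seed)

    n = int(round(params.duration / params.dt))
    t = np.arange(n) * params.dt

    f_base = -params.f_vesicle
    f_peak = -params.f_vesicle * (1.0 + params.gain_frac)
    f_final = f_peak * (1.0 - params.loss_frac)

    t1 = params.t_inject
    t2 = t1 + params.gain_duration
    t3 = t2 + params.peak_hold
    t4 = t3 + params.loss_duration

    delta_f = np.full(n, f_base)
    gain = (t >= t1) & (t < t2)
    delta_f[gain] = _normalized_approach(t[gain], t1, t2, f_base, f_peak, params.tau_gain)
    hold = (t >= t2) & (t < t3)
    delta_f[hold] = f_peak
    loss = (t >= t3) & (t < t4)
    delta_f[loss] = _normalized_approach(t[loss], t3, t4, f_peak, f_final, params.tau_loss)
    delta_f[t >= t4] = f_final

    delta_D = params.dissipation_scale * (-delta_f)
    if params.noise_sd > 0:
        delta_f = delta_f + rng.normal(0.0, params.noise_sd, size=n)
        delta_D = delta_D + rng.normal(0.0, params.dissipation_scale * params.noise_sd, size=n)

    return QcmdTrace(
        time=t,
        delta_f=delta_f,
        delta_D=delta_D,
        overtone=params.overtone,
        meta={
            "truth": {
                "f_vesicle": params.f_vesicle,
                "gain_frac": params.gain_frac,
                "loss_frac": params.loss_frac,
                "t_inject": params.t_inject,
            },
            "seed": seed,
        },
    )


def _normalized_approach(t, t_start, t_end, v0, v1, tau):
    """Exponential approach rescaled to reach v1 exactly at t_end."""
    x = -np.expm1(-(t - t_start) / tau)
    x_end = -np.expm1(-(t_end - t_start) / tau)
    return v0 + (v1 - v0) * x / x_end
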