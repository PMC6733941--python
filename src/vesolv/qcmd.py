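"""QCM-D analysis: Sauerbrey mass conversion and solubilization mass phases.

Frequency shifts are converted to areal mass with the rigid-film Sauerbrey
relation ``dm = -C * df / n`` (C = 17.7 ng Hz^-1 cm^-2 for the standard
5 MHz AT-cut quartz, n the odd overtone number); a frequency decrease
therefore reads as a mass increase. Solubilization is segmented into a
mass-gain phase (detergent insertion) and a mass-loss phase (lipid
release), with the percent gain referenced to the vesicle-layer mass and
the percent loss referenced to the peak mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = ["QcmdTrace", "MassPhaseResult", "sauerbrey_mass", "detect_mass_phases", "df_plot_data"]

SAUERBREY_C = 17.7  # ng Hz^-1 cm^-2
#: |dD / (-df/n)| above which the rigid-film assumption is dubious (per Hz),
#: with dD in absolute (not 1e-6) units.
SOFT_FILM_RATIO = 4e-7


@dataclass
class QcmdTrace:
    """Frequency/dissipation time series for one overtone.

    ``delta_f`` in Hz (relative to the bare-sensor reference, so the
    immobilized vesicle layer sits at a negative baseline), ``delta_D`` in
    the conventional 1e-6 units.
    """

    time: np.ndarray
    delta_f: np.ndarray
    delta_D: np.ndarray
    overtone: int = 7
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        self.delta_D = np.asarray(self.delta_D, dtype=float)
        if not (len(self.time) == len(self.delta_f) == len(self.delta_D)):
            raise ValueError("time/delta_f/delta_D must have equal length")
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ValueError("overtone must be an odd integer >= 1")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "delta_f_hz": self.delta_f,
                "delta_D": self.delta_D,
                "overtone": self.overtone,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "QcmdTrace":
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            delta_f=df["delta_f_hz"].to_numpy(),
            delta_D=df["delta_D"].to_numpy(),
            overtone=int(df["overtone"].iloc[0]) if "overtone" in df else 7,
        )


@dataclass
class MassPhaseResult:
    m_vesicle: float  # ng/cm^2, baseline vesicle-layer mass
    m_peak: float
    m_final: float
    gain_pct: float  # 100*(m_peak - m_vesicle)/m_vesicle
    loss_pct: float  # 100*(m_peak - m_final)/m_peak
    t_peak: float | None = None
    t_settled: float | None = None  # first time mass is within 5% of final
    gain_detected: bool = True
    loss_detected: bool = True
    flags: list = field(default_factory=list)


def sauerbrey_mass(delta_f, overtone: int = 1, C: float = SAUERBREY_C):
    """Areal mass change (ng/cm^2) from a frequency shift (Hz).

    ``dm = -C * df / n``; linear, and positive for a frequency decrease.
    """
    if overtone < 1 or overtone % 2 == 0:
        raise ValueError("overtone must be an odd integer >= 1")
    dm = -C * np.asarray(delta_f, dtype=float) / overtone
    return float(dm) if dm.ndim == 0 else dm


def detect_mass_phases(
    trace: QcmdTrace,
    injection_time: float,
    baseline_window: tuple[float, float] | None = None,
    C: float = SAUERBREY_C,
    terminal_frac: float = 0.05,
    smooth_kernel: int = 5,
    reference_delta_f: float = 0.0,
) -> MassPhaseResult:
    """Segment a solubilization trace into mass-gain and mass-loss phases.

    The baseline window (default: everything before `injection_time`) sets
    the vesicle-layer mass and the noise floor; the peak is the maximum of
    the median-filtered mass after injection, and the final mass is the
    mean over the terminal ``terminal_frac`` of the trace. A gain (loss)
    phase is declared only when the peak exceeds the baseline (the final
    mass undercuts the peak) by more than 3 baseline noise SDs.

    `reference_delta_f` is the bare-sensor frequency reference: masses are
    computed from ``delta_f - reference_delta_f``, which makes the analysis
    invariant to constant offsets when the reference is moved along.
    """
    t = trace.time
    if baseline_window is None:
        baseline_window = (float(t[0]), float(injection_time))
    b_lo, b_hi = baseline_window
    if b_hi > injection_time:
        raise ValueError("baseline window must precede the injection time")
    base_mask = (t >= b_lo) & (t < b_hi)
    if base_mask.sum() < 2:
        raise ValueError("baseline window contains fewer than 2 samples")

    mass = sauerbrey_mass(trace.delta_f - reference_delta_f, trace.overtone, C)
    _soft_film_check(trace)

    m_vesicle = float(mass[base_mask].mean())
    noise_sd = float(mass[base_mask].std())

    post = t >= injection_time
    if post.sum() < smooth_kernel:
        raise ValueError("too few samples after injection")
    smoothed = medfilt(mass, kernel_size=smooth_kernel)
    post_smoothed = smoothed[post]
    post_t = t[post]

    i_peak = int(np.argmax(post_smoothed))
    m_peak = float(post_smoothed[i_peak])
    t_peak = float(post_t[i_peak])

    n_term = max(2, int(round(terminal_frac * t.size)))
    m_final = float(mass[-n_term:].mean())

    flags: list[str] = []
    layer_present = m_vesicle > 3 * noise_sd and m_vesicle > 0
    if not layer_present:
        flags.append("no_vesicle_layer")

    gain_detected = layer_present and (m_peak > m_vesicle + 3 * noise_sd) and (m_peak > m_vesicle)
    loss_detected = layer_present and (m_final < m_peak - 3 * noise_sd) and (m_final < m_peak)
    if not gain_detected:
        flags.append("no_gain_phase")
    if not loss_detected:
        flags.append("no_loss_phase")

    gain_pct = 100.0 * (m_peak - m_vesicle) / m_vesicle if gain_detected else 0.0
    loss_pct = 100.0 * (m_peak - m_final) / m_peak if loss_detected else 0.0

    t_settled = None
    if loss_detected:
        span = m_peak - m_final
        after_peak = post_t >= t_peak
        settled = np.abs(post_smoothed - m_final) <= 0.05 * span
        hit = np.nonzero(settled & after_peak)[0]
        if hit.size:
            t_settled = float(post_t[hit[0]])

    return MassPhaseResult(
        m_vesicle=m_vesicle,
        m_peak=m_peak,
        m_final=m_final,
        gain_pct=gain_pct,
        loss_pct=loss_pct,
        t_peak=t_peak if gain_detected or loss_detected else None,
        t_settled=t_settled,
        gain_detected=bool(gain_detected),
        loss_detected=bool(loss_detected),
        flags=flags,
    )


def df_plot_data(trace: QcmdTrace, decimate: int = 1) -> pd.DataFrame:
    """Time-ordered (delta_f, delta_D) pairs for dissipation-frequency plots."""
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    return pd.DataFrame(
        {
            "delta_f_hz": trace.delta_f[::decimate],
            "delta_D": trace.delta_D[::decimate],
            "time_s": trace.time[::decimate],
        }
    )


def _soft_film_check(trace: QcmdTrace) -> None:
    df_norm = -trace.delta_f / trace.overtone
    mask = np.abs(df_norm) > 1.0  # only meaningful at appreciable loading
    if not mask.any():
        return
    ratio = np.abs(trace.delta_D[mask] * 1e-6) / np.abs(df_norm[mask])
    if np.nanmax(ratio) > SOFT_FILM_RATIO:
        warnings.warn(
            "dissipation/frequency ratio exceeds the rigid-film regime; "
            "Sauerbrey masses may underestimate the true areal mass",
            stacklevel=3,
        )
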