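"""Online SMR feedback computation and the within-session learning index.

The neurofeedback protocol up-regulates the sensorimotor rhythm (SMR,
12–15 Hz) recorded over central electrodes.  During training the raw EEG is
band-pass filtered, and every 100 ms the power in the SMR band is computed
from an FFT of the trailing 10-s window.  The feedback threshold adapts
between runs to the median SMR power of the previous run, and a reward point
is granted whenever the power stays above threshold for more than one
second.  Learning within a session is summarised by the slope of an ordinary
least-squares regression of per-run median SMR power on run index; the
learning index (LI) of a participant is the mean of those slopes across
sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats

__all__ = [
    "FeedbackConfig",
    "RunSummary",
    "LearningResult",
    "online_smr_power",
    "adapt_threshold",
    "score_rewards",
    "learning_index",
    "run_feedback_session",
    "li_normality",
]


@dataclass(frozen=True)
class FeedbackConfig:
    """Parameters of the online feedback loop.

    Attributes
    ----------
    fs : float
        Sampling rate of the feedback channel in Hz.
    online_band : tuple of float
        Band-pass applied to the raw signal before power estimation (Hz).
    smr_band : tuple of float
        Frequency band whose power drives the feedback bar (Hz),
        endpoints inclusive.
    window_s : float
        Length of the trailing analysis window in seconds.
    step_s : float
        Interval between consecutive power estimates in seconds.
    reward_hold_s : float
        Minimum time the power must stay above threshold to earn a point.
    taper : str or None
        Taper applied to each analysis window before the FFT.  ``None``
        means a rectangular window.
    filter_order : int
        Order of the Butterworth band-pass filter.
    """

    fs: float = 250.0
    online_band: tuple[float, float] = (0.5, 45.0)
    smr_band: tuple[float, float] = (12.0, 15.0)
    window_s: float = 10.0
    step_s: float = 0.1
    reward_hold_s: float = 1.0
    taper: str | None = None
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (self.window_s > self.step_s > 0):
            raise ValueError("require window_s > step_s > 0")
        lo, hi = self.smr_band
        olo, ohi = self.online_band
        if not (olo <= lo < hi <= ohi):
            raise ValueError("smr_band must lie within online_band")
        if self.fs <= 2 * ohi:
            raise ValueError("sampling rate must exceed twice the online band edge")

    @property
    def window_n(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def step_n(self) -> int:
        return int(round(self.step_s * self.fs))


@dataclass
class RunSummary:
    """Per-run outcome of the feedback loop."""

    run_index: int
    median_smr_power: float
    threshold_used: float
    reward_points: int
    n_windows: int


@dataclass
class LearningResult:
    """Per-participant learning summary.

    ``li`` is the arithmetic mean of the per-session OLS slopes of median
    SMR power versus run index.
    """

    session_slopes: np.ndarray
    li: float
    session_medians: list[np.ndarray] = field(default_factory=list)


def _band_power_windows(windows: np.ndarray, fs: float,
                        band: tuple[float, float],
                        taper: str | None) -> np.ndarray:
    """Band power of each row of ``windows`` via a one-sided periodogram.

    Power is ``(2 / N**2) * sum |X_k|**2`` over non-DC bins whose centre
    frequency lies in ``band`` (endpoints inclusive), so a pure sinusoid of
    amplitude A on a bin centre contributes A**2 / 2 — its mean power.
    """
    n = windows.shape[-1]
    if taper is not None:
        w = sps.get_window(taper, n, fftbins=True)
        windows = windows * w
        scale = 2.0 / (w.sum() ** 2)
    else:
        scale = 2.0 / (n ** 2)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    spec = np.fft.rfft(windows, axis=-1)
    return scale * np.sum(np.abs(spec[..., sel]) ** 2, axis=-1)


def online_smr_power(signal: np.ndarray, cfg: FeedbackConfig | None = None) -> np.ndarray:
    """Causal sliding-window SMR band power of a feedback-channel signal.

    The signal is band-pass filtered to ``cfg.online_band`` with a causal
    Butterworth filter, then the SMR band power of each trailing window of
    ``cfg.window_s`` seconds is computed every ``cfg.step_s`` seconds.

    Returns an array with ``floor((len - window) / step) + 1`` values, one
    per window, the first aligned to the window ending at ``window_s``.
    """
    cfg = cfg or FeedbackConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if x.size < cfg.window_n:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one "
            f"{cfg.window_n}-sample analysis window"
        )
    sos = sps.butter(cfg.filter_order, cfg.online_band, btype="bandpass",
                     fs=cfg.fs, output="sos")
    x = sps.sosfilt(sos, x)  # causal: the online loop cannot see the future
    windows = sliding_window_view(x, cfg.window_n)[:: cfg.step_n]
    return _band_power_windows(windows, cfg.fs, cfg.smr_band, cfg.taper)


def adapt_threshold(previous_run_powers: np.ndarray) -> float:
    """Feedback threshold for the next run: median power of the previous run."""
    p = np.asarray(previous_run_powers, dtype=float)
    if p.size == 0:
        raise ValueError("cannot adapt threshold from an empty power series")
    return float(np.median(p))


def score_rewards(powers: np.ndarray, threshold: float,
                  cfg: FeedbackConfig | None = None) -> int:
    """Count reward points earned by a power trace.

    One point is granted per maximal above-threshold stretch lasting strictly
    longer than ``cfg.reward_hold_s``; a stretch earns exactly one point no
    matter how long it persists.
    """
    cfg = cfg or FeedbackConfig()
    above = np.asarray(powers, dtype=float) > threshold
    if not above.any():
        return 0
    # run-length encode the boolean trace
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, above.size - 1]
    lengths = ends - starts + 1
    run_is_above = above[starts]
    durations = lengths[run_is_above] * cfg.step_s
    return int(np.sum(durations > cfg.reward_hold_s))


def learning_index(session_run_medians: list[np.ndarray],
                   include_baseline: bool = True) -> LearningResult:
    """Learning index from per-session run medians of SMR power.

    Parameters
    ----------
    session_run_medians : list of array
        One array per session with the median SMR power of each run, in run
        order (index 0 is the baseline run).
    include_baseline : bool
        Whether run 0 enters the regression.  Default True: the slope is fit
        on all runs.

    Returns
    -------
    LearningResult
        Per-session OLS slopes (power per run, 0-based run index) and their
        mean, the LI.
    """
    if len(session_run_medians) == 0:
        raise ValueError("need at least one session")
    medians = [np.asarray(m, dtype=float) for m in session_run_medians]
    n_runs = {m.size for m in medians}
    if len(n_runs) != 1:
        raise ValueError("sessions must have equal run counts")
    slopes = []
    for m in medians:
        if not np.all(np.isfinite(m)):
            raise ValueError("run medians must be finite")
        x = np.arange(m.size, dtype=float)
        if not include_baseline:
            x, m = x[1:], m[1:]
        if m.size < 2:
            raise ValueError("need at least two run medians per session to fit a slope")
        slopes.append(np.polyfit(x, m, 1)[0])
    slopes = np.asarray(slopes)
    return LearningResult(session_slopes=slopes, li=float(slopes.mean()),
                          session_medians=medians)


def run_feedback_session(run_signals: list[np.ndarray],
                         cfg: FeedbackConfig | None = None) -> list[RunSummary]:
    """Replay the online loop over one session's runs.

    Run 0 is the baseline: its median power seeds the threshold of run 1,
    and thereafter the threshold adapts to the previous run's median.
    """
    cfg = cfg or FeedbackConfig()
    summaries: list[RunSummary] = []
    threshold = np.nan
    for idx, sig in enumerate(run_signals):
        powers = online_smr_power(sig, cfg)
        med = float(np.median(powers))
        points = 0 if idx == 0 else score_rewards(powers, threshold, cfg)
        summaries.append(RunSummary(run_index=idx, median_smr_power=med,
                                    threshold_used=threshold,
                                    reward_points=points,
                                    n_windows=powers.size))
        threshold = adapt_threshold(powers)
    return summaries


def li_normality(li_values: np.ndarray) -> float:
    """Shapiro–Wilk p-value for normality of cohort LI values."""
    li_values = np.asarray(li_values, dtype=float)
    if li_values.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(li_values).pvalue)
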