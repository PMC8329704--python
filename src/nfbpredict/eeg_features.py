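"""Resting-state EEG band power per scalp region of interest.

Multichannel resting recordings (eyes open / eyes closed) are band-pass
filtered, re-referenced to the common average, cut into 1-s epochs and
transformed to power spectral densities with Welch's method.  Relative band
power — the band-integrated PSD divided by the full-band integral — is
computed per epoch, z-standardized across epochs, and summarised by the
across-epoch median; regional values average the channels of nine scalp
ROIs (frontal / central / parietal × left / middle / right).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "BandScheme",
    "SCALP_ROIS",
    "preprocess_resting",
    "welch_power",
    "relative_band_power",
    "roi_band_table",
    "resting_feature_table",
]


@dataclass(frozen=True)
class BandScheme:
    """Frequency bands (Hz) used for relative power.

    ``full_band`` is the denominator range of the relative-power ratio and
    defaults to the preprocessing pass-band.  Bands may overlap (SMR and
    beta do).
    """

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 12.0)
    smr: tuple[float, float] = (12.0, 15.0)
    beta: tuple[float, float] = (12.5, 30.0)
    full_band: tuple[float, float] = (1.0, 100.0)

    def bands(self) -> dict[str, tuple[float, float]]:
        return {"theta": self.theta, "alpha": self.alpha,
                "smr": self.smr, "beta": self.beta}

    def __post_init__(self) -> None:
        lo, hi = self.full_band
        for name, (b0, b1) in self.bands().items():
            if not (b0 < b1):
                raise ValueError(f"band {name!r} is empty")
            if b0 < lo or b1 > hi:
                raise ValueError(f"band {name!r} lies outside full_band")


#: Nine scalp ROIs (10-20 labels), frontal/central/parietal x left/middle/right.
SCALP_ROIS: dict[str, tuple[str, ...]] = {
    "left frontal": ("F5", "F3", "FC5", "FC3"),
    "middle frontal": ("F1", "Fz", "F2", "FC1", "FCz", "FC2"),
    "right frontal": ("F4", "F6", "FC4", "FC6"),
    "left central": ("C5", "C3", "CP5", "CP3"),
    "middle central": ("C1", "Cz", "C2", "CP1", "CPz", "CP2"),
    "right central": ("C4", "C6", "CP4", "CP6"),
    "left parietal": ("P5", "P3", "PO7", "PO3"),
    "middle parietal": ("P1", "Pz", "P2", "POz"),
    "right parietal": ("P4", "P6", "PO4", "PO8"),
}


def preprocess_resting(signal: np.ndarray, fs: float,
                       band: tuple[float, float] = (1.0, 100.0),
                       epoch_s: float = 1.0,
                       reject_uv: float | None = None) -> np.ndarray:
    """Filter, re-reference and epoch a resting multichannel recording.

    Parameters
    ----------
    signal : array, shape (n_channels, n_samples)
    fs : float
        Sampling rate in Hz; must exceed twice the upper filter edge.
    band : tuple
        Band-pass edges in Hz (zero-phase Butterworth).
    epoch_s : float
        Epoch length in seconds; non-overlapping epochs.
    reject_uv : float, optional
        If given, epochs whose peak absolute amplitude exceeds this value
        on any channel are dropped (a simple stand-in for manual artifact
        rejection; off by default).

    Returns
    -------
    array, shape (n_epochs, n_channels, samples_per_epoch)
        Band-passed, common-average-referenced epochs.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if fs <= 2 * band[1]:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    n_epoch = int(round(epoch_s * fs))
    if x.shape[1] < n_epoch:
        raise ValueError("recording shorter than one epoch")
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    x = x - x.mean(axis=0, keepdims=True)  # common average reference
    n_epochs = x.shape[1] // n_epoch
    epochs = x[:, : n_epochs * n_epoch].reshape(x.shape[0], n_epochs, n_epoch)
    epochs = np.moveaxis(epochs, 1, 0)
    if reject_uv is not None:
        keep = np.abs(epochs).max(axis=(1, 2)) <= reject_uv
        epochs = epochs[keep]
        if epochs.shape[0] == 0:
            raise ValueError("all epochs rejected by the amplitude threshold")
    return epochs


def welch_power(x: np.ndarray, fs: float, nfft: int = 1000,
                axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD: Hamming-tapered segments, 50% overlap.

    ``nfft`` is the segment/FFT length (1000 points at 1 kHz sampling by
    default); inputs shorter than ``nfft`` use a single full-length segment.
    Returns ``(freqs, psd)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 8:
        raise ValueError(f"input of {n} samples is too short for a PSD (minimum 8)")
    nperseg = min(nfft, n)
    return sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend=False, axis=axis)


def relative_band_power(freqs: np.ndarray, psd: np.ndarray,
                        band: tuple[float, float],
                        full_band: tuple[float, float] = (1.0, 100.0),
                        axis: int = -1) -> np.ndarray:
    """Band-integrated PSD divided by the full-band integral (in [0, 1]).

    Integration is a bin sum over frequencies inside the (inclusive) band;
    ``band`` must lie within ``full_band`` so the ratio cannot exceed 1.
    """
    if band[0] >= band[1]:
        raise ValueError("zero- or negative-width band")
    if band[0] < full_band[0] or band[1] > full_band[1]:
        raise ValueError("band must lie within full_band")
    freqs = np.asarray(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    sel_full = (freqs >= full_band[0]) & (freqs <= full_band[1])
    if not sel.any():
        raise ValueError("no PSD bins inside the requested band")
    num = np.take(psd, np.flatnonzero(sel), axis=axis).sum(axis=axis)
    den = np.take(psd, np.flatnonzero(sel_full), axis=axis).sum(axis=axis)
    return num / den


def epoch_relative_powers(epochs: np.ndarray, fs: float,
                          bands: BandScheme | None = None,
                          nfft: int = 1000) -> np.ndarray:
    """Relative band power of every epoch and channel.

    Returns an array of shape (n_epochs, n_channels, n_bands) in the band
    order of :meth:`BandScheme.bands`.
    """
    bands = bands or BandScheme()
    freqs, psd = welch_power(epochs, fs, nfft=nfft, axis=-1)  # (epochs, ch, f)
    out = [relative_band_power(freqs, psd, brange, bands.full_band, axis=-1)
           for brange in bands.bands().values()]
    return np.stack(out, axis=-1)


def roi_band_table(epochs: np.ndarray, fs: float, channel_names: list[str],
                   roi_map: dict[str, tuple[str, ...]] | None = None,
                   bands: BandScheme | None = None,
                   nfft: int = 1000,
                   standardize: tuple[np.ndarray, np.ndarray] | None = None,
                   ) -> pd.DataFrame:
    """ROI x band relative-power table for one recording.

    Per channel and band the relative power is computed for every epoch,
    standardized, and the across-epoch median is taken; the ROI value is
    the mean over its channels.

    ``standardize`` supplies per-(channel, band) ``(mean, sd)`` arrays —
    typically pooled over all epochs of the whole cohort (see
    :func:`resting_feature_table`) so the values become unit-free without
    disturbing the between-participant ordering.  ``None`` leaves the raw
    relative powers (the ordering-relevant quantity) untouched.  Cells with
    zero pooled dispersion are set to 0 with a warning.

    Returns a DataFrame indexed by ROI name with one column per band.
    """
    roi_map = roi_map or SCALP_ROIS
    bands = bands or BandScheme()
    names = list(channel_names)
    missing = sorted({ch for chans in roi_map.values() for ch in chans} - set(names))
    if missing:
        raise ValueError(f"missing required channels: {', '.join(missing)}")
    rp = epoch_relative_powers(epochs, fs, bands, nfft)  # (epochs, ch, band)
    if standardize is not None:
        mean, sd = standardize
        if np.any(sd == 0):
            warnings.warn("zero pooled dispersion; standardized value set to 0",
                          RuntimeWarning, stacklevel=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            rp = np.where(sd > 0, (rp - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    med = np.median(rp, axis=0)  # (ch, band)
    idx = {ch: i for i, ch in enumerate(names)}
    band_names = list(bands.bands())
    rows = {}
    for roi, chans in roi_map.items():
        sel = [idx[c] for c in chans]
        rows[roi] = {b: float(med[sel, j].mean()) for j, b in enumerate(band_names)}
    return pd.DataFrame.from_dict(rows, orient="index")[band_names]


def resting_feature_table(recordings: dict[str, dict[str, tuple[np.ndarray, list[str], float]]],
                          roi_map: dict[str, tuple[str, ...]] | None = None,
                          bands: BandScheme | None = None,
                          nfft: int = 1000,
                          preprocess_band: tuple[float, float] = (1.0, 100.0)) -> pd.DataFrame:
    """Cohort-level resting power table.

    ``recordings[participant][condition] = (signal, channel_names, fs)`` with
    condition in {"eyes_open", "eyes_closed"}.  Per condition, the
    per-epoch relative powers of the whole cohort are pooled to compute
    the standardization mean/SD per channel and band (an affine map shared
    by all participants, so between-participant ordering is untouched);
    each participant's value is then the standardized across-epoch median,
    averaged over ROI channels.

    Returns a DataFrame of participants x MultiIndex columns
    (condition, roi, band).
    """
    # first pass: epoch-wise relative powers per participant and condition
    cache: dict[tuple, tuple[np.ndarray, list[str], float]] = {}
    pooled: dict[str, list[np.ndarray]] = {}
    for pid, conds in recordings.items():
        for cond, (sig, names, fs) in conds.items():
            epochs = preprocess_resting(sig, fs, band=preprocess_band)
            rp = epoch_relative_powers(epochs, fs, bands, nfft)
            cache[(pid, cond)] = (rp, names, fs)
            pooled.setdefault(cond, []).append(rp)
    stats_by_cond = {}
    for cond, mats in pooled.items():
        allrp = np.concatenate(mats, axis=0)
        stats_by_cond[cond] = (allrp.mean(axis=0), allrp.std(axis=0, ddof=0))

    use_bands = bands or BandScheme()
    band_names = list(use_bands.bands())
    use_rois = roi_map or SCALP_ROIS
    rows = {}
    for pid, conds in recordings.items():
        cells = {}
        for cond in conds:
            rp, names, fs = cache[(pid, cond)]
            mean, sd = stats_by_cond[cond]
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(sd > 0, (rp - mean) / np.where(sd > 0, sd, 1.0), 0.0)
            med = np.median(z, axis=0)
            idx = {ch: i for i, ch in enumerate(names)}
            for roi, chans in use_rois.items():
                sel = [idx[c] for c in chans]
                for j, band in enumerate(band_names):
                    cells[(cond, roi, band)] = float(med[sel, j].mean())
        rows[pid] = cells
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["condition", "roi", "band"])
    return out.sort_index(axis=1)
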