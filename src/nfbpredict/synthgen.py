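"""Synthetic multimodal cohorts with planted learning-ability effects.

Every downstream stage of the pipeline (feedback engine, EEG and fMRI
feature extraction, screening, prediction) is testable against ground truth
via this generator.  A cohort couples a per-participant *true learning
slope* (the drift of SMR band power across training runs, in median-power
units per run) to baseline features across modalities:

* neurofeedback runs: 1/f noise plus a 12–15 Hz oscillator whose power
  grows linearly with run index at the participant's true slope;
* resting EEG: pink noise plus theta/alpha/SMR/beta oscillators; planted
  effects modulate the SMR amplitude of chosen scalp-ROI channels;
* resting fMRI: masked Gaussian noise with planted low-frequency amplitude
  (ALFF), local synchrony (ReHo) and shared-signal connectivity (FC)
  effects;
* morphometry: smooth random fields with clusters whose intensity is
  linear in the true slope.

Rank correlations between latent features and the true slope are controlled
with a Gaussian copula: latents are jointly Gaussian with the slope, and a
target Spearman rho is mapped to the Gaussian correlation via
``rho_g = 2 sin(pi * rho_s / 6)``.  Monotone maps from latent to signal
amplitude then preserve the planted rank correlation exactly.

Ground truth is stored alongside the cohort and is never consumed by any
analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .eeg_features import SCALP_ROIS

__all__ = [
    "PlantedEffect",
    "CohortConfig",
    "GroundTruth",
    "CohortDataset",
    "generate_cohort",
    "generate_latent_cohort",
    "generate_split_effect_cohort",
    "synth_nfb_run",
    "synth_resting_eeg",
    "synth_fmri",
    "synth_morphometry",
    "spearman_to_gaussian",
    "default_roi_table",
    "REQUIRED_EEG_CHANNELS",
]

MODALITIES = ("eeg_power", "gmv", "wmv", "alff", "reho", "fc")

#: channels required by the nine scalp ROI definitions
REQUIRED_EEG_CHANNELS: tuple[str, ...] = tuple(
    ch for chans in SCALP_ROIS.values() for ch in chans)

NETWORKS = ("cerebellar", "cingulo-opercular", "default mode", "frontoparietal",
            "occipital", "sensorimotor", "emotional")


def spearman_to_gaussian(rho_s: float) -> float:
    """Gaussian (Pearson) correlation yielding Spearman ``rho_s`` under a copula."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted association between a baseline feature and the true slope.

    Parameters
    ----------
    modality : str
        One of ``eeg_power, gmv, wmv, alff, reho, fc``.
    target : dict
        Location of the effect; by modality:
        ``eeg_power``: ``{"roi": name, "condition": ..., }`` (condition
        defaults to eyes_open); ``gmv/wmv/alff/reho``: ``{"center": (i,j,k),
        "radius": voxels}``; ``fc``: ``{"edge": (roi_name, roi_name)}``.
    true_correlation : float
        Target Spearman correlation (|rho| < 1) between the latent feature
        and the true slope.
    noise_sd : float
        SD of latent-scale measurement noise added on top of the copula
        latent before it is painted into the signal.
    """

    modality: str
    target: dict
    true_correlation: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not abs(self.true_correlation) < 1:
            raise ValueError("|true_correlation| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of a synthetic cohort.

    Defaults mirror the emulated study: 27 participants, three training
    sessions of 12 three-minute runs (run 0 a no-trend baseline), 3-min
    64-channel resting EEG at 1 kHz, and small abstract-grid volumes (3-mm
    isotropic identity-like affine; registration is out of scope and the
    statistics are geometry-agnostic).
    """

    n_participants: int = 27
    n_sessions: int = 3
    runs_per_session: int = 12
    run_duration_s: float = 180.0
    fs_nfb: float = 250.0
    fs_eeg: float = 1000.0
    eeg_duration_s: float = 180.0
    eeg_channels: tuple[str, ...] = REQUIRED_EEG_CHANNELS
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_volumes: int = 100
    tr_s: float = 2.0
    voxel_mm: float = 3.0
    n_rois: int = 20
    roi_radius_mm: float = 8.0
    effect_map: tuple[PlantedEffect, ...] = ()
    slope_mean: float = 0.05
    slope_sd: float = 0.1
    nfb_base_power: float = 1.0
    nfb_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_sessions", "runs_per_session",
                     "n_volumes", "n_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.run_duration_s <= 0 or self.eeg_duration_s <= 0:
            raise ValueError("durations must be positive")


@dataclass
class GroundTruth:
    """Planted parameters of a generated cohort (write-only for analyses)."""

    true_slopes: np.ndarray
    latents: dict[int, np.ndarray] = field(default_factory=dict)
    effects: tuple[PlantedEffect, ...] = ()

    def to_dict(self) -> dict:
        return {
            "true_slopes": self.true_slopes.tolist(),
            "latents": {str(k): v.tolist() for k, v in self.latents.items()},
            "effects": [asdict(e) for e in self.effects],
        }


@dataclass
class CohortDataset:
    """In-memory bundle of one synthetic cohort.

    ``nfb_runs[p][s][r]`` is the raw feedback-channel signal of participant
    p, session s, run r.  ``resting_eeg[p][condition]`` is
    ``(signal, channel_names, fs)``.  ``fmri[p]`` is a
    :class:`~nfbpredict.fmri_features.VolumeSeries`; ``gmv[p]`` / ``wmv[p]``
    are 3D maps sharing ``mask``.
    """

    config: CohortConfig
    participants: pd.DataFrame  # id, age, sex
    nfb_runs: list[list[list[np.ndarray]]]
    resting_eeg: list[dict[str, tuple[np.ndarray, list[str], float]]]
    fmri: list
    gmv: list[np.ndarray]
    wmv: list[np.ndarray]
    mask: np.ndarray
    roi_table: pd.DataFrame
    affine: np.ndarray


# ---------------------------------------------------------------------------
# latent layer

def _draw_latents(config: CohortConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint Gaussian draw of slope factor and per-effect latents.

    Returns ``(g_slope, latents_clean, latents_noisy)`` with latents of
    shape (n_effects, n_participants).  Each effect's latent correlates
    with the slope factor at the Gaussian level implied by its target
    Spearman correlation; noise is added on the latent scale.
    """
    n = config.n_participants
    g = rng.standard_normal(n)
    clean = np.empty((len(config.effect_map), n))
    noisy = np.empty_like(clean)
    for i, eff in enumerate(config.effect_map):
        rho_g = spearman_to_gaussian(eff.true_correlation)
        eps = rng.standard_normal(n)
        clean[i] = rho_g * g + np.sqrt(1.0 - rho_g ** 2) * eps
        noisy[i] = clean[i] + eff.noise_sd * rng.standard_normal(n)
    return g, clean, noisy


def generate_latent_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Latent-level cohort: the feature table the signals would encode.

    Returns a participants x effects DataFrame of noisy latent feature
    values together with the ground truth.  This is the copula layer the
    signal synthesizers paint into data; it is useful for statistical
    studies (screening calibration, prediction benchmarks) where full
    signal synthesis would add nothing but runtime.
    """
    rng = np.random.default_rng(config.seed)
    g, clean, noisy = _draw_latents(config, rng)
    slopes = config.slope_mean + config.slope_sd * g
    cols = {f"effect_{i}_{e.modality}": noisy[i]
            for i, e in enumerate(config.effect_map)}
    table = pd.DataFrame(cols, index=pd.RangeIndex(config.n_participants, name="participant"))
    gt = GroundTruth(true_slopes=slopes,
                     latents={i: clean[i] for i in range(len(config.effect_map))},
                     effects=tuple(config.effect_map))
    return table, gt


def generate_split_effect_cohort(n_participants: int = 27,
                                 modalities: tuple[str, ...] = ("eeg", "smri", "alff", "fc"),
                                 features_per_modality: int = 3,
                                 feature_noise_sd: float = 0.5,
                                 slope_noise_sd: float = 0.3,
                                 seed: int = 0,
                                 ) -> tuple[dict[str, pd.DataFrame], np.ndarray]:
    """Latent cohort whose learning ability is split across modalities.

    Each modality carries one independent standard-normal component
    ``c_m``; the learning index is their equal-weight sum plus noise,
    ``li = sum_m c_m / sqrt(M) + slope_noise_sd * eps``, and every feature
    of modality m is ``c_m + feature_noise_sd * nu``.  No single modality
    can see the other components, so a multimodal predictor has strictly
    more signal available — the construction behind the
    multimodal-beats-single-modality property.

    Returns ``(tables, li)`` with one participants x features DataFrame
    per modality.
    """
    rng = np.random.default_rng(seed)
    m = len(modalities)
    comps = rng.standard_normal((m, n_participants))
    li = comps.sum(axis=0) / np.sqrt(m) + slope_noise_sd * rng.standard_normal(n_participants)
    tables = {}
    for i, name in enumerate(modalities):
        feats = comps[i][:, None] + feature_noise_sd * rng.standard_normal(
            (n_participants, features_per_modality))
        tables[name] = pd.DataFrame(
            feats, columns=[f"{name}_f{j}" for j in range(features_per_modality)])
    return tables, li


# ---------------------------------------------------------------------------
# signal synthesizers

def _pink_noise(n: int, rng: np.random.Generator, slope: float = 1.0) -> np.ndarray:
    """1/f^slope noise via spectral shaping, unit variance."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spec *= freqs ** (-slope / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_nfb_run(true_slope: float, run_index: int, fs: float = 250.0,
                  duration_s: float = 180.0,
                  rng: np.random.Generator | None = None,
                  base_power: float = 1.0, noise_sd: float = 0.3,
                  smr_freq: float = 13.5, power_floor: float = 1e-3) -> np.ndarray:
    """One training run's raw feedback-channel signal.

    Broadband 1/f noise plus a narrowband SMR oscillator whose *band power*
    equals ``base_power + true_slope * run_index`` (floored at
    ``power_floor``); a sinusoid of amplitude A has band power A^2/2, so
    the oscillator amplitude is ``sqrt(2 * power)``.  Run 0 is the baseline
    run and carries no trend (power = base_power).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    trend_idx = 0 if run_index == 0 else run_index
    power = max(base_power + true_slope * trend_idx, power_floor)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.sqrt(2.0 * power) * np.sin(2 * np.pi * smr_freq * t + phase)
    if noise_sd > 0:
        x = x + noise_sd * _pink_noise(n, rng)
    return x


_BAND_OSCILLATORS = {  # band name -> (freq Hz, baseline amplitude)
    "theta": (6.0, 1.0),
    "alpha": (10.0, 1.5),
    "smr": (13.5, 0.8),
    "beta": (22.0, 0.6),
}


def synth_resting_eeg(n_channels_or_names, fs: float = 1000.0,
                      duration_s: float = 180.0,
                      rng: np.random.Generator | None = None,
                      smr_latents: dict[str, float] | None = None,
                      latent_gain: float = 0.35,
                      noise_amp: float = 1.0,
                      amp_overrides: dict[tuple[str, str], float] | None = None,
                      ) -> tuple[np.ndarray, list[str]]:
    """Multichannel resting EEG: pink noise plus band oscillators.

    Parameters
    ----------
    n_channels_or_names : int or list of str
        Channel names; an integer pads the required scalp-ROI channels
        with extra ``EXTn`` channels.  All channels of the nine scalp ROIs
        must be present.
    smr_latents : dict, optional
        ``channel -> latent`` values; the SMR oscillator amplitude of a
        channel is scaled by ``exp(latent_gain * latent)`` — a monotone map,
        so planted rank correlations survive extraction.
    amp_overrides : dict, optional
        ``(channel, band) -> amplitude`` overrides of the baseline
        oscillator amplitudes.

    Returns ``(signal (n_channels, n_samples), channel_names)``.
    """
    if isinstance(n_channels_or_names, int):
        names = list(REQUIRED_EEG_CHANNELS)
        if n_channels_or_names < len(names):
            raise ValueError(
                f"need at least {len(names)} channels to cover the scalp ROIs")
        names += [f"EXT{i}" for i in range(n_channels_or_names - len(names))]
    else:
        names = list(n_channels_or_names)
        missing = sorted(set(REQUIRED_EEG_CHANNELS) - set(names))
        if missing:
            raise ValueError(f"missing required channels: {', '.join(missing)}")
    rng = rng or np.random.default_rng()
    smr_latents = smr_latents or {}
    amp_overrides = amp_overrides or {}
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    sig = np.empty((len(names), n))
    for i, ch in enumerate(names):
        x = noise_amp * _pink_noise(n, rng)
        for band, (freq, amp0) in _BAND_OSCILLATORS.items():
            amp = amp_overrides.get((ch, band), amp0)
            if band == "smr" and ch in smr_latents:
                amp = amp * np.exp(latent_gain * smr_latents[ch])
            x = x + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        sig[i] = x
    return sig, names


def _cluster_voxels(center, radius: float, shape) -> np.ndarray:
    """Voxel indices of a spherical cluster (radius in voxels)."""
    center = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, shape)
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    d2 = np.sum((pts - center) ** 2, axis=1)
    return pts[d2 <= radius ** 2 + 1e-9]


def _ellipsoid_mask(shape) -> np.ndarray:
    c = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) / 2.0
    ii, jj, kk = np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]]
    return ((ii - c[0]) / semi[0]) ** 2 + ((jj - c[1]) / semi[1]) ** 2 \
        + ((kk - c[2]) / semi[2]) ** 2 <= 1.0


def default_roi_table(n_rois: int, grid_shape, voxel_mm: float = 3.0,
                      radius_mm: float = 8.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """ROI definition table with centres spread inside the grid.

    Columns: name, x, y, z (world mm under a ``voxel_mm``-isotropic affine
    with origin at the grid corner), radius (mm), network.
    """
    rng = rng or np.random.default_rng(0)
    shape = np.asarray(grid_shape)
    mask = _ellipsoid_mask(grid_shape)
    centers = []
    r_vox = radius_mm / voxel_mm
    tries = 0
    while len(centers) < n_rois:
        c = rng.uniform(low=r_vox * 0.5, high=shape - 1 - r_vox * 0.5, size=3)
        ci = tuple(np.round(c).astype(int))
        if not mask[ci]:
            tries += 1
            if tries > 10000:
                raise ValueError("could not place ROIs inside the mask")
            continue
        if centers and np.min([np.sum((c - p) ** 2) for p in centers]) < (1.2 * r_vox) ** 2:
            tries += 1
            if tries > 10000:
                raise ValueError("could not place non-overlapping ROIs")
            continue
        centers.append(c)
    rows = []
    for i, c in enumerate(centers):
        rows.append({"name": f"roi{i:03d}",
                     "x": c[0] * voxel_mm, "y": c[1] * voxel_mm, "z": c[2] * voxel_mm,
                     "radius": radius_mm,
                     "network": NETWORKS[i % len(NETWORKS)]})
    return pd.DataFrame(rows)


def synth_fmri(grid_shape, n_volumes: int = 100, tr_s: float = 2.0,
               rng: np.random.Generator | None = None,
               mask: np.ndarray | None = None,
               alff_effects: list[tuple[np.ndarray, float]] | None = None,
               reho_effects: list[tuple[np.ndarray, float]] | None = None,
               fc_effects: list[tuple[np.ndarray, np.ndarray, float]] | None = None,
               noise_sd: float = 1.0, base_level: float = 100.0,
               ) -> tuple[np.ndarray, np.ndarray]:
    """One participant's 4D BOLD-like volume.

    Parameters
    ----------
    alff_effects : list of (voxels, amplitude)
        Add an in-band (0.01–0.08 Hz) sinusoid of the given amplitude to
        the listed voxels.
    reho_effects : list of (voxels, weight)
        Mix a shared band-limited time course into the listed voxels with
        the given weight, creating local rank synchrony.
    fc_effects : list of (voxels_a, voxels_b, weight)
        Mix a shared low-frequency latent signal into both voxel sets,
        raising the correlation of their mean series with the weight.

    Returns ``(data (x,y,z,t), mask)``.  Raises if any effect voxel falls
    outside the mask.
    """
    rng = rng or np.random.default_rng()
    shape = tuple(grid_shape)
    if mask is None:
        mask = _ellipsoid_mask(shape)
    t = np.arange(n_volumes) * tr_s
    data = np.zeros(shape + (n_volumes,))
    data[mask] = base_level + noise_sd * rng.standard_normal((int(mask.sum()), n_volumes))

    def _check(vox, what):
        if not mask[tuple(vox.T)].all():
            raise ValueError(f"{what} cluster extends outside the brain mask")

    for vox, amp in (alff_effects or []):
        _check(vox, "ALFF")
        freq = rng.uniform(0.02, 0.06)
        phase = rng.uniform(0, 2 * np.pi)
        data[tuple(vox.T)] += amp * np.sin(2 * np.pi * freq * t + phase)
    for vox, w in (reho_effects or []):
        _check(vox, "ReHo")
        shared = _band_limited(n_volumes, tr_s, rng)
        data[tuple(vox.T)] += w * shared
    for vox_a, vox_b, w in (fc_effects or []):
        _check(vox_a, "FC")
        _check(vox_b, "FC")
        shared = _band_limited(n_volumes, tr_s, rng)
        data[tuple(vox_a.T)] += w * shared
        data[tuple(vox_b.T)] += w * shared
    return data, mask


def _band_limited(n: int, tr: float, rng: np.random.Generator,
                  band: tuple[float, float] = (0.01, 0.08)) -> np.ndarray:
    """Unit-variance random signal confined to a low-frequency band."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    spec[~keep] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synth_morphometry(grid_shape,
                      rng: np.random.Generator | None = None,
                      clusters: list[tuple[np.ndarray, float, float]] | None = None,
                      mask: np.ndarray | None = None,
                      smooth_sigma: float = 1.0, base_level: float = 0.5,
                      field_sd: float = 0.05) -> np.ndarray:
    """One participant's morphometry (GMV- or WMV-like) map.

    A smooth random field; inside each planted cluster the intensity is
    ``base + offset + noise_sd * eps`` with ``(voxels, offset, noise_sd)``
    per cluster.  The cohort assembler sets ``offset`` proportional to the
    participant's latent feature value, so across participants the cluster
    intensity is linear in (a noisy correlate of) the true learning slope.
    """
    from scipy.ndimage import gaussian_filter
    rng = rng or np.random.default_rng()
    shape = tuple(grid_shape)
    if mask is None:
        mask = _ellipsoid_mask(shape)
    vol = gaussian_filter(rng.standard_normal(shape), smooth_sigma, mode="reflect")
    vol = base_level + field_sd * vol
    vol[~mask] = 0.0
    for vox, offset, noise_sd in (clusters or []):
        if not mask[tuple(vox.T)].all():
            raise ValueError("morphometry cluster extends outside the mask")
        vol[tuple(vox.T)] += offset + noise_sd * rng.standard_normal(len(vox))
    return vol


# ---------------------------------------------------------------------------
# cohort assembly

#: cluster intensity per unit latent, in map units (background field SD 0.05)
MORPH_EFFECT_GAIN = 0.2


def generate_cohort(config: CohortConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a full multimodal cohort with planted ground truth.

    Deterministic under ``config.seed``.  Raises a configuration error if
    any planted effect does not resolve to a valid location for the
    configured geometry (ROI name unknown, cluster outside the brain mask,
    FC edge naming an absent ROI).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    g, clean, noisy = _draw_latents(config, rng)
    slopes = config.slope_mean + config.slope_sd * g
    gt = GroundTruth(true_slopes=slopes,
                     latents={i: clean[i] for i in range(len(config.effect_map))},
                     effects=tuple(config.effect_map))

    participants = pd.DataFrame({
        "id": [f"sub-{i:03d}" for i in range(n)],
        "age": np.round(rng.normal(23.1, 2.36, n), 1),
        "sex": rng.choice(["M", "F"], size=n, p=[12 / 27, 15 / 27]),
    })

    mask = _ellipsoid_mask(config.grid_shape)
    affine = np.diag([config.voxel_mm] * 3 + [1.0])
    roi_table = default_roi_table(config.n_rois, config.grid_shape,
                                  config.voxel_mm, config.roi_radius_mm,
                                  rng=np.random.default_rng(config.seed + 1))
    roi_centers_vox = {row["name"]: np.array([row["x"], row["y"], row["z"]]) / config.voxel_mm
                       for _, row in roi_table.iterrows()}
    r_vox = config.roi_radius_mm / config.voxel_mm

    # resolve effect targets once, validating geometry
    eeg_effs, alff_effs, reho_effs, fc_effs, gmv_effs, wmv_effs = [], [], [], [], [], []
    for i, eff in enumerate(config.effect_map):
        if eff.modality == "eeg_power":
            roi = eff.target.get("roi")
            if roi not in SCALP_ROIS:
                raise ValueError(f"effect {i}: unknown scalp ROI {roi!r}")
            eeg_effs.append((i, roi, eff.target.get("condition", "eyes_open")))
        elif eff.modality in ("alff", "reho"):
            vox = _cluster_voxels(eff.target["center"], eff.target["radius"],
                                  config.grid_shape)
            if vox.size == 0 or not mask[tuple(vox.T)].all():
                raise ValueError(f"effect {i} ({eff.modality}): cluster outside the mask")
            (alff_effs if eff.modality == "alff" else reho_effs).append((i, vox))
        elif eff.modality == "fc":
            a, b = eff.target["edge"]
            for name in (a, b):
                if name not in roi_centers_vox:
                    raise ValueError(f"effect {i}: unknown ROI {name!r} in FC edge")
            vox_a = _cluster_voxels(roi_centers_vox[a], r_vox, config.grid_shape)
            vox_b = _cluster_voxels(roi_centers_vox[b], r_vox, config.grid_shape)
            # ROI spheres clip at the mask edge, like extraction does
            vox_a = vox_a[mask[tuple(vox_a.T)]]
            vox_b = vox_b[mask[tuple(vox_b.T)]]
            if vox_a.size == 0 or vox_b.size == 0:
                raise ValueError(f"effect {i}: FC ROI sphere has no in-mask voxels")
            fc_effs.append((i, vox_a, vox_b))
        else:  # gmv / wmv
            vox = _cluster_voxels(eff.target["center"], eff.target["radius"],
                                  config.grid_shape)
            if vox.size == 0 or not mask[tuple(vox.T)].all():
                raise ValueError(f"effect {i} ({eff.modality}): cluster outside the mask")
            (gmv_effs if eff.modality == "gmv" else wmv_effs).append((i, vox))

    nfb_runs, resting, fmri_list, gmv_list, wmv_list = [], [], [], [], []
    from .fmri_features import VolumeSeries

    for p in range(n):
        prng = np.random.default_rng(rng.integers(0, 2 ** 31))
        sessions = []
        for _s in range(config.n_sessions):
            runs = [synth_nfb_run(slopes[p], r, config.fs_nfb,
                                  config.run_duration_s, prng,
                                  base_power=config.nfb_base_power,
                                  noise_sd=config.nfb_noise_sd)
                    for r in range(config.runs_per_session)]
            sessions.append(runs)
        nfb_runs.append(sessions)

        conds = {}
        for cond in ("eyes_open", "eyes_closed"):
            latents = {}
            for (i, roi, eff_cond) in eeg_effs:
                if eff_cond == cond:
                    for ch in SCALP_ROIS[roi]:
                        latents[ch] = noisy[i][p]
            sig, names = synth_resting_eeg(list(config.eeg_channels), config.fs_eeg,
                                           config.eeg_duration_s, prng,
                                           smr_latents=latents)
            conds[cond] = (sig, names, config.fs_eeg)
        resting.append(conds)

        a_eff = [(vox, 1.5 * np.exp(0.5 * noisy[i][p])) for (i, vox) in alff_effs]
        r_eff = [(vox, 1.0 * np.exp(0.5 * noisy[i][p])) for (i, vox) in reho_effs]
        f_eff = [(va, vb, 0.8 * np.exp(0.5 * noisy[i][p])) for (i, va, vb) in fc_effs]
        data, _ = synth_fmri(config.grid_shape, config.n_volumes, config.tr_s,
                             prng, mask=mask, alff_effects=a_eff,
                             reho_effects=r_eff, fc_effects=f_eff)
        fmri_list.append(VolumeSeries(data=data, tr=config.tr_s, mask=mask,
                                      affine=affine))

        g_cl = [(vox, MORPH_EFFECT_GAIN * noisy[i][p], 0.01)
                for (i, vox) in gmv_effs]
        w_cl = [(vox, MORPH_EFFECT_GAIN * noisy[i][p], 0.01)
                for (i, vox) in wmv_effs]
        gmv_list.append(synth_morphometry(config.grid_shape, prng,
                                          clusters=g_cl, mask=mask))
        wmv_list.append(synth_morphometry(config.grid_shape, prng,
                                          clusters=w_cl, mask=mask))

    dataset = CohortDataset(config=config, participants=participants,
                            nfb_runs=nfb_runs, resting_eeg=resting,
                            fmri=fmri_list, gmv=gmv_list, wmv=wmv_list,
                            mask=mask, roi_table=roi_table, affine=affine)
    return dataset, gt
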