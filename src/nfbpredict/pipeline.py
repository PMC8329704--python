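"""End-to-end orchestration: LI -> features -> screening -> prediction.

Each stage is a plain function over the in-memory cohort so stages can be
run (and tested) independently; :func:`run_pipeline` chains them and writes
TSV/JSON/NIfTI outputs.  All randomness flows from a single seed recorded
in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .eeg_features import BandScheme, resting_feature_table
from .fmri_features import (alff, bandpass_timeseries, extract_roi_series,
                            fc_matrix, gaussian_smooth, reho,
                            z_standardize_map)
from .nfb_engine import FeedbackConfig, learning_index, li_normality, online_smr_power
from .prediction import assemble_features, predict_all_sets
from .screening import ScreenResult, edge_screen, permutation_glm_map, spearman_screen

__all__ = [
    "PipelineConfig",
    "compute_learning",
    "extract_features",
    "screen_features",
    "run_prediction",
    "run_pipeline",
]

_KNOWN_KEYS = {
    "n_perm", "voxel_p", "min_cluster", "alpha_fdr", "edge_p", "models",
    "seed", "include_baseline", "alff_band", "smooth_fwhm_mm", "nfft",
    "eeg_full_band", "n_trees", "stages",
}


@dataclass
class PipelineConfig:
    """Tunable analysis parameters (schema-validated; unknown keys rejected)."""

    n_perm: int = 10000
    voxel_p: float = 0.005
    min_cluster: int = 50
    alpha_fdr: float = 0.05
    edge_p: float = 0.005
    models: tuple[str, ...] = ("svr_linear",)
    seed: int = 0
    include_baseline: bool = True
    alff_band: tuple[float, float] = (0.01, 0.08)
    smooth_fwhm_mm: float = 6.0
    nfft: int = 1000
    eeg_full_band: tuple[float, float] = (1.0, 100.0)
    n_trees: int = 500
    stages: tuple[str, ...] = ("li", "features", "screen", "predict")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("models", "alff_band", "eeg_full_band", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def compute_learning(dataset, feedback_cfg: FeedbackConfig | None = None,
                     include_baseline: bool = True) -> pd.DataFrame:
    """Replay the feedback engine over every run and compute per-participant LI."""
    cfg = feedback_cfg or FeedbackConfig(fs=dataset.config.fs_nfb)
    rows = []
    for p, pid in enumerate(dataset.participants["id"]):
        session_medians = []
        for runs in dataset.nfb_runs[p]:
            meds = [float(np.median(online_smr_power(sig, cfg))) for sig in runs]
            session_medians.append(np.asarray(meds))
        res = learning_index(session_medians, include_baseline=include_baseline)
        rows.append({"id": pid, "li": res.li,
                     **{f"slope_s{j + 1}": s for j, s in enumerate(res.session_slopes)}})
    return pd.DataFrame(rows)


def extract_features(dataset, alff_band=(0.01, 0.08), smooth_fwhm_mm: float = 6.0,
                     nfft: int = 1000, bands: BandScheme | None = None) -> dict:
    """Baseline feature extraction for every modality.

    Returns a dict with the EEG power table, per-participant z-standardized
    (and, for ALFF/ReHo, smoothed per convention) metric maps, morphometry
    map stacks and Fisher-z connectomes.
    """
    cfg = dataset.config
    eeg_recs = {pid: dataset.resting_eeg[p]
                for p, pid in enumerate(dataset.participants["id"])}
    full_band = bands.full_band if bands is not None else (1.0, min(100.0, cfg.fs_eeg / 2 - 1))
    use_bands = bands or BandScheme(full_band=full_band)
    eeg_table = resting_feature_table(eeg_recs, bands=use_bands, nfft=nfft,
                                      preprocess_band=use_bands.full_band)

    n = cfg.n_participants
    mask = dataset.mask
    vox = float(dataset.affine[0, 0])
    alff_maps, falff_maps, reho_maps, conn = [], [], [], []
    from .fmri_features import falff as _falff
    for p in range(n):
        vol = dataset.fmri[p]
        smoothed = np.stack([gaussian_smooth(vol.data[..., t], smooth_fwhm_mm, vox)
                             for t in range(vol.n_volumes)], axis=-1)
        a = alff(smoothed, vol.tr, band=alff_band, axis=-1)
        fa = _falff(smoothed, vol.tr, band=alff_band, axis=-1)
        alff_maps.append(z_standardize_map(a, mask))
        falff_maps.append(z_standardize_map(fa, mask))
        bp = bandpass_timeseries(vol.data, vol.tr, axis=-1)
        rh = reho(bp, mask)
        rh = gaussian_smooth(z_standardize_map(rh, mask), smooth_fwhm_mm, vox)
        reho_maps.append(rh)
        filt_vol = type(vol)(data=bp, tr=vol.tr, mask=mask, affine=vol.affine)
        roi_series = extract_roi_series(filt_vol, dataset.roi_table)
        conn.append(fc_matrix(roi_series))

    return {
        "eeg": eeg_table,
        "gmv": np.stack(dataset.gmv),
        "wmv": np.stack(dataset.wmv),
        "alff": np.stack(alff_maps),
        "falff": np.stack(falff_maps),
        "reho": np.stack(reho_maps),
        "connectomes": np.stack([c.to_numpy() for c in conn]),
        "roi_names": list(conn[0].index),
    }


def _cluster_mean_table(maps: np.ndarray, stat_maps, prefix: str) -> tuple[pd.DataFrame, list[ScreenResult]]:
    """Per-cluster mean intensities as candidate predictor columns."""
    cols = {}
    results = []
    for contrast, sm in zip(("pos", "neg"), stat_maps):
        for c in sm.clusters:
            name = f"{prefix}_{contrast}_c{c.label}"
            vals = maps[:, c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]].mean(axis=1)
            cols[name] = vals
            results.append(ScreenResult(feature=name, rho=c.peak_t,
                                        p=float(sm.p_map[c.peak_ijk]), selected=True))
    return pd.DataFrame(cols), results


def screen_features(features: dict, li: np.ndarray, covariates: pd.DataFrame,
                    n_perm: int = 10000, voxel_p: float = 0.005,
                    min_cluster: int = 50, alpha_fdr: float = 0.05,
                    edge_p: float = 0.005, mask: np.ndarray | None = None,
                    seed: int = 0) -> dict:
    """Screen every modality against LI.

    EEG cells: Spearman + BH-FDR.  GMV/WMV/ALFF maps: Freedman–Lane
    permutation GLM with age and sex covariates, cluster extraction.
    FC edges: partial Spearman at an uncorrected threshold.
    """
    rng = np.random.default_rng(seed)
    out: dict = {}
    out["eeg"] = spearman_screen(features["eeg"], li, alpha=alpha_fdr)
    for key in ("gmv", "wmv", "alff"):
        out[key] = permutation_glm_map(features[key], li, covariates, mask=mask,
                                       n_perm=n_perm, voxel_p=voxel_p,
                                       min_cluster=min_cluster,
                                       seed=np.random.default_rng(rng.integers(2 ** 31)))
    names = features["roi_names"]
    iu = np.triu_indices(len(names), k=1)
    edge_names = [(names[i], names[j]) for i, j in zip(*iu)]
    out["fc"] = edge_screen(features["connectomes"], li, covariates,
                            p_thresh=edge_p, edge_names=edge_names)
    return out


def run_prediction(features: dict, screens: dict, li: np.ndarray,
                   models=("svr_linear",), seed: int = 0,
                   n_trees: int = 500) -> dict:
    """Assemble screened feature sets and run LOOCV with each model."""
    gmv_tab, gmv_res = _cluster_mean_table(features["gmv"], screens["gmv"], "gmv")
    wmv_tab, wmv_res = _cluster_mean_table(features["wmv"], screens["wmv"], "wmv")
    smri_tab = pd.concat([gmv_tab, wmv_tab], axis=1)
    if smri_tab.shape[1] == 0:
        smri_tab = pd.DataFrame({
            "gmv_global": features["gmv"].reshape(len(li), -1).mean(axis=1),
            "wmv_global": features["wmv"].reshape(len(li), -1).mean(axis=1)})
    alff_tab, alff_res = _cluster_mean_table(features["alff"], screens["alff"], "alff")
    if alff_tab.shape[1] == 0:
        alff_tab = pd.DataFrame(
            {"alff_global": features["alff"].reshape(len(li), -1).mean(axis=1)})
    iu = np.triu_indices(features["connectomes"].shape[1], k=1)
    names = features["roi_names"]
    fc_tab = pd.DataFrame(features["connectomes"][:, iu[0], iu[1]],
                          columns=[(names[i], names[j]) for i, j in zip(*iu)])
    tables = {"eeg": features["eeg"], "smri": smri_tab,
              "alff": alff_tab, "fc": fc_tab}
    for t in tables.values():  # align rows on participant order
        t.index = pd.RangeIndex(len(li))
    screen_results = {"eeg": screens["eeg"], "smri": gmv_res + wmv_res,
                      "alff": alff_res, "fc": screens["fc"]}
    sets = assemble_features(tables, screen_results)
    degenerate = [s.name for s in sets if s.degenerate]
    if degenerate:
        warnings.warn("no screened features for: " + ", ".join(degenerate)
                      + "; falling back to modality means", RuntimeWarning,
                      stacklevel=2)
    reports = {}
    for m in models:
        reports[m] = predict_all_sets(sets, li, model=m, seed=seed, n_trees=n_trees)
    return {"feature_sets": sets, "reports": reports}


def run_pipeline(dataset, config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the requested stages end to end over an in-memory cohort.

    Returns a bundle with the LI table, features, screening output and
    prediction reports; when ``outdir`` is given, writes ``li.tsv``,
    ``eeg_features.tsv``, stat-map NIfTIs, ``prediction.json`` and a run
    log.  Deterministic given the same inputs and seed.
    """
    cfg = config or PipelineConfig()
    stages = set(cfg.stages)
    # later stages imply their prerequisites
    if "predict" in stages:
        stages |= {"li", "features", "screen"}
    if "screen" in stages:
        stages |= {"li", "features"}
    bundle: dict = {"config": cfg}
    if "li" in stages:
        li_df = compute_learning(dataset, include_baseline=cfg.include_baseline)
        bundle["li"] = li_df
        bundle["li_normality_p"] = li_normality(li_df["li"].to_numpy())
    if "features" in stages:
        bundle["features"] = extract_features(dataset, alff_band=cfg.alff_band,
                                              smooth_fwhm_mm=cfg.smooth_fwhm_mm,
                                              nfft=cfg.nfft)
    if "screen" in stages:
        covars = dataset.participants[["age", "sex"]]
        bundle["screens"] = screen_features(
            bundle["features"], bundle["li"]["li"].to_numpy(), covars,
            n_perm=cfg.n_perm, voxel_p=cfg.voxel_p, min_cluster=cfg.min_cluster,
            alpha_fdr=cfg.alpha_fdr, edge_p=cfg.edge_p, mask=dataset.mask,
            seed=cfg.seed)
    if "predict" in stages:
        bundle["prediction"] = run_prediction(
            bundle["features"], bundle["screens"], bundle["li"]["li"].to_numpy(),
            models=cfg.models, seed=cfg.seed, n_trees=cfg.n_trees)
    if outdir is not None:
        _write_outputs(bundle, dataset, Path(outdir))
    return bundle


def _write_outputs(bundle: dict, dataset, outdir: Path) -> None:
    from .io import write_volume

    outdir.mkdir(parents=True, exist_ok=True)
    if "li" in bundle:
        bundle["li"].to_csv(outdir / "li.tsv", sep="\t", index=False)
    if "features" in bundle:
        eeg = bundle["features"]["eeg"].copy()
        eeg.columns = ["|".join(map(str, c)) for c in eeg.columns]
        eeg.to_csv(outdir / "eeg_features.tsv", sep="\t")
    if "screens" in bundle:
        for key in ("gmv", "wmv", "alff"):
            pos, neg = bundle["screens"][key]
            write_volume(pos.t_map, dataset.affine, outdir / f"{key}_tmap.nii.gz")
            write_volume(pos.p_map, dataset.affine, outdir / f"{key}_pmap.nii.gz")
    report: dict = {"version": __version__, "seed": bundle["config"].seed}
    if "li" in bundle:
        report["li_normality_p"] = bundle["li_normality_p"]
    if "prediction" in bundle:
        report["prediction"] = {
            m: {"mae": r.mae, "pearson_r": r.r,
                "steiger_vs_multimodal": {k: list(v) for k, v in r.comparisons.items()},
                "predictions": {k: v.tolist() for k, v in r.predictions.items()}}
            for m, r in bundle["prediction"]["reports"].items()}
        report["degenerate_sets"] = [s.name for s in
                                     bundle["prediction"]["feature_sets"] if s.degenerate]
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
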