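"""File formats: EEG matrices, NIfTI volumes, TSV tables, JSON reports.

EEG recordings are stored as ``.csv``/``.csv.gz`` matrices (one row per
channel, no header) with a ``*_channels.tsv`` sidecar carrying the channel
names and sampling rate; EDF files are read through MNE when it is
available.  Volumes are NIfTI-1 with the TR in ``pixdim[4]``.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fmri_features import VolumeSeries

__all__ = [
    "read_eeg",
    "write_eeg_csv",
    "read_volume",
    "write_volume",
    "save_cohort",
    "load_cohort",
]


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suf in (".csv.gz", ".csv"):
        if stem.endswith(suf):
            return path.with_name(stem[: -len(suf)] + "_channels.tsv")
    raise ValueError(f"not a CSV EEG file: {path}")


def write_eeg_csv(signal: np.ndarray, names: list[str], fs: float,
                  path: str | Path) -> Path:
    """Write an (n_channels, n_samples) EEG matrix plus its sidecar."""
    path = Path(path)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if signal.shape[0] != len(names):
        raise ValueError("number of names must match number of channels")
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        np.savetxt(fh, signal, delimiter=",", fmt="%.17g")  # round-trip exact
    sidecar = _sidecar_path(path)
    pd.DataFrame({"name": names, "sfreq": fs}).to_csv(sidecar, sep="\t", index=False)
    return path


def read_eeg(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EEG recording; returns ``(signal, channel_names, fs)``.

    Supports ``.edf`` (via MNE) and ``.csv``/``.csv.gz`` matrices with a
    ``*_channels.tsv`` sidecar (columns ``name`` and ``sfreq``).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, EDF only
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"channel sidecar {sidecar.name} not found next to {path.name}")
    meta = pd.read_csv(sidecar, sep="\t")
    if "name" not in meta.columns:
        raise ValueError("sidecar must have a 'name' column")
    if "sfreq" not in meta.columns or meta["sfreq"].isna().all():
        raise ValueError("sampling rate missing from channel sidecar")
    names = meta["name"].astype(str).tolist()
    if len(set(names)) != len(names):
        raise ValueError("duplicate channel names in sidecar")
    fs = float(meta["sfreq"].iloc[0])
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        sig = np.loadtxt(fh, delimiter=",", ndmin=2)
    if sig.shape[0] != len(names):
        raise ValueError(
            f"matrix has {sig.shape[0]} rows but sidecar lists {len(names)} channels")
    return sig, names, fs


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path,
                 tr: float | None = None) -> Path:
    """Write a 3D/4D array as NIfTI-1; TR stored in pixdim[4] for 4D data."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    if tr is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = tr
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return Path(path)


def read_volume(path: str | Path, mask_path: str | Path | None = None,
                require_4d: bool = True) -> VolumeSeries | tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; 4D files return a :class:`VolumeSeries`.

    The TR is taken from ``pixdim[4]``.  Without ``mask_path`` the mask is
    all voxels with non-zero temporal variance.  3D files (``require_4d``
    False) return ``(data, affine)``.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if require_4d:
            raise ValueError(f"{path}: expected a 4D series, got a 3D volume")
        return data, img.affine
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 3D or 4D data, got {data.ndim}D")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: non-positive TR in pixdim[4]")
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match data spatial shape")
    else:
        mask = data.std(axis=3) > 0
    return VolumeSeries(data=data, tr=tr, mask=mask, affine=img.affine)


# ---------------------------------------------------------------------------
# cohort directory layout

def save_cohort(dataset, ground_truth=None, outdir: str | Path = ".") -> Path:
    """Write a cohort to a directory tree of text/NIfTI files.

    Layout: ``participants.tsv``, ``rois.tsv``, ``mask.nii.gz``,
    ``ground_truth.json`` (if given), and per participant
    ``sub-XXX/{nfb/ses-S_run-RR.csv.gz, eeg/<condition>.csv.gz,
    func/bold.nii.gz, anat/{gmv,wmv}.nii.gz}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    dataset.roi_table.to_csv(outdir / "rois.tsv", sep="\t", index=False)
    write_volume(dataset.mask.astype(np.float64), dataset.affine,
                 outdir / "mask.nii.gz")
    cfg = dataset.config
    meta = {"n_participants": cfg.n_participants, "n_sessions": cfg.n_sessions,
            "runs_per_session": cfg.runs_per_session, "fs_nfb": cfg.fs_nfb,
            "tr_s": cfg.tr_s, "seed": cfg.seed}
    (outdir / "cohort.json").write_text(json.dumps(meta, indent=2))
    if ground_truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(ground_truth.to_dict(), indent=2))
    for p, pid in enumerate(dataset.participants["id"]):
        pdir = outdir / pid
        (pdir / "nfb").mkdir(parents=True, exist_ok=True)
        (pdir / "eeg").mkdir(exist_ok=True)
        (pdir / "func").mkdir(exist_ok=True)
        (pdir / "anat").mkdir(exist_ok=True)
        for s, runs in enumerate(dataset.nfb_runs[p]):
            for r, sig in enumerate(runs):
                write_eeg_csv(sig[None, :], ["NFB"], cfg.fs_nfb,
                              pdir / "nfb" / f"ses-{s + 1}_run-{r:02d}.csv.gz")
        for cond, (sig, names, fs) in dataset.resting_eeg[p].items():
            write_eeg_csv(sig, names, fs, pdir / "eeg" / f"{cond}.csv.gz")
        vol = dataset.fmri[p]
        write_volume(vol.data, vol.affine, pdir / "func" / "bold.nii.gz", tr=vol.tr)
        write_volume(dataset.gmv[p], dataset.affine, pdir / "anat" / "gmv.nii.gz")
        write_volume(dataset.wmv[p], dataset.affine, pdir / "anat" / "wmv.nii.gz")
    return outdir


def load_cohort(indir: str | Path):
    """Load a cohort directory written by :func:`save_cohort`."""
    from .synthgen import CohortConfig, CohortDataset

    indir = Path(indir)
    meta = json.loads((indir / "cohort.json").read_text())
    participants = pd.read_csv(indir / "participants.tsv", sep="\t")
    roi_table = pd.read_csv(indir / "rois.tsv", sep="\t")
    mask, affine = read_volume(indir / "mask.nii.gz", require_4d=False)
    mask = mask > 0
    nfb_runs, resting, fmri, gmv, wmv = [], [], [], [], []
    for pid in participants["id"]:
        pdir = indir / pid
        sessions = []
        for s in range(meta["n_sessions"]):
            runs = []
            for r in range(meta["runs_per_session"]):
                sig, _, _ = read_eeg(pdir / "nfb" / f"ses-{s + 1}_run-{r:02d}.csv.gz")
                runs.append(sig[0])
            sessions.append(runs)
        nfb_runs.append(sessions)
        conds = {}
        for f in sorted((pdir / "eeg").glob("*.csv.gz")):
            cond = f.name[: -len(".csv.gz")]
            conds[cond] = read_eeg(f)
        resting.append(conds)
        vol = read_volume(pdir / "func" / "bold.nii.gz")
        vol.mask = mask
        fmri.append(vol)
        gmv.append(read_volume(pdir / "anat" / "gmv.nii.gz", require_4d=False)[0])
        wmv.append(read_volume(pdir / "anat" / "wmv.nii.gz", require_4d=False)[0])
    config = CohortConfig(n_participants=len(participants),
                          n_sessions=meta["n_sessions"],
                          runs_per_session=meta["runs_per_session"],
                          fs_nfb=meta["fs_nfb"], tr_s=meta["tr_s"],
                          grid_shape=tuple(mask.shape), seed=meta.get("seed", 0))
    return CohortDataset(config=config, participants=participants,
                         nfb_runs=nfb_runs, resting_eeg=resting, fmri=fmri,
                         gmv=gmv, wmv=wmv, mask=mask, roi_table=roi_table,
                         affine=affine)
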