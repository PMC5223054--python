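"""Storage: versioned HDF5 cohort containers, event tables, NIfTI masks.

Layout (version 1) of a cohort container::

    cohort.h5
      attrs: version, master_seed
      /sub-XX/data      float32 (trials, channels, samples)
      /sub-XX/times     float64 (samples,)
      /sub-XX/labels    utf-8 strings (trials,)
      /sub-XX attrs: srate
    manifest.json       ground-truth effects, trial counts, config echo
    sub-XX_events.tsv   trial, condition, memory

ROI masks are accepted either as NIfTI volumes (any affine; grid
coordinates in meters are converted to mm and mapped through the inverse
affine) or as plain-text grid-index lists, everywhere a ROI is named.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import Cohort, EpochedEEG, SensorSpace, SourceModel, make_sensor_space, build_leadfield

__all__ = ["save_cohort", "load_cohort", "write_events_tsv", "read_events_tsv",
           "roi_mask_from_nifti", "roi_mask_to_nifti", "read_roi_indices",
           "write_roi_indices", "source_map_to_nifti", "read_raw_brainvision",
           "read_raw_edf"]

FORMAT_VERSION = 1


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write subjects, events and the manifest; returns the HDF5 path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    h5path = directory / "cohort.h5"
    with h5py.File(h5path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["master_seed"] = cohort.manifest.get("master_seed", -1)
        for subj in cohort.subjects:
            g = f.create_group(subj.subject_id)
            g.create_dataset("data", data=subj.data, compression="gzip",
                             compression_opts=1)
            g.create_dataset("times", data=subj.times)
            g.create_dataset("labels",
                             data=np.array(subj.cell_labels, dtype=object),
                             dtype=h5py.string_dtype())
            g.attrs["srate"] = subj.srate
    (directory / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
    for subj in cohort.subjects:
        write_events_tsv(subj, directory / f"{subj.subject_id}_events.tsv")
    return h5path


def load_cohort(directory: str | Path, with_model: bool = True) -> Cohort:
    """Reload a cohort container written by :func:`save_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    subjects = []
    with h5py.File(directory / "cohort.h5", "r") as f:
        if int(f.attrs["version"]) != FORMAT_VERSION:
            raise ValueError("unsupported cohort container version")
        for sid in sorted(f.keys()):
            g = f[sid]
            labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                               for s in g["labels"][()]])
            subjects.append(EpochedEEG(sid, g["data"][()], float(g.attrs["srate"]),
                                       g["times"][()], labels))
    sensors = model = None
    if with_model:
        cfg = manifest.get("config", {})
        sensors = make_sensor_space(cfg.get("n_channels", 63))
        model = build_leadfield(sensors, cfg.get("grid_spacing", 0.012),
                                cfg.get("head_radius", 0.09))
    return Cohort(subjects, sensors, model, manifest, {})


def write_events_tsv(subj: EpochedEEG, path: str | Path) -> None:
    cond = [c.split("/")[0] for c in subj.cell_labels]
    mem = [c.split("/")[1] for c in subj.cell_labels]
    pd.DataFrame({"trial": np.arange(1, subj.n_trials + 1),
                  "condition": cond, "memory": mem}).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return np.array([f"{c}/{m}" for c, m in zip(df["condition"], df["memory"])])


# ---------------------------------------------------------------------------
# ROI masks (NIfTI and plain text)
# ---------------------------------------------------------------------------


def roi_mask_from_nifti(path: str | Path, grid_m: np.ndarray,
                        threshold: float = 0.5) -> np.ndarray:
    """Sample a NIfTI mask volume at grid coordinates (meters -> mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    inv = np.linalg.inv(img.affine)
    mm = np.c_[grid_m * 1000.0, np.ones(len(grid_m))]
    vox = (mm @ inv.T)[:, :3]
    ijk = np.round(vox).astype(int)
    ok = np.all((ijk >= 0) & (ijk < vol.shape[:3]), axis=1)
    out = np.zeros(len(grid_m), dtype=bool)
    out[ok] = vol[tuple(ijk[ok].T)] > threshold
    return out


def roi_mask_to_nifti(mask: np.ndarray, model: SourceModel, path: str | Path) -> None:
    """Rasterize a grid mask to a NIfTI volume on the source grid lattice."""
    source_map_to_nifti(mask.astype(np.float32), model, path)


def source_map_to_nifti(values: np.ndarray, model: SourceModel,
                        path: str | Path) -> None:
    """Write per-grid-point values as a NIfTI volume (grid-resolution voxels)."""
    import nibabel as nib

    step = model.spacing * 1000.0  # mm
    mm = model.grid * 1000.0
    origin = mm.min(axis=0)
    ijk = np.round((mm - origin) / step).astype(int)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape, dtype=np.float32)
    vol[tuple(ijk.T)] = values
    affine = np.diag([step, step, step, 1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_roi_indices(mask: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("\n".join(str(i) for i in np.flatnonzero(mask)) + "\n")


def read_roi_indices(path: str | Path, n_grid: int) -> np.ndarray:
    idx = [int(line) for line in Path(path).read_text().split()]
    mask = np.zeros(n_grid, dtype=bool)
    mask[idx] = True
    return mask


# ---------------------------------------------------------------------------
# Optional raw-EEG readers (convenience only; require the `readers` extra)
# ---------------------------------------------------------------------------


def _epochs_from_raw(raw, onsets_s, labels, srate, epoch=(-2.5, 3.5),
                     subject_id="sub-raw") -> EpochedEEG:
    data = raw.get_data() * 1e6  # volts -> µV
    n0 = int(round(epoch[0] * srate))
    n1 = int(round(epoch[1] * srate))
    times = np.arange(n0, n1 + 1) / srate
    trials = []
    for onset in onsets_s:
        c = int(round(onset * srate))
        trials.append(data[:, c + n0:c + n1 + 1])
    return EpochedEEG(subject_id, np.stack(trials).astype(np.float32),
                      srate, times, np.asarray(labels))


def read_raw_brainvision(vhdr_path: str | Path, onsets_s, labels,
                         epoch=(-2.5, 3.5)) -> EpochedEEG:
    """Epoch a BrainVision recording around the given onsets (seconds)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    return _epochs_from_raw(raw, onsets_s, labels, raw.info["sfreq"], epoch)


def read_raw_edf(edf_path: str | Path, onsets_s, labels,
                 epoch=(-2.5, 3.5)) -> EpochedEEG:
    """Epoch an EDF recording around the given onsets (seconds)."""
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    return _epochs_from_raw(raw, onsets_s, labels, raw.info["sfreq"], epoch)
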