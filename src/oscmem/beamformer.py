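"""LCMV beamforming: spatial filters, virtual electrodes, source power maps.

The linearly constrained minimum-variance beamformer passes activity from
one source location with unit gain while minimizing output variance from
everywhere else: W(r) = (L' C⁻¹ L)⁻¹ L' C⁻¹, with C the sensor covariance
pooled over the whole length of all trials (diagonally loaded by a small
regularization fraction) and L the 3-column leadfield at r.  A scalar
filter per grid point follows by selecting the orientation of maximal
output power.  Virtual electrodes average the scalar source time courses
over the grid points of a region of interest; source power maps project
band-limited data through the filters and z-score the resulting envelope
over time, mirroring the sensor-level normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import EpochedEEG, SourceModel

__all__ = ["SpatialFilterSet", "VirtualElectrode", "sensor_covariance",
           "lcmv_filters", "virtual_electrode", "source_power_map",
           "bandpass_data", "localize_peak"]


@dataclass
class SpatialFilterSet:
    """Per-grid-point LCMV weights (scalar, orientation-selected)."""

    weights: np.ndarray  # (n_grid, n_ch): channels -> source amplitude
    orientations: np.ndarray  # (n_grid, 3) unit dipole orientation retained
    vector_weights: np.ndarray | None  # (n_grid, 3, n_ch) full 3D filters
    regularization: float
    cov_condition: float

    @property
    def n_points(self) -> int:
        return self.weights.shape[0]


@dataclass
class VirtualElectrode:
    """ROI-averaged source time courses with the trial structure of the EEG."""

    roi: str
    data: np.ndarray  # (n_trials, 1, n_samples) source units
    srate: float
    times: np.ndarray
    cell_labels: np.ndarray
    grid_points: np.ndarray  # indices averaged

    def as_epochs(self) -> EpochedEEG:
        return EpochedEEG(f"ve-{self.roi}", self.data.astype(np.float32),
                          self.srate, self.times, self.cell_labels)


def _average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=-2, keepdims=True)


def sensor_covariance(epochs: EpochedEEG) -> np.ndarray:
    """Channel covariance pooled over the whole length of all trials.

    Data are average-referenced and channel means removed before pooling;
    the result is symmetric positive semidefinite (rank <= n_ch - 1 after
    average referencing, which diagonal loading in the filter step absorbs).
    """
    data = _average_reference(np.asarray(epochs.data, dtype=float))
    n_trials, n_ch, n_samp = data.shape
    if n_trials * n_samp < 10 * n_ch:
        raise ValueError("too few samples for a stable covariance estimate")
    x = data.transpose(1, 0, 2).reshape(n_ch, -1)
    x = x - x.mean(axis=1, keepdims=True)
    cov = x @ x.T / (x.shape[1] - 1)
    return 0.5 * (cov + cov.T)


def lcmv_filters(model: SourceModel, cov: np.ndarray,
                 lam: float = 0.05) -> SpatialFilterSet:
    """LCMV spatial filters for every grid point.

    ``lam`` is the diagonal-loading fraction: C_reg = C + lam * mean(diag C) * I.
    The scalar orientation at each point is the eigenvector of the
    smallest eigenvalue of L' C_reg⁻¹ L (the direction of maximal output
    power under the unit-gain constraint).
    """
    cov = np.asarray(cov, dtype=float)
    n_ch = cov.shape[0]
    loading = lam * float(np.trace(cov)) / n_ch
    c_reg = cov + loading * np.eye(n_ch)
    evals = np.linalg.eigvalsh(c_reg)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError("regularized covariance not positive definite")
    c_inv = np.linalg.inv(c_reg)

    n_grid = model.n_points
    weights = np.empty((n_grid, n_ch))
    vector_weights = np.empty((n_grid, 3, n_ch))
    orientations = np.empty((n_grid, 3))
    for i in range(n_grid):
        L = model.leadfield[i]  # (n_ch, 3)
        A = c_inv @ L
        M = L.T @ A  # (3, 3)
        if np.linalg.matrix_rank(M, tol=1e-12 * np.abs(M).max()) < 3:
            raise np.linalg.LinAlgError(
                f"rank-deficient leadfield at grid point {i}")
        W = np.linalg.solve(M, A.T)  # (3, n_ch); W @ L = I
        vector_weights[i] = W
        w_evals, w_evecs = np.linalg.eigh(M)
        ori = w_evecs[:, 0]  # smallest eigenvalue -> max output power
        # deterministic sign: largest-magnitude component positive
        ori = ori * np.sign(ori[np.argmax(np.abs(ori))])
        orientations[i] = ori
        l_s = L @ ori
        a_s = c_inv @ l_s
        weights[i] = a_s / (l_s @ a_s)
    return SpatialFilterSet(weights, orientations, vector_weights, lam,
                            float(np.linalg.cond(c_reg)))


def _align_roi_orientations(model: SourceModel, filters: SpatialFilterSet,
                            idx: np.ndarray) -> np.ndarray:
    """Sign-align orientations inside a ROI so averaging does not cancel."""
    signs = np.ones(idx.size)
    ref = filters.orientations[idx[0]]
    for k, i in enumerate(idx[1:], start=1):
        if filters.orientations[i] @ ref < 0:
            signs[k] = -1.0
    return signs


def virtual_electrode(filters: SpatialFilterSet, epochs: EpochedEEG,
                      model: SourceModel, roi: str | np.ndarray) -> VirtualElectrode:
    """ROI-averaged scalar source time course per trial.

    ``roi`` is a ROI name from the source model, or an explicit boolean
    mask / index array over grid points.  Orientations are sign-aligned
    within the ROI before averaging.
    """
    if isinstance(roi, str):
        idx = model.resolve(roi)
        name = roi
    else:
        roi = np.asarray(roi)
        idx = np.flatnonzero(roi) if roi.dtype == bool else roi.astype(int)
        name = "custom"
    if idx.size == 0:
        raise KeyError("empty ROI")
    signs = _align_roi_orientations(model, filters, idx)
    w = (signs[:, None] * filters.weights[idx]).mean(axis=0)  # (n_ch,)
    data = _average_reference(np.asarray(epochs.data, dtype=float))
    tc = np.einsum("c,tcs->ts", w, data)[:, None, :]
    return VirtualElectrode(name, tc, epochs.srate, epochs.times,
                            epochs.cell_labels, idx)


def bandpass_data(data: np.ndarray, srate: float, band: tuple[float, float],
                  transition: float = 0.5) -> np.ndarray:
    """Zero-phase FFT band-pass with raised-cosine transitions."""
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    lo, hi = band
    gain = np.zeros_like(freqs)
    gain[(freqs >= lo) & (freqs <= hi)] = 1.0
    for f0, sgn in ((lo, -1.0), (hi, 1.0)):
        edge = (freqs - f0) * sgn
        ramp = (edge > 0) & (edge < transition)
        gain[ramp] = 0.5 * (1.0 + np.cos(np.pi * edge[ramp] / transition))
    return np.fft.irfft(np.fft.rfft(data, axis=-1) * gain, n=n, axis=-1)


def source_power_map(
    filters: SpatialFilterSet,
    epochs: EpochedEEG,
    band: tuple[float, float],
    window: tuple[float, float],
) -> dict[str, np.ndarray]:
    """Per-cell z-scored band power per grid point.

    Sensor data are band-passed, projected through the scalar filters, and
    the squared amplitude envelope (via the analytic signal) is z-scored
    per grid point across all trials and time points - the source-level
    analogue of the sensor z-transform.  The result per design cell is the
    mean z power over that cell's trials within ``window``.
    """
    from scipy.signal import hilbert

    data = _average_reference(np.asarray(epochs.data, dtype=float))
    filt = bandpass_data(data, epochs.srate, band)
    src = np.einsum("gc,tcs->tgs", filters.weights, filt)
    power = np.abs(hilbert(src, axis=-1)) ** 2
    tsel = (epochs.times >= window[0] - 1e-9) & (epochs.times <= window[1] + 1e-9)
    m = power.mean(axis=(0, 2), keepdims=True)
    sd = power.std(axis=(0, 2), ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate source power distribution")
    z = (power - m) / sd
    out = {}
    for cell in np.unique(epochs.cell_labels):
        sel = epochs.cell_labels == cell
        out[str(cell)] = z[sel][:, :, tsel].mean(axis=(0, 2))  # (n_grid,)
    return out


def localize_peak(filters: SpatialFilterSet, cov: np.ndarray) -> tuple[int, np.ndarray]:
    """Grid argmax of noise-normalized output power (neural activity index).

    Output power w' C w is normalized by the unit-noise projection w' w,
    correcting the beamformer's depth bias.
    """
    w = filters.weights
    power = np.einsum("gc,cd,gd->g", w, cov, w)
    noise = np.einsum("gc,gc->g", w, w)
    nai = power / noise
    return int(np.argmax(nai)), nai
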