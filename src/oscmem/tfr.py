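"""Morlet wavelet time-frequency power with study-specific normalization.

The decomposition convolves each trial with complex Morlet wavelets of a
fixed cycle count (default 5; Gaussian envelope SD ``n_cycles / (2*pi*f)``)
and squares the magnitude.  Power is then z-transformed per channel and
frequency against the mean and SD pooled over *all* trials and valid time
points, averaged per design cell, and smoothed with a separable Gaussian
kernel (default FWHM 200 ms x 2 Hz) whose edge taps are renormalized so a
constant map passes through unchanged.

Frames too close to an epoch edge for the wavelet at a given frequency are
flagged invalid rather than silently attenuated; invalid bins are excluded
from the pooled z-scoring moments and downstream cluster statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import fft as sfft
from scipy import signal

from .cohort import CELLS, EpochedEEG

__all__ = ["TimeFrequencyMap", "morlet_power", "zscore_power", "average_cells",
           "smooth_tf", "crop_map", "morlet_kernel"]

_STATES = ("raw_power", "zscored", "cell_average", "smoothed")


@dataclass
class TimeFrequencyMap:
    """Power over (trials x) space x frequency x time with axis metadata.

    ``values`` has shape (n_trials, n_space, n_freq, n_time) for per-trial
    states and (n_space, n_freq, n_time) once averaged.  ``valid`` marks
    (freq, time) bins whose wavelet estimate is uncontaminated by epoch
    edges.  ``state`` tracks the processing stage and may only advance
    raw_power -> zscored -> cell_average -> smoothed.
    """

    values: np.ndarray
    freqs: np.ndarray  # (n_freq,) Hz, strictly increasing
    times: np.ndarray  # (n_time,) s, strictly increasing
    valid: np.ndarray  # (n_freq, n_time) bool
    state: str
    space: tuple[str, ...]  # channel / voxel names
    n_trials_used: dict[str, int] | None = None  # set by average_cells

    def __post_init__(self):
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("axes must be strictly increasing")

    def _advance(self, new_state: str, values: np.ndarray, **kw) -> "TimeFrequencyMap":
        if _STATES.index(new_state) <= _STATES.index(self.state):
            raise ValueError(f"cannot go from {self.state} to {new_state}")
        return replace(self, values=values, state=new_state, **kw)


def morlet_kernel(freq: float, srate: float, n_cycles: float = 5.0,
                  truncate: float = 3.0) -> np.ndarray:
    """Complex Morlet kernel at ``freq`` Hz, truncated at ``truncate`` sigma.

    Scaled so that convolving a unit-amplitude sinusoid at ``freq`` yields
    an analytic signal of magnitude ~1 (power ~1).
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(math.ceil(truncate * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    env = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = env * np.exp(2j * np.pi * freq * t)
    return (2.0 / env.sum()) * kernel


def _decimate(data: np.ndarray, srate: float, target: float) -> tuple[np.ndarray, float]:
    """Polyphase resampling to ``target`` Hz (exact rational ratio)."""
    if target >= srate:
        return data, srate
    frac = Fraction(target / srate).limit_denominator(1000)
    out = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return out, srate * frac.numerator / frac.denominator

def morlet_power(
    epochs: EpochedEEG,
    freqs,
    n_cycles: float = 5.0,
    frame_rate: float = 50.0,
    work_srate: float | None = 100.0,
    edge_sigmas: float = 2.0,
    space_names: tuple[str, ...] | None = None,
) -> TimeFrequencyMap:
    """Per-trial wavelet power, sampled on a coarse time-frame grid.

    The signal is first resampled to ``work_srate`` (must keep all analysis
    frequencies below Nyquist; power envelopes below 30 Hz have bandwidth
    f / n_cycles so 100 Hz loses nothing), convolved per frequency via FFT,
    and the squared magnitude is read out at ``frame_rate`` frames aligned
    to t = 0.  Frames within ``edge_sigmas`` wavelet SDs of an epoch edge
    are flagged invalid.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if freqs.max() >= epochs.srate / 2:
        raise ValueError("max frequency above Nyquist")
    data = np.asarray(epochs.data, dtype=np.float32)
    srate = epochs.srate
    if work_srate is not None and work_srate < srate:
        if freqs.max() >= work_srate / 2:
            raise ValueError("max frequency above working-rate Nyquist")
        data, srate = _decimate(data, srate, work_srate)
        data = data.astype(np.float32)
    n_trials, n_ch, n_samp = data.shape
    t0 = float(epochs.times[0])
    t_end = t0 + (n_samp - 1) / srate
    # longest kernel governs the FFT size
    max_half = int(math.ceil(3.0 * n_cycles / (2.0 * np.pi * freqs.min()) * srate))
    if 2 * max_half + 1 > n_samp:
        raise ValueError("epoch shorter than the widest wavelet")
    nfft = int(2 ** math.ceil(math.log2(n_samp + 2 * max_half + 1)))
    spec = sfft.fft(data.reshape(-1, n_samp).astype(np.complex64), n=nfft, axis=-1)

    # frame grid: multiples of 1/frame_rate inside the epoch
    k0 = math.ceil(round(t0 * frame_rate, 9))
    k1 = math.floor(round(t_end * frame_rate, 9))
    frame_times = np.arange(k0, k1 + 1) / frame_rate
    frame_idx = np.round((frame_times - t0) * srate).astype(int)

    power = np.empty((n_trials, n_ch, freqs.size, frame_times.size), dtype=np.float32)
    valid = np.empty((freqs.size, frame_times.size), dtype=bool)
    for fi, f in enumerate(freqs):
        kern = morlet_kernel(f, srate, n_cycles)
        half = (kern.size - 1) // 2
        kspec = sfft.fft(kern.astype(np.complex64), n=nfft)
        conv = sfft.ifft(spec * kspec, axis=-1)[:, half:half + n_samp]
        p = np.abs(conv[:, frame_idx]) ** 2
        power[:, :, fi, :] = p.reshape(n_trials, n_ch, -1)
        sigma_t = n_cycles / (2.0 * np.pi * f)
        margin = edge_sigmas * sigma_t
        valid[fi] = (frame_times - t0 >= margin) & (t_end - frame_times >= margin)

    if space_names is None:
        space_names = tuple(f"ch{i + 1:02d}" for i in range(n_ch))
    return TimeFrequencyMap(power, freqs, frame_times, valid, "raw_power",
                            space_names)


def zscore_power(tf: TimeFrequencyMap) -> TimeFrequencyMap:
    """z-transform per channel x frequency, pooling trials and valid times."""
    if tf.state != "raw_power":
        raise ValueError("zscore_power expects a raw per-trial map")
    vals = tf.values  # (T, C, F, time)
    if vals.ndim != 4:
        raise ValueError("expected per-trial values (trials, space, freq, time)")
    n_valid = tf.valid.sum(axis=-1)  # per freq
    if np.any(n_valid * vals.shape[0] < 2):
        raise ValueError("need >=2 pooled valid samples per channel x frequency")
    m = np.empty(vals.shape[1:3])
    sd = np.empty(vals.shape[1:3])
    for fi in range(vals.shape[2]):
        sel = vals[:, :, fi, tf.valid[fi]].astype(np.float64)  # (T, C, n_valid)
        m[:, fi] = sel.mean(axis=(0, 2))
        sd[:, fi] = sel.std(axis=(0, 2), ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate distribution: zero SD in some channel x frequency")
    z = (vals - m[None, :, :, None]) / sd[None, :, :, None]
    return tf._advance("zscored", z)


def average_cells(tf: TimeFrequencyMap, labels) -> dict[str, TimeFrequencyMap]:
    """First-level averages: mean over trials within each design cell."""
    if tf.state != "zscored":
        raise ValueError("average_cells expects z-scored per-trial maps")
    labels = np.asarray(labels)
    if labels.size != tf.values.shape[0]:
        raise ValueError("one label per trial required")
    out = {}
    for cell in CELLS:
        sel = labels == cell
        if not sel.any():
            raise ValueError(f"empty design cell {cell!r}")
        out[cell] = tf._advance(
            "cell_average", tf.values[sel].mean(axis=0),
            n_trials_used={cell: int(sel.sum())})
    return out


def _gauss_kernel(fwhm_bins: float, truncate: float = 4.0) -> np.ndarray:
    sigma = fwhm_bins / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    half = max(1, int(math.ceil(truncate * sigma)))
    x = np.arange(-half, half + 1)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _smooth_axis(values: np.ndarray, weights: np.ndarray, kernel: np.ndarray,
                 axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (mask-aware, edge-renormalized) convolution along one axis."""
    num = signal.convolve(values * weights,
                          _shape_kernel(kernel, values.ndim, axis), mode="same")
    den = signal.convolve(weights, _shape_kernel(kernel, weights.ndim, axis),
                          mode="same")
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out, den


def _shape_kernel(kernel: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = kernel.size
    return kernel.reshape(shape)


def smooth_tf(tf: TimeFrequencyMap, fwhm_time: float = 0.2,
              fwhm_freq: float = 2.0) -> TimeFrequencyMap:
    """Separable Gaussian smoothing over time and frequency.

    Each axis uses a truncated Gaussian renormalized by the smoothed
    validity mask, so constants are preserved exactly and invalid bins do
    not bleed into valid ones.
    """
    if tf.state != "cell_average":
        raise ValueError("smooth_tf expects a cell-average map")
    if fwhm_time <= 0 or fwhm_freq <= 0:
        raise ValueError("kernel FWHMs must be positive")
    dt = float(tf.times[1] - tf.times[0]) if tf.times.size > 1 else None
    df = float(tf.freqs[1] - tf.freqs[0]) if tf.freqs.size > 1 else None
    vals = tf.values.astype(float)
    w = tf.valid.astype(float)[None, :, :] * np.ones_like(vals)
    for fwhm, delta, axis, span in (
        (fwhm_freq, df, -2, None if df is None else df * (tf.freqs.size - 1)),
        (fwhm_time, dt, -1, None if dt is None else dt * (tf.times.size - 1)),
    ):
        if delta is None:
            continue
        if fwhm > span + delta:
            raise ValueError("smoothing kernel wider than the axis span")
        kernel = _gauss_kernel(fwhm / delta)
        vals, wsm = _smooth_axis(vals, w, kernel, axis)
        w = (wsm > 0).astype(float)
    out = np.where(tf.valid[None, :, :], vals, tf.values)
    return tf._advance("smoothed", out)


def crop_map(tf: TimeFrequencyMap, tmin: float | None = None,
             tmax: float | None = None, fmin: float | None = None,
             fmax: float | None = None) -> TimeFrequencyMap:
    """Restrict a map to an analysis window / frequency band (any state)."""
    tsel = np.ones(tf.times.size, dtype=bool)
    fsel = np.ones(tf.freqs.size, dtype=bool)
    if tmin is not None:
        tsel &= tf.times >= tmin - 1e-9
    if tmax is not None:
        tsel &= tf.times <= tmax + 1e-9
    if fmin is not None:
        fsel &= tf.freqs >= fmin - 1e-9
    if fmax is not None:
        fsel &= tf.freqs <= fmax + 1e-9
    vals = tf.values[..., fsel, :][..., tsel]
    return replace(tf, values=vals, freqs=tf.freqs[fsel], times=tf.times[tsel],
                   valid=tf.valid[np.ix_(fsel, tsel)])
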