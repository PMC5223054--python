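"""Sliding-window cluster statistic over time-frequency tiles.

An exploratory screen for effects outside a predefined frequency band: a
small electrode-wise cluster permutation test is run for every 300 ms x
1 Hz window, sliding in 100 ms and 0.5 Hz steps across the analysis
window and band.  Each tile stores the best cluster p value per polarity.
The tile-level tests are deliberately uncorrected across tiles; instead a
*coherence filter* keeps only contiguous regions of significant tiles
whose extent reaches a minimum span (default 3 time x 4 frequency bins,
i.e. 500 ms and 2 Hz at the default step sizes), discarding isolated
significant tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cluster import permutation_test

__all__ = ["SlidingGeometry", "SlidingPMap", "tile_seed", "sliding_map",
           "coherence_filter"]


@dataclass(frozen=True)
class SlidingGeometry:
    """Window and step sizes of the sliding statistic (seconds / Hz)."""

    win_time: float = 0.3
    win_freq: float = 1.0
    step_time: float = 0.1
    step_freq: float = 0.5

    def tile_axes(self, times: np.ndarray, freqs: np.ndarray):
        """Window start positions fully contained in the axes.

        Returns (time_starts, freq_starts); the number of time positions
        for a span T is floor((T - win) / step) + 1.
        """
        t0, t1 = float(times[0]), float(times[-1])
        f0, f1 = float(freqs[0]), float(freqs[-1])
        nt = int(np.floor((t1 - t0 - self.win_time) / self.step_time + 1e-9)) + 1
        nf = int(np.floor((f1 - f0 - self.win_freq) / self.step_freq + 1e-9)) + 1
        if nt < 1 or nf < 1:
            raise ValueError("analysis window/band smaller than one tile")
        return (t0 + self.step_time * np.arange(nt),
                f0 + self.step_freq * np.arange(nf))


@dataclass
class SlidingPMap:
    """Per-tile best cluster p values, kept separately per polarity.

    Arrays are (n_freq_tiles, n_time_tiles); tiles are identified by their
    window-center coordinates.
    """

    p_pos: np.ndarray
    p_neg: np.ndarray
    time_centers: np.ndarray
    freq_centers: np.ndarray
    geometry: SlidingGeometry


def tile_seed(seed: int, fi: int, ti: int) -> list[int]:
    """Deterministic per-tile seed schedule (shared across analyses)."""
    return [int(seed), int(fi), int(ti)]


def sliding_map(
    subject_maps: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    adjacency,
    geometry: SlidingGeometry = SlidingGeometry(),
    n_perm: int = 500,
    seed: int = 0,
    t_threshold: float | None = None,
    valid: np.ndarray | None = None,
) -> SlidingPMap:
    """Tile-wise electrode-cluster permutation p values.

    ``subject_maps`` is (n_subjects, n_channels, n_freq, n_time) of
    per-subject contrast values; each tile averages the contrast over its
    window (valid bins only) and runs a 1D cluster permutation test across
    electrodes with a per-tile seed from :func:`tile_seed`.
    """
    arr = np.asarray(subject_maps, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected (subjects, channels, freqs, times)")
    times = np.asarray(times, float)
    freqs = np.asarray(freqs, float)
    t_starts, f_starts = geometry.tile_axes(times, freqs)
    ok = np.ones((freqs.size, times.size), bool) if valid is None else np.asarray(valid, bool)

    p_pos = np.ones((f_starts.size, t_starts.size))
    p_neg = np.ones_like(p_pos)
    for fi, f0 in enumerate(f_starts):
        fsel = (freqs >= f0 - 1e-9) & (freqs <= f0 + geometry.win_freq + 1e-9)
        for ti, t0 in enumerate(t_starts):
            tsel = (times >= t0 - 1e-9) & (times <= t0 + geometry.win_time + 1e-9)
            window_ok = ok[np.ix_(fsel, tsel)]
            if not window_ok.any():
                continue
            win = arr[:, :, fsel, :][:, :, :, tsel]
            avg = win[:, :, window_ok].mean(axis=-1)  # (n_subj, n_ch)
            res = permutation_test(
                avg, adjacency, dims=("space",), t_threshold=t_threshold,
                n_perm=n_perm, seed=tile_seed(seed, fi, ti))
            p_pos[fi, ti] = res.min_p("pos")
            p_neg[fi, ti] = res.min_p("neg")
    return SlidingPMap(
        p_pos, p_neg,
        t_starts + geometry.win_time / 2, f_starts + geometry.win_freq / 2,
        geometry)


def coherence_filter(
    pvals: np.ndarray,
    alpha: float = 0.05,
    min_extent: tuple[int, int] = (3, 4),
    mode: str = "extent",
    min_area: int = 8,
) -> np.ndarray:
    """Keep contiguous significant-tile regions of sufficient size.

    ``pvals`` is one polarity's (n_freq_tiles, n_time_tiles) map.
    Components of {p < alpha} under 4-connectivity survive when their
    bounding extent spans at least ``min_extent`` = (time_bins, freq_bins)
    in *both* axes (mode "extent"; the default (3, 4) equals 500 ms and
    2 Hz at 100 ms / 0.5 Hz steps), or when their area reaches
    ``min_area`` tiles (mode "area", the interaction screen's rule).
    Returns the boolean mask of surviving tiles.
    """
    if mode not in ("extent", "area"):
        raise ValueError("mode must be 'extent' or 'area'")
    if min_extent[0] < 1 or min_extent[1] < 1:
        raise ValueError("min_extent must be at least (1, 1)")
    sig = np.asarray(pvals) < alpha
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, _ = ndimage.label(sig, structure=structure)
    keep = np.zeros_like(sig)
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        f_span = sl[0].stop - sl[0].start
        t_span = sl[1].stop - sl[1].start
        if mode == "extent":
            ok = t_span >= min_extent[0] and f_span >= min_extent[1]
        else:
            ok = comp.sum() >= min_area
        if ok:
            keep[sl] |= comp
    return keep
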