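"""Per-subject contrasts for the 2x2 (condition x memory) design.

Each contrast reduces the four first-level cell averages to a single
difference map whose one-sample t test across subjects is equivalent to
the matching effect of a 2x2 repeated-measures ANOVA (t^2 = F):

* ``main_condition``  = mean(spatial cells) - mean(nonspatial cells)
* ``main_memory``     = mean(remembered cells) - mean(forgotten cells)
* ``interaction``     = (spat_rem - spat_forg) - (nonspat_rem - nonspat_forg)
* ``simple_remembered`` = spatial_remembered - nonspatial_remembered

Cell means enter unweighted (not trial-pooled), so unequal trial counts
between cells cannot bias the main effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tfr import TimeFrequencyMap

__all__ = ["CONTRASTS", "ContrastMap", "build_contrast", "group_t"]

_SR, _SF, _NR, _NF = (
    "spatial/remembered", "spatial/forgotten",
    "nonspatial/remembered", "nonspatial/forgotten",
)

#: contrast name -> cell weights
CONTRASTS: dict[str, dict[str, float]] = {
    "main_condition": {_SR: 0.5, _SF: 0.5, _NR: -0.5, _NF: -0.5},
    "main_memory": {_SR: 0.5, _NR: 0.5, _SF: -0.5, _NF: -0.5},
    "interaction": {_SR: 1.0, _SF: -1.0, _NR: -1.0, _NF: 1.0},
    "simple_remembered": {_SR: 1.0, _NR: -1.0},
}


@dataclass
class ContrastMap:
    """One subject's contrast map (same axes as the cell averages)."""

    values: np.ndarray  # (n_space, n_freq, n_time)
    contrast: str
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    space: tuple[str, ...]


def build_contrast(cells: dict[str, TimeFrequencyMap], contrast: str) -> ContrastMap:
    """Combine the four cell averages into a signed difference map."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; have {sorted(CONTRASTS)}")
    weights = CONTRASTS[contrast]
    missing = [c for c in weights if c not in cells]
    if missing:
        raise ValueError(f"missing design cells {missing}")
    ref = next(iter(cells.values()))
    vals = np.zeros_like(ref.values, dtype=float)
    for cell, w in weights.items():
        tf = cells[cell]
        if tf.state not in ("cell_average", "smoothed"):
            raise ValueError("contrasts expect cell-average (optionally smoothed) maps")
        vals += w * tf.values
    return ContrastMap(vals, contrast, ref.freqs, ref.times, ref.valid, ref.space)


def group_t(maps: list[ContrastMap] | np.ndarray) -> tuple[np.ndarray, int]:
    """Bin-wise one-sample t against zero across subjects; df = n - 1.

    Zero-variance bins yield t = 0 (with a warning when their mean is
    nonzero) so degenerate bins cannot destabilize cluster formation.
    """
    if isinstance(maps, (list, tuple)):
        arr = np.stack([m.values for m in maps])
    else:
        arr = np.asarray(maps, dtype=float)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("group t test needs at least 2 subjects")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var & (mean != 0)):
        warnings.warn("zero-variance bins with nonzero mean set to t=0",
                      RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, mean / (sd / np.sqrt(n)))
    return t, n - 1
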