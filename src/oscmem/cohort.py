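"""Synthetic multi-subject EEG cohort with forward-modeled oscillatory effects.

This module generates epoched scalp EEG for a 2x2 memory-encoding design
(encoding condition: spatial vs. nonspatial mnemonic x subsequent memory:
remembered vs. forgotten).  Each subject is a sum of

* spatially correlated 1/f background noise, produced by many randomly
  placed and oriented dipoles inside a homogeneous conducting sphere and
  projected to the scalp through an analytic single-sphere leadfield,
* band-limited oscillatory sources (amplitude-modulated narrowband noise)
  at medial-temporal and posterior-parietal locations whose amplitude is
  scaled by ``1 + amplitude_delta`` inside a time window for the design
  cells an effect targets, and
* a small amount of white sensor noise.

A cohort is reproducible bit-for-bit from a single master seed, and every
injected effect is recorded in a ground-truth manifest so downstream
statistics can be validated against what was actually simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CELLS",
    "SensorSpace",
    "SourceModel",
    "EffectSpec",
    "EpochedEEG",
    "Cohort",
    "CohortConfig",
    "make_sensor_space",
    "build_leadfield",
    "default_rois",
    "default_effects",
    "simulate_subject",
    "sample_trial_counts",
    "generate_cohort",
    "bandpass_noise",
    "pink_noise",
]

#: Design cells, fixed order: condition x memory.
CELLS = (
    "spatial/remembered",
    "spatial/forgotten",
    "nonspatial/remembered",
    "nonspatial/forgotten",
)

#: Cohort-mean trial counts per cell (remembered/forgotten x spatial/nonspatial).
DEFAULT_TRIAL_MEANS = {
    "spatial/remembered": 62.9,
    "spatial/forgotten": 34.7,
    "nonspatial/remembered": 45.7,
    "nonspatial/forgotten": 49.7,
}

CONDUCTIVITY = 0.33  # S/m, brain-tissue scale; leadfield units are arbitrary anyway


# ---------------------------------------------------------------------------
# Sensor space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorSpace:
    """Electrode montage: labels, 3D positions (m) and a neighbour graph."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_ch, 3), head-centered meters
    adjacency: np.ndarray  # (n_ch, n_ch) bool, symmetric, irreflexive
    radius: float  # sphere radius the electrodes sit on

    @property
    def n_channels(self) -> int:
        return len(self.labels)


def make_sensor_space(
    n_channels: int = 63,
    neighbor_distance: float | None = None,
    radius: float = 0.09,
) -> SensorSpace:
    """Quasi-uniform electrode layout on the upper hemisphere.

    Channels are placed on a deterministic Fibonacci spiral covering the
    upper half of a sphere of ``radius`` meters, emulating an equidistant
    montage.  Two channels are neighbours when their Euclidean distance is
    at most ``neighbor_distance``; the default is 1.6x the median
    nearest-neighbour distance, which yields ~5-7 neighbours per channel.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for a meaningful montage")
    k = np.arange(n_channels, dtype=float)
    # z descends from near-vertex to just above the equator
    z = 1.0 - (k + 0.5) / n_channels  # in (0, 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * k
    rho = np.sqrt(1.0 - z**2)
    pos = radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])

    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if neighbor_distance is None:
        offdiag = dist + np.diag(np.full(n_channels, np.inf))
        neighbor_distance = 1.6 * float(np.median(offdiag.min(axis=1)))
    adj = (dist <= neighbor_distance) & ~np.eye(n_channels, dtype=bool)
    labels = tuple(f"E{i + 1:02d}" for i in range(n_channels))
    return SensorSpace(labels, pos, adj, radius)


# ---------------------------------------------------------------------------
# Source model: analytic single-sphere EEG leadfield
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SourceModel:
    """Cubic source grid with per-point gain matrices and named ROI masks."""

    grid: np.ndarray  # (n_grid, 3) meters, head-centered
    spacing: float  # meters
    leadfield: np.ndarray  # (n_grid, n_ch, 3), average-referenced
    roi_masks: dict[str, np.ndarray]  # name -> (n_grid,) bool
    head_radius: float

    @property
    def n_points(self) -> int:
        return self.grid.shape[0]

    def resolve(self, source) -> np.ndarray:
        """Resolve a ROI name or coordinate to grid-point indices."""
        if isinstance(source, str):
            if source not in self.roi_masks:
                raise KeyError(f"unknown ROI {source!r}; have {sorted(self.roi_masks)}")
            idx = np.flatnonzero(self.roi_masks[source])
            if idx.size == 0:
                raise KeyError(f"ROI {source!r} covers no grid points")
            return idx
        coord = np.asarray(source, dtype=float)
        return np.array([int(np.argmin(np.linalg.norm(self.grid - coord, axis=1)))])

    def grid_adjacency(self, factor: float = 1.5) -> np.ndarray:
        """Boolean neighbour matrix: Euclidean distance <= factor x spacing."""
        d = np.linalg.norm(self.grid[:, None, :] - self.grid[None, :, :], axis=-1)
        return (d <= factor * self.spacing) & (d > 0)


def sphere_potential(
    electrodes: np.ndarray, dipole_pos: np.ndarray, radius: float, n_terms: int = 80
) -> np.ndarray:
    """Surface potential gain of unit x/y/z dipoles in a homogeneous sphere.

    Returns an (n_el, 3) matrix for a single dipole position, using the
    Legendre series solution for an insulated homogeneous sphere: writing
    b for the dipole eccentricity, c = cos of the angle between electrode
    and dipole, the n-th infinite-medium multipole coefficient is boosted
    by (2n+1)/n to satisfy the zero-current boundary at r = R.
    Electrodes are projected radially onto the sphere surface.
    """
    el = np.asarray(electrodes, dtype=float)
    e_hat = el / np.linalg.norm(el, axis=1, keepdims=True)
    r0 = np.asarray(dipole_pos, dtype=float)
    b = float(np.linalg.norm(r0))
    if b >= radius:
        raise ValueError("dipole must lie strictly inside the sphere")
    if b < 1e-12:
        # central dipole: only the n=1 term survives
        return (3.0 / (4.0 * np.pi * CONDUCTIVITY * radius**2)) * e_hat
    r0_hat = r0 / b
    c = e_hat @ r0_hat  # (n_el,)

    # Legendre P_n(c) and P_n'(c) by upward recurrence
    n_el = el.shape[0]
    out = np.zeros((n_el, 3))
    p_prev = np.ones(n_el)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros(n_el)  # P_0'
    dp_cur = np.ones(n_el)  # P_1'
    # q·e_hat decomposition: q_r = q·r0_hat ; tangential dot = q·e_hat - q_r*c
    for n in range(1, n_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * c * p_cur - (n - 1) * p_prev) / n
            dp_next = dp_prev + (2 * n - 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
        f_n = (2 * n + 1) / n * b ** (n - 1) / radius ** (n + 1)
        for k in range(3):
            q_r = r0_hat[k]
            tang = e_hat[:, k] - q_r * c
            out[:, k] += f_n * (n * q_r * p_cur + tang * dp_cur)
    return out / (4.0 * np.pi * CONDUCTIVITY)


def default_rois(grid: np.ndarray) -> dict[str, np.ndarray]:
    """Coordinate-box stand-ins for anatomical ROIs inside the sphere.

    Boxes (meters, head-centered) emulate left/right medial temporal lobe
    (parahippocampal cortex + hippocampus) and posterior parietal cortex.
    """
    x, y, z = grid.T

    def box(xr, yr, zr):
        return (
            (x >= xr[0]) & (x <= xr[1])
            & (y >= yr[0]) & (y <= yr[1])
            & (z >= zr[0]) & (z <= zr[1])
        )

    masks = {
        "mtl_left": box((-0.052, -0.016), (-0.046, -0.004), (-0.040, -0.002)),
        "mtl_right": box((0.016, 0.052), (-0.046, -0.004), (-0.040, -0.002)),
        "parietal_left": box((-0.042, -0.006), (-0.066, -0.028), (0.020, 0.056)),
        "parietal_right": box((0.006, 0.042), (-0.066, -0.028), (0.020, 0.056)),
    }
    masks["mtl_bilateral"] = masks["mtl_left"] | masks["mtl_right"]
    masks["parietal_bilateral"] = masks["parietal_left"] | masks["parietal_right"]
    return masks


def build_leadfield(
    sensors: SensorSpace,
    grid_spacing: float = 0.012,
    head_radius: float | None = None,
    n_terms: int = 80,
    rois: dict[str, np.ndarray] | None = None,
) -> SourceModel:
    """Cubic grid inside the sphere + analytic average-referenced gains.

    The grid covers the sphere interior at ``grid_spacing`` (default 12 mm),
    keeping points with |r| <= R - spacing/2 so the Legendre series
    converges quickly.  Gains are computed per grid point for unit dipoles
    along x/y/z and re-referenced to the channel average.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if head_radius is None:
        head_radius = sensors.radius
    rmax = head_radius - 0.5 * grid_spacing
    ax = np.arange(-head_radius, head_radius + grid_spacing / 2, grid_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    grid = grid[np.linalg.norm(grid, axis=1) <= rmax]
    if grid.shape[0] == 0:
        raise ValueError("grid empty: spacing too large for the sphere radius")

    lf = np.empty((grid.shape[0], sensors.n_channels, 3))
    for i, r0 in enumerate(grid):
        lf[i] = sphere_potential(sensors.positions, r0, head_radius, n_terms)
    lf -= lf.mean(axis=1, keepdims=True)  # average reference
    masks = default_rois(grid) if rois is None else rois
    return SourceModel(grid, grid_spacing, lf, masks, head_radius)


# ---------------------------------------------------------------------------
# Effects and epochs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """A band-limited oscillatory effect tied to design cells.

    ``amplitude_delta`` is the fractional amplitude change applied inside
    ``window`` for trials in ``cells_affected`` (e.g. -0.3 = 30% amplitude
    decrease); the oscillation itself is present in *all* trials at base
    ``amplitude`` so that decreases are meaningful.
    """

    name: str
    band: tuple[float, float]  # Hz
    window: tuple[float, float]  # s, relative to item onset
    cells_affected: tuple[str, ...]
    amplitude_delta: float
    source: str | tuple[float, float, float]  # ROI name or coordinate (m)
    amplitude: float = 2.0  # base source RMS, in units of one noise dipole's RMS

    def __post_init__(self):
        if not (2.0 <= self.band[0] < self.band[1] <= 30.0):
            raise ValueError(f"band {self.band} outside [2, 30] Hz")
        if self.amplitude_delta <= -1.0:
            raise ValueError("amplitude_delta must be > -1")
        for cell in self.cells_affected:
            if cell not in CELLS:
                raise ValueError(f"unknown design cell {cell!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["window"] = list(self.window)
        d["cells_affected"] = list(self.cells_affected)
        if not isinstance(self.source, str):
            d["source"] = list(self.source)
        return d


def default_effects() -> tuple[EffectSpec, ...]:
    """The reference effect structure for the 2x2 memory-encoding design.

    Theta (3-7 Hz) amplitude is lower throughout the trial for the spatial
    mnemonic (bilateral MTL source) and lower from 0.5 s post-onset for
    later-remembered items (left MTL source); alpha/beta amplitude is
    higher late in the trial for the spatial condition (bilateral
    posterior parietal) and for remembered items (right parietal).
    Condition and memory effects live on separate sources and combine
    additively, so the design contains no interaction by construction.
    """
    return (
        EffectSpec(
            "theta_condition", (3.0, 7.0), (-1.0, 3.0),
            ("spatial/remembered", "spatial/forgotten"), -0.3, "mtl_bilateral",
        ),
        EffectSpec(
            "theta_sme", (3.0, 7.0), (0.5, 3.0),
            ("spatial/remembered", "nonspatial/remembered"), -0.3, "mtl_left",
        ),
        EffectSpec(
            "alphabeta_condition", (10.0, 15.0), (1.0, 3.0),
            ("spatial/remembered", "spatial/forgotten"), 0.3, "parietal_bilateral",
        ),
        EffectSpec(
            "alphabeta_sme", (15.0, 30.0), (1.0, 3.0),
            ("spatial/remembered", "nonspatial/remembered"), 0.3, "parietal_right",
        ),
    )


@dataclass
class EpochedEEG:
    """Per-subject epoched data: trials x channels x samples (nominal µV)."""

    subject_id: str
    data: np.ndarray  # (n_trials, n_ch, n_samples) float32
    srate: float
    times: np.ndarray  # (n_samples,) seconds relative to item onset
    cell_labels: np.ndarray  # (n_trials,) str, values in CELLS

    def __post_init__(self):
        if not np.isfinite(self.data).all():
            raise ValueError("epoched data contains non-finite samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def cell_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.cell_labels == c)) for c in CELLS}


# ---------------------------------------------------------------------------
# Noise and oscillation synthesis
# ---------------------------------------------------------------------------


def _spectral_shape(n_samples: int, srate: float, exponent: float = -1.0) -> np.ndarray:
    """rfft amplitude profile giving a power spectrum ∝ f**exponent."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    amp = np.zeros_like(freqs)
    f_floor = 0.5  # flatten below 0.5 Hz to avoid a DC blow-up
    f_eff = np.maximum(freqs, f_floor)
    amp[1:] = f_eff[1:] ** (exponent / 2.0)
    return amp


def _colored_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                   amp: np.ndarray) -> np.ndarray:
    """Gaussian noise with a given rfft amplitude profile, unit RMS.

    Synthesized in single precision (complex64 spectra) - noise realism is
    unaffected and the inverse FFT dominates the simulation budget.
    """
    n_r = n_samples // 2 + 1
    spec = np.empty((*shape, n_r), dtype=np.complex64)
    spec.real = rng.standard_normal((*shape, n_r), dtype=np.float32)
    spec.imag = rng.standard_normal((*shape, n_r), dtype=np.float32)
    spec *= amp.astype(np.float32)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # analytic variance of irfft with unit-variance real+imag parts per bin:
    # var(x_t) = 4 * sum(amp^2) / n^2
    scale = np.float32(2.0 * np.sqrt(np.sum(amp**2)) / n_samples)
    return x / scale


def pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
               srate: float, exponent: float = -1.0) -> np.ndarray:
    """1/f-spectrum Gaussian noise, unit RMS, shape ``(*shape, n_samples)``."""
    return _colored_noise(rng, shape, n_samples, _spectral_shape(n_samples, srate, exponent))


def bandpass_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                   srate: float, band: tuple[float, float],
                   transition: float = 0.5) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` with cosine edges."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / srate)
    amp = np.zeros_like(freqs)
    lo, hi = band
    inside = (freqs >= lo) & (freqs <= hi)
    amp[inside] = 1.0
    for f0, sgn in ((lo, -1.0), (hi, 1.0)):
        edge = (freqs - f0) * sgn
        ramp = (edge > 0) & (edge < transition)
        amp[ramp] = 0.5 * (1.0 + np.cos(np.pi * edge[ramp] / transition))
    amp[0] = 0.0
    return _colored_noise(rng, shape, n_samples, amp)


def _effect_envelope(times: np.ndarray, window: tuple[float, float],
                     delta: float, edge: float = 0.1) -> np.ndarray:
    """1 + delta inside the window, raised-cosine transitions of ``edge`` s."""
    t0, t1 = window
    w = np.zeros_like(times)
    w[(times >= t0) & (times <= t1)] = 1.0
    for tc, sgn in ((t0, 1.0), (t1, -1.0)):
        rel = (times - tc) * sgn
        ramp = (rel > -edge) & (rel < 0)
        w[ramp] = 0.5 * (1.0 + np.cos(np.pi * rel[ramp] / edge))
    return 1.0 + delta * w


# ---------------------------------------------------------------------------
# Subject and cohort simulation
# ---------------------------------------------------------------------------


def sample_trial_counts(rng: np.random.Generator,
                        means: dict[str, float] | None = None,
                        sd: float = 12.0, minimum: int = 15,
                        maximum: int | None = 110) -> dict[str, int]:
    """Per-cell trial counts: truncated normal around the cohort means."""
    means = DEFAULT_TRIAL_MEANS if means is None else means
    counts = {}
    for cell in CELLS:
        n = int(np.round(rng.normal(means[cell], sd)))
        n = max(minimum, n)
        if maximum is not None:
            n = min(n, maximum)
        counts[cell] = n
    return counts


def simulate_subject(
    sensors: SensorSpace,
    model: SourceModel,
    effects: Sequence[EffectSpec],
    trial_counts: dict[str, int],
    noise_level: float = 1.0,
    seed: int | np.random.Generator = 0,
    srate: float = 500.0,
    epoch: tuple[float, float] = (-2.5, 3.5),
    n_noise_dipoles: int = 60,
    sensor_noise: float = 0.2,
    subject_id: str = "sub-00",
) -> EpochedEEG:
    """Forward-simulate one subject's epoched EEG.

    Background: ``n_noise_dipoles`` random grid dipoles (half drawn from the
    deepest, half from the most superficial third of the grid) each emit
    independent unit-RMS 1/f noise, scaled by ``noise_level``.  Effects:
    each :class:`EffectSpec` places coherent band-limited noise on its
    source grid points; trials in ``cells_affected`` have the source
    amplitude multiplied by ``1 + amplitude_delta`` inside the effect
    window.  White sensor noise of RMS ``sensor_noise`` (same units) is
    added per channel.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for cell in trial_counts:
        if cell not in CELLS:
            raise ValueError(f"unknown cell {cell!r}")
    for cell in CELLS:
        if trial_counts.get(cell, 0) < 1:
            raise ValueError(f"every design cell needs at least one trial ({cell})")

    t0, t1 = epoch
    n_samples = int(round((t1 - t0) * srate)) + 1
    times = t0 + np.arange(n_samples) / srate
    labels = np.concatenate([[c] * trial_counts.get(c, 0) for c in CELLS])
    order = rng.permutation(labels.size)  # interleave cells across the session
    labels = labels[order]
    n_trials = labels.size

    # --- background: 1/f dipole noise mixed through the leadfield
    depth = np.linalg.norm(model.grid, axis=1)
    qlow, qhigh = np.quantile(depth, [1 / 3, 2 / 3])
    deep = np.flatnonzero(depth <= qlow)
    shallow = np.flatnonzero(depth >= qhigh)
    n_deep = n_noise_dipoles // 2
    idx = np.concatenate([
        rng.choice(deep, size=n_deep, replace=True),
        rng.choice(shallow, size=n_noise_dipoles - n_deep, replace=True),
    ])
    ori = rng.standard_normal((n_noise_dipoles, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    gains = np.einsum("kcd,kd->kc", model.leadfield[idx], ori)  # (K, n_ch)
    gains = gains.astype(np.float32)
    # normalize the typical gain so amplitudes are comparable across setups
    gscale = np.sqrt(np.mean(gains**2))
    gains /= gscale

    src = pink_noise(rng, (n_trials, n_noise_dipoles), n_samples, srate)
    mix = (gains * np.float32(noise_level)).T  # (n_ch, K)
    data = np.matmul(mix[None, :, :], src)  # (T, n_ch, S) via batched BLAS

    # --- oscillatory effect sources
    for eff in effects:
        pts = model.resolve(eff.source)
        pori = rng.standard_normal((pts.size, 3))
        pori /= np.linalg.norm(pori, axis=1, keepdims=True)
        pg = np.einsum("kcd,kd->kc", model.leadfield[pts], pori) / gscale
        net_gain = pg.sum(axis=0).astype(np.float32) / np.sqrt(pts.size)
        osc = bandpass_noise(rng, (n_trials,), n_samples, srate, eff.band)
        affected = np.isin(labels, eff.cells_affected)
        env = np.where(
            affected[:, None],
            _effect_envelope(times, eff.window, eff.amplitude_delta).astype(np.float32)[None, :],
            np.float32(1.0),
        )
        osc = osc * env * np.float32(eff.amplitude)
        data += osc[:, None, :] * net_gain[None, :, None]

    if sensor_noise > 0:
        data += np.float32(sensor_noise) * rng.standard_normal(
            data.shape, dtype=np.float32)

    return EpochedEEG(subject_id, data.astype(np.float32), srate, times, labels)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort (defaults mirror the design)."""

    n_subjects: int = 21
    n_channels: int = 63
    srate: float = 500.0
    epoch: tuple[float, float] = (-2.5, 3.5)
    trial_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRIAL_MEANS))
    trial_sd: float = 12.0
    min_trials: int = 15
    noise_level: float = 1.0
    sensor_noise: float = 0.2
    n_noise_dipoles: int = 60
    grid_spacing: float = 0.012
    head_radius: float = 0.09
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    n_lists: int = 6  # word lists per condition
    n_items: int = 20  # items per list
    oos_mean: float = 1.5  # mean out-of-sequence recalls per condition

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = [e.to_dict() for e in self.effects]
        d["epoch"] = list(self.epoch)
        return d


@dataclass
class Cohort:
    """Simulated subjects plus the ground-truth manifest."""

    subjects: list[EpochedEEG]
    sensors: SensorSpace
    model: SourceModel
    manifest: dict
    recall_logs: dict  # subject_id -> condition -> list of recall sequences

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _recall_sequences(rng: np.random.Generator, n_remembered: int, n_oos: int,
                      n_lists: int, n_items: int) -> list[list[int]]:
    """Recall sequences per list that score to the requested counts.

    Remembered items are recalled in presentation order; out-of-sequence
    items are late-list items recalled first (in decreasing order), which
    guarantees the order-scoring rule labels them out-of-sequence whenever
    at least two items are recalled in order.
    """
    capacity = n_lists * n_items
    n_remembered = min(n_remembered, capacity - n_oos)
    base, extra = divmod(n_remembered, n_lists)
    rem_per_list = [base + (1 if i < extra else 0) for i in range(n_lists)]
    oos_per_list = [0] * n_lists
    for _ in range(n_oos):
        eligible = [i for i in range(n_lists)
                    if rem_per_list[i] >= 2 and oos_per_list[i] + rem_per_list[i] < n_items]
        if not eligible:
            break
        oos_per_list[int(rng.choice(eligible))] += 1
    sequences = []
    for r, o in zip(rem_per_list, oos_per_list):
        items = np.arange(1, n_items + 1)
        oos_items = items[n_items - o:][::-1] if o else items[:0]
        pool = items[: n_items - o]
        rem_items = np.sort(rng.choice(pool, size=min(r, pool.size), replace=False))
        sequences.append([int(i) for i in np.concatenate([oos_items, rem_items])])
    return sequences


def generate_cohort(
    n_subjects: int | None = None,
    config: CohortConfig | None = None,
    master_seed: int = 0,
    sensors: SensorSpace | None = None,
    model: SourceModel | None = None,
) -> Cohort:
    """Simulate a cohort; per-subject seeds spawn from the master seed.

    ``sensors``/``model`` may be passed in to reuse a prebuilt leadfield
    (they must match the config's channel count and grid settings).
    """
    config = CohortConfig() if config is None else config
    if n_subjects is None:
        n_subjects = config.n_subjects
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")

    if sensors is None:
        sensors = make_sensor_space(config.n_channels)
    if model is None:
        model = build_leadfield(sensors, config.grid_spacing, config.head_radius)
    if sensors.n_channels != config.n_channels:
        raise ValueError("sensor space does not match config channel count")

    root = np.random.SeedSequence(master_seed)
    child_seqs = root.spawn(n_subjects)
    subjects, counts_list, recall_logs = [], [], {}
    for i, seq in enumerate(child_seqs):
        rng = np.random.default_rng(seq)
        counts = sample_trial_counts(rng, config.trial_means, config.trial_sd,
                                     config.min_trials)
        sid = f"sub-{i + 1:02d}"
        subj = simulate_subject(
            sensors, model, config.effects, counts,
            noise_level=config.noise_level, seed=rng,
            srate=config.srate, epoch=config.epoch,
            n_noise_dipoles=config.n_noise_dipoles,
            sensor_noise=config.sensor_noise, subject_id=sid,
        )
        logs = {}
        for cond in ("spatial", "nonspatial"):
            n_rem = counts[f"{cond}/remembered"]
            n_oos = int(rng.poisson(config.oos_mean))
            logs[cond] = _recall_sequences(rng, n_rem, n_oos,
                                           config.n_lists, config.n_items)
        recall_logs[sid] = logs
        subjects.append(subj)
        counts_list.append(counts)

    manifest = {
        "version": 1,
        "master_seed": int(master_seed),
        "n_subjects": n_subjects,
        "config": config.to_dict(),
        "effects": [e.to_dict() for e in config.effects],
        "trial_counts": {s.subject_id: c for s, c in zip(subjects, counts_list)},
    }
    return Cohort(subjects, sensors, model, manifest, recall_logs)
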