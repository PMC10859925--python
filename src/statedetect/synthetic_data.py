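"""Piecewise-stationary multichannel signal simulator with planted states.

Each recording is a sequence of "states": contiguous runs of 1-s epochs
whose spectral content is stationary within the run and changes at the run
boundaries.  Every channel is built as

    pink (1/f) background
    + per-band band-limited Gaussian noise, amplitude-scaled by the
      state's (band, region) gain
    + a per-band *shared driver* mixed into all channels of the state in
      proportion to the state's synchrony level,

so band powers and inter-channel coherence/PLV are directly controllable —
exactly the statistics the feature recipe measures.  Band components are
synthesized by spectral masking of white noise (exact band edges); the
shared-driver mixing uses amplitude weights sqrt(1-s) and sqrt(s), so the
synchrony level ``s`` is the driver's share of band power.

Two null/rearrangement controls accompany the generator:

* :func:`make_surrogate` — one random permutation applied identically to
  epochs and per-epoch feature rows, destroying temporal structure while
  preserving the multiset of rows;
* :func:`rearrange_states` — state blocks permuted as contiguous units,
  preserving within-state structure while shuffling state order.

The simulator makes no attempt at biophysical realism (no dipole forward
model, no volume conduction); it emulates the statistical structure the
detector consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._partition import SegmentPartition
from .data_io import ContinuousRecording, EpochedRecording
from .features import BANDS, CHANNELS_38, ROI_15, FeatureTable, ROIMap

__all__ = [
    "StateSpec",
    "SimRecipe",
    "generate_recording",
    "make_surrogate",
    "rearrange_states",
    "default_recipe",
]


@dataclass(frozen=True)
class StateSpec:
    """One planted state: duration plus per-band power gains and synchrony.

    ``band_gains`` maps band -> amplitude gain (scalar, applied to all
    regions) or band -> {region: gain}; unlisted bands/regions default to
    gain 1.  ``sync_levels`` maps band -> share in [0, 1] of the band power
    carried by a driver common to all channels.
    """

    duration_epochs: int
    band_gains: dict = field(default_factory=dict)
    sync_levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_epochs < 1:
            raise ValueError("state duration must be >= 1 epoch")
        for band, gain in self.band_gains.items():
            vals = gain.values() if isinstance(gain, dict) else [gain]
            if any(g <= 0 for g in vals):
                raise ValueError(f"gains must be positive (band {band})")
        for band, s in self.sync_levels.items():
            if not 0 <= s <= 1:
                raise ValueError(f"synchrony level for {band} must lie in [0, 1]")

    def gain(self, band: str, region: str) -> float:
        g = self.band_gains.get(band, 1.0)
        return float(g.get(region, 1.0)) if isinstance(g, dict) else float(g)


@dataclass(frozen=True)
class SimRecipe:
    """An ordered state sequence over a montage."""

    states: tuple[StateSpec, ...]
    channel_names: tuple[str, ...] = tuple(CHANNELS_38)
    rois: ROIMap = field(default_factory=ROIMap)
    sfreq: float = 500.0
    epoch_len_s: float = 1.0
    background_amp: float = 1.0
    band_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("recipe needs at least one state")
        # every channel must belong to a region so gains are defined
        covered = {ch for chs in self.rois.regions.values() for ch in chs}
        missing = [ch for ch in self.channel_names if ch not in covered]
        if missing:
            raise ValueError(f"channels not covered by the region map: {missing}")

    @property
    def total_epochs(self) -> int:
        return sum(s.duration_epochs for s in self.states)

    @property
    def truth(self) -> SegmentPartition:
        bounds = np.cumsum([0] + [s.duration_epochs for s in self.states])
        return SegmentPartition(bounds)


def _band_noise(rng: np.random.Generator, n: int, sfreq: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, sfreq: float) -> np.ndarray:
    """Unit-variance 1/f background (flat below 1 Hz to avoid divergence)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / x.std()


def generate_recording(recipe: SimRecipe) -> tuple[ContinuousRecording, SegmentPartition]:
    """Synthesize a recording; returns it with its ground-truth partition."""
    rng = np.random.default_rng(recipe.seed)
    spe = int(round(recipe.epoch_len_s * recipe.sfreq))
    n_ch = len(recipe.channel_names)
    region_of = {}
    for region, chs in recipe.rois.regions.items():
        for ch in chs:
            region_of[ch] = region
    blocks = []
    for state in recipe.states:
        n = state.duration_epochs * spe
        block = np.empty((n_ch, n))
        drivers = {band: _band_noise(rng, n, recipe.sfreq, lo, hi) for band, (lo, hi) in BANDS.items()}
        for c, ch in enumerate(recipe.channel_names):
            x = recipe.background_amp * _pink_noise(rng, n, recipe.sfreq)
            for band, (lo, hi) in BANDS.items():
                s = float(state.sync_levels.get(band, 0.0))
                own = _band_noise(rng, n, recipe.sfreq, lo, hi)
                comp = np.sqrt(1.0 - s) * own + np.sqrt(s) * drivers[band]
                x = x + recipe.band_amp * state.gain(band, region_of[ch]) * comp
            block[c] = x
        blocks.append(block)
    signal = np.concatenate(blocks, axis=1)
    rec = ContinuousRecording(signal, recipe.sfreq, list(recipe.channel_names))
    return rec, recipe.truth


def default_recipe(seed: int = 0, *, scale: float = 1.0) -> SimRecipe:
    """An 8-state recording with strong band-power and synchrony contrasts.

    Mirrors the staged-protocol regime the detector targets: 38 channels at
    500 Hz, eight states of 60-180 one-second epochs.  ``scale`` shrinks
    the durations proportionally (minimum 25 epochs) for quick runs.
    """
    rng = np.random.default_rng(seed)
    durations = rng.integers(60, 181, size=8)
    durations = np.maximum((durations * scale).astype(int), 25)
    states = [StateSpec(int(dur), *_distinct_state_params(i)) for i, dur in enumerate(durations)]
    return SimRecipe(states=tuple(states), seed=seed)


# equally sized (3-channel) regions of the standard montage, so every
# planted boost carries comparable weight in the montage-wide feature set
_DEFAULT_BOOST_REGIONS = ("prefrontal", "temporal_left", "occipital_right")


def _distinct_state_params(i: int, regions=_DEFAULT_BOOST_REGIONS) -> tuple[dict, dict]:
    """Pairwise-distinct state patterns: one (band, region) power boost each.

    State *i* boosts band ``i mod 5`` in region ``i mod len(regions)`` by a
    4x amplitude gain (16x power) over the uniform baseline.  Every
    transition therefore swaps two independent column groups of comparable
    weight, keeping adjacent contrasts homogeneous: with strongly
    heterogeneous contrasts the detector's relative merge rule prunes the
    weakest real boundaries first, which is a property of the method, not a
    failure of it.  Distinctness also matters for block-rearrangement
    controls — identical states that become adjacent after a permutation
    merge into one, by design.  A moderate common beta synchrony keeps the
    phase-coupling features active.
    """
    band = list(BANDS)[i % len(BANDS)]
    region = regions[i % len(regions)]
    return {band: {region: 4.0}}, {"beta": 0.3}


def _permute_epochs(obj, perm: np.ndarray):
    if isinstance(obj, EpochedRecording):
        return EpochedRecording(
            obj.data[perm], obj.epoch_len_s, obj.sfreq, list(obj.channel_names), np.arange(len(perm))
        )
    if isinstance(obj, FeatureTable):
        return obj.take_epochs(perm)
    raise TypeError(f"cannot permute object of type {type(obj).__name__}")


def make_surrogate(obj, seed: int = 0):
    """Epoch-shuffled surrogate of a recording or feature table.

    One random permutation is applied to epochs (and feature rows move with
    their epochs), so the multiset of rows — hence all marginal feature
    distributions — is preserved while temporal structure is destroyed.
    Returns (surrogate, permutation).
    """
    n = obj.n_epochs
    if n < 2:
        raise ValueError("need at least two epochs to shuffle")
    perm = np.random.default_rng(seed).permutation(n)
    return _permute_epochs(obj, perm), perm


def rearrange_states(obj, partition: SegmentPartition, seed: int = 0):
    """Permute state blocks as contiguous units.

    Returns (rearranged object, expected boundaries after the permutation,
    block permutation).  Epoch order within each state is preserved.
    """
    if partition.n_epochs != obj.n_epochs:
        raise ValueError("partition does not match the object's epoch count")
    rng = np.random.default_rng(seed)
    order = rng.permutation(partition.n_states)
    pieces = [partition.state_indices(s) for s in order]
    perm = np.concatenate(pieces)
    new_durations = [len(p) for p in pieces]
    expected = SegmentPartition(np.cumsum([0] + new_durations))
    return _permute_epochs(obj, perm), expected, order
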