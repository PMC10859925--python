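"""Per-epoch EEG feature engineering.

The feature set mirrors common quantitative-EEG practice for 1-s epochs:

* band- and region-averaged power spectral densities (adaptive multitaper),
* 16 band-power ratios per region (ratios of linear, non-logged powers),
* magnitude-squared coherence and phase-locking value (PLV) per channel
  pair, estimated from DPSS-tapered cross-spectra over a sliding window of
  ``window_epochs`` adjacent epochs centred on the current one,
* thresholded coherence/PLV *indices*: per channel, the count of other
  channels whose synchrony reaches a threshold P, region-averaged,
* region-pair coherence/PLV averages (descriptive only, never fed to the
  state detector).

On the standard 38-channel / 15-region montage the construction yields
75 PSD + 240 ratio + 225 coherence-index + 225 PLV-index = 765 detector
input columns, and with the 525 + 525 region-pair columns 1,815 analysis
columns in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import windows

from .data_io import EpochedRecording

__all__ = [
    "BANDS",
    "CHANNELS_38",
    "ROI_15",
    "ROI_9",
    "BandScheme",
    "ROIMap",
    "ConnectivityIndexConfig",
    "FeatureTable",
    "compute_band_roi_psd",
    "compute_psd_ratios",
    "compute_pairwise_sync",
    "compute_connectivity_index",
    "region_pair_features",
    "compute_all_features",
]

# Conventional band edges in Hz.  Membership uses half-open [low, high)
# intervals so shared edges (4, 8, 14, 25 Hz) are never double-counted;
# gamma is closed at 40 Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.9, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 25.0),
    "gamma": (25.0, 40.0),
}

BAND_ORDER = tuple(BANDS)

# The 38 scalp channels of the 10-20 montage used for analysis (ear
# electrodes A1/A2 excluded).
CHANNELS_38 = [
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6", "P5", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

# 15 spatial regions of interest (channel groups for feature averaging).
ROI_15: dict[str, list[str]] = {
    "prefrontal": ["Fp1", "Fp2", "Fpz"],
    "frontal_left": ["F3", "F7", "FC3", "FT7"],
    "frontal_mid": ["Fz", "FCz"],
    "frontal_right": ["F4", "F8", "FC4", "FT8"],
    "central_left": ["C3", "CP3"],
    "central_mid": ["Cz", "CPz"],
    "central_right": ["C4", "CP4"],
    "temporal_left": ["T3", "T5", "TP7"],
    "temporal_right": ["T4", "T6", "TP8"],
    "parietal_left": ["P3", "P5"],
    "parietal_mid": ["Pz"],
    "parietal_right": ["P4", "P6"],
    "occipital_left": ["PO3", "PO7", "O1"],
    "occipital_mid": ["POz", "Oz"],
    "occipital_right": ["PO4", "PO8", "O2"],
}

# Merged 9-region display variant (central/parietal/occipital collapsed).
ROI_9: dict[str, list[str]] = {
    "prefrontal": ROI_15["prefrontal"],
    "frontal_left": ROI_15["frontal_left"],
    "frontal_mid": ROI_15["frontal_mid"],
    "frontal_right": ROI_15["frontal_right"],
    "temporal_left": ROI_15["temporal_left"],
    "temporal_right": ROI_15["temporal_right"],
    "central": ROI_15["central_left"] + ROI_15["central_mid"] + ROI_15["central_right"],
    "parietal": ROI_15["parietal_left"] + ROI_15["parietal_mid"] + ROI_15["parietal_right"],
    "occipital": ROI_15["occipital_left"] + ROI_15["occipital_mid"] + ROI_15["occipital_right"],
}

# The 16 band-power ratios computed per region.
PSD_RATIOS: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("theta/delta", ("theta",), ("delta",)),
    ("alpha/delta", ("alpha",), ("delta",)),
    ("alpha/theta", ("alpha",), ("theta",)),
    ("alpha/(delta+theta)", ("alpha",), ("delta", "theta")),
    ("beta/delta", ("beta",), ("delta",)),
    ("beta/theta", ("beta",), ("theta",)),
    ("beta/alpha", ("beta",), ("alpha",)),
    ("beta/(delta+theta)", ("beta",), ("delta", "theta")),
    ("beta/(theta+alpha)", ("beta",), ("theta", "alpha")),
    ("gamma/delta", ("gamma",), ("delta",)),
    ("gamma/theta", ("gamma",), ("theta",)),
    ("gamma/alpha", ("gamma",), ("alpha",)),
    ("gamma/beta", ("gamma",), ("beta",)),
    ("gamma/(delta+theta)", ("gamma",), ("delta", "theta")),
    ("gamma/(theta+alpha)", ("gamma",), ("theta", "alpha")),
    ("gamma/(alpha+beta)", ("gamma",), ("alpha", "beta")),
]


@dataclass(frozen=True)
class BandScheme:
    """Named, ordered, non-overlapping frequency intervals in Hz."""

    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(BANDS))

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (_, hi), (lo, _) in zip(edges[:-1], edges[1:]):
            if lo < hi:
                raise ValueError("bands must be ordered and non-overlapping")
        for lo, hi in edges:
            if hi <= lo:
                raise ValueError("band high edge must exceed low edge")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def fmin(self) -> float:
        return next(iter(self.bands.values()))[0]

    @property
    def fmax(self) -> float:
        return list(self.bands.values())[-1][1]

    def masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean frequency masks; half-open [lo, hi), last band closed."""
        names = self.names
        out = {}
        for i, name in enumerate(names):
            lo, hi = self.bands[name]
            if i == len(names) - 1:
                m = (freqs >= lo) & (freqs <= hi)
            else:
                m = (freqs >= lo) & (freqs < hi)
            if not m.any():
                raise ValueError(f"no frequency bins fall inside band {name!r}")
            out[name] = m
        return out


@dataclass(frozen=True)
class ROIMap:
    """Mapping region name -> channel list, validated against a channel set."""

    regions: dict[str, list[str]] = field(default_factory=lambda: {k: list(v) for k, v in ROI_15.items()})

    def __post_init__(self) -> None:
        for name, chs in self.regions.items():
            if not chs:
                raise ValueError(f"region {name!r} has no channels")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def indices(self, channel_names: list[str]) -> dict[str, np.ndarray]:
        """Per-region channel indices into ``channel_names``."""
        lookup = {ch: i for i, ch in enumerate(channel_names)}
        out = {}
        for name, chs in self.regions.items():
            missing = [ch for ch in chs if ch not in lookup]
            if missing:
                raise ValueError(f"region {name!r} channels not in recording: {missing}")
            out[name] = np.array([lookup[ch] for ch in chs])
        return out

    @classmethod
    def from_file(cls, path) -> "ROIMap":
        import yaml

        return cls(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class ConnectivityIndexConfig:
    """Thresholds and window for coherence/PLV index features."""

    thresholds: tuple[float, ...] = (0.6, 0.7, 0.8)
    window_epochs: int = 5
    measure: str = "coherence"

    def __post_init__(self) -> None:
        if any(not 0 < p < 1 for p in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.window_epochs % 2 == 0 or self.window_epochs < 1:
            raise ValueError("window_epochs must be odd and positive")
        if self.measure not in ("coherence", "plv"):
            raise ValueError(f"unknown measure {self.measure!r}")


class FeatureTable:
    """Epochs x features matrix with per-column metadata.

    ``meta`` is a DataFrame indexed by feature name with columns
    ``kind`` (psd, psd_ratio, coherence, plv, coh_index, plv_index),
    ``band``, ``region`` (region, region pair "a|b", or channel pair),
    and ``threshold`` (NaN unless an index feature).
    """

    KINDS = ("psd", "psd_ratio", "coherence", "plv", "coh_index", "plv_index")

    def __init__(self, values: np.ndarray, meta: pd.DataFrame):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (epochs x features)")
        if len(meta) != values.shape[1]:
            raise ValueError(f"{len(meta)} metadata rows for {values.shape[1]} columns")
        if not np.isfinite(values).all():
            raise ValueError("feature values must be finite")
        self.values = values
        self.meta = meta

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return list(self.meta.index)

    def mask(self, *, kind=None, band=None, region=None, threshold=None) -> np.ndarray:
        """Boolean column mask by metadata; each criterion may be a value or list."""
        m = np.ones(self.n_features, dtype=bool)
        for col, want in (("kind", kind), ("band", band), ("region", region), ("threshold", threshold)):
            if want is None:
                continue
            vals = self.meta[col]
            if isinstance(want, (list, tuple, set)):
                m &= vals.isin(list(want)).to_numpy()
            else:
                m &= (vals == want).to_numpy()
        return m

    def select(self, **criteria) -> "FeatureTable":
        m = self.mask(**criteria)
        return FeatureTable(self.values[:, m], self.meta.loc[m])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.meta.index.get_loc(name)]

    def take_epochs(self, idx) -> "FeatureTable":
        return FeatureTable(self.values[idx], self.meta)

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        n = {t.n_epochs for t in tables}
        if len(n) != 1:
            raise ValueError(f"tables disagree on epoch count: {sorted(n)}")
        return FeatureTable(
            np.hstack([t.values for t in tables]),
            pd.concat([t.meta for t in tables]),
        )

    def to_csv(self, path) -> None:
        """Serialize as delimited text with a multi-row metadata header."""
        cols = pd.MultiIndex.from_arrays(
            [
                self.meta.index,
                self.meta["kind"],
                self.meta["band"].fillna(""),
                self.meta["region"].fillna(""),
                self.meta["threshold"],
            ],
            names=["name", "kind", "band", "region", "threshold"],
        )
        pd.DataFrame(self.values, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, header=[0, 1, 2, 3, 4])
        name, kind, band, region, thr = (df.columns.get_level_values(i) for i in range(5))

        def _clean(level):
            return [None if (isinstance(v, str) and v.startswith("Unnamed")) or v == "" else v for v in level]

        meta = pd.DataFrame(
            {
                "kind": _clean(kind),
                "band": _clean(band),
                "region": _clean(region),
                "threshold": pd.to_numeric(pd.Series(_clean(thr)), errors="coerce"),
            },
            index=pd.Index(name, name="name"),
        )
        return cls(df.to_numpy(dtype=np.float64), meta)


def _make_meta(names, kind, bands, regions, thresholds=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kind": kind,
            "band": bands,
            "region": regions,
            "threshold": thresholds if thresholds is not None else np.nan,
        },
        index=pd.Index(names, name="name"),
    )


def compute_band_roi_psd(
    epochs: EpochedRecording,
    bands: BandScheme | None = None,
    rois: ROIMap | None = None,
    *,
    bandwidth: float = 8.0,
    adaptive: bool = True,
) -> FeatureTable:
    """Band- and region-averaged adaptive multitaper PSD per epoch.

    ``bandwidth`` is the full spectral bandwidth in Hz handed to the
    multitaper estimator; the default 8 Hz on a 1-s epoch corresponds to a
    time-half-bandwidth product of 4 (7 DPSS tapers), a standard choice for
    short epochs.  Taper weighting is adaptive (Thomson) by default.
    """
    from mne.time_frequency import psd_array_multitaper

    bands = bands or BandScheme()
    rois = rois or ROIMap()
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    if epochs.sfreq < 2 * bands.fmax:
        raise ValueError(
            f"sampling rate {epochs.sfreq} below Nyquist for top band edge {bands.fmax}"
        )
    psd, freqs = psd_array_multitaper(
        epochs.data,
        sfreq=epochs.sfreq,
        fmin=bands.fmin,
        fmax=bands.fmax,
        bandwidth=bandwidth,
        adaptive=adaptive,
        normalization="full",
        verbose="error",
    )
    masks = bands.masks(freqs)
    roi_idx = rois.indices(epochs.channel_names)
    cols, names, bnames, regions = [], [], [], []
    for band in bands.names:
        band_power = psd[:, :, masks[band]].mean(axis=2)  # (epochs, channels)
        for region in rois.names:
            cols.append(band_power[:, roi_idx[region]].mean(axis=1))
            names.append(f"psd:{band}:{region}")
            bnames.append(band)
            regions.append(region)
    values = np.column_stack(cols)
    return FeatureTable(values, _make_meta(names, "psd", bnames, regions))


def compute_psd_ratios(psd: FeatureTable) -> FeatureTable:
    """The 16 per-region band-power ratios, on linear (non-logged) powers."""
    sub = psd.select(kind="psd")
    if sub.n_features == 0:
        raise ValueError("no psd columns present")
    if np.any(sub.values <= 0):
        raise ValueError("band powers must be strictly positive to form ratios")
    regions = list(dict.fromkeys(sub.meta["region"]))
    band_cols = {}
    for region in regions:
        for band in BAND_ORDER:
            m = sub.mask(band=band, region=region)
            if m.sum() != 1:
                raise ValueError(f"expected one psd column for ({band}, {region})")
            band_cols[band, region] = sub.values[:, m][:, 0]
    cols, names, bnames, rnames = [], [], [], []
    for region in regions:
        for label, num, den in PSD_RATIOS:
            numerator = sum(band_cols[b, region] for b in num)
            denominator = sum(band_cols[b, region] for b in den)
            cols.append(numerator / denominator)
            names.append(f"ratio:{label}:{region}")
            bnames.append(num[0])  # band group = numerator band
            rnames.append(region)
    return FeatureTable(np.column_stack(cols), _make_meta(names, "psd_ratio", bnames, rnames))


def _tapered_spectra(epochs: EpochedRecording, bands: BandScheme, bandwidth: float):
    """DPSS-tapered FFTs restricted to the analysis band.

    Returns (spectra (n_epochs, n_tapers, n_channels, n_freqs), freqs).
    Epochs are processed in chunks so the full-resolution tapered FFT is
    never materialized for the whole recording at once.
    """
    n_times = epochs.data.shape[2]
    half_nbw = bandwidth * n_times / (2.0 * epochs.sfreq)
    n_tapers = max(int(2 * half_nbw) - 1, 1)
    tapers = windows.dpss(n_times, half_nbw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n_times, 1.0 / epochs.sfreq)
    keep = (freqs >= bands.fmin) & (freqs <= bands.fmax)
    n_ep, n_ch = epochs.data.shape[:2]
    spectra = np.empty((n_ep, n_tapers, n_ch, int(keep.sum())), dtype=np.complex128)
    chunk = max(1, int(2**24 // (n_tapers * n_ch * n_times)))
    for lo in range(0, n_ep, chunk):
        hi = min(lo + chunk, n_ep)
        tapered = epochs.data[lo:hi, np.newaxis, :, :] * tapers[np.newaxis, :, np.newaxis, :]
        spectra[lo:hi] = np.fft.rfft(tapered, axis=3)[:, :, :, keep]
    return spectra, freqs[keep]


def _window_slices(n_epochs: int, window: int):
    """Centered sliding-window bounds, truncated at the record edges."""
    half = window // 2
    lo = np.maximum(np.arange(n_epochs) - half, 0)
    hi = np.minimum(np.arange(n_epochs) + half + 1, n_epochs)
    return lo, hi


def compute_pairwise_sync(
    epochs: EpochedRecording,
    bands: BandScheme | None = None,
    cfg: ConnectivityIndexConfig | None = None,
    *,
    bandwidth: float = 8.0,
) -> FeatureTable:
    """Coherence or PLV per unordered channel pair, band-averaged per epoch.

    For each epoch the cross-spectral density is averaged over the tapers
    and epochs of a ``window_epochs``-wide window centred on it (truncated
    at the record edges so every epoch keeps a feature row).  Coherence at a
    frequency is |mean CSD|^2 / (mean PSD_x * mean PSD_y); PLV is the
    magnitude of the mean unit-normalized per-taper cross-spectrum.  Both
    are then averaged over the band's frequency bins and lie in [0, 1].
    """
    bands = bands or BandScheme()
    cfg = cfg or ConnectivityIndexConfig()
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    spectra, freqs = _tapered_spectra(epochs, bands, bandwidth)
    n_ep, n_tap, n_ch, n_fr = spectra.shape
    power = (spectra.real**2 + spectra.imag**2).sum(axis=1)  # (ep, ch, fr)
    if np.any(power.sum(axis=(0, 2)) == 0):
        silent = int(np.argwhere(power.sum(axis=(0, 2)) == 0)[0][0])
        raise ValueError(f"channel {epochs.channel_names[silent]} has zero power")

    ix, iy = np.triu_indices(n_ch, k=1)
    n_pairs = len(ix)
    # Per-epoch taper-summed cross-spectra and taper-summed unit cross-spectra.
    csd = np.empty((n_ep, n_pairs, n_fr), dtype=np.complex128)
    unit = np.empty((n_ep, n_pairs, n_fr), dtype=np.complex128)
    for e in range(n_ep):
        prod = spectra[e][:, ix, :] * np.conj(spectra[e][:, iy, :])  # (tap, pair, fr)
        csd[e] = prod.sum(axis=0)
        mag = np.abs(prod)
        np.maximum(mag, np.finfo(float).tiny, out=mag)
        unit[e] = (prod / mag).sum(axis=0)

    # Sliding-window sums via cumulative sums along the epoch axis.
    def _winsum(arr):
        cum = np.concatenate([np.zeros((1,) + arr.shape[1:], arr.dtype), np.cumsum(arr, axis=0)])
        lo, hi = _window_slices(n_ep, cfg.window_epochs)
        return cum[hi] - cum[lo]

    lo, hi = _window_slices(n_ep, cfg.window_epochs)
    counts = (hi - lo).astype(np.float64)

    masks = bands.masks(freqs)
    names, bnames, pnames, cols = [], [], [], []
    if cfg.measure == "coherence":
        csd_w = _winsum(csd)
        pow_w = _winsum(power)
        num = csd_w.real**2 + csd_w.imag**2
        den = pow_w[:, ix, :] * pow_w[:, iy, :]
        np.maximum(den, np.finfo(float).tiny, out=den)
        sync = num / den  # (ep, pair, fr), in [0, 1]
    else:
        unit_w = _winsum(unit)
        sync = np.abs(unit_w) / (counts[:, None, None] * n_tap)
    for band in bands.names:
        band_val = sync[:, :, masks[band]].mean(axis=2)
        for p in range(n_pairs):
            pair = f"{epochs.channel_names[ix[p]]}|{epochs.channel_names[iy[p]]}"
            names.append(f"{cfg.measure}:{band}:{pair}")
            bnames.append(band)
            pnames.append(pair)
        cols.append(band_val)
    values = np.hstack(cols)
    return FeatureTable(values, _make_meta(names, cfg.measure, bnames, pnames))


def compute_connectivity_index(
    sync: FeatureTable,
    cfg: ConnectivityIndexConfig | None = None,
    rois: ROIMap | None = None,
    *,
    channel_names: list[str] | None = None,
) -> FeatureTable:
    """Thresholded synchrony counts, region-averaged.

    For every epoch, channel, band and threshold P: the number of *other*
    channels whose pairwise synchrony with this channel is >= P; the counts
    are then channel-averaged within each region.
    """
    cfg = cfg or ConnectivityIndexConfig()
    rois = rois or ROIMap()
    measure = sync.meta["kind"].iloc[0]
    if measure not in ("coherence", "plv"):
        raise ValueError("sync table must hold coherence or plv columns")
    kind = "coh_index" if measure == "coherence" else "plv_index"
    if channel_names is None:
        chs: list[str] = []
        for pair in sync.meta["region"]:
            for ch in pair.split("|"):
                if ch not in chs:
                    chs.append(ch)
        channel_names = chs
    n_ch = len(channel_names)
    ch_pos = {c: i for i, c in enumerate(channel_names)}
    bands_present = list(dict.fromkeys(sync.meta["band"]))
    roi_idx = rois.indices(channel_names)

    n_ep = sync.n_epochs
    cols, names, bnames, rnames, thrs = [], [], [], [], []
    for band in bands_present:
        sub = sync.select(band=band)
        if sub.n_features != n_ch * (n_ch - 1) // 2:
            raise ValueError(
                f"band {band!r}: expected {n_ch * (n_ch - 1) // 2} pairs, got {sub.n_features}"
            )
        # symmetric (ep, ch, ch) synchrony matrix
        mat = np.zeros((n_ep, n_ch, n_ch))
        for j, pair in enumerate(sub.meta["region"]):
            a, b = (ch_pos[c] for c in pair.split("|"))
            mat[:, a, b] = mat[:, b, a] = sub.values[:, j]
        for P in cfg.thresholds:
            count = (mat >= P).sum(axis=2).astype(np.float64)  # diag is 0 < P
            for region in rois.names:
                cols.append(count[:, roi_idx[region]].mean(axis=1))
                names.append(f"{kind}:P{P}:{band}:{region}")
                bnames.append(band)
                rnames.append(region)
                thrs.append(P)
    return FeatureTable(np.column_stack(cols), _make_meta(names, kind, bnames, rnames, thrs))


def region_pair_features(sync: FeatureTable, rois: ROIMap | None = None) -> FeatureTable:
    """Mean synchrony over cross-region channel pairs, per region pair.

    Descriptive characteristics only; not part of the detector input.
    """
    rois = rois or ROIMap()
    measure = sync.meta["kind"].iloc[0]
    region_of = {}
    for region, chs in rois.regions.items():
        for ch in chs:
            region_of[ch] = region
    bands_present = list(dict.fromkeys(sync.meta["band"]))
    rnames_list = rois.names
    cols, names, bnames, rnames = [], [], [], []
    for band in bands_present:
        sub = sync.select(band=band)
        pair_regions = []
        for pair in sub.meta["region"]:
            a, b = pair.split("|")
            ra, rb = region_of.get(a), region_of.get(b)
            if ra is None or rb is None:
                raise ValueError(f"channel pair {pair} has channels outside the region map")
            pair_regions.append((ra, rb))
        for i, r1 in enumerate(rnames_list):
            for r2 in rnames_list[i + 1:]:
                m = np.array([{pr[0], pr[1]} == {r1, r2} for pr in pair_regions])
                if not m.any():
                    raise ValueError(f"no channel pairs span regions {r1!r} and {r2!r}")
                cols.append(sub.values[:, m].mean(axis=1))
                names.append(f"{measure}:{band}:{r1}|{r2}")
                bnames.append(band)
                rnames.append(f"{r1}|{r2}")
    return FeatureTable(np.column_stack(cols), _make_meta(names, measure, bnames, rnames))


def compute_all_features(
    epochs: EpochedRecording,
    bands: BandScheme | None = None,
    rois: ROIMap | None = None,
    cfg: ConnectivityIndexConfig | None = None,
    *,
    bandwidth: float = 8.0,
    adaptive: bool = True,
    include_pairs: bool = True,
) -> dict[str, FeatureTable]:
    """Run the full feature recipe.

    Returns a dict with ``psd``, ``ratios``, ``coh_index``, ``plv_index``,
    ``sda_input`` (their concatenation) and, when ``include_pairs``,
    ``region_pairs`` and ``analysis`` (detector input + region-pair
    coherence/PLV).
    """
    bands = bands or BandScheme()
    rois = rois or ROIMap()
    cfg = cfg or ConnectivityIndexConfig()
    psd = compute_band_roi_psd(epochs, bands, rois, bandwidth=bandwidth, adaptive=adaptive)
    ratios = compute_psd_ratios(psd)
    out = {"psd": psd, "ratios": ratios}
    indices, pairs = [], []
    for measure in ("coherence", "plv"):
        mcfg = ConnectivityIndexConfig(cfg.thresholds, cfg.window_epochs, measure)
        sync = compute_pairwise_sync(epochs, bands, mcfg, bandwidth=bandwidth)
        idx = compute_connectivity_index(sync, mcfg, rois, channel_names=epochs.channel_names)
        out["coh_index" if measure == "coherence" else "plv_index"] = idx
        indices.append(idx)
        if include_pairs:
            pairs.append(region_pair_features(sync, rois))
    out["sda_input"] = FeatureTable.concat([psd, ratios, *indices])
    if include_pairs:
        out["region_pairs"] = FeatureTable.concat(pairs)
        out["analysis"] = FeatureTable.concat([out["sda_input"], *pairs])
    return out
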