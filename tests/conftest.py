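import numpy as np
import pandas as pd
import pytest

from statedetect import FeatureTable, ROIMap, SimRecipe, StateSpec


@pytest.fixture
def small_rois():
    return ROIMap({"front": ["ch0", "ch1"], "back": ["ch2", "ch3"]})


@pytest.fixture
def small_channels():
    return ("ch0", "ch1", "ch2", "ch3")


def three_state_recipe(small_rois, small_channels, seed=2, dur=(60, 80, 70)):
    states = (
        StateSpec(dur[0], {"alpha": 3.0}, {"alpha": 0.7}),
        StateSpec(dur[1], {"beta": 3.0}),
        StateSpec(dur[2], {"delta": 2.5}, {"beta": 0.6}),
    )
    return SimRecipe(states=states, channel_names=small_channels, rois=small_rois, seed=seed)


@pytest.fixture
def recipe3(small_rois, small_channels):
    return three_state_recipe(small_rois, small_channels)


def make_table(values, kind="psd", bands=None, regions=None):
    """Wrap a plain matrix as a FeatureTable with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    meta = pd.DataFrame(
        {
            "kind": kind if isinstance(kind, list) else [kind] * n,
            "band": bands if bands is not None else [None] * n,
            "region": regions if regions is not None else [None] * n,
            "threshold": np.nan,
        },
        index=pd.Index([f"f{i}" for i in range(n)], name="name"),
    )
    return FeatureTable(values, meta)


def write_minimal_edf(path, signals, sfreq, channel_names, phys_max=1000.0):
    """Write a minimal single-record EDF file (16-bit, one data record).

    Enough of the format for round-trip testing of the reader: fixed-width
    ASCII header plus little-endian int16 samples, one record holding the
    whole signal.
    """
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    record_dur = n_samp / sfreq
    header = bytearray()

    def fixed(text, width):
        s = str(text)[:width]
        header.extend(s.ljust(width).encode("ascii"))

    fixed("0", 8)  # version
    fixed("X X X X", 80)  # patient id
    fixed("Startdate X X X X", 80)  # recording id
    fixed("01.01.20", 8)
    fixed("00.00.00", 8)
    fixed(256 + 256 * n_ch, 8)  # header bytes
    fixed("", 44)
    fixed(1, 8)  # number of data records
    fixed(f"{record_dur:g}", 8)
    fixed(n_ch, 4)
    for name in channel_names:
        fixed(name, 16)
    for _ in channel_names:
        fixed("", 80)  # transducer
    for _ in channel_names:
        fixed("uV", 8)
    for _ in channel_names:
        fixed(f"{-phys_max:g}", 8)  # physical min
    for _ in channel_names:
        fixed(f"{phys_max:g}", 8)
    for _ in channel_names:
        fixed(-32768, 8)  # digital min
    for _ in channel_names:
        fixed(32767, 8)
    for _ in channel_names:
        fixed("", 80)  # prefiltering
    for _ in channel_names:
        fixed(n_samp, 8)  # samples per record
    for _ in channel_names:
        fixed("", 32)
    digital = np.clip(signals / phys_max * 32767, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(digital.tobytes())
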