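"""Event-based spike datasets: the SHD HDF5 layout and a synthetic twin.

The Spiking Heidelberg Digits (SHD) benchmark stores spoken digits
(twenty classes: zero-nine in English and German) as 700-channel cochlear
spike trains in HDF5, with per-sample variable-length spike times (s) and
unit indices under ``spikes/times`` and ``spikes/units`` and integer
labels under ``labels``.  This module reads and writes that layout,
performs the channel downsampling used throughout the package (keep every
``factor``-th channel, 0-based, so 700 -> 70 at factor 10), and generates
synthetic datasets with the same structure so the full pipeline runs
without any download.

The synthetic generator emulates multi-channel spoken-digit spike trains:
each class owns a fixed random template of (channel, time) events drawn
as per-channel Poisson processes; a sample is the template with Gaussian
time jitter, per-event dropout, and Poisson background spikes layered on
every channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "SpikeSample",
    "Dataset",
    "SyntheticSpec",
    "load_shd",
    "save_shd",
    "downsample_channels",
    "generate_synthetic",
]


@dataclass
class SpikeSample:
    """One labeled multi-channel spike train (times in seconds, ascending)."""

    times: np.ndarray
    channels: np.ndarray
    label: int
    duration: float
    n_channels: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.channels = np.asarray(self.channels, dtype=np.int64)
        if self.times.shape != self.channels.shape:
            raise ValueError("times and channels must have equal length")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be ascending")
            if self.times[0] < 0 or self.times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")
            if self.channels.min() < 0 or self.channels.max() >= self.n_channels:
                raise ValueError("channel index out of range")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Dataset:
    """A labeled split of spike samples sharing one channel count."""

    samples: list[SpikeSample]
    n_classes: int
    split: str = "train"

    def __post_init__(self) -> None:
        if self.samples:
            n_ch = self.samples[0].n_channels
            for s in self.samples:
                if s.n_channels != n_ch:
                    raise ValueError("all samples must share n_channels")
                if not 0 <= s.label < self.n_classes:
                    raise ValueError(
                        f"label {s.label} outside the {self.n_classes}-class range"
                    )

    @property
    def n_channels(self) -> int:
        return self.samples[0].n_channels if self.samples else 0

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.samples], dtype=np.int64)


def load_shd(
    path,
    n_classes: int = 20,
    n_channels: int = 700,
    duration: float | None = None,
    split: str = "train",
) -> Dataset:
    """Read a dataset stored in the SHD HDF5 layout.

    Expects ``spikes/times`` and ``spikes/units`` (variable-length arrays
    per sample) and ``labels``.  A missing key raises a format error
    naming it.  Each sample's duration is its last spike time (or
    ``duration`` if given, which also bounds validation).
    """
    with h5py.File(path, "r") as fh:
        for key in ("spikes/times", "spikes/units", "labels"):
            if key not in fh:
                raise KeyError(f"not an SHD-layout file: missing dataset '{key}'")
        times = fh["spikes/times"][:]
        units = fh["spikes/units"][:]
        labels = fh["labels"][:]
    samples = []
    for t, u, lab in zip(times, units, labels):
        t = np.asarray(t, dtype=np.float64)
        order = np.argsort(t, kind="stable")
        t = t[order]
        u = np.asarray(u, dtype=np.int64)[order]
        dur = duration if duration is not None else (float(t[-1]) if t.size else 1.0)
        samples.append(
            SpikeSample(times=t, channels=u, label=int(lab), duration=dur, n_channels=n_channels)
        )
    return Dataset(samples=samples, n_classes=n_classes, split=split)


def save_shd(dataset: Dataset, path) -> None:
    """Write a dataset in the SHD HDF5 layout (fixture writer)."""
    vlen_f = h5py.special_dtype(vlen=np.dtype("float64"))
    vlen_i = h5py.special_dtype(vlen=np.dtype("int64"))
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("spikes")
        n = len(dataset)
        dt = grp.create_dataset("times", (n,), dtype=vlen_f)
        du = grp.create_dataset("units", (n,), dtype=vlen_i)
        for i, s in enumerate(dataset.samples):
            dt[i] = s.times
            du[i] = s.channels
        fh.create_dataset("labels", data=dataset.labels)


def downsample_channels(dataset: Dataset, factor: int) -> Dataset:
    """Keep every ``factor``-th channel starting at channel 0.

    Spikes on a kept channel ``c`` are remapped to ``c // factor``; spikes
    on all other channels are dropped.  The new channel count is
    ``ceil(n_channels / factor)``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if not dataset.samples:
        return dataset
    n_ch = dataset.n_channels
    if factor > n_ch:
        raise ValueError(f"factor {factor} exceeds channel count {n_ch}")
    new_n = -(-n_ch // factor)
    new_samples = []
    for s in dataset.samples:
        keep = (s.channels % factor) == 0
        new_samples.append(
            SpikeSample(
                times=s.times[keep],
                channels=s.channels[keep] // factor,
                label=s.label,
                duration=s.duration,
                n_channels=new_n,
            )
        )
    return Dataset(samples=new_samples, n_classes=dataset.n_classes, split=dataset.split)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic spoken-digit stand-in.

    Defaults: 4 classes, 70 channels, 40 samples per class, 300 ms
    samples.  Template events are per-channel Poisson at ``template_rate``
    Hz (20 Hz, matching the per-channel event rates of active cochlear
    channels in spoken-digit data); samples perturb the template with
    20 ms Gaussian jitter, 20 % event dropout, and 5 Hz per-channel
    Poisson background — noise levels chosen to leave class structure
    recoverable but not trivially so.
    """

    n_classes: int = 4
    n_channels: int = 70
    n_samples_per_class: int = 40
    n_test_per_class: int = 15
    duration: float = 0.3
    template_rate: float = 20.0
    jitter_sd: float = 0.02
    event_dropout: float = 0.2
    background_rate: float = 5.0
    seed: int = 0


def generate_synthetic(
    n_classes: int = 4,
    n_channels: int = 70,
    n_samples_per_class: int = 40,
    duration: float = 0.3,
    jitter_sd: float = 0.02,
    background_rate: float = 5.0,
    seed: int = 0,
    template_rate: float = 20.0,
    event_dropout: float = 0.2,
    split: str = "train",
    template_seed: int | None = None,
) -> Dataset:
    """Generate a labeled synthetic spike dataset.

    Class templates are drawn from ``template_seed`` (default: ``seed``),
    so train and test splits of the same task share templates by passing
    the same ``template_seed`` with different ``seed`` values.  Samples of
    each class are the template with Gaussian time jitter (sd
    ``jitter_sd`` s, clipped to the sample window), independent per-event
    dropout, and uniform-time Poisson background spikes on every channel.
    Deterministic per ``(seed, template_seed)``.
    """
    if min(n_classes, n_channels, n_samples_per_class) < 1 or duration <= 0:
        raise ValueError("all counts and the duration must be positive")
    t_rng = np.random.default_rng(seed if template_seed is None else template_seed)
    templates = []
    for _ in range(n_classes):
        counts = t_rng.poisson(template_rate * duration, size=n_channels)
        ch = np.repeat(np.arange(n_channels), counts)
        tt = t_rng.uniform(0.0, duration, size=ch.size)
        templates.append((tt, ch))

    rng = np.random.default_rng(seed)
    samples = []
    for label in range(n_classes):
        tt, ch = templates[label]
        for _ in range(n_samples_per_class):
            keep = rng.random(tt.size) >= event_dropout
            times = tt[keep] + rng.normal(0.0, jitter_sd, size=int(keep.sum()))
            np.clip(times, 0.0, duration, out=times)
            chans = ch[keep]
            bg_counts = rng.poisson(background_rate * duration, size=n_channels)
            bg_ch = np.repeat(np.arange(n_channels), bg_counts)
            bg_t = rng.uniform(0.0, duration, size=bg_ch.size)
            all_t = np.concatenate([times, bg_t])
            all_c = np.concatenate([chans, bg_ch])
            order = np.argsort(all_t, kind="stable")
            samples.append(
                SpikeSample(
                    times=all_t[order],
                    channels=all_c[order],
                    label=label,
                    duration=duration,
                    n_channels=n_channels,
                )
            )
    return Dataset(samples=samples, n_classes=n_classes, split=split)


def from_spec(spec: SyntheticSpec, split: str = "train", seed_offset: int = 0) -> Dataset:
    """Instantiate a split from a :class:`SyntheticSpec`.

    The template seed is the spec seed, so different ``seed_offset``
    values (e.g. train vs test) draw different noise around the same
    class templates.  The test split holds ``n_test_per_class`` samples
    per class and uses a disjoint noise seed.
    """
    if split == "test" and seed_offset == 0:
        seed_offset = 104729  # keep test noise disjoint from any train seed
    return generate_synthetic(
        n_classes=spec.n_classes,
        n_channels=spec.n_channels,
        n_samples_per_class=(
            spec.n_test_per_class if split == "test" else spec.n_samples_per_class
        ),
        duration=spec.duration,
        jitter_sd=spec.jitter_sd,
        background_rate=spec.background_rate,
        seed=spec.seed + seed_offset,
        template_rate=spec.template_rate,
        event_dropout=spec.event_dropout,
        split=split,
        template_seed=spec.seed,
    )
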