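"""Spike encoders and synthetic fixtures.

Converts intensity images into Poisson spike streams, tones into
cochlea-style phase-locked spike streams, and decodes those via inter-spike
interval (ISI) histogramming into the auditory input representation.  Also
generates the synthetic multi-class digit-like dataset used throughout the
tests, so the package is exercisable without any downloads, plus optional
readers for IDX image files and jAER AEDAT recordings.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .events import EventStream

__all__ = [
    "ToneSpec",
    "IsiHistogramConfig",
    "image_to_poisson",
    "downsample_events",
    "synthetic_cochlea",
    "isi_encode",
    "audio_rate_vectors",
    "equal_tempered_frequency",
    "make_toy_digits",
    "mix_streams",
    "tone_for_class",
    "TONE_TABLE",
    "read_idx",
    "read_aedat",
]


@dataclass(frozen=True)
class ToneSpec:
    """A pure tone: note label, frequency (Hz) and duration (s)."""

    name: str
    freq_hz: float
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.freq_hz <= 0:
            raise ValueError("frequency must be positive")


def equal_tempered_frequency(semitones_from_a4: int) -> float:
    """Equal-tempered frequency in Hz, rounded to 0.1 Hz for display."""
    return round(440.0 * 2.0 ** (semitones_from_a4 / 12.0), 1)


# A-minor harmonic scale A4..C6 paired with digit classes 0..9.
_TONE_SEMITONES = [("A4", 0), ("B4", 2), ("C5", 3), ("D5", 5), ("E5", 7),
                   ("F5", 8), ("G5#", 11), ("A5", 12), ("B5", 14), ("C6", 15)]
TONE_TABLE: List[ToneSpec] = [
    ToneSpec(name, equal_tempered_frequency(s)) for name, s in _TONE_SEMITONES]


def tone_for_class(digit: int, duration_s: float = 1.0) -> ToneSpec:
    """The tone paired with a digit class (class k -> k-th scale tone)."""
    base = TONE_TABLE[digit]
    return ToneSpec(base.name, base.freq_hz, duration_s)


@dataclass(frozen=True)
class IsiHistogramConfig:
    """Logarithmic ISI binning (defaults cover 350-1200 Hz pure tones)."""

    n_bins: int = 100
    isi_min_ms: float = 0.833
    isi_max_ms: float = 2.85

    def __post_init__(self) -> None:
        if not 0 < self.isi_min_ms < self.isi_max_ms:
            raise ValueError("require 0 < isi_min_ms < isi_max_ms")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


def image_to_poisson(image, total_rate_hz: float, duration_s: float,
                     seed: int = 0, layer: str = "visual_input") -> EventStream:
    """Encode an intensity image as independent per-pixel Poisson trains.

    Per-pixel rate is proportional to intensity, scaled so the summed rate
    over the image equals ``total_rate_hz``.  Spike times are drawn by
    exponential inter-arrival sampling.
    """
    img = np.asarray(image, dtype=float).ravel()
    total = img.sum()
    if total <= 0:
        raise ValueError("cannot encode an all-zero image (rate undefined)")
    if total_rate_hz <= 0:
        raise ValueError("total rate must be positive")
    rates = total_rate_hz * img / total
    rng = np.random.default_rng(seed)
    times, units = [], []
    for px in np.flatnonzero(rates):
        r = rates[px]
        t = rng.exponential(1.0 / r)
        while t < duration_s:
            times.append(int(round(t * 1e6)))
            units.append(px)
            t += rng.exponential(1.0 / r)
    return EventStream.from_unsorted(np.array(times, np.int64),
                                     np.array(units, np.int64), layer)


def downsample_events(stream: EventStream, in_width: int = 128,
                      out_width: int = 28,
                      layer: Optional[str] = None) -> EventStream:
    """Spatially down-sample pixel-addressed events.

    Unit addresses encode ``y * in_width + x``; pixel (x, y) maps to
    (floor(x * out/in), floor(y * out/in)).  Timestamps are unchanged and
    every event is kept (polarity, if any, was dropped upstream).
    """
    x = stream.unit % in_width
    y = stream.unit // in_width
    if len(stream) and (y.max() >= in_width):
        raise ValueError("event address outside the input resolution")
    xs = x * out_width // in_width
    ys = y * out_width // in_width
    layers = stream.layer if layer is None else layer
    return EventStream(stream.t_us, ys * out_width + xs, layers)


def synthetic_cochlea(tone: ToneSpec, n_channels: int = 64,
                      jitter_sd_s: float = 5e-5, seed: int = 0,
                      tuning_width: float = 1.5,
                      f_lo: float = 350.0, f_hi: float = 1200.0,
                      layer: str = "cochlea") -> EventStream:
    """Phase-locked cochlea model: one spike per waveform period.

    Channels are tuned logarithmically between ``f_lo`` and ``f_hi``;
    channels within about ``tuning_width`` channel widths of the tone's
    best frequency respond, each emitting one spike per period with
    Gaussian timing jitter, phase-aligned across channels (the device's
    phase-locking).  The mapping of tones onto channels is a model choice;
    only the ISI structure matters downstream.
    """
    if tone.duration_s <= 0:
        return EventStream((), (), layer)
    rng = np.random.default_rng(seed)
    centers = np.geomspace(f_lo, f_hi, n_channels)
    best = np.argmin(np.abs(np.log(centers) - np.log(tone.freq_hz)))
    dist = np.abs(np.arange(n_channels) - best)
    active = np.flatnonzero(dist <= np.ceil(2 * tuning_width))
    period = 1.0 / tone.freq_hz
    n_cycles = int(np.floor(tone.duration_s / period))
    times, units = [], []
    base = (np.arange(1, n_cycles + 1)) * period
    for ch in active:
        # spike probability per cycle falls off with tuning distance
        p = np.exp(-0.5 * (dist[ch] / tuning_width) ** 2)
        keep = rng.random(n_cycles) < p
        t = base[keep] + rng.normal(0.0, jitter_sd_s, keep.sum())
        t = t[(t >= 0) & (t < tone.duration_s)]
        times.append(np.round(t * 1e6).astype(np.int64))
        units.append(np.full(t.size, ch, np.int64))
    if not times:
        return EventStream((), (), layer)
    return EventStream.from_unsorted(np.concatenate(times),
                                     np.concatenate(units), layer)


def isi_encode(stream: EventStream, config: IsiHistogramConfig = IsiHistogramConfig(),
               layer: str = "auditory_input") -> EventStream:
    """Histogram successive inter-spike intervals into log-spaced bin units.

    ISIs are measured on the stream pooled over all channels; each ISI
    within [isi_min, isi_max] emits one event (at the later spike's time)
    to the unit of its logarithmic bin; out-of-range ISIs are dropped.
    """
    if len(stream) < 2:
        return EventStream((), (), layer)
    isi_ms = np.diff(stream.t_us) * 1e-3
    lo, hi = config.isi_min_ms, config.isi_max_ms
    ok = (isi_ms >= lo) & (isi_ms <= hi)
    scale = config.n_bins / np.log(hi / lo)
    bins = np.floor(np.log(isi_ms[ok] / lo) * scale).astype(np.int64)
    bins = np.minimum(bins, config.n_bins - 1)  # upper edge closes the range
    return EventStream(stream.t_us[1:][ok], bins, layer)


def audio_rate_vectors(stream: EventStream, n_units: int, duration_s: float,
                       bin_width_s: float = 0.1,
                       stride_s: float = 0.03) -> np.ndarray:
    """Sliding-window rate vectors over ISI-unit events, for RBM training.

    Windows of ``bin_width_s`` evaluated every ``stride_s``; each window's
    per-unit rate is normalized to [0, 1] by the window maximum.  Returns
    an array of shape (n_windows, n_units); empty if the stream is shorter
    than one window.
    """
    if duration_s < bin_width_s:
        return np.zeros((0, n_units))
    n_win = int(np.floor((duration_s - bin_width_s) / stride_s)) + 1
    out = np.zeros((n_win, n_units))
    for k in range(n_win):
        t0 = int(round(k * stride_s * 1e6))
        t1 = t0 + int(round(bin_width_s * 1e6))
        win = stream.in_window(t0, t1)
        counts = win.counts(n_units).astype(float)
        m = counts.max()
        if m > 0:
            out[k] = counts / m
    return out


# ---------------------------------------------------------------------------
# synthetic digit-like dataset

def _glyph_strokes(cls: int) -> List[Tuple[float, float, float, float]]:
    """Stroke endpoints (x0, y0, x1, y1) in the unit square per class.

    The glyphs use distinct stroke orientations per class; ambiguous-input
    experiments create confusion by mixing the spike streams of two
    classes, not by glyph similarity.
    """
    g = {
        0: [(.2, .15, .8, .15), (.2, .85, .8, .85), (.2, .15, .2, .85),
            (.8, .15, .8, .85)],                              # ring
        1: [(.5, .1, .5, .9), (.3, .3, .5, .1)],              # one
        2: [(.2, .15, .8, .15), (.8, .15, .2, .85),
            (.2, .85, .8, .85)],                              # zed
        3: [(.2, .15, .5, .85), (.8, .15, .5, .85)],          # vee
        4: [(.3, .15, .3, .5), (.3, .5, .7, .5), (.7, .15, .7, .85)],
        5: [(.3, .2, .7, .2), (.7, .2, .4, .85)],             # seven
        6: [(.3, .15, .7, .85), (.7, .15, .3, .85)],          # cross
        7: [(.3, .15, .3, .85), (.3, .85, .7, .85)],          # ell
        8: [(.5, .2, .5, .8), (.2, .5, .8, .5)],              # plus
        9: [(.3, .15, .3, .85), (.7, .15, .7, .85), (.3, .5, .7, .5)],
    }
    return g[cls]


def _render_glyph(cls: int, size: int) -> np.ndarray:
    from skimage.draw import line
    img = np.zeros((size, size))
    for x0, y0, x1, y1 in _glyph_strokes(cls):
        rr, cc = line(int(round(y0 * (size - 1))), int(round(x0 * (size - 1))),
                      int(round(y1 * (size - 1))), int(round(x1 * (size - 1))))
        img[rr, cc] = 1.0
    img = ndimage.gaussian_filter(img, 0.6)
    return np.clip(img / img.max(), 0.0, 1.0)


def _augment(img: np.ndarray, shift_xy, angle_deg: float,
             scale: float) -> np.ndarray:
    """Affine augmentation about the image center."""
    size = img.shape[0]
    c = (size - 1) / 2.0
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    mat = rot / scale  # output->input mapping
    center = np.array([c, c])
    offset = center - mat @ (center + np.array(shift_xy[::-1]))
    out = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                   mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def make_toy_digits(n_classes: int = 4, size: int = 16,
                    samples_per_class: int = 200, augment: bool = True,
                    seed: int = 0):
    """Labeled synthetic digit-like dataset (MNIST stand-in).

    Renders one stroke glyph prototype per class and, when ``augment`` is
    on, applies random translations (+-15% of the image size), rotations
    (+-3 degrees) and scalings (+-10%) -- the augmentation ranges used for
    robust training.  Returns (images, labels, meta): flattened images in
    [0, 1] of shape (n, size*size), integer class labels, and the drawn
    augmentation parameters.
    """
    if n_classes < 2 or n_classes > 10:
        raise ValueError("n_classes must be in [2, 10]")
    if size < 8:
        raise ValueError("image too small to render glyphs (< 8x8)")
    rng = np.random.default_rng(seed)
    protos = [_render_glyph(c, size) for c in range(n_classes)]
    n = n_classes * samples_per_class
    images = np.empty((n, size * size))
    labels = np.empty(n, dtype=int)
    meta = {"shift": np.zeros((n, 2)), "angle": np.zeros(n),
            "scale": np.ones(n)}
    i = 0
    for c in range(n_classes):
        for _ in range(samples_per_class):
            if augment:
                shift = rng.uniform(-0.15, 0.15, 2) * size
                angle = rng.uniform(-3.0, 3.0)
                scale = rng.uniform(0.9, 1.1)
                img = _augment(protos[c], shift, angle, scale)
            else:
                shift, angle, scale = np.zeros(2), 0.0, 1.0
                img = protos[c]
            images[i] = img.ravel()
            labels[i] = c
            meta["shift"][i] = shift
            meta["angle"][i] = angle
            meta["scale"][i] = scale
            i += 1
    return images, labels, meta


def mix_streams(stream_a: EventStream, stream_b: EventStream,
                share_a: float, seed: int = 0) -> EventStream:
    """Mix two streams so expected spike shares are share_a : 1 - share_a.

    Each stream is thinned by an independent Bernoulli keep; the stream on
    the abundant side is thinned, the other kept whole, so as many spikes
    as possible survive.  The result is time-sorted (ties: stream a first).
    """
    if not 0.0 <= share_a <= 1.0:
        raise ValueError("share_a must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    na, nb = len(stream_a), len(stream_b)
    qa, qb = 1.0, 1.0
    if share_a == 0.0:
        qa = 0.0
    elif share_a == 1.0:
        qb = 0.0
    elif na > 0 and nb > 0:
        # target ratio qa*na : qb*nb = share_a : 1-share_a
        qa = share_a * nb / ((1.0 - share_a) * na)
        if qa > 1.0:
            qb = 1.0 / qa
            qa = 1.0
    keep_a = rng.random(na) < qa
    keep_b = rng.random(nb) < qb
    a = EventStream(stream_a.t_us[keep_a], stream_a.unit[keep_a],
                    stream_a.layer[keep_a])
    b = EventStream(stream_b.t_us[keep_b], stream_b.unit[keep_b],
                    stream_b.layer[keep_b])
    return EventStream.merge([a, b])


# ---------------------------------------------------------------------------
# optional external-format readers

def read_idx(path) -> np.ndarray:
    """Read an IDX file (the standard MNIST container format)."""
    data = Path(path).read_bytes()
    if data[0] != 0 or data[1] != 0:
        raise ValueError("not an IDX file")
    dtype = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
             0x0D: ">f4", 0x0E: ">f8"}[data[2]]
    ndim = data[3]
    dims = struct.unpack(f">{ndim}I", data[4:4 + 4 * ndim])
    arr = np.frombuffer(data, dtype=dtype, offset=4 + 4 * ndim)
    return arr.reshape(dims)


def read_aedat(path, layer: str = "dvs") -> EventStream:
    """Read a jAER AEDAT recording (DVS128 dialect).

    Header lines start with '#'; records are big-endian 4-byte address +
    4-byte timestamp (microseconds).  DVS128 addresses carry x in bits
    1-7, y in bits 8-14 and polarity in bit 0; polarity is dropped and the
    unit becomes y*128 + x.
    """
    raw = Path(path).read_bytes()
    pos = 0
    while pos < len(raw) and raw[pos:pos + 1] == b"#":
        pos = raw.index(b"\n", pos) + 1
    body = raw[pos:]
    n = len(body) // 8
    rec = np.frombuffer(body[:n * 8], dtype=">u4").reshape(-1, 2)
    addr, ts = rec[:, 0].astype(np.int64), rec[:, 1].astype(np.int64)
    x = (addr >> 1) & 0x7F
    y = (addr >> 8) & 0x7F
    ts = ts - ts.min() if n else ts
    return EventStream.from_unsorted(ts, y * 128 + x, layer)
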