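"""Address-event containers: timestamped spikes with a layer and unit address.

Timestamps are integer microseconds (the address-event convention), which
keeps merged streams exactly ordered and avoids floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import numpy as np

__all__ = ["SpikeEvent", "EventStream"]


@dataclass(frozen=True)
class SpikeEvent:
    t_us: int
    layer: str
    unit: int


class EventStream:
    """Time-ordered sequence of address events.

    Stored as parallel arrays ``t_us`` (int64), ``unit`` (int64) and
    ``layer`` (str).  Order must be non-decreasing in time; events with
    equal timestamps keep their insertion order (stable sort everywhere).
    """

    def __init__(self, t_us=(), unit=(), layer=()):
        self.t_us = np.asarray(t_us, dtype=np.int64)
        self.unit = np.asarray(unit, dtype=np.int64)
        if isinstance(layer, str):
            layer = [layer] * self.t_us.size
        self.layer = np.asarray(layer, dtype=object)
        if not (self.t_us.size == self.unit.size == self.layer.size):
            raise ValueError("t_us/unit/layer arrays must have equal length")
        if self.t_us.size and np.any(np.diff(self.t_us) < 0):
            raise ValueError("event timestamps must be non-decreasing")
        if self.t_us.size and np.any(self.t_us < 0):
            raise ValueError("event timestamps must be non-negative")

    def __len__(self) -> int:
        return int(self.t_us.size)

    def __iter__(self):
        for t, l, u in zip(self.t_us, self.layer, self.unit):
            yield SpikeEvent(int(t), str(l), int(u))

    def __eq__(self, other) -> bool:
        return (isinstance(other, EventStream)
                and np.array_equal(self.t_us, other.t_us)
                and np.array_equal(self.unit, other.unit)
                and np.array_equal(self.layer, other.layer))

    @classmethod
    def from_events(cls, events: Iterable[SpikeEvent]) -> "EventStream":
        ev = list(events)
        return cls([e.t_us for e in ev], [e.unit for e in ev],
                   [e.layer for e in ev])

    @classmethod
    def from_unsorted(cls, t_us, unit, layer) -> "EventStream":
        """Build a stream, stably sorting by timestamp."""
        t = np.asarray(t_us, dtype=np.int64)
        u = np.asarray(unit, dtype=np.int64)
        if isinstance(layer, str):
            layer = [layer] * t.size
        l = np.asarray(layer, dtype=object)
        order = np.argsort(t, kind="stable")
        return cls(t[order], u[order], l[order])

    @classmethod
    def merge(cls, streams: List["EventStream"]) -> "EventStream":
        """Time-ordered merge; ties keep the order of the input list."""
        if not streams:
            return cls()
        t = np.concatenate([s.t_us for s in streams])
        u = np.concatenate([s.unit for s in streams])
        l = np.concatenate([s.layer for s in streams])
        order = np.argsort(t, kind="stable")
        return cls(t[order], u[order], l[order])

    def for_layer(self, name: str) -> "EventStream":
        mask = self.layer == name
        return EventStream(self.t_us[mask], self.unit[mask], self.layer[mask])

    def in_window(self, t0_us: int, t1_us: int) -> "EventStream":
        mask = (self.t_us >= t0_us) & (self.t_us < t1_us)
        return EventStream(self.t_us[mask], self.unit[mask], self.layer[mask])

    def counts(self, n_units: int) -> np.ndarray:
        return np.bincount(self.unit, minlength=n_units).astype(int)

    def __repr__(self) -> str:
        layers = sorted(set(self.layer.tolist()))
        return f"EventStream({len(self)} events, layers={layers})"
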