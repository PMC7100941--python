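"""Shared domain types and small utilities used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

#: Behavioral state labels, in flagging-precedence order.
STATES = ("forward", "reverse", "pause", "turn")
MISSING = "missing"


@dataclass
class StimulusEvent:
    """A single targeted laser pulse.

    Attributes
    ----------
    time_s : float
        Onset time, seconds from the start of the recording.
    frame : int
        Frame index at (or immediately before) onset.
    target_mm : tuple[float, float]
        Target position in world coordinates (mm), normally on the worm's
        head at the moment of targeting.
    current_mA : float
        Laser diode drive current.
    duration_ms : float
        Pulse duration.
    lens_mm : float
        Focal length of the focusing lens.
    """

    time_s: float
    frame: int
    target_mm: tuple[float, float]
    current_mA: float = 75.0
    duration_ms: float = 100.0
    lens_mm: float = 75.0

    def __post_init__(self) -> None:
        if self.current_mA <= 0:
            raise ValueError(f"laser current must be > 0, got {self.current_mA}")
        if self.duration_ms <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.duration_ms}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_mm"] = list(self.target_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEvent":
        d = dict(d)
        d["target_mm"] = tuple(d["target_mm"])
        return cls(**d)


def segments_from_labels(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Run-length encode a label sequence.

    Returns a list of ``(label, start, stop)`` with ``stop`` exclusive;
    segments tile ``range(len(labels))``.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(str(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def arc_length_resample(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to `n` points uniformly spaced in arc length."""
    points = np.asarray(points, dtype=float)
    d = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(d)))
    if s[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack(
        [np.interp(target, s, points[:, k]) for k in range(points.shape[1])]
    )


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())
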