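"""Four-state behavioral flagging, minimum-bout enforcement, and
stimulus-aligned population summaries.

Frames are labelled forward / reverse / pause / turn from the cleaned
phase velocity and the skeleton geometry: a deep (omega) turn collapses
the head-tail distance below half its average, a pause is a near-zero
undulation rate (|ω| < 0.02 cycles/s), and otherwise the sign of ω names
the direction.  Turn is tested first because coiled frames have no
reliable phase.  Bouts shorter than 0.25 s are absorbed into their
surroundings, shortest first, until every interior bout is at least the
minimum — worms do not flicker between states at the frame scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wormetho.core import MISSING, STATES, StimulusEvent, segments_from_labels
from wormetho.kinematics import PAUSE_OMEGA_THRESHOLD

MIN_SEGMENT_S = 0.25
TURN_HEADTAIL_FACTOR = 0.5


@dataclass
class Ethogram:
    states: np.ndarray  # (n,) str, one of STATES or 'missing'
    frame_rate_hz: float
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        if self.timestamps is None:
            self.timestamps = np.arange(len(self.states)) / self.frame_rate_hz

    @property
    def segments(self) -> pd.DataFrame:
        rows = []
        for label, a, b in segments_from_labels(self.states):
            rows.append({
                "state": label,
                "start_frame": a,
                "end_frame": b - 1,
                "t_start": self.timestamps[a],
                "t_end": self.timestamps[b - 1] + 1.0 / self.frame_rate_hz,
                "duration_s": (b - a) / self.frame_rate_hz,
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "frame": np.arange(len(self.states)),
            "time_s": self.timestamps,
            "state": self.states,
        }).to_csv(path, index=False)


def average_head_tail(head_tail: np.ndarray) -> float:
    """Robust per-recording average head-tail distance.

    Median over non-turn-candidate frames: the overall median is itself
    robust to a minority of coiled frames, so frames below half of it are
    excluded and the median of the remainder is the average used by the
    turn rule.
    """
    ht = np.asarray(head_tail, dtype=float)
    ht = ht[~np.isnan(ht)]
    if ht.size == 0:
        raise ValueError("no head-tail distances available")
    rough = np.median(ht)
    keep = ht >= TURN_HEADTAIL_FACTOR * rough
    return float(np.median(ht[keep])) if keep.any() else float(rough)


def flag_states(
    omega: np.ndarray,
    head_tail: np.ndarray,
    avg_head_tail: float | None = None,
    pause_threshold: float = PAUSE_OMEGA_THRESHOLD,
    turn_factor: float = TURN_HEADTAIL_FACTOR,
) -> np.ndarray:
    """Raw per-frame states from cleaned ω and head-tail distances.

    Precedence: turn (head-tail < 0.5 × average) over pause
    (|ω| < 0.02 cycles/s) over forward/reverse (sign of ω).  Frames whose
    ω was removed and that are not turns are 'missing'.
    """
    omega = np.asarray(omega, dtype=float)
    ht = np.asarray(head_tail, dtype=float)
    if len(omega) != len(ht):
        raise ValueError("omega and head-tail series must be aligned")
    if avg_head_tail is None:
        avg_head_tail = average_head_tail(ht)
    n = len(omega)
    out = np.empty(n, dtype=object)
    for i in range(n):
        if not np.isnan(ht[i]) and ht[i] < turn_factor * avg_head_tail:
            out[i] = "turn"
        elif np.isnan(omega[i]):
            out[i] = MISSING
        elif abs(omega[i]) < pause_threshold:
            out[i] = "pause"
        elif omega[i] > 0:
            out[i] = "forward"
        else:
            out[i] = "reverse"
    return out


def enforce_min_duration(
    raw_states: np.ndarray,
    frame_rate_hz: float,
    min_duration_s: float = MIN_SEGMENT_S,
    timestamps: np.ndarray | None = None,
) -> Ethogram:
    """Absorb sub-minimum bouts into the surrounding behavior.

    Iteratively, shortest offending interior segment first (ties: the
    earliest): if both neighbors share a state the segment takes it;
    otherwise it merges into the longer neighbor (ties: the preceding
    one).  Segments touching the recording boundary are exempt — their
    true extent is unobserved.  The procedure is deterministic, never
    invents a state label, and terminates because every step reduces the
    segment count.
    """
    states = np.asarray(raw_states, dtype=object).copy()
    min_frames = int(round(min_duration_s * frame_rate_hz))
    while True:
        segs = segments_from_labels(states)
        if len(segs) <= 2:
            break
        interior = [
            (b - a, idx)
            for idx, (label, a, b) in enumerate(segs)
            if idx not in (0, len(segs) - 1) and (b - a) < min_frames
        ]
        if not interior:
            break
        _, idx = min(interior)
        label, a, b = segs[idx]
        prev_label, pa, pb = segs[idx - 1]
        next_label, na, nb = segs[idx + 1]
        if prev_label == next_label:
            states[a:b] = prev_label
        elif (pb - pa) >= (nb - na):
            states[a:b] = prev_label
        else:
            states[a:b] = next_label
    return Ethogram(states=states, frame_rate_hz=frame_rate_hz,
                    timestamps=timestamps)


def escape_distance(
    centroid_mm: np.ndarray,
    timestamps: np.ndarray,
    event: StimulusEvent,
) -> np.ndarray:
    """Radial distance from the centroid position at stimulus time.

    Defined for t >= the event time (NaN before).  Zero at the stimulus by
    construction; nonnegative always; may return toward zero if the worm
    loops back.
    """
    c = np.asarray(centroid_mm, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if not (t[0] - 1e-9 <= event.time_s <= t[-1] + 1e-9):
        raise ValueError(
            f"stimulus at {event.time_s} s lies outside the recording "
            f"({t[0]}-{t[-1]} s)")
    i0 = int(np.argmin(np.abs(t - event.time_s)))
    d = np.linalg.norm(c - c[i0], axis=1)
    d[t < t[i0]] = np.nan
    return d


# ---------------------------------------------------------------------------
# population summaries


@dataclass
class AnimalSeries:
    """One animal's analyzed recording, ready for population alignment."""

    timestamps: np.ndarray
    states: np.ndarray
    omega: np.ndarray
    centroid_mm: np.ndarray
    events: list[StimulusEvent] = field(default_factory=list)
    label: str = ""


@dataclass
class PopulationSummary:
    t_rel_s: np.ndarray
    fractions: dict[str, np.ndarray]  # state -> fraction of non-missing
    mean_omega: np.ndarray
    sem_omega: np.ndarray
    mean_escape_mm: np.ndarray
    sem_escape_mm: np.ndarray
    n: np.ndarray  # animals contributing per time point
    baseline: dict = field(default_factory=dict)
    label: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_rel_s": self.t_rel_s})
        for s in STATES:
            df[f"frac_{s}"] = self.fractions[s]
        df["mean_omega"] = self.mean_omega
        df["sem_omega"] = self.sem_omega
        df["mean_escape_mm"] = self.mean_escape_mm
        df["sem_escape_mm"] = self.sem_escape_mm
        df["n"] = self.n
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _sem(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return np.nan
    if v.size == 1:
        return 0.0
    return float(v.std(ddof=1) / np.sqrt(v.size))


def align_to_stimulus(
    animals: list[AnimalSeries],
    window_s: tuple[float, float] = (-10.0, 30.0),
    grid_step_s: float = 0.05,
) -> PopulationSummary:
    """Stimulus-aligned population summary on a common relative-time grid.

    Every (animal, event) pair contributes one trace; state, ω and escape
    distance are sampled at the nearest frame.  State fractions are over
    the non-missing animals at each time point and sum to one there; means
    carry the standard error (std/√n).  Pre-stimulus baselines (means over
    the pre-window) are reported alongside.
    """
    if not animals:
        raise ValueError("empty cohort")
    pre, post = window_s
    if post <= pre:
        raise ValueError("empty alignment window")
    grid = np.arange(pre, post + grid_step_s / 2, grid_step_s)
    traces_state, traces_omega, traces_esc = [], [], []
    for an in animals:
        for ev in an.events:
            t_rel = an.timestamps - ev.time_s
            esc = escape_distance(an.centroid_mm, an.timestamps, ev)
            idx = np.clip(
                np.searchsorted(t_rel, grid), 0, len(t_rel) - 1)
            # snap to nearest frame
            idx = np.where(
                (idx > 0)
                & (np.abs(t_rel[idx - 1] - grid)
                   < np.abs(t_rel[np.minimum(idx, len(t_rel) - 1)] - grid)),
                idx - 1, idx)
            inside = (grid >= t_rel[0] - grid_step_s) & (
                grid <= t_rel[-1] + grid_step_s)
            st = np.where(inside, an.states[idx], None)
            om = np.where(inside, an.omega[idx], np.nan)
            es = np.where(inside, esc[idx], np.nan)
            traces_state.append(st)
            traces_omega.append(om)
            traces_esc.append(es)
    S = np.array(traces_state, dtype=object)
    O = np.array(traces_omega, dtype=float)
    E = np.array(traces_esc, dtype=float)

    m = len(grid)
    fractions = {s: np.full(m, np.nan) for s in STATES}
    n_arr = np.zeros(m, dtype=int)
    mean_o = np.full(m, np.nan)
    sem_o = np.full(m, np.nan)
    mean_e = np.full(m, np.nan)
    sem_e = np.full(m, np.nan)
    for j in range(m):
        col = S[:, j]
        present = np.array([s in STATES for s in col])
        n_j = int(present.sum())
        n_arr[j] = n_j
        if n_j:
            for s in STATES:
                fractions[s][j] = np.sum(col[present] == s) / n_j
        o = O[:, j]
        if (~np.isnan(o)).any():
            mean_o[j] = np.nanmean(o)
            sem_o[j] = _sem(o)
        e = E[:, j]
        if (~np.isnan(e)).any():
            mean_e[j] = np.nanmean(e)
            sem_e[j] = _sem(e)

    pre_mask = grid < 0
    baseline = {}
    with np.errstate(invalid="ignore"):
        for s in STATES:
            baseline[f"frac_{s}"] = float(np.nanmean(fractions[s][pre_mask]))
        baseline["mean_omega"] = float(np.nanmean(mean_o[pre_mask]))
    return PopulationSummary(
        t_rel_s=grid, fractions=fractions, mean_omega=mean_o, sem_omega=sem_o,
        mean_escape_mm=mean_e, sem_escape_mm=sem_e, n=n_arr, baseline=baseline)


def modal_state(states: np.ndarray) -> str | None:
    vals, counts = np.unique(
        np.array([s for s in states if s in STATES]), return_counts=True)
    if len(vals) == 0:
        return None
    return str(vals[np.argmax(counts)])


def split_by_initial_state(
    animals: list[AnimalSeries],
    window_s: tuple[float, float] = (-5.0, 0.0),
    align_kwargs: dict | None = None,
) -> dict[str, PopulationSummary | None]:
    """Partition a cohort by each animal's modal pre-stimulus state.

    Every state with at least one animal gets its own summary; states with
    an empty partition are reported as None (n = 0), never dropped
    silently.
    """
    align_kwargs = align_kwargs or {}
    parts: dict[str, list[AnimalSeries]] = {s: [] for s in STATES}
    for an in animals:
        if not an.events:
            continue
        ev = an.events[0]
        t_rel = an.timestamps - ev.time_s
        sel = (t_rel >= window_s[0]) & (t_rel < window_s[1])
        st = modal_state(an.states[sel])
        if st is not None:
            parts[st].append(an)
    out: dict[str, PopulationSummary | None] = {}
    for s, group in parts.items():
        if group:
            summ = align_to_stimulus(group, **align_kwargs)
            summ.label = s
            out[s] = summ
        else:
            out[s] = None
    return out


def split_by_state_at(
    animals: list[AnimalSeries],
    offset_s: float,
    labels: dict[str, str] | None = None,
    align_kwargs: dict | None = None,
) -> dict[str, PopulationSummary | None]:
    """Partition by the state occupied at a fixed offset after the first
    stimulus — e.g. the double-stimulus rule that animals still reversing
    2 s after the first pulse are LONG responders and animals already
    paused are SHORT."""
    labels = labels or {"reverse": "LONG", "pause": "SHORT"}
    align_kwargs = align_kwargs or {}
    parts: dict[str, list[AnimalSeries]] = {v: [] for v in labels.values()}
    for an in animals:
        if not an.events:
            continue
        ev = an.events[0]
        i = int(np.argmin(np.abs(an.timestamps - (ev.time_s + offset_s))))
        st = an.states[i]
        if st in labels:
            parts[labels[st]].append(an)
    out: dict[str, PopulationSummary | None] = {}
    for name, group in parts.items():
        if group:
            summ = align_to_stimulus(group, **align_kwargs)
            summ.label = name
            out[name] = summ
        else:
            out[name] = None
    return out
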