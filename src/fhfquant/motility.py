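"""Single-molecule motility event classification and rate statistics.

Input is a table of localized positions along a microtubule versus time
(one row per frame per event, as extracted from kymographs upstream).
Events are classified with the 600-nm excursion taxonomy:

* **diffusive** — the trace makes at least one excursion greater than
  0.6 um in *each* direction (an excursion is the displacement from a
  running positional extremum);
* **processive** — net unidirectional motion with every reversal at most
  0.6 um and total displacement at least the static threshold;
* **static** — everything else (total net displacement below 0.6 um).

Processive events are split into constant-velocity segments by bottom-up
merging of per-frame velocities; near-zero segments of sufficient duration
are marked as pauses.  From the classified events the module computes the
field's standard summary statistics: segment velocities (events spanning
more than five frames only), run lengths (sum of moving-segment lengths),
landing rate (interior events per um of microtubule per second), pausing
frequency (pauses per um of run length), and the colocalized fraction of
processive events, plus Welch-t / Mann-Whitney group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import mann_whitney, welch_t

__all__ = [
    "MovieParams",
    "SegmentationParams",
    "Segment",
    "MotilityEvent",
    "MotilitySummary",
    "segment_event",
    "events_from_table",
    "compute_velocities",
    "landing_rate",
    "pausing_frequency",
    "colocalized_fraction",
    "compare_groups",
    "summarize",
]


@dataclass(frozen=True)
class MovieParams:
    """Acquisition metadata for one movie."""

    frame_interval: float  # s
    n_frames: int
    mt_length: float  # um

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("a movie needs >=2 frames")
        if self.mt_length <= 0:
            raise ValueError("mt_length must be positive")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for event classification and segmentation.

    ``reversal_threshold`` and ``static_threshold`` are the 0.6-um length
    scale of the event taxonomy.  ``velocity_merge_threshold`` controls the
    bottom-up merging of per-frame velocities into constant-velocity
    segments; ``min_segment_frames`` suppresses spurious short segments.
    A pause is a segment of at least ``min_pause_frames`` frame intervals
    whose total displacement magnitude stays below
    ``pause_max_displacement``.  ``smoothing_window`` (frames, 0 = off)
    applies a centered moving average before classification only.
    """

    reversal_threshold: float = 0.6  # um
    static_threshold: float = 0.6  # um
    velocity_merge_threshold: float = 0.2  # um/s
    min_segment_frames: int = 3
    pause_max_displacement: float = 0.1  # um
    min_pause_frames: int = 3
    smoothing_window: int = 0

    def __post_init__(self):
        if self.reversal_threshold <= 0 or self.static_threshold <= 0:
            raise ValueError("length thresholds must be positive")
        if self.velocity_merge_threshold <= 0:
            raise ValueError("velocity_merge_threshold must be positive")
        if self.min_segment_frames < 1 or self.min_pause_frames < 1:
            raise ValueError("minimum frame counts must be >=1")


@dataclass(frozen=True)
class Segment:
    """A constant-velocity stretch covering frame intervals [start, end)."""

    start_frame: int
    end_frame: int  # exclusive; segment covers samples start..end inclusive
    velocity: float  # um/s, signed
    displacement: float  # um, signed
    is_pause: bool

    @property
    def n_intervals(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class MotilityEvent:
    """A classified single-molecule event."""

    event_id: str
    event_class: str  # processive | diffusive | static
    frames: np.ndarray
    positions: np.ndarray
    segments: list[Segment] = field(default_factory=list)
    run_length: float = 0.0  # um, processive only
    starts_after_first_frame: bool = False
    ends_before_last_frame: bool = False
    colocalized: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def span_frames(self) -> int:
        return int(self.frames[-1] - self.frames[0])

    @property
    def n_pauses(self) -> int:
        return sum(1 for s in self.segments if s.is_pause)

    @property
    def is_multivelocity(self) -> bool:
        return len(self.segments) > 1


def _excursions(positions: np.ndarray) -> tuple[float, float]:
    """Largest upward and downward excursions (from running extrema)."""
    running_min = np.minimum.accumulate(positions)
    running_max = np.maximum.accumulate(positions)
    up = float(np.max(positions - running_min))
    down = float(np.max(running_max - positions))
    return up, down


def classify_trace(positions: np.ndarray, params: SegmentationParams) -> str:
    """Apply the 600-nm excursion taxonomy to a position series."""
    up, down = _excursions(positions)
    thr = params.reversal_threshold
    if up > thr and down > thr:
        return "diffusive"
    if abs(positions[-1] - positions[0]) >= params.static_threshold:
        return "processive"
    return "static"


def _detect_pauses(positions: np.ndarray, params: SegmentationParams) -> list[tuple[int, int]]:
    """Maximal low-displacement windows: sample-index spans (i, j).

    A pause is a stretch of at least ``min_pause_frames`` frame intervals
    over which the positional range (max - min) stays below
    ``pause_max_displacement``; scanning greedily from the left keeps the
    definition deterministic.
    """
    n = len(positions)
    spans = []
    i = 0
    while i < n - 1:
        lo = hi = positions[i]
        j = i
        while j + 1 < n:
            nlo, nhi = min(lo, positions[j + 1]), max(hi, positions[j + 1])
            if nhi - nlo >= params.pause_max_displacement:
                break
            lo, hi = nlo, nhi
            j += 1
        if j - i >= params.min_pause_frames:
            spans.append((i, j))
            i = j
        else:
            i += 1
    # coalesce windows that a single noise excursion split apart: if the
    # net displacement across the separating gap is itself below the pause
    # threshold, the whole stretch is one pause
    merged: list[tuple[int, int]] = []
    for span in spans:
        if (
            merged
            and abs(positions[span[0]] - positions[merged[-1][1]])
            < params.pause_max_displacement
        ):
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)
    return merged


def _bottom_up_segments(velocities: np.ndarray, params: SegmentationParams) -> list[tuple[int, int]]:
    """Merge per-frame velocities into segments; returns interval spans.

    Starts from one segment per frame interval, repeatedly merges the
    adjacent pair with the smallest mean-velocity difference until every
    remaining difference exceeds the merge threshold, then absorbs
    segments shorter than ``min_segment_frames`` into the neighbor with
    the closer velocity.
    """
    n = len(velocities)
    bounds = list(range(n + 1))  # segment k spans intervals [bounds[k], bounds[k+1])

    def seg_mean(a: int, b: int) -> float:
        return float(velocities[a:b].mean())

    means = [float(v) for v in velocities]
    while len(means) > 1:
        diffs = [abs(means[k + 1] - means[k]) for k in range(len(means) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] > params.velocity_merge_threshold:
            break
        bounds.pop(k + 1)
        means[k] = seg_mean(bounds[k], bounds[k + 1])
        means.pop(k + 1)
    # absorb short segments
    changed = True
    while changed and len(means) > 1:
        changed = False
        for k in range(len(means)):
            if bounds[k + 1] - bounds[k] < params.min_segment_frames:
                if k == 0:
                    j = 1
                elif k == len(means) - 1:
                    j = k - 1
                else:
                    j = k - 1 if abs(means[k - 1] - means[k]) <= abs(means[k + 1] - means[k]) else k + 1
                lo, hi = min(j, k), max(j, k)
                bounds.pop(hi)
                means[lo] = seg_mean(bounds[lo], bounds[lo + 1])
                means.pop(hi)
                changed = True
                break
    return [(bounds[k], bounds[k + 1]) for k in range(len(means))]


def segment_event(
    frames,
    positions,
    movie: MovieParams,
    params: SegmentationParams | None = None,
    *,
    event_id: str = "event",
    channel2=None,
) -> MotilityEvent:
    """Classify one trace and split it into constant-velocity segments.

    Parameters
    ----------
    frames : integer array
        Strictly increasing 0-based frame indices.
    positions : float array
        Position along the microtubule (um) at each frame.
    movie : MovieParams
    params : SegmentationParams, optional
    channel2 : boolean array, optional
        Per-sample second-channel presence; any True sample marks the
        event as colocalized (partial overlap counts).
    """
    params = params or SegmentationParams()
    frames = np.asarray(frames, dtype=int)
    positions = np.asarray(positions, dtype=float)
    if len(frames) < 2:
        raise ValueError("an event needs >=2 samples")
    if np.any(np.diff(frames) <= 0):
        raise ValueError("frames must be strictly increasing")

    cls_positions = positions
    if params.smoothing_window > 1:
        w = params.smoothing_window
        kernel = np.ones(w) / w
        cls_positions = np.convolve(positions, kernel, mode="same")
    event_class = classify_trace(cls_positions, params)

    dt = movie.frame_interval
    event = MotilityEvent(
        event_id=event_id,
        event_class=event_class,
        frames=frames,
        positions=positions,
        starts_after_first_frame=bool(frames[0] > 0),
        ends_before_last_frame=bool(frames[-1] < movie.n_frames - 1),
        colocalized=bool(np.any(channel2)) if channel2 is not None else False,
    )

    if event_class != "processive":
        disp = float(positions[-1] - positions[0])
        total_t = (frames[-1] - frames[0]) * dt
        event.segments = [
            Segment(int(frames[0]), int(frames[-1]), disp / total_t, disp, False)
        ]
        return event

    # per-interval velocities; gaps in frame numbering are handled by
    # dividing by the actual interval length
    dpos = np.diff(positions)
    dframes = np.diff(frames)
    vel = dpos / (dframes * dt)

    def make_segment(a: int, b: int, is_pause: bool, pause_left=False, pause_right=False) -> Segment:
        f0, f1 = int(frames[a]), int(frames[b])
        disp = float(positions[b] - positions[a])
        # the frame interval straddling a pause boundary mixes paused and
        # moving time; estimate the slope away from such intervals when
        # the segment is long enough to afford it
        ta, tb = a, b
        if not is_pause:
            if pause_left and tb - ta >= 2:
                ta += 1
            if pause_right and tb - ta >= 2:
                tb -= 1
        vel_seg = float(positions[tb] - positions[ta]) / ((frames[tb] - frames[ta]) * dt)
        return Segment(f0, f1, vel_seg, disp, is_pause)

    # pauses are found on positions first; bottom-up velocity merging then
    # runs only within the moving stretches between them, so a short burst
    # of motion can never be absorbed into a pause or vice versa
    segments: list[Segment] = []
    cursor = 0
    n = len(positions)
    pause_spans = _detect_pauses(positions, params)
    pause_samples = {s for span in pause_spans for s in span}
    for i, j in pause_spans + [(n - 1, n - 1)]:
        if i > cursor:
            for a, b in _bottom_up_segments(vel[cursor:i], params):
                segments.append(
                    make_segment(
                        cursor + a,
                        cursor + b,
                        False,
                        pause_left=cursor + a in pause_samples,
                        pause_right=cursor + b in pause_samples,
                    )
                )
        if j > i:
            segments.append(make_segment(i, j, True))
        cursor = j
    event.segments = segments
    event.run_length = float(sum(abs(s.displacement) for s in segments if not s.is_pause))
    return event


def events_from_table(
    traces: pd.DataFrame,
    movie: MovieParams,
    params: SegmentationParams | None = None,
) -> list[MotilityEvent]:
    """Segment every event in a trace table (grouped by ``event_id``)."""
    events = []
    for event_id, grp in traces.groupby("event_id", sort=True):
        grp = grp.sort_values("frame")
        channel2 = grp["channel2_present"].to_numpy() if "channel2_present" in grp else None
        events.append(
            segment_event(
                grp["frame"].to_numpy(),
                grp["position_um"].to_numpy(),
                movie,
                params,
                event_id=str(event_id),
                channel2=channel2,
            )
        )
    return events


def compute_velocities(events: list[MotilityEvent], min_span_frames: int = 5) -> list[float]:
    """Per-segment speeds (um/s) from qualifying processive events.

    Only processive events spanning more than ``min_span_frames`` frames
    contribute; pause segments are excluded, and each non-pause segment of
    a multivelocity event contributes its own entry.  Diffusive and static
    events contribute nothing.
    """
    out: list[float] = []
    for ev in events:
        if ev.event_class != "processive" or ev.span_frames <= min_span_frames:
            continue
        out.extend(abs(s.velocity) for s in ev.segments if not s.is_pause)
    return out


def landing_rate(events: list[MotilityEvent], mt_length: float, movie_duration: float) -> float:
    """Interior processive events per um of microtubule per second.

    Counts processive events that start after the first frame and end
    before the last frame of the movie, divided by (microtubule length x
    movie time).  For multiple movies, sum counts and divide by the summed
    length-time product.
    """
    if mt_length <= 0 or movie_duration <= 0:
        raise ValueError("mt_length and movie_duration must be positive")
    n = sum(
        1
        for ev in events
        if ev.event_class == "processive"
        and ev.starts_after_first_frame
        and ev.ends_before_last_frame
    )
    return n / (mt_length * movie_duration)


def pausing_frequency(events: list[MotilityEvent]) -> float:
    """Pauses per um of run length over all processive events.

    Total pause segments (pauses occur within multivelocity events)
    divided by the total run length of processive events.
    """
    processive = [ev for ev in events if ev.event_class == "processive"]
    total_run = sum(ev.run_length for ev in processive)
    if total_run <= 0:
        raise ValueError("pausing frequency undefined: total run length is zero")
    n_pauses = sum(ev.n_pauses for ev in processive if ev.is_multivelocity)
    return n_pauses / total_run


def colocalized_fraction(events: list[MotilityEvent]) -> float:
    """Fraction of processive events with second-channel signal on >=1 sample."""
    processive = [ev for ev in events if ev.event_class == "processive"]
    if not processive:
        raise ValueError("colocalized fraction undefined: no processive events")
    return sum(ev.colocalized for ev in processive) / len(processive)


def compare_groups(values_a, values_b, test: str = "welch_t", *, method: str = "auto"):
    """Two-sided group comparison: ``welch_t`` or ``mann_whitney``.

    Returns (statistic, p_value).  ``method`` selects the Mann-Whitney
    p-value computation ("auto", "exact", "asymptotic").
    """
    if test == "welch_t":
        return welch_t(values_a, values_b)
    if test == "mann_whitney":
        return mann_whitney(values_a, values_b, method=method)
    raise ValueError(f"unknown test {test!r}")


@dataclass(frozen=True)
class MotilitySummary:
    """Pooled motility statistics over one or more movies."""

    velocities: list[float]
    run_lengths: list[float]
    landing_rate: float  # events / (um * s)
    pausing_frequency: float | None  # pauses / um; None if no run length
    n_processive: int
    n_diffusive: int
    n_static: int
    colocalized_fraction: float | None


def summarize(events: list[MotilityEvent], movies: list[MovieParams]) -> MotilitySummary:
    """Aggregate events from one or more movies into a summary.

    ``events`` must be the concatenation of per-movie event lists and
    ``movies`` the matching movie metadata; the landing rate denominator
    is the summed (length x duration) over movies.
    """
    classes = [ev.event_class for ev in events]
    n_proc = classes.count("processive")
    denom = sum(m.mt_length * m.duration for m in movies)
    if denom <= 0:
        raise ValueError("movies provide no observation length-time")
    n_land = sum(
        1
        for ev in events
        if ev.event_class == "processive"
        and ev.starts_after_first_frame
        and ev.ends_before_last_frame
    )
    processive = [ev for ev in events if ev.event_class == "processive"]
    total_run = sum(ev.run_length for ev in processive)
    pf = (
        sum(ev.n_pauses for ev in processive if ev.is_multivelocity) / total_run
        if total_run > 0
        else None
    )
    return MotilitySummary(
        velocities=compute_velocities(events),
        run_lengths=[ev.run_length for ev in processive],
        landing_rate=n_land / denom,
        pausing_frequency=pf,
        n_processive=n_proc,
        n_diffusive=classes.count("diffusive"),
        n_static=classes.count("static"),
        colocalized_fraction=(
            sum(ev.colocalized for ev in processive) / n_proc if n_proc else None
        ),
    )
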