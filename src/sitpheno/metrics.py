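"""Per-session behavioral metrics, social interaction ratios, and the
Social Engagement Index.

From one session's keypoint track and arena geometry we compute three
scalars: total time the body centre spent in the social interaction zone
(seconds), the per-frame mean nose-to-POI distance (metres), and total
path length of the body centre (metres).  Two sessions — target absent
(S1) and target present (S2) — are then combined into ratios:

* type A: ``metric(S2) / metric(S1)``, boundary 1;
* type B: ``metric(S2) / (metric(S2) + metric(S1))``, boundary 0.5 — a
  monotone transform of type A, ``b = a / (1 + a)``, bounded in [0, 1].

The Social Engagement Index (SEI) is the time-based type-B ratio divided
by the distance-based type-B ratio: SEI > 1 marks robust approach (much
zone time, close to the target), SEI < 1 avoidance or hesitancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaSpec, in_zone, px_to_m
from .io_tracks import KeypointTrack

__all__ = [
    "SessionMetrics",
    "SIRProfile",
    "session_metrics",
    "sir_type_a",
    "sir_type_b",
    "social_engagement_index",
    "build_profile",
    "DEFAULT_SESSION_MINUTES",
]

#: Sessions are trimmed to this duration from their first frame so unequal
#: recording overruns cannot bias type-B ratios.
DEFAULT_SESSION_MINUTES = 2.5

FLAG_ZERO_DENOM = "zero_denominator"
FLAG_UNDEFINED = "undefined_ratio"


@dataclass(frozen=True)
class SessionMetrics:
    """Scalar summaries of one social-interaction-test session.

    ``time_in_siz`` counts frames whose body-centre point lies in the SIZ,
    divided by fps; ``mean_dist_poi`` is the per-frame mean Euclidean
    nose-to-POI distance in metres; ``total_distance`` is the summed
    frame-to-frame body-centre displacement in metres.  Frames inside
    over-long tracking gaps are excluded from the mean distance and counted
    in ``n_flagged_frames``.
    """

    animal_id: str
    session: str
    time_in_siz: float
    mean_dist_poi: float
    total_distance: float
    n_frames: int
    n_flagged_frames: int = 0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.time_in_siz < 0 or self.time_in_siz > self.n_frames / self.fps + 1e-9:
            raise ValueError("time_in_siz outside [0, session duration]")
        if self.mean_dist_poi < 0 or self.total_distance < 0:
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class SIRProfile:
    """The four social interaction ratios plus the SEI for one animal.

    Degenerate inputs never raise here: an all-zero denominator yields
    ``inf`` or ``nan`` with an explanatory entry in ``flags``.
    """

    animal_id: str
    time_sir_a: float
    time_sir_b: float
    dist_sir_a: float
    dist_sir_b: float
    sei: float
    flags: frozenset[str] = field(default_factory=frozenset)


def session_metrics(
    track: KeypointTrack,
    arena: ArenaSpec,
    *,
    flagged_frames: np.ndarray | None = None,
    session_minutes: float | None = DEFAULT_SESSION_MINUTES,
) -> SessionMetrics:
    """Compute :class:`SessionMetrics` for one (gap-filled) track.

    Zone occupancy uses the body-centre keypoint (the conventional "centre
    of the body in the SIZ" readout); the continuous proximity metric uses
    the nose.  ``flagged_frames`` (e.g. from a
    :class:`~sitpheno.io_tracks.GapReport`) are excluded from the mean
    nose-POI distance and reported in ``n_flagged_frames``.
    ``session_minutes`` trims the track to a fixed duration from its first
    frame; pass ``None`` to use every frame.
    """
    n_keep = track.n_frames
    if session_minutes is not None:
        n_keep = min(n_keep, int(round(session_minutes * 60.0 * track.fps)))

    center = track.xy("center")[:n_keep]
    nose = track.xy("nose")[:n_keep]

    occupied = in_zone(center, arena.siz_polygon_px)
    time_in_siz = float(np.count_nonzero(occupied)) / track.fps

    keep = np.ones(n_keep, dtype=bool)
    if flagged_frames is not None and len(flagged_frames):
        ff = np.asarray(flagged_frames, dtype=int)
        ff = ff[ff < n_keep]
        keep[ff] = False
    d_px = np.linalg.norm(nose - arena.poi_px, axis=1)
    mean_dist = float(px_to_m(arena, d_px[keep].mean())) if keep.any() else math.nan

    steps = np.linalg.norm(np.diff(center, axis=0), axis=1)
    total_dist = float(px_to_m(arena, steps.sum()))

    return SessionMetrics(
        animal_id=track.animal_id,
        session=track.session,
        time_in_siz=time_in_siz,
        mean_dist_poi=mean_dist,
        total_distance=total_dist,
        n_frames=n_keep,
        n_flagged_frames=int(n_keep - np.count_nonzero(keep)),
        fps=track.fps,
    )


def sir_type_a(metric_s2: float, metric_s1: float) -> tuple[float, frozenset[str]]:
    """Type-A social interaction ratio ``metric(S2) / metric(S1)``.

    Returns ``(value, flags)``: ``inf`` with a zero-denominator flag when
    only S1 is zero, ``nan`` with an undefined flag for 0/0.  Negative
    inputs raise.
    """
    if metric_s1 < 0 or metric_s2 < 0:
        raise ValueError("session metrics must be non-negative")
    if metric_s1 == 0:
        if metric_s2 == 0:
            return math.nan, frozenset({FLAG_UNDEFINED})
        return math.inf, frozenset({FLAG_ZERO_DENOM})
    return metric_s2 / metric_s1, frozenset()


def sir_type_b(metric_s2: float, metric_s1: float) -> tuple[float, frozenset[str]]:
    """Type-B social interaction ratio ``metric(S2) / (metric(S2) + metric(S1))``.

    Bounded in [0, 1] whenever defined; equals ``a / (1 + a)`` for the
    type-A ratio ``a``.  0/0 yields ``nan`` with an undefined flag.
    """
    if metric_s1 < 0 or metric_s2 < 0:
        raise ValueError("session metrics must be non-negative")
    denom = metric_s1 + metric_s2
    if denom == 0:
        return math.nan, frozenset({FLAG_UNDEFINED})
    return metric_s2 / denom, frozenset()


def social_engagement_index(
    time_sir_b: float, dist_sir_b: float
) -> tuple[float, frozenset[str]]:
    """Social Engagement Index: time-based over distance-based type-B ratio.

    SEI > 1 — long zone occupancy relative to proximity: robust approach.
    SEI < 1 — the converse: avoidance, or hesitant lingering at a distance.
    A zero or undefined denominator yields ``nan`` with a flag.
    """
    if not math.isfinite(dist_sir_b) or dist_sir_b == 0:
        return math.nan, frozenset({FLAG_UNDEFINED})
    if not math.isfinite(time_sir_b):
        return math.nan, frozenset({FLAG_UNDEFINED})
    return time_sir_b / dist_sir_b, frozenset()


def build_profile(s1: SessionMetrics, s2: SessionMetrics) -> SIRProfile:
    """Combine the two sessions' metrics into a full :class:`SIRProfile`."""
    if s1.animal_id != s2.animal_id:
        raise ValueError(
            f"session metrics belong to different animals: {s1.animal_id!r} vs {s2.animal_id!r}"
        )
    flags: set[str] = set()
    ta, f = sir_type_a(s2.time_in_siz, s1.time_in_siz)
    flags |= {f"time_a:{x}" for x in f}
    tb, f = sir_type_b(s2.time_in_siz, s1.time_in_siz)
    flags |= {f"time_b:{x}" for x in f}
    da, f = sir_type_a(s2.mean_dist_poi, s1.mean_dist_poi)
    flags |= {f"dist_a:{x}" for x in f}
    db, f = sir_type_b(s2.mean_dist_poi, s1.mean_dist_poi)
    flags |= {f"dist_b:{x}" for x in f}
    sei, f = social_engagement_index(tb, db)
    flags |= {f"sei:{x}" for x in f}
    return SIRProfile(
        animal_id=s1.animal_id,
        time_sir_a=ta,
        time_sir_b=tb,
        dist_sir_a=da,
        dist_sir_b=db,
        sei=sei,
        flags=frozenset(flags),
    )
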