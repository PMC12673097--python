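"""Seeded synthetic cohorts for the two-session social interaction test.

The generator stands in for a chronic-social-defeat cohort: each animal
yields two 2.5-minute, 30 fps keypoint tracks in a 42 x 42 cm arena, one
with the social target absent (S1) and one with it present (S2).  The body
centre follows a reflected Ornstein-Uhlenbeck walk (Euler-Maruyama step
1/fps) with a phenotype-dependent drift toward (approach) or away from
(avoidance) the point of interest; the nose rides 2 cm ahead of the centre
along the heading with tracking jitter, and a configurable fraction of
frames are given low likelihood to emulate pose-estimation dropouts.

Presets encode the phenotypes the study conditions distinguish:
``resilient_like`` animals approach the target in S2, ``susceptible_like``
animals avoid it, and ``control`` animals show mild approach.  Synthetic
nest-building scores (1-5 ordinal) increase with the programmed
sociability so the downstream rank-correlation stage has signal.

Reproducibility: one master seed; each animal/session stream is seeded by
the tuple ``(master_seed, animal_index, session_index)`` through
``numpy.random.SeedSequence``, so cohorts are bit-reproducible and
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import DEFAULT_SIDE_CM, ArenaSpec, in_zone, make_arena
from .io_tracks import KeypointTrack, write_keypoint_table

__all__ = [
    "PhenotypeParams",
    "CohortDesign",
    "SimulatedAnimal",
    "PRESETS",
    "default_arena",
    "simulate_session",
    "simulate_cohort",
    "write_cohort",
]

NOSE_OFFSET_CM = 2.0  # nose leads the body centre by this much
NOSE_JITTER_CM = 0.15  # tracking jitter on the nose keypoint


@dataclass(frozen=True)
class PhenotypeParams:
    """Movement-model parameters for one programmed phenotype.

    drift_s1, drift_s2 : cm/s
        Signed drift along the unit vector toward the POI (positive =
        approach, negative = avoidance) in each session.
    mean_reversion : 1/s
        Pull toward the arena centre keeping the walk stationary.
    noise_sigma : cm/sqrt(s)
        Diffusion scale of the walk.
    dwell_bias : probability
        Chance of freezing in place on a frame spent inside the SIZ
        (sniffing/dwelling at the cage).
    dropout_rate : fraction
        Fraction of frames assigned likelihood below 0.5.
    """

    drift_s1: float = 0.0
    drift_s2: float = 0.0
    mean_reversion: float = 0.2
    noise_sigma: float = 6.0
    dwell_bias: float = 0.0
    dropout_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.mean_reversion <= 0:
            raise ValueError("mean_reversion must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 <= self.dwell_bias <= 1:
            raise ValueError("dwell_bias must lie in [0, 1]")


#: Documented phenotype presets.  Drift magnitudes are chosen so that over a
#: 2.5-minute session the programmed approach/avoidance clearly dominates the
#: diffusive noise, mirroring the separation real cohorts show between
#: resilient and susceptible animals.
PRESETS: dict[str, PhenotypeParams] = {
    "control": PhenotypeParams(drift_s1=0.0, drift_s2=1.5, dwell_bias=0.25),
    "resilient_like": PhenotypeParams(drift_s1=0.0, drift_s2=3.5, dwell_bias=0.45),
    "susceptible_like": PhenotypeParams(drift_s1=0.5, drift_s2=-3.5, dwell_bias=0.0),
}


def default_arena(side_cm: float = DEFAULT_SIDE_CM, scale: float = 10.0) -> ArenaSpec:
    """Synthetic imaging geometry: square arena at ``scale`` px/cm with the
    target cage against the top wall (cage face 10 cm wide, 10 cm into the
    arena, centred)."""
    s = side_cm * scale
    cage_half = 5.0 * scale
    cage_depth = 10.0 * scale
    return make_arena(
        [(0.0, 0.0), (s, 0.0), (s, s), (0.0, s)],
        side_cm=side_cm,
        cage_corners_px=[(s / 2 - cage_half, cage_depth), (s / 2 + cage_half, cage_depth)],
    )


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic two-session cohort (defaults follow the study
    conventions: 2.5-minute sessions at 30 fps in a 42 cm square arena)."""

    n_control: int = 8
    n_resilient_like: int = 8
    n_susceptible_like: int = 8
    session_minutes: float = 2.5
    fps: float = 30.0
    arena: ArenaSpec = field(default_factory=default_arena)
    seed: int = 0
    nest_scores: bool = True

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_resilient_like, self.n_susceptible_like) < 0:
            raise ValueError("animal counts must be non-negative")
        if self.n_control + self.n_resilient_like + self.n_susceptible_like == 0:
            raise ValueError("cohort must contain at least one animal")
        if self.session_minutes <= 0:
            raise ValueError("session_minutes must be positive")


@dataclass(frozen=True)
class SimulatedAnimal:
    """One synthetic animal: metadata plus its two session tracks."""

    animal_id: str
    condition: str  # "control" | "stress"
    preset: str
    s1: KeypointTrack
    s2: KeypointTrack
    nest_score: int | None = None


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), *key)))


def simulate_session(
    params: PhenotypeParams,
    *,
    arena: ArenaSpec,
    session: str,
    fps: float = 30.0,
    session_minutes: float = 2.5,
    animal_id: str = "sim",
    seed: int | np.random.Generator = 0,
) -> KeypointTrack:
    """Simulate one session's keypoint track for one animal.

    The centre position X (in cm, arena frame) evolves as

        dX = [theta (c - X) + v u(X)] dt + sigma dW,   reflected at walls,

    with theta the mean reversion toward the arena centre c, v the signed
    session drift along the unit vector u toward the POI, and sigma the
    noise scale; dt = 1/fps.  Identical seed → bit-identical track.
    """
    if session not in ("S1", "S2"):
        raise ValueError("session must be 'S1' or 'S2'")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed, 0, 0)
    dt = 1.0 / fps
    side = arena.side_cm
    drift = params.drift_s1 if session == "S1" else params.drift_s2
    # numerical sanity: one step must not traverse the arena
    if abs(drift) * dt + 4.0 * params.noise_sigma * np.sqrt(dt) > side:
        raise ValueError(
            "parameters drive steps larger than the arena; reduce drift or noise"
        )
    n = int(round(session_minutes * 60.0 * fps))
    poi_cm = arena.poi_px / arena.scale
    centre_cm = arena.arena_corners_px.mean(axis=0) / arena.scale

    pos = np.empty((n, 2))
    x = rng.uniform(0.3 * side, 0.7 * side, size=2)
    sqdt = np.sqrt(dt)
    noise = rng.normal(0.0, params.noise_sigma * sqdt, size=(n, 2))
    dwell_draw = rng.uniform(size=n)
    siz_poly_cm = arena.siz_polygon_px / arena.scale
    for i in range(n):
        pos[i] = x
        if params.dwell_bias > 0 and dwell_draw[i] < params.dwell_bias and in_zone(
            x, siz_poly_cm
        ):
            continue  # freeze at the cage this frame
        to_poi = poi_cm - x
        dist = np.linalg.norm(to_poi)
        u = to_poi / dist if dist > 1e-9 else np.zeros(2)
        x = (
            x
            + (params.mean_reversion * (centre_cm - x) + drift * u) * dt
            + noise[i]
        )
        # reflect at the walls
        x = np.where(x < 0, -x, x)
        x = np.where(x > side, 2 * side - x, x)
        x = np.clip(x, 0.0, side)  # guards pathological multi-reflections

    # nose: 2 cm ahead of the centre along the heading, with jitter
    head = np.diff(pos, axis=0, prepend=pos[:1])
    norms = np.linalg.norm(head, axis=1, keepdims=True)
    fallback = poi_cm - pos
    fb_norms = np.linalg.norm(fallback, axis=1, keepdims=True)
    unit = np.where(norms > 1e-9, head / np.maximum(norms, 1e-12),
                    fallback / np.maximum(fb_norms, 1e-12))
    nose = pos + NOSE_OFFSET_CM * unit + rng.normal(0.0, NOSE_JITTER_CM, size=(n, 2))

    lik_center = rng.uniform(0.9, 1.0, size=n)
    lik_nose = rng.uniform(0.9, 1.0, size=n)
    if params.dropout_rate > 0:
        drop_c = rng.uniform(size=n) < params.dropout_rate
        drop_n = rng.uniform(size=n) < params.dropout_rate
        lik_center[drop_c] = rng.uniform(0.0, 0.5, size=int(drop_c.sum()))
        lik_nose[drop_n] = rng.uniform(0.0, 0.5, size=int(drop_n.sum()))

    scale = arena.scale
    data = pd.concat(
        {
            "nose": pd.DataFrame(
                {"x": nose[:, 0] * scale, "y": nose[:, 1] * scale, "likelihood": lik_nose}
            ),
            "center": pd.DataFrame(
                {"x": pos[:, 0] * scale, "y": pos[:, 1] * scale, "likelihood": lik_center}
            ),
        },
        axis=1,
    )
    data.columns.names = ["bodyparts", "coords"]
    return KeypointTrack(
        animal_id=animal_id,
        session=session,
        fps=fps,
        data=data,
        bodypart_map={"nose": "nose", "center": "center"},
    )


def _nest_score(rng: np.random.Generator, drift_s2: float) -> int:
    """Ordinal 1-5 nest score whose mean increases with programmed
    sociability (the S2 approach drift)."""
    latent = 3.0 + 0.55 * drift_s2 + rng.normal(0.0, 0.9)
    return int(np.clip(round(latent), 1, 5))


def simulate_cohort(design: CohortDesign) -> list[SimulatedAnimal]:
    """Generate a full two-session cohort from a :class:`CohortDesign`.

    Per-animal and per-session random streams are derived from the master
    seed by counter-based sub-seeding, so the same design always yields a
    bit-identical cohort regardless of generation order.
    """
    roster: list[tuple[str, str]] = []
    roster += [("control", "control")] * design.n_control
    roster += [("stress", "resilient_like")] * design.n_resilient_like
    roster += [("stress", "susceptible_like")] * design.n_susceptible_like

    animals: list[SimulatedAnimal] = []
    for idx, (condition, preset) in enumerate(roster):
        params = PRESETS[preset]
        animal_id = f"m{idx:03d}"
        tracks = {}
        for s_idx, session in enumerate(("S1", "S2")):
            tracks[session] = simulate_session(
                params,
                arena=design.arena,
                session=session,
                fps=design.fps,
                session_minutes=design.session_minutes,
                animal_id=animal_id,
                seed=_rng(design.seed, idx, s_idx),
            )
        nest = (
            _nest_score(_rng(design.seed, idx, 99), params.drift_s2)
            if design.nest_scores
            else None
        )
        animals.append(
            SimulatedAnimal(
                animal_id=animal_id,
                condition=condition,
                preset=preset,
                s1=tracks["S1"],
                s2=tracks["S2"],
                nest_score=nest,
            )
        )
    return animals


def write_cohort(
    animals: list[SimulatedAnimal], out_dir: str | Path, dialect: str = "dlc_csv"
) -> Path:
    """Write every track in the DLC dialect plus a cohort manifest CSV;
    returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "dlc_csv" else "h5"
    rows = []
    for a in animals:
        paths = {}
        for session, track in (("S1", a.s1), ("S2", a.s2)):
            p = out_dir / f"{a.animal_id}_{session}.{ext}"
            write_keypoint_table(track, p, dialect)
            paths[session] = p.name
        rows.append(
            {
                "animal_id": a.animal_id,
                "condition": a.condition,
                "preset": a.preset,
                "s1_path": paths["S1"],
                "s2_path": paths["S2"],
                "fps": a.s1.fps,
                "nest_score": a.nest_score if a.nest_score is not None else "",
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
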