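"""Cohort-level orchestration: tracks → metrics → phenotypes → stats tables.

These functions tie the per-animal operations into the tabular outputs the
command-line interface writes: a per-session metrics table, a per-animal
phenotype table (ratios, SEI, label, flags), a plot-ready 3-D export, and
the group-statistics report.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .io_tracks import KeypointTrack, fill_low_confidence
from .metrics import (
    DEFAULT_SESSION_MINUTES,
    SessionMetrics,
    build_profile,
    session_metrics,
)
from .phenotype import classify, flag_ambiguous
from .stats import CorrResult, ManovaResult, manova_wilks, spearman_rho

__all__ = ["analyze_animal", "analyze_cohort", "export_3d", "run_group_stats"]

log = logging.getLogger("sitpheno")


def analyze_animal(
    s1: KeypointTrack,
    s2: KeypointTrack,
    arena: ArenaSpec,
    *,
    likelihood_threshold: float = 0.6,
    max_gap: float = 1.0,
    session_minutes: float | None = DEFAULT_SESSION_MINUTES,
) -> tuple[SessionMetrics, SessionMetrics, "pd.Series"]:
    """Gap-fill both sessions and compute metrics plus the ratio profile."""
    out = []
    for track in (s1, s2):
        filled, report = fill_low_confidence(track, likelihood_threshold, max_gap)
        m = session_metrics(
            filled,
            arena,
            flagged_frames=report.flagged_frames,
            session_minutes=session_minutes,
        )
        out.append(m)
    profile = build_profile(out[0], out[1])
    return out[0], out[1], profile


def analyze_cohort(
    cohort,
    arena: ArenaSpec,
    *,
    basis: str = "time_sir_b",
    likelihood_threshold: float = 0.6,
    max_gap: float = 1.0,
    session_minutes: float | None = DEFAULT_SESSION_MINUTES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full per-animal pipeline over a cohort.

    ``cohort`` is an iterable of objects with ``animal_id``, ``condition``,
    ``s1`` and ``s2`` attributes (e.g.
    :class:`~sitpheno.simulate.SimulatedAnimal`), optionally ``nest_score``.

    Returns ``(metrics_table, phenotype_table)``: one row per animal/session
    and one row per animal respectively.  Bidimensional ambiguity flags are
    computed against the whole cohort's Session-2 distribution and logged.
    """
    cohort = list(cohort)
    metrics_rows = []
    per_animal = []
    for a in cohort:
        m1, m2, profile = analyze_animal(
            a.s1,
            a.s2,
            arena,
            likelihood_threshold=likelihood_threshold,
            max_gap=max_gap,
            session_minutes=session_minutes,
        )
        call = classify(profile, a.condition, basis=basis)
        per_animal.append((a, m1, m2, profile, call))
        for m in (m1, m2):
            metrics_rows.append(
                {
                    "animal_id": a.animal_id,
                    "condition": a.condition,
                    "session": m.session,
                    "time_in_siz_s": m.time_in_siz,
                    "mean_dist_poi_m": m.mean_dist_poi,
                    "total_distance_m": m.total_distance,
                    "n_frames": m.n_frames,
                    "n_flagged_frames": m.n_flagged_frames,
                }
            )

    cohort_dist = np.array([m2.mean_dist_poi for _, _, m2, _, _ in per_animal])
    cohort_time = np.array([m2.time_in_siz for _, _, m2, _, _ in per_animal])

    pheno_rows = []
    for a, m1, m2, profile, call in per_animal:
        amb = flag_ambiguous(
            m2,
            profile,
            call,
            cohort_dist_poi=cohort_dist if len(cohort_dist) >= 4 else None,
            cohort_time_siz=cohort_time if len(cohort_time) >= 4 else None,
        )
        all_flags = sorted(set(profile.flags) | set(amb))
        if all_flags:
            log.info("animal %s flags: %s", a.animal_id, ",".join(all_flags))
        pheno_rows.append(
            {
                "animal_id": a.animal_id,
                "condition": a.condition,
                "label": call.label,
                "basis": call.basis,
                "time_sir_a": profile.time_sir_a,
                "time_sir_b": profile.time_sir_b,
                "dist_sir_a": profile.dist_sir_a,
                "dist_sir_b": profile.dist_sir_b,
                "sei": profile.sei,
                "nest_score": getattr(a, "nest_score", None),
                "flags": ";".join(all_flags),
            }
        )
    return pd.DataFrame(metrics_rows), pd.DataFrame(pheno_rows)


def export_3d(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (time ratio, distance ratio, SEI, label) table.

    Animals without a defined SEI or with an ``unclassifiable`` label are
    excluded (and logged) — they have no position in the 3-D space.
    """
    required = {"animal_id", "time_sir_b", "dist_sir_b", "sei", "label"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    ok = phenotypes["sei"].apply(lambda v: isinstance(v, (int, float)) and math.isfinite(v))
    ok &= phenotypes["label"] != "unclassifiable"
    for aid in phenotypes.loc[~ok, "animal_id"]:
        log.info("excluding %s from 3-D export (undefined SEI or unclassifiable)", aid)
    return phenotypes.loc[ok, ["animal_id", "time_sir_b", "dist_sir_b", "sei", "label"]].reset_index(
        drop=True
    )


def run_group_stats(
    phenotypes: pd.DataFrame,
    *,
    features: tuple[str, str] = ("time_sir_b", "dist_sir_b"),
    group_col: str = "label",
) -> dict:
    """Group-level statistics on the bidimensional feature space.

    Runs the Wilks'-Lambda MANOVA over ``features`` by ``group_col`` and,
    when a ``nest_score`` column is present, the Spearman correlation of
    SEI with the nest score.  Returns a JSON-serialisable dict.
    """
    sub = phenotypes.dropna(subset=list(features))
    sub = sub[np.isfinite(sub[list(features)]).all(axis=1)]
    out: dict = {}
    try:
        res: ManovaResult = manova_wilks(
            sub[list(features)].to_numpy(dtype=float), sub[group_col].to_numpy()
        )
        out["manova"] = {
            "features": list(features),
            "wilks_lambda": res.wilks_lambda,
            "f_stat": res.f_stat,
            "df1": res.df1,
            "df2": res.df2,
            "p": res.p,
            "text": str(res),
        }
    except ValueError as exc:
        out["manova"] = {"error": str(exc)}

    if "nest_score" in phenotypes.columns and phenotypes["nest_score"].notna().any():
        sub2 = phenotypes.dropna(subset=["nest_score", "sei"])
        sub2 = sub2[np.isfinite(sub2["sei"])]
        try:
            corr: CorrResult = spearman_rho(
                sub2["sei"].to_numpy(dtype=float),
                sub2["nest_score"].to_numpy(dtype=float),
            )
            out["spearman_sei_nest"] = {
                "rho": corr.rho,
                "p": corr.p,
                "n": corr.n,
                "text": str(corr),
            }
        except ValueError as exc:
            out["spearman_sei_nest"] = {"error": str(exc)}
    return out
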