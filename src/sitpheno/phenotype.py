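"""Resilient / susceptible classification and bidimensional ambiguity flags.

Stress-exposed animals are stratified by the time-based type-B social
interaction ratio: below 0.5 → susceptible, at or above 0.5 → resilient
(the boundary is inclusive to resilient).  The equivalent type-A rule uses
boundary 1.  Control animals keep the label ``control`` regardless of
their ratios, which are still reported.

Two kinds of bidimensional ambiguity are flagged on top of the binary
label: an animal sitting close to the point of interest while barely
entering the zone (proximity without engagement), and an animal whose
Social Engagement Index falls on the opposite side of 1 from its label's
expected cluster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import SessionMetrics, SIRProfile

__all__ = [
    "PhenotypeCall",
    "classify",
    "flag_ambiguous",
    "TYPE_B_BOUNDARY",
    "TYPE_A_BOUNDARY",
    "SEI_CLUSTER_BOUNDARY",
]

#: Susceptible below, resilient at-or-above (inclusive boundary).
TYPE_B_BOUNDARY = 0.5
TYPE_A_BOUNDARY = 1.0

#: SEI side on which each phenotype's cluster is expected to fall.
SEI_CLUSTER_BOUNDARY = 1.0

FLAG_NEAR_POI_LOW_TIME = "near_poi_low_time"
FLAG_SEI_CLUSTER_MISMATCH = "sei_cluster_mismatch"


@dataclass(frozen=True)
class PhenotypeCall:
    """Classification outcome for one animal."""

    animal_id: str
    condition: str  # "control" | "stress"
    label: str  # "control" | "resilient" | "susceptible" | "unclassifiable"
    basis: str  # "time_sir_a" | "time_sir_b"
    ambiguity_flags: frozenset[str] = field(default_factory=frozenset)


def classify(
    profile: SIRProfile,
    condition: str,
    basis: str = "time_sir_b",
) -> PhenotypeCall:
    """Assign the resilience/susceptibility label from a ratio profile.

    Parameters
    ----------
    profile
        The animal's computed ratios.
    condition
        ``"control"`` or ``"stress"``; controls are labelled ``control``
        unconditionally.
    basis
        ``"time_sir_b"`` (default; boundary 0.5) or ``"time_sir_a"``
        (boundary 1).  The two rules agree whenever both ratios are finite,
        since ``b = a / (1 + a)`` is monotone with ``b(1) = 0.5``.

    An undefined basis ratio (0/0 sessions) yields ``unclassifiable`` with
    the profile's flags carried over.
    """
    if condition not in ("control", "stress"):
        raise ValueError(f"condition must be 'control' or 'stress', got {condition!r}")
    if basis == "time_sir_b":
        value, boundary = profile.time_sir_b, TYPE_B_BOUNDARY
    elif basis == "time_sir_a":
        value, boundary = profile.time_sir_a, TYPE_A_BOUNDARY
    else:
        raise ValueError(f"unknown basis {basis!r}")

    if condition == "control":
        label = "control"
    elif math.isnan(value):
        label = "unclassifiable"
    else:
        # inf (S1 occupancy exactly zero, S2 positive) is maximal approach
        label = "resilient" if value >= boundary else "susceptible"
    return PhenotypeCall(
        animal_id=profile.animal_id,
        condition=condition,
        label=label,
        basis=basis,
        ambiguity_flags=profile.flags,
    )


def flag_ambiguous(
    metrics_s2: SessionMetrics,
    profile: SIRProfile,
    call: PhenotypeCall,
    cohort_dist_poi: np.ndarray | None = None,
    cohort_time_siz: np.ndarray | None = None,
    *,
    quantile: float = 0.25,
) -> frozenset[str]:
    """Raise bidimensional ambiguity flags for one animal.

    ``near_poi_low_time``
        The Session-2 mean POI distance falls below the cohort's lower
        quartile (the animal stays close to the target) while its Session-2
        SIZ time is also below the cohort's lower quartile (it barely enters
        the zone) — the "remaining nearby without engaging" pattern that a
        time-only readout cannot see.  Requires cohort arrays of >= 4
        animals; with fewer the quartile criterion is disabled with a
        warning.
    ``sei_cluster_mismatch``
        A susceptible label with SEI > 1, or a resilient label with SEI < 1
        — the animal clusters with the opposite phenotype in the
        (time ratio, distance ratio, SEI) space.

    The quartile ``quantile`` is configurable; the criteria are a stated
    operationalisation of a qualitative pattern, not a universal rule.
    """
    flags: set[str] = set()
    if cohort_dist_poi is not None and cohort_time_siz is not None:
        if len(cohort_dist_poi) < 4 or len(cohort_time_siz) < 4:
            warnings.warn(
                "cohort smaller than 4 animals: quartile-based ambiguity "
                "criterion disabled",
                stacklevel=2,
            )
        else:
            d_q = np.quantile(np.asarray(cohort_dist_poi, dtype=float), quantile)
            t_q = np.quantile(np.asarray(cohort_time_siz, dtype=float), quantile)
            if metrics_s2.mean_dist_poi <= d_q and metrics_s2.time_in_siz <= t_q:
                flags.add(FLAG_NEAR_POI_LOW_TIME)
    if math.isfinite(profile.sei):
        if call.label == "susceptible" and profile.sei > SEI_CLUSTER_BOUNDARY:
            flags.add(FLAG_SEI_CLUSTER_MISMATCH)
        elif call.label == "resilient" and profile.sei < SEI_CLUSTER_BOUNDARY:
            flags.add(FLAG_SEI_CLUSTER_MISMATCH)
    return frozenset(flags)
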