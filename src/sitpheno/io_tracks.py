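"""Keypoint tracking tables in the DeepLabCut dialect.

A track is the pose-estimation output for one animal in one session of the
social interaction test: per-frame (x, y, likelihood) triples for each
tracked body part, stored here as a pandas DataFrame with MultiIndex
columns ``(bodypart, coord)``.  Readers accept both the CSV export (three
stacked header rows ``scorer`` / ``bodyparts`` / ``coords``, with an
optional ``individuals`` row for multi-animal projects) and the HDF5
export.  Low-confidence frames — tracking dropouts — are repaired by
per-bodypart linear interpolation, with gaps longer than a configurable
duration flagged rather than silently trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KeypointTrack",
    "GapReport",
    "TrackFormatError",
    "TrackConfigError",
    "UnrecoverableTrackError",
    "read_keypoint_table",
    "write_keypoint_table",
    "fill_low_confidence",
    "resolve_bodypart_map",
    "DEFAULT_LIKELIHOOD_THRESHOLD",
    "DEFAULT_MAX_GAP_S",
]

COORDS = ("x", "y", "likelihood")

#: Conventional DeepLabCut confidence cutoff below which a frame is treated
#: as a tracking dropout.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.6

#: Gaps longer than this many seconds are interpolated but flagged.
DEFAULT_MAX_GAP_S = 1.0


class TrackFormatError(ValueError):
    """The file does not follow the expected DLC header structure."""


class TrackConfigError(ValueError):
    """A configured bodypart name is absent from the file."""


class UnrecoverableTrackError(ValueError):
    """A bodypart has no confident frame at all; interpolation is impossible."""


@dataclass(frozen=True)
class KeypointTrack:
    """Time-indexed keypoint coordinates + likelihoods for one animal/session.

    Attributes
    ----------
    animal_id : str
        Identifier of the tracked animal.
    session : str
        ``"S1"`` (social target absent) or ``"S2"`` (target present).
    fps : float
        Acquisition frame rate (frames/second); timestamps are ``index/fps``.
    data : pandas.DataFrame
        MultiIndex columns ``(bodypart, coord)`` with ``coord`` in
        ``{"x", "y", "likelihood"}``; one row per frame, in acquisition order.
        Coordinates are raw image pixels (origin top-left, y down).
    bodypart_map : dict
        Role → bodypart-name mapping; must resolve the ``"nose"`` and
        ``"center"`` roles used by the metrics layer.
    """

    animal_id: str
    session: str
    fps: float
    data: pd.DataFrame
    bodypart_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.session not in ("S1", "S2"):
            raise ValueError(f"session must be 'S1' or 'S2', got {self.session!r}")
        if len(self.data) == 0:
            raise ValueError("track must contain at least one frame")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy()
        finite = lik[np.isfinite(lik)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihoods must lie in [0, 1]")

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def xy(self, role_or_name: str) -> np.ndarray:
        """(n_frames, 2) pixel coordinates for a bodypart role or literal name."""
        name = self.bodypart_map.get(role_or_name, role_or_name)
        if name not in self.bodyparts:
            raise TrackConfigError(
                f"bodypart {name!r} not in track; available: {self.bodyparts}"
            )
        return self.data[name][["x", "y"]].to_numpy(dtype=float)

    def likelihood(self, role_or_name: str) -> np.ndarray:
        name = self.bodypart_map.get(role_or_name, role_or_name)
        if name not in self.bodyparts:
            raise TrackConfigError(
                f"bodypart {name!r} not in track; available: {self.bodyparts}"
            )
        return self.data[name]["likelihood"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GapReport:
    """Outcome of dropout repair for one track.

    ``long_gaps`` maps bodypart → list of ``(start_frame, end_frame_exclusive)``
    runs that exceeded ``max_gap`` (filled anyway, but not to be trusted);
    ``n_filled`` maps bodypart → number of interpolated frames.
    """

    likelihood_threshold: float
    max_gap_s: float
    n_filled: dict[str, int]
    long_gaps: dict[str, list[tuple[int, int]]]

    @property
    def flagged_frames(self) -> np.ndarray:
        """Sorted union of frame indices inside any over-long gap."""
        idx: set[int] = set()
        for runs in self.long_gaps.values():
            for start, stop in runs:
                idx.update(range(start, stop))
        return np.array(sorted(idx), dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bodypart": bp, "start_frame": a, "end_frame": b, "n_frames": b - a}
            for bp, runs in self.long_gaps.items()
            for a, b in runs
        ]
        return pd.DataFrame(rows, columns=["bodypart", "start_frame", "end_frame", "n_frames"])


def resolve_bodypart_map(
    bodyparts: list[str], bodypart_map: dict[str, str] | None = None
) -> dict[str, str]:
    """Resolve the nose/center roles against the bodyparts present in a file.

    An explicit mapping wins; otherwise the first name containing the role
    substring (case-insensitive) is used, so DLC skeletons with labels like
    ``Nose`` or ``Center`` or ``spine_center`` work out of the box.
    """
    resolved: dict[str, str] = {}
    bodypart_map = bodypart_map or {}
    for role in ("nose", "center"):
        if role in bodypart_map:
            name = bodypart_map[role]
            if name not in bodyparts:
                raise TrackConfigError(
                    f"bodypart_map[{role!r}] = {name!r} not found in file; "
                    f"available: {bodyparts}"
                )
            resolved[role] = name
            continue
        matches = [bp for bp in bodyparts if role in bp.lower()]
        if matches:
            resolved[role] = matches[0]
    # extra user-supplied roles pass through unchanged (validated)
    for role, name in bodypart_map.items():
        if role in resolved:
            continue
        if name not in bodyparts:
            raise TrackConfigError(
                f"bodypart_map[{role!r}] = {name!r} not found in file; "
                f"available: {bodyparts}"
            )
        resolved[role] = name
    return resolved


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Reduce DLC multi-index columns to (bodypart, coord), dropping the
    scorer level and an optional individuals level."""
    cols = df.columns
    if cols.nlevels < 2:
        raise TrackFormatError(
            "expected stacked DLC header rows (scorer/bodyparts/coords); "
            f"found a flat header: {list(cols)[:4]}..."
        )
    names = [str(n).lower() if n is not None else "" for n in cols.names]
    # locate the coords level: the one whose values are x/y/likelihood
    coord_level = None
    for lev in range(cols.nlevels):
        vals = set(cols.get_level_values(lev))
        if vals <= {"x", "y", "likelihood"} and vals:
            coord_level = lev
            break
    if coord_level is None:
        raise TrackFormatError(
            "missing 'coords' header row with x/y/likelihood labels"
        )
    bp_level = None
    if "bodyparts" in names:
        bp_level = names.index("bodyparts")
    else:
        bp_level = coord_level - 1
    if bp_level < 0:
        raise TrackFormatError("missing 'bodyparts' header row")
    out = df.copy()
    out.columns = pd.MultiIndex.from_arrays(
        [cols.get_level_values(bp_level), cols.get_level_values(coord_level)],
        names=["bodyparts", "coords"],
    )
    return out


def read_keypoint_table(
    path: str | Path,
    dialect: str = "dlc_csv",
    *,
    fps: float = 30.0,
    animal_id: str | None = None,
    session: str = "S1",
    bodypart_map: dict[str, str] | None = None,
) -> KeypointTrack:
    """Read a DLC-dialect keypoint table into a :class:`KeypointTrack`.

    Parameters
    ----------
    path
        CSV (``dialect="dlc_csv"``) or HDF5 (``dialect="dlc_h5"``) file.
    fps
        Frame rate the video was recorded at (the table itself carries no
        clock); the study convention is 30 fps.
    animal_id, session
        Metadata attached to the track; ``animal_id`` defaults to the file
        stem.
    bodypart_map
        Optional role → bodypart-name mapping (see
        :func:`resolve_bodypart_map`).

    Notes
    -----
    A missing ``likelihood`` column for a bodypart is tolerated and treated
    as full confidence (1.0).  Frame order follows file row order;
    coordinates are returned untouched, in pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dlc_csv":
        # sniff header depth: 3 rows (scorer/bodyparts/coords) or 4 with an
        # 'individuals' row inserted by multi-animal projects
        with open(path) as fh:
            head = [fh.readline() for _ in range(4)]
        n_header = 3
        if any(line.split(",")[0].strip().lower() == "individuals" for line in head):
            n_header = 4
        first_fields = [line.split(",")[0].strip().lower() for line in head[:n_header]]
        expected = (
            ["scorer", "bodyparts", "coords"]
            if n_header == 3
            else ["scorer", "individuals", "bodyparts", "coords"]
        )
        for want, got in zip(expected, first_fields):
            if got != want:
                raise TrackFormatError(
                    f"malformed DLC CSV header: expected a {want!r} row, found {got!r}"
                )
        df = pd.read_csv(
            path,
            header=list(range(n_header)),
            index_col=0,
            float_precision="round_trip",
        )
    elif dialect == "dlc_h5":
        df = pd.read_hdf(path)
        if not isinstance(df, pd.DataFrame):
            raise TrackFormatError(f"{path} does not hold a keypoint DataFrame")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    df = _normalise_columns(df)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(0)))

    # tolerate missing likelihood columns → confidence 1.0
    blocks = {}
    for bp in bodyparts:
        sub = df[bp]
        if "x" not in sub.columns or "y" not in sub.columns:
            raise TrackFormatError(f"bodypart {bp!r} lacks x/y columns")
        block = pd.DataFrame(
            {
                "x": pd.to_numeric(sub["x"], errors="coerce"),
                "y": pd.to_numeric(sub["y"], errors="coerce"),
                "likelihood": (
                    pd.to_numeric(sub["likelihood"], errors="coerce")
                    if "likelihood" in sub.columns
                    else 1.0
                ),
            }
        )
        blocks[bp] = block
    data = pd.concat(blocks, axis=1)
    data.columns.names = ["bodyparts", "coords"]
    data = data.reset_index(drop=True)

    return KeypointTrack(
        animal_id=animal_id if animal_id is not None else path.stem,
        session=session,
        fps=fps,
        data=data,
        bodypart_map=resolve_bodypart_map(bodyparts, bodypart_map),
    )


def write_keypoint_table(
    track: KeypointTrack, path: str | Path, dialect: str = "dlc_csv",
    scorer: str = "sitpheno",
) -> None:
    """Write a track back out in the DLC dialect; round-trips bit-equal
    coordinates through :func:`read_keypoint_table`."""
    path = Path(path)
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    if dialect == "dlc_csv":
        # repr-level float formatting so the round trip is bit-exact
        df.to_csv(path, float_format="%.17g")
    elif dialect == "dlc_h5":
        df.to_hdf(path, key="df_with_missing", mode="w", format="fixed")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _interp_series(
    vals: np.ndarray, good: np.ndarray
) -> np.ndarray:
    """Linear interpolation of ``vals`` at ~good positions from good ones;
    edges take the nearest good value."""
    idx = np.arange(vals.size)
    return np.interp(idx, idx[good], vals[good])


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open intervals."""
    out = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, mask.size))
    return out


def fill_low_confidence(
    track: KeypointTrack,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> tuple[KeypointTrack, GapReport]:
    """Repair tracking dropouts by per-bodypart linear interpolation.

    Frames whose likelihood falls below ``likelihood_threshold`` are replaced
    by linear interpolation between the nearest confident neighbours (nearest
    confident value at the track edges).  Runs of low-confidence frames longer
    than ``max_gap`` seconds are still filled but reported in the returned
    :class:`GapReport` so downstream metrics can exclude them.  Confident
    frames are never altered, and the operation is idempotent.

    Raises
    ------
    UnrecoverableTrackError
        If a bodypart has no confident frame at all.
    """
    if not 0 <= likelihood_threshold <= 1:
        raise ValueError("likelihood_threshold must lie in [0, 1]")
    max_gap_frames = max_gap * track.fps
    data = track.data.copy()
    n_filled: dict[str, int] = {}
    long_gaps: dict[str, list[tuple[int, int]]] = {}
    for bp in track.bodyparts:
        lik = data[(bp, "likelihood")].to_numpy(dtype=float)
        bad = ~(lik >= likelihood_threshold)  # NaN likelihood counts as bad
        if not bad.any():
            n_filled[bp] = 0
            long_gaps[bp] = []
            continue
        good = ~bad
        if not good.any():
            raise UnrecoverableTrackError(
                f"bodypart {bp!r} has no frame with likelihood >= "
                f"{likelihood_threshold}; track cannot be repaired"
            )
        for coord in ("x", "y"):
            vals = data[(bp, coord)].to_numpy(dtype=float)
            filled = vals.copy()
            filled[bad] = _interp_series(vals, good)[bad]
            data[(bp, coord)] = filled
        n_filled[bp] = int(bad.sum())
        long_gaps[bp] = [
            (a, b) for a, b in _runs(bad) if (b - a) > max_gap_frames
        ]
    report = GapReport(
        likelihood_threshold=likelihood_threshold,
        max_gap_s=max_gap,
        n_filled=n_filled,
        long_gaps=long_gaps,
    )
    return replace(track, data=data), report
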