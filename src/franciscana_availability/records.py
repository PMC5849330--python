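"""Surface-dive cycle records: data model, validation, filtering, summaries.

A *surface-dive cycle* is one surfacing interval (at least one group member
visible at or near the surface) followed by one diving interval (no member
visible).  The *proportion at surface* of cycle ``i`` is ``s_i / (s_i + d_i)``.
Records are organised as :class:`GroupSession` objects: one tracked group with
its covariates and an ordered list of :class:`DiveCycle` objects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("high", "moderate", "low")

#: Covariate validation bounds (defaults follow the study ranges).
DEFAULT_BOUNDS = {
    "group_size": (1, 7),
    "depth_m": (4.4, 12.0),
    "transparency_cm": (77.0, 162.0),
    "tide_m": (0.3, 1.2),
}

#: Column order of the cycle CSV interchange format.
CSV_COLUMNS = [
    "group_id",
    "cycle_index",
    "surface_s",
    "dive_s",
    "group_size",
    "calves",
    "depth_m",
    "transparency_cm",
    "tide_m",
    "confidence",
    "reaction",
    "first_interval",
]


class ValidationError(ValueError):
    """A record violates a structural invariant."""


@dataclass(frozen=True)
class DiveCycle:
    """One surfacing interval plus the following dive interval.

    Parameters
    ----------
    group_id : str
        Identifier of the tracked group the cycle belongs to.
    cycle_index : int
        1-based position of the cycle within its group's record.
    surface_s, dive_s : float
        Surfacing and diving interval durations in seconds; both must be
        strictly positive.
    reaction : bool
        Whether a disturbance response to the survey platform was noted.
    confidence : str
        Observer tracking-confidence class: ``high``, ``moderate`` or ``low``.
    """

    group_id: str
    cycle_index: int
    surface_s: float
    dive_s: float
    reaction: bool = False
    confidence: str = "high"

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ValidationError(
                f"cycle_index must be >= 1, got {self.cycle_index} "
                f"(group {self.group_id})"
            )
        if not self.surface_s > 0:
            raise ValidationError(
                f"non-positive surfacing interval {self.surface_s} s in cycle "
                f"{self.cycle_index} of group {self.group_id}"
            )
        if not self.dive_s > 0:
            raise ValidationError(
                f"non-positive diving interval {self.dive_s} s in cycle "
                f"{self.cycle_index} of group {self.group_id}"
            )
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"unknown confidence class {self.confidence!r} in cycle "
                f"{self.cycle_index} of group {self.group_id}"
            )

    @property
    def proportion_at_surface(self) -> float:
        """s_i / (s_i + d_i), strictly inside (0, 1)."""
        return self.surface_s / (self.surface_s + self.dive_s)


def proportion_at_surface(cycle: DiveCycle) -> float:
    """Proportion of the cycle the group spent visually available.

    Defined as ``s_i / (s_i + d_i)``; strictly in (0, 1) because both
    durations are strictly positive.
    """
    return cycle.proportion_at_surface


#: Group-size class threshold: groups of <= 4 individuals count as small.
LARGE_GROUP_MIN = 5


@dataclass(frozen=True)
class GroupSession:
    """A tracked group: covariates plus its ordered surface-dive cycles."""

    group_id: str
    group_size: int
    calves: bool
    depth_m: float
    transparency_cm: float
    tide_m: float
    cycles: tuple[DiveCycle, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", tuple(self.cycles))
        if self.group_size < 1:
            raise ValidationError(
                f"group {self.group_id}: group_size must be >= 1, "
                f"got {self.group_size}"
            )
        idx = [c.cycle_index for c in self.cycles]
        if idx != list(range(1, len(idx) + 1)):
            raise ValidationError(
                f"group {self.group_id}: cycle_index values must be contiguous "
                f"from 1, got {idx}"
            )
        for c in self.cycles:
            if c.group_id != self.group_id:
                raise ValidationError(
                    f"cycle {c.cycle_index} carries group_id {c.group_id!r} "
                    f"inside session {self.group_id!r}"
                )

    @property
    def size_class(self) -> str:
        """``small`` for groups of 1-4 individuals, ``large`` for 5+."""
        return "large" if self.group_size >= LARGE_GROUP_MIN else "small"

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def validate_covariates(
    sessions: Iterable[GroupSession],
    bounds: dict | None = None,
    strict: bool = False,
) -> list[str]:
    """Check session covariates against validation bounds.

    Out-of-range values produce warnings (returned as a list of messages);
    with ``strict=True`` the first violation raises :class:`ValidationError`.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    messages = []
    for s in sessions:
        for attr in ("group_size", "depth_m", "transparency_cm", "tide_m"):
            if attr not in bounds:
                continue
            lo, hi = bounds[attr]
            val = getattr(s, attr)
            if not lo <= val <= hi:
                msg = (
                    f"group {s.group_id}: {attr}={val} outside [{lo}, {hi}]"
                )
                if strict:
                    raise ValidationError(msg)
                warnings.warn(msg, stacklevel=2)
                messages.append(msg)
    return messages


@dataclass(frozen=True)
class FilterConfig:
    """Cycle exclusion rules.

    Defaults mirror the study protocol: keep only high-confidence cycles and
    drop cycles where a disturbance reaction was documented.
    """

    keep_confidence: tuple[str, ...] = ("high",)
    drop_reaction: bool = True


@dataclass
class ExclusionReport:
    """Accounting of cycles and groups removed by :func:`filter_cycles`."""

    n_cycles_in: int
    n_cycles_out: int
    n_reaction_removed: int
    n_confidence_removed: int
    n_groups_in: int
    n_groups_out: int
    groups_lost: tuple[str, ...]

    @property
    def n_groups_lost(self) -> int:
        return len(self.groups_lost)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cycles_in", self.n_cycles_in),
            ("cycles_removed_reaction", self.n_reaction_removed),
            ("cycles_removed_confidence", self.n_confidence_removed),
            ("cycles_out", self.n_cycles_out),
            ("groups_in", self.n_groups_in),
            ("groups_lost", self.n_groups_lost),
            ("groups_out", self.n_groups_out),
        ]
        return pd.DataFrame(rows, columns=["quantity", "count"])


def filter_cycles(
    sessions: Sequence[GroupSession],
    rules: FilterConfig | None = None,
) -> tuple[list[GroupSession], ExclusionReport]:
    """Apply the exclusion rules and drop groups left with no cycles.

    Reaction-flagged cycles are removed first, then cycles outside the kept
    confidence classes; a cycle failing both rules is counted against the
    reaction rule.  Surviving cycles are re-indexed contiguously from 1 so the
    result is again a valid session list (and the operation is idempotent).
    """
    rules = rules or FilterConfig()
    kept_sessions: list[GroupSession] = []
    n_in = n_react = n_conf = 0
    lost: list[str] = []
    for s in sessions:
        kept: list[DiveCycle] = []
        for c in s.cycles:
            n_in += 1
            if rules.drop_reaction and c.reaction:
                n_react += 1
                continue
            if c.confidence not in rules.keep_confidence:
                n_conf += 1
                continue
            kept.append(c)
        if kept:
            kept = [
                replace(c, cycle_index=i + 1) for i, c in enumerate(kept)
            ]
            kept_sessions.append(replace(s, cycles=tuple(kept)))
        else:
            lost.append(s.group_id)
    report = ExclusionReport(
        n_cycles_in=n_in,
        n_cycles_out=sum(s.n_cycles for s in kept_sessions),
        n_reaction_removed=n_react,
        n_confidence_removed=n_conf,
        n_groups_in=len(sessions),
        n_groups_out=len(kept_sessions),
        groups_lost=tuple(lost),
    )
    logger.info(
        "filter: %d -> %d cycles (%d reaction, %d confidence), "
        "%d -> %d groups",
        n_in,
        report.n_cycles_out,
        n_react,
        n_conf,
        report.n_groups_in,
        report.n_groups_out,
    )
    return kept_sessions, report


@dataclass(frozen=True)
class DiveSummary:
    """Pooled summary statistics over a collection of surface-dive cycles.

    Durations are pooled over cycles (not per-group means); dispersion fields
    are sample standard deviations over cycles.
    """

    n_cycles: int
    n_groups: int
    mean_surface_s: float
    sd_surface_s: float
    median_surface_s: float
    mean_dive_s: float
    sd_dive_s: float
    median_dive_s: float
    mean_proportion: float
    sd_proportion: float

    @property
    def mean_cycles_per_group(self) -> float:
        return self.n_cycles / self.n_groups

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["mean_cycles_per_group"] = self.mean_cycles_per_group
        return d


def _sd(x: np.ndarray) -> float:
    # sample SD; the source tables label these dispersions "SE"
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize(sessions: Sequence[GroupSession]) -> DiveSummary:
    """Pooled dive-parameter summary: E(s), E(d), dispersions, proportions."""
    cycles = [c for s in sessions for c in s.cycles]
    if not cycles:
        raise ValidationError("cannot summarize an empty cycle collection")
    surf = np.array([c.surface_s for c in cycles], dtype=float)
    dive = np.array([c.dive_s for c in cycles], dtype=float)
    prop = surf / (surf + dive)
    return DiveSummary(
        n_cycles=len(cycles),
        n_groups=len(sessions),
        mean_surface_s=float(surf.mean()),
        sd_surface_s=_sd(surf),
        median_surface_s=float(median(surf)),
        mean_dive_s=float(dive.mean()),
        sd_dive_s=_sd(dive),
        median_dive_s=float(median(dive)),
        mean_proportion=float(prop.mean()),
        sd_proportion=_sd(prop),
    )


# ---------------------------------------------------------------------------
# CSV interchange


def sessions_to_frame(sessions: Sequence[GroupSession]) -> pd.DataFrame:
    """Flatten sessions to the one-row-per-cycle interchange table."""
    rows = []
    for s in sessions:
        for c in s.cycles:
            rows.append(
                {
                    "group_id": s.group_id,
                    "cycle_index": c.cycle_index,
                    "surface_s": c.surface_s,
                    "dive_s": c.dive_s,
                    "group_size": s.group_size,
                    "calves": int(s.calves),
                    "depth_m": s.depth_m,
                    "transparency_cm": s.transparency_cm,
                    "tide_m": s.tide_m,
                    "confidence": c.confidence,
                    "reaction": int(c.reaction),
                    "first_interval": 0,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_sessions(df: pd.DataFrame) -> list[GroupSession]:
    """Assemble :class:`GroupSession` objects from the interchange table.

    Rows flagged ``first_interval`` are rejected: the record protocol starts
    each group's cycle sequence at the first dive, so a first post-sighting
    surface interval is not a complete cycle.
    """
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if "first_interval" in df.columns:
        n_first = int(df["first_interval"].astype(int).sum())
        if n_first:
            logger.warning(
                "dropping %d first-interval record(s): not complete cycles",
                n_first,
            )
            df = df[df["first_interval"].astype(int) == 0]
    sessions = []
    for gid, grp in df.groupby("group_id", sort=False):
        grp = grp.sort_values("cycle_index")
        meta = grp.iloc[0]
        cycles = tuple(
            DiveCycle(
                group_id=str(gid),
                cycle_index=int(r.cycle_index),
                surface_s=float(r.surface_s),
                dive_s=float(r.dive_s),
                reaction=bool(int(r.reaction)),
                confidence=str(r.confidence),
            )
            for r in grp.itertuples()
        )
        sessions.append(
            GroupSession(
                group_id=str(gid),
                group_size=int(meta.group_size),
                calves=bool(int(meta.calves)),
                depth_m=float(meta.depth_m),
                transparency_cm=float(meta.transparency_cm),
                tide_m=float(meta.tide_m),
                cycles=cycles,
            )
        )
    return sessions


def write_cycles_csv(sessions: Sequence[GroupSession], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_cycles_csv(path) -> list[GroupSession]:
    """Read the cycle CSV (UTF-8, header row, decimal point)."""
    df = pd.read_csv(path, comment="#")
    return frame_to_sessions(df)
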