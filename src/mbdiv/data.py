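"""Domain types and I/O for fossil diversification analyses.

Time is measured in Ma before present: the present is 0 and values
increase into the past.  A lineage record holds a genus's origination
time ``ts`` and extinction time ``te`` (``te = 0`` marks an extant
genus).  An extinct lineage occupies the half-open interval ``(te, ts]``;
an extant lineage occupies ``[0, ts]``.

All tabular formats are plain TSV:

* lineage table: columns ``taxon``, ``ts``, ``te``;
* occurrence table: columns ``taxon``, ``age_min``, ``age_max``,
  ``extant`` (0/1);
* covariate table: columns ``time``, ``value``, one file per covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCovariateError,
    FormatError,
    ValidationError,
)

__all__ = [
    "LineageRecord",
    "FossilOccurrence",
    "CovariateTrajectory",
    "EpochGrid",
    "read_lineage_table",
    "write_lineage_table",
    "read_occurrence_table",
    "write_occurrence_table",
    "read_covariate_table",
    "write_covariate_table",
    "read_covariate_dir",
    "read_epoch_grid",
    "rescale_covariate",
    "resample_occurrence_ages",
    "lineages_from_occurrence_ages",
    "diversity_trajectory",
]


@dataclass(frozen=True)
class LineageRecord:
    """One genus: origination time ``ts`` and extinction time ``te`` (Ma).

    ``te = 0`` denotes an extant genus.  Invariant: ``ts > te >= 0``.
    """

    taxon: str
    ts: float
    te: float

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("lineage record with empty taxon name")
        if not np.isfinite(self.ts) or not np.isfinite(self.te):
            raise ValidationError(f"non-finite times for taxon {self.taxon!r}")
        if self.te < 0:
            raise ValidationError(f"negative te for taxon {self.taxon!r}")
        if self.ts <= self.te:
            raise ValidationError(
                f"taxon {self.taxon!r}: ts ({self.ts}) must exceed te ({self.te})"
            )

    @property
    def extant(self) -> bool:
        return self.te == 0.0

    @property
    def duration(self) -> float:
        return self.ts - self.te


@dataclass(frozen=True)
class FossilOccurrence:
    """A fossil occurrence with stratigraphic age bounds (Ma)."""

    taxon: str
    age_min: float
    age_max: float
    extant: bool = False

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("occurrence with empty taxon name")
        if self.age_min < 0 or self.age_max < self.age_min:
            raise ValidationError(
                f"taxon {self.taxon!r}: need age_max >= age_min >= 0, "
                f"got [{self.age_min}, {self.age_max}]"
            )


@dataclass
class CovariateTrajectory:
    """A time-continuous predictor C(t) tabulated on a time grid.

    Stored oldest-first (times strictly decreasing).  Between tabulated
    points the value is piecewise-linear; outside the tabulated range it
    is constant-extrapolated from the nearest endpoint.  Covariates must
    be min-max rescaled to [0, 1] (``rescaled=True``) before entering a
    multivariate birth-death model.
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    rescaled: bool = False
    _asc_times: np.ndarray = field(init=False, repr=False)
    _asc_values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValidationError(f"covariate {self.name!r}: times/values mismatch")
        if t.size < 2:
            raise ValidationError(f"covariate {self.name!r}: need >= 2 points")
        d = np.diff(t)
        if np.any(d == 0):
            raise ValidationError(f"covariate {self.name!r}: duplicate times")
        if np.all(d < 0):
            pass  # already oldest first
        elif np.all(d > 0):
            t, v = t[::-1], v[::-1]
        else:
            raise ValidationError(f"covariate {self.name!r}: times not monotone")
        if self.rescaled and (v.min() < 0.0 or v.max() > 1.0):
            raise ValidationError(
                f"covariate {self.name!r}: flagged rescaled but range is "
                f"[{v.min()}, {v.max()}]"
            )
        self.times = t
        self.values = v
        self._asc_times = t[::-1].copy()
        self._asc_values = v[::-1].copy()

    def at(self, t) -> np.ndarray:
        """Interpolated value(s) at time(s) ``t`` (linear inside the
        tabulated range, constant outside it)."""
        return np.interp(t, self._asc_times, self._asc_values)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EpochGrid:
    """Stratigraphic interval boundaries, oldest first, ending at 0 Ma.

    ``K = len(boundaries) - 1`` intervals.  A time falling exactly on a
    boundary belongs to the younger interval (half-open convention
    ``(older, younger]`` with the older bound included in the interval
    whose older edge it is).
    """

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValidationError("epoch grid needs >= 2 boundaries")
        if np.any(np.diff(b) >= 0):
            raise ValidationError("epoch boundaries must be strictly decreasing")
        if b[-1] != 0.0:
            raise ValidationError("youngest epoch boundary must be 0")
        object.__setattr__(self, "boundaries", b)

    @property
    def k(self) -> int:
        return self.boundaries.size - 1

    @property
    def span(self) -> float:
        return float(self.boundaries[0])

    def index_of(self, t) -> np.ndarray:
        """Epoch index (0 = oldest) containing time(s) ``t``.

        Boundary times map to the younger epoch; t = 0 maps to the
        youngest epoch.
        """
        asc = self.boundaries[::-1]  # ascending: 0 ... oldest
        j = np.searchsorted(asc, np.asarray(t, dtype=float), side="left") - 1
        j = np.clip(j, 0, self.k - 1)
        return (self.k - 1) - j

    def overlap_lengths(self, t_young, t_old) -> np.ndarray:
        """Length of (t_young, t_old] falling in each epoch, oldest first."""
        old_edges = self.boundaries[:-1]
        young_edges = self.boundaries[1:]
        lo = np.maximum(young_edges, float(t_young))
        hi = np.minimum(old_edges, float(t_old))
        return np.maximum(0.0, hi - lo)

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.boundaries[:-1] + self.boundaries[1:])


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_lineage_table(path) -> list[LineageRecord]:
    """Read a TSV with columns taxon, ts, te into lineage records.

    Row order is preserved; duplicate taxa raise a validation error.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["taxon", "ts", "te"], path)
    records = [
        LineageRecord(str(r.taxon), float(r.ts), float(r.te))
        for r in df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.taxon in seen:
            raise ValidationError(f"duplicate taxon {rec.taxon!r} in {path}")
        seen.add(rec.taxon)
    return records


def write_lineage_table(lineages: Iterable[LineageRecord], path) -> None:
    df = pd.DataFrame(
        [(l.taxon, l.ts, l.te) for l in lineages], columns=["taxon", "ts", "te"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_occurrence_table(path) -> list[FossilOccurrence]:
    """Read a TSV with columns taxon, age_min, age_max, extant (0/1)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["taxon", "age_min", "age_max", "extant"], path)
    return [
        FossilOccurrence(
            str(r.taxon), float(r.age_min), float(r.age_max), bool(int(r.extant))
        )
        for r in df.itertuples(index=False)
    ]


def write_occurrence_table(occs: Iterable[FossilOccurrence], path) -> None:
    df = pd.DataFrame(
        [(o.taxon, o.age_min, o.age_max, int(o.extant)) for o in occs],
        columns=["taxon", "age_min", "age_max", "extant"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_covariate_table(path, name: str | None = None) -> CovariateTrajectory:
    """Read one covariate trajectory from a two-column TSV (time, value)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["time", "value"], path)
    if len(df) < 2:
        raise FormatError(f"{path}: covariate needs >= 2 rows")
    if name is None:
        name = Path(path).stem
    return CovariateTrajectory(
        name, df["time"].to_numpy(float), df["value"].to_numpy(float)
    )


def write_covariate_table(traj: CovariateTrajectory, path) -> None:
    pd.DataFrame({"time": traj.times, "value": traj.values}).to_csv(
        path, sep="\t", index=False
    )


def read_covariate_dir(directory) -> list[CovariateTrajectory]:
    """Read every ``*.tsv`` in a directory as a covariate, sorted by name."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise FormatError(f"no covariate .tsv files found in {directory}")
    return [read_covariate_table(p) for p in paths]


def read_epoch_grid(path) -> EpochGrid:
    """Read epoch boundaries from a one-column TSV (a header line is skipped
    if it is not numeric)."""
    vals: list[float] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            s = line.strip()
            if not s:
                continue
            try:
                vals.append(float(s))
            except ValueError:
                if i == 0:
                    continue
                raise FormatError(f"{path}: non-numeric boundary {s!r}")
    return EpochGrid(np.asarray(vals, dtype=float))


# ---------------------------------------------------------------------------
# transformations


def rescale_covariate(
    traj: CovariateTrajectory, window: tuple[float, float] | None = None
) -> CovariateTrajectory:
    """Min-max rescale a covariate to [0, 1].

    ``window = (t_young, t_old)`` restricts the min/max to tabulated
    points inside the analysis window; by default the full tabulated
    range is used.  A constant trajectory carries no information and
    raises :class:`DegenerateCovariateError`.
    """
    if traj.rescaled:
        raise ValidationError(f"covariate {traj.name!r} is already rescaled")
    v = traj.values
    if window is not None:
        t_young, t_old = window
        mask = (traj.times >= t_young) & (traj.times <= t_old)
        if mask.sum() < 2:
            raise ValidationError(
                f"covariate {traj.name!r}: window {window} covers < 2 points"
            )
        ref = v[mask]
    else:
        ref = v
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        raise DegenerateCovariateError(
            f"covariate {traj.name!r} is constant over the rescaling window"
        )
    scaled = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    return CovariateTrajectory(traj.name, traj.times.copy(), scaled, rescaled=True)


def resample_occurrence_ages(
    occs: Sequence[FossilOccurrence], n_reps: int, seed: int
) -> np.ndarray:
    """Draw ``n_reps`` replicate age assignments for every occurrence.

    Each age is drawn uniformly on [age_min, age_max], independently per
    occurrence and replicate; replicate ``r`` uses the derived stream
    ``seed + r`` so individual replicates are reproducible in isolation.
    Returns an array of shape ``(n_reps, n_occurrences)``.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    lo = np.array([o.age_min for o in occs], dtype=float)
    hi = np.array([o.age_max for o in occs], dtype=float)
    out = np.empty((n_reps, len(occs)), dtype=float)
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        u = rng.random(len(occs))
        out[r] = lo + u * (hi - lo)
    return out


def lineages_from_occurrence_ages(
    occs: Sequence[FossilOccurrence], ages: np.ndarray
) -> list[LineageRecord]:
    """Build per-taxon lineage records from one replicate of sampled ages.

    The observed stratigraphic range is used as a proxy for the true
    lineage span: ts is the oldest sampled age of the taxon, te the
    youngest (0 for extant taxa).  Extinct taxa whose range collapses to
    a point (e.g. a single occurrence) cannot enter the likelihood and
    are dropped with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.shape != (len(occs),):
        raise ValidationError("ages must align with the occurrence list")
    table: dict[str, list[float]] = {}
    extant: dict[str, bool] = {}
    order: list[str] = []
    for o, a in zip(occs, ages):
        if o.taxon not in table:
            table[o.taxon] = []
            extant[o.taxon] = False
            order.append(o.taxon)
        table[o.taxon].append(float(a))
        extant[o.taxon] = extant[o.taxon] or o.extant
    out: list[LineageRecord] = []
    for taxon in order:
        ts = max(table[taxon])
        te = 0.0 if extant[taxon] else min(table[taxon])
        if ts <= te:
            warnings.warn(
                f"taxon {taxon!r}: degenerate sampled range (ts={ts}, te={te}); "
                "dropped",
                stacklevel=2,
            )
            continue
        out.append(LineageRecord(taxon, ts, te))
    return out


def diversity_trajectory(
    lineages: Sequence[LineageRecord], grid
) -> CovariateTrajectory:
    """Standing lineage diversity evaluated on a time grid.

    A lineage counts at time t if ``ts >= t`` and it has not yet gone
    extinct at t (extinct lineages occupy ``(te, ts]``, extant ones
    ``[0, ts]``).  Returned un-rescaled, suitable as a diversity
    covariate after :func:`rescale_covariate`.
    """
    t = np.asarray(grid, dtype=float)
    counts = np.zeros_like(t)
    for l in lineages:
        alive = (l.ts >= t) & ((t > l.te) | (l.te == 0.0))
        counts += alive
    return CovariateTrajectory("diversity", t, counts, rescaled=False)
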