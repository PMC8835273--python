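"""Study inventory and data plumbing.

Holds the variable inventory (12 spatial, 2 activity, 3 individual-difference
and 2 social-interaction variables), the 35-unit spatial inventory of the
three parks, the continuous-to-categorical discretization rules, and dataset
validation.  All category systems are ordered; numeric bins follow a
half-open ``[lower, upper)`` convention with the last bin closed, so every
in-domain measurement maps to exactly one state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SPACE_TYPES",
    "PARKS",
    "QUESTIONNAIRES_BY_PARK",
    "VariableSpec",
    "SpatialUnit",
    "ObservationRecord",
    "Dataset",
    "ValidationReport",
    "FixtureError",
    "OutOfRangeError",
    "load_variable_specs",
    "load_units",
    "discretize",
    "unit_inventory_counts",
    "validate_dataset",
    "fit_quantile_spec",
]

#: Sentinel for a cell that was not observed.  Stored as an empty CSV cell /
#: NaN in frames; never a modeled category.
MISSING = None

SPACE_TYPES = ("fitness_equipment", "path", "sports_court")
PARKS = ("Dashuijing", "Huilongwan", "Danlong")

#: Valid questionnaires collected per park in the field campaign.
QUESTIONNAIRES_BY_PARK = {"Dashuijing": 124, "Huilongwan": 133, "Danlong": 96}

_ROLES = ("spatial", "activity", "individual", "interaction")


class FixtureError(ValueError):
    """A packaged or user-supplied fixture failed to parse or validate."""


class OutOfRangeError(ValueError):
    """A measurement fell outside every declared bin of its variable."""


@dataclass(frozen=True)
class VariableSpec:
    """A named categorical variable with ordered states.

    ``bin_edges`` (when present) map a continuous measurement onto the
    states: state ``i`` covers ``[edges[i], edges[i+1])``, the last state's
    interval is closed on the right.  ``math.inf``/``-math.inf`` edges mark
    unbounded outer bins.
    """

    name: str
    role: str
    states: tuple[str, ...]
    bin_edges: tuple[float, ...] | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise FixtureError(f"variable {self.name!r}: unknown role {self.role!r}")
        if len(self.states) < 2:
            raise FixtureError(f"variable {self.name!r}: needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise FixtureError(f"variable {self.name!r}: duplicate states")
        object.__setattr__(self, "states", tuple(self.states))
        if self.bin_edges is not None:
            edges = tuple(float(e) for e in self.bin_edges)
            if len(edges) != len(self.states) + 1:
                raise FixtureError(
                    f"variable {self.name!r}: {len(edges)} edges for "
                    f"{len(self.states)} states (need n_states + 1)"
                )
            if any(a >= b for a, b in zip(edges, edges[1:])):
                raise FixtureError(f"variable {self.name!r}: bin edges not strictly increasing")
            object.__setattr__(self, "bin_edges", edges)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(f"{state!r} is not a state of variable {self.name!r}") from None


@dataclass(frozen=True)
class SpatialUnit:
    """One of the 35 numbered spatial study units."""

    unit_id: int
    park: str
    space_type: str
    subtype: str

    def __post_init__(self) -> None:
        if self.park not in PARKS:
            raise FixtureError(f"unit {self.unit_id}: unknown park {self.park!r}")
        if self.space_type not in SPACE_TYPES:
            raise FixtureError(f"unit {self.unit_id}: unknown space type {self.space_type!r}")


@dataclass(frozen=True)
class ObservationRecord:
    """One respondent/observation row: unit, variable states, weight."""

    unit_id: int
    values: Mapping[str, str | None]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("record weight must be positive")


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    missingness: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class Dataset:
    """Variable specs plus an observation table.

    Internally the records live in a :class:`pandas.DataFrame` with one
    column per variable (``object`` dtype, NaN = missing) plus ``unit_id``
    and ``weight``; :class:`ObservationRecord` views are built on demand.
    """

    specs: list[VariableSpec]
    frame: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        names = {s.name for s in self.specs}
        extra = set(self.variable_columns()) - names
        if extra:
            raise ValueError(f"dataset columns without a spec: {sorted(extra)}")
        if "unit_id" not in self.frame.columns:
            self.frame = self.frame.assign(unit_id=0)
        if "weight" not in self.frame.columns:
            self.frame = self.frame.assign(weight=1.0)
        self.frame = self.frame.reset_index(drop=True)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        specs: Sequence[VariableSpec],
        records: Iterable[ObservationRecord],
        provenance: str = "survey",
    ) -> "Dataset":
        rows = []
        for rec in records:
            row = {"unit_id": rec.unit_id, "weight": rec.weight}
            row.update({k: (np.nan if v is MISSING else v) for k, v in rec.values.items()})
            rows.append(row)
        frame = pd.DataFrame(rows)
        return cls(list(specs), frame, provenance)

    def variable_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("unit_id", "weight")]

    def spec_by_name(self) -> dict[str, VariableSpec]:
        return {s.name: s for s in self.specs}

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[ObservationRecord]:
        cols = self.variable_columns()
        out = []
        for _, row in self.frame.iterrows():
            values = {c: (MISSING if pd.isna(row[c]) else row[c]) for c in cols}
            out.append(ObservationRecord(int(row["unit_id"]), values, float(row["weight"])))
        return out

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        cols = ["unit_id", "weight"] + self.variable_columns()
        self.frame[cols].to_csv(path, index=False, na_rep="")

    @classmethod
    def read_csv(
        cls, path: str | Path, specs: Sequence[VariableSpec], provenance: str = "survey"
    ) -> "Dataset":
        frame = pd.read_csv(path, dtype={"unit_id": int}, keep_default_na=False)
        for c in frame.columns:
            if c in ("unit_id", "weight"):
                continue
            frame[c] = frame[c].replace("", np.nan)
        return cls(list(specs), frame, provenance)

    def subset(self, index: Sequence[int]) -> "Dataset":
        return Dataset(self.specs, self.frame.iloc[list(index)].reset_index(drop=True), self.provenance)

    def codes(self, columns: Sequence[str] | None = None) -> np.ndarray:
        """Integer state codes, ``-1`` for missing; shape (n_records, n_cols)."""
        cols = list(columns) if columns is not None else self.variable_columns()
        by_name = self.spec_by_name()
        out = np.empty((len(self.frame), len(cols)), dtype=np.int64)
        for j, c in enumerate(cols):
            spec = by_name[c]
            cat = pd.Categorical(self.frame[c], categories=list(spec.states))
            bad = self.frame[c].notna() & pd.Series(cat.codes == -1, index=self.frame.index)
            if bad.any():
                i = int(bad.idxmax())
                raise ValueError(
                    f"record {i}: {self.frame[c].iloc[i]!r} is not a state of {c!r}"
                )
            out[:, j] = cat.codes
        return out


# ---------------------------------------------------------------------------
# fixtures


def _packaged(name: str) -> Path:
    return Path(str(resources.files("parksocial").joinpath("data", name)))


def load_variable_specs(fixture_path: str | Path | None = None) -> list[VariableSpec]:
    """Load the variable inventory (packaged fixture by default)."""
    path = Path(fixture_path) if fixture_path is not None else _packaged("variables.json")
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FixtureError(f"cannot parse variable fixture {path}: {exc}") from exc
    if not isinstance(doc, dict) or "variables" not in doc:
        raise FixtureError(f"variable fixture {path} lacks a 'variables' list")
    specs = []
    seen = set()
    for entry in doc["variables"]:
        try:
            name = entry["name"]
            if name in seen:
                raise FixtureError(f"variable {name!r} appears twice")
            seen.add(name)
            edges = entry.get("bin_edges")
            if edges is not None:
                # null in JSON marks an unbounded outer edge
                edges = tuple(
                    (-math.inf if i == 0 else math.inf) if e is None else float(e)
                    for i, e in enumerate(edges)
                )
            specs.append(
                VariableSpec(
                    name=name,
                    role=entry["role"],
                    states=tuple(entry["states"]),
                    bin_edges=edges,
                    unit=entry.get("unit"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise FixtureError(
                f"malformed variable entry {entry.get('name', entry)!r}: {exc}"
            ) from exc
    return specs


def load_units(fixture_path: str | Path | None = None) -> list[SpatialUnit]:
    """Load the 35-unit spatial inventory (packaged fixture by default)."""
    path = Path(fixture_path) if fixture_path is not None else _packaged("units.json")
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FixtureError(f"cannot parse unit fixture {path}: {exc}") from exc
    units = [SpatialUnit(**entry) for entry in doc["units"]]
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate unit_id in unit fixture")
    return units


# ---------------------------------------------------------------------------
# discretization


def discretize(value: float, spec: VariableSpec) -> str:
    """Map a continuous measurement onto its categorical state.

    Bins are half-open ``[lower, upper)``; the last bin is closed so the
    declared maximum maps to the top state.  Out-of-domain values raise
    :class:`OutOfRangeError` rather than being clamped.
    """
    if spec.bin_edges is None:
        raise ValueError(f"variable {spec.name!r} has no bin edges; it is already categorical")
    value = float(value)
    if math.isnan(value):
        raise OutOfRangeError(f"{spec.name}: NaN measurement")
    edges = spec.bin_edges
    if value < edges[0] or value > edges[-1]:
        raise OutOfRangeError(
            f"{spec.name}: value {value!r} outside declared domain [{edges[0]}, {edges[-1]}]"
        )
    if value == edges[-1]:
        return spec.states[-1]
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return spec.states[idx]


def fit_quantile_spec(
    name: str,
    values: Sequence[float],
    states: Sequence[str],
    role: str = "interaction",
    unit: str | None = None,
) -> VariableSpec:
    """Build a spec with equal-frequency bins fitted on ``values``.

    Used for the two interaction scores, whose category systems have no
    published numeric edges: cut points are the ``i/k`` quantiles of the
    training values, with unbounded outer bins so held-out values always
    discretize.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name}: no values to fit quantile bins on")
    k = len(states)
    inner = np.quantile(arr, [i / k for i in range(1, k)])
    edges = (-math.inf, *inner, math.inf)
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError(
            f"{name}: tied quantile cut points {inner.tolist()}; "
            "supply explicit bin edges instead"
        )
    return VariableSpec(name=name, role=role, states=tuple(states), bin_edges=edges, unit=unit)


# ---------------------------------------------------------------------------
# inventory and validation


def unit_inventory_counts(units: Sequence[SpatialUnit]) -> dict:
    """Tally units by space type, park and subtype; totals partition the set."""
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id in unit inventory")
    by_type: dict[str, int] = {}
    by_park: dict[str, int] = {}
    by_subtype: dict[str, int] = {}
    for u in units:
        by_type[u.space_type] = by_type.get(u.space_type, 0) + 1
        by_park[u.park] = by_park.get(u.park, 0) + 1
        by_subtype[u.subtype] = by_subtype.get(u.subtype, 0) + 1
    return {
        "total": len(units),
        "by_space_type": by_type,
        "by_park": by_park,
        "by_subtype": by_subtype,
    }


def validate_dataset(ds: Dataset, units: Sequence[SpatialUnit] | None = None) -> ValidationReport:
    """Report illegal states, unknown units and per-variable missingness."""
    report = ValidationReport()
    by_name = ds.spec_by_name()
    if ds.n_records == 0:
        report.warnings.append("dataset has no records")
    unit_ids = {u.unit_id for u in units} if units is not None else None
    for col in ds.variable_columns():
        spec = by_name[col]
        series = ds.frame[col]
        observed = series.notna()
        legal = series.isin(spec.states)
        bad = observed & ~legal
        for i in ds.frame.index[bad]:
            report.errors.append(
                f"record {i}: {series[i]!r} is not a state of variable {col!r}"
            )
        n = len(series)
        report.missingness[col] = float((~observed).sum() / n) if n else 0.0
    if unit_ids is not None:
        unknown = ~ds.frame["unit_id"].isin(list(unit_ids))
        for i in ds.frame.index[unknown]:
            report.errors.append(f"record {i}: unknown unit_id {ds.frame['unit_id'][i]}")
    return report
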