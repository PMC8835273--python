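"""Synthetic observation generator with known ground truth.

The field data behind the original survey are not deposited, so every stage
of the analysis is exercised on synthetic data instead: per-space-type
ground-truth belief networks shaped like the published influence mechanisms
("spatial factors -> activity type -> social interaction"), ancestral
sampling of categorical records from them, and raw behavior-mapping
primitives (congregate sessions, questionnaire items) whose index means are
configured per space type.

Where the source prints child-given-single-parent conditional slices (the
crowds-congregate and engagement CPT tables), those percentages seed the
generator CPTs; multi-parent rows combine the per-parent slices by a
normalized product, and slices never printed are filled with Dirichlet(1)
draws from a fixed fingerprint seed so the packaged nets are fully
reproducible.  An ``effect_strength`` temperature sharpens CPT rows
(``p_i^beta``, renormalized) to produce the strong-effect variants used in
recovery experiments.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bbn import BeliefNetwork, ConditionalTable, NetworkStructure
from .domain import (
    SPACE_TYPES,
    Dataset,
    SpatialUnit,
    VariableSpec,
    load_units,
    load_variable_specs,
)
from .interaction import MAX_CONGREGATE_MINUTES, CongregateSession, EngagementResponse

__all__ = [
    "ScenarioConfig",
    "SessionParams",
    "ground_truth_network",
    "network_variables",
    "sample_records",
    "simulate_sessions",
    "min_row_tv_distance",
    "TARGET_CONGREGATE_MEANS",
    "TARGET_ENGAGEMENT_MEANS",
]

#: Configured per-space-type mean of the congregate index (the published
#: ranking order sports court > path > fitness equipment).
TARGET_CONGREGATE_MEANS = {"sports_court": 0.550, "path": 0.503, "fitness_equipment": 0.426}

#: Configured per-space-type mean engagement score (1-7 scale).
TARGET_ENGAGEMENT_MEANS = {"sports_court": 4.69, "fitness_equipment": 4.42, "path": 4.27}

# ---------------------------------------------------------------------------
# mechanism structure per space type

_EDGES: dict[str, tuple[tuple[str, str], ...]] = {
    "fitness_equipment": (
        ("green_view_index", "physical_activity"),
        ("accessibility", "physical_activity"),
        ("visual_obstacles", "physical_activity"),
        ("fitness_equipment", "physical_activity"),
        ("physical_activity", "crowds_congregate"),
        ("gender", "crowds_congregate"),
        ("seats_density", "leisure_activity"),
        ("leisure_activity", "engagement"),
        ("childrens_play_equipment", "engagement"),
        ("age", "engagement"),
        ("social_relationship", "engagement"),
    ),
    "path": (
        ("visual_obstacles", "crowds_congregate"),
        ("path_width", "crowds_congregate"),
        ("seats_density", "crowds_congregate"),
        ("shrub_area", "leisure_activity"),
        ("leisure_activity", "engagement"),
        ("vegetation_diversity", "engagement"),
        ("seats_density", "engagement"),
        ("social_relationship", "engagement"),
    ),
    "sports_court": (
        ("space_enclosure", "physical_activity"),
        ("accessibility", "physical_activity"),
        ("tree_cover", "physical_activity"),
        ("sports_court", "physical_activity"),
        ("physical_activity", "leisure_activity"),
        ("seats_density", "leisure_activity"),
        ("physical_activity", "engagement"),
        ("crowds_congregate", "engagement"),
        ("social_relationship", "engagement"),
        ("sports_court", "crowds_congregate"),
        ("age", "crowds_congregate"),
    ),
}

# Published conditional slices, percent rows over the child's states,
# keyed (space_type, child, parent) -> rows in parent-state order.
_PRINTED_SLICES: dict[tuple[str, str, str], list[list[float]]] = {
    ("fitness_equipment", "crowds_congregate", "physical_activity"): [
        [31.7, 28.4, 19.5, 17.1, 3.3],
        [19.3, 23.6, 23.9, 23.9, 9.3],
    ],
    ("fitness_equipment", "crowds_congregate", "gender"): [
        [31.4, 27.6, 19.3, 17.9, 3.6],
        [19.6, 24.4, 24.1, 23.1, 8.8],
    ],
    ("path", "crowds_congregate", "visual_obstacles"): [
        [21.4, 19.1, 18.8, 20.0, 20.0],
        [25.1, 21.8, 22.3, 20.0, 20.0],
        [18.5, 23.6, 20.8, 20.0, 20.0],
        [17.6, 18.3, 19.3, 20.0, 20.0],
    ],
    ("path", "crowds_congregate", "path_width"): [
        [19.8, 22.3, 19.5, 19.3, 19.3],
        [20.1, 21.2, 22.0, 18.7, 17.9],
        [19.7, 22.7, 20.8, 18.6, 18.2],
    ],
    ("path", "crowds_congregate", "seats_density"): [
        [21.4, 21.0, 19.5, 19.1, 19.1],
        [20.0, 20.0, 20.0, 20.0, 20.0],
        [18.9, 20.7, 21.8, 19.3, 18.9],
        [19.5, 22.6, 21.8, 18.3, 17.9],
    ],
    ("sports_court", "crowds_congregate", "sports_court"): [
        [15.2, 17.6, 24.4, 21.9, 20.8],
        [14.0, 21.5, 17.9, 20.1, 19.5],
        [17.8, 22.6, 20.5, 17.7, 21.1],
    ],
    ("sports_court", "crowds_congregate", "age"): [
        [20.0, 20.0, 20.0, 20.0, 20.0],
        [29.6, 18.2, 43.5, 33.3, 17.5],
        [12.2, 29.8, 26.1, 15.9, 15.9],
        [9.8, 19.7, 31.7, 17.8, 20.6],
        [14.0, 9.0, 38.5, 21.3, 17.3],
        [12.5, 26.5, 16.3, 15.9, 32.7],
        [24.9, 24.9, 15.3, 15.3, 15.3],
    ],
    ("fitness_equipment", "engagement", "childrens_play_equipment"): [
        [31.4, 36.4, 31.4],
        [31.4, 33.9, 33.9],
        [31.0, 31.0, 37.2],
    ],
    ("fitness_equipment", "engagement", "leisure_activity"): [
        [29.5, 34.5, 35.3],
        [33.3, 33.3, 33.3],
    ],
    ("fitness_equipment", "engagement", "age"): [[31.4, 33.9, 34.3]] * 7,
    ("fitness_equipment", "engagement", "social_relationship"): [
        [33.3, 33.3, 33.3],
        [33.3, 33.3, 33.3],
        [33.3, 33.3, 33.3],
        [25.9, 35.9, 37.6],
    ],
    ("path", "engagement", "leisure_activity"): [
        [33.3, 33.3, 32.3],
        [34.7, 34.0, 31.9],
    ],
    ("path", "engagement", "seats_density"): [
        [35.0, 33.3, 32.2],
        [33.3, 33.3, 33.3],
        [32.8, 36.1, 31.2],
        [33.1, 35.6, 31.3],
    ],
    ("path", "engagement", "vegetation_diversity"): [
        [33.3, 33.3, 33.3],
        [35.5, 32.5, 31.5],
        [33.5, 35.5, 30.5],
        [31.5, 34.5, 33.1],
        [33.3, 33.3, 33.3],
        [34.7, 33.4, 31.8],
    ],
    ("path", "engagement", "social_relationship"): [
        [34.9, 32.9, 32.2],
        [34.3, 34.0, 31.1],
        [32.7, 35.3, 31.7],
        [32.4, 35.4, 31.8],
    ],
    ("sports_court", "engagement", "physical_activity"): [
        [26.9, 36.8, 36.1],
        [26.7, 42.9, 30.1],
    ],
    ("sports_court", "engagement", "social_relationship"): [
        [32.8, 37.8, 28.8],
        [29.1, 37.6, 33.2],
        [22.7, 36.9, 40.2],
        [22.0, 47.0, 30.3],
    ],
    ("sports_court", "engagement", "crowds_congregate"): [
        [42.6, 34.1, 23.2],
        [33.8, 40.6, 25.1],
        [17.0, 57.9, 25.0],
        [18.7, 34.2, 47.0],
        [21.9, 32.4, 45.4],
    ],
}


def network_variables(space_type: str) -> tuple[str, ...]:
    """Variables participating in the space type's mechanism network."""
    edges = _edges_for(space_type)
    seen: list[str] = []
    for p, c in edges:
        for v in (p, c):
            if v not in seen:
                seen.append(v)
    return tuple(seen)


def _edges_for(space_type: str) -> tuple[tuple[str, str], ...]:
    try:
        return _EDGES[space_type]
    except KeyError:
        raise ValueError(
            f"unknown space type {space_type!r}; expected one of {SPACE_TYPES}"
        ) from None


def _fingerprint_seed(*parts: str) -> int:
    """Stable per-name seed for reproducible Dirichlet fills."""
    return zlib.crc32("/".join(parts).encode()) & 0x7FFFFFFF


def _slice_for(
    space_type: str, child: str, parent: str, specs: Mapping[str, VariableSpec]
) -> np.ndarray:
    printed = _PRINTED_SLICES.get((space_type, child, parent))
    if printed is not None:
        rows = np.asarray(printed, dtype=float)
    else:
        rng = np.random.default_rng(_fingerprint_seed(space_type, child, parent))
        rows = rng.dirichlet(
            np.ones(specs[child].n_states), size=specs[parent].n_states
        )
    rows = rows / rows.sum(axis=1, keepdims=True)
    return rows


def _sharpen(rows: np.ndarray, beta: float) -> np.ndarray:
    sharp = np.power(np.maximum(rows, 1e-12), beta)
    return sharp / sharp.sum(axis=-1, keepdims=True)


def ground_truth_network(space_type: str, effect_strength: float = 1.0) -> BeliefNetwork:
    """Packaged generator network for one space type.

    CPT rows for multi-parent children are normalized products of the
    per-parent conditional slices; root marginals are uniform over the
    fixture states.  ``effect_strength`` > 1 sharpens every conditional row,
    strengthening parent effects without changing their direction.
    """
    edges = _edges_for(space_type)
    variables = network_variables(space_type)
    specs = {s.name: s for s in load_variable_specs()}
    structure = NetworkStructure(variables, edges)
    tables: dict[str, ConditionalTable] = {}
    for node in variables:
        spec = specs[node]
        parents = structure.parents(node)
        if not parents:
            probs = np.full(spec.n_states, 1.0 / spec.n_states)
        else:
            slices = [_slice_for(space_type, node, p, specs) for p in parents]
            shape = tuple(specs[p].n_states for p in parents) + (spec.n_states,)
            probs = np.ones(shape)
            for axis, rows in enumerate(slices):
                bshape = [1] * len(parents) + [spec.n_states]
                bshape[axis] = rows.shape[0]
                probs = probs * rows.reshape(bshape)
            probs = probs / probs.sum(axis=-1, keepdims=True)
        if effect_strength != 1.0 and parents:
            probs = _sharpen(probs, effect_strength)
        tables[node] = ConditionalTable(
            node,
            spec.states,
            parents,
            tuple(specs[p].states for p in parents),
            np.atleast_1d(probs),
        )
    return BeliefNetwork(structure, tables)


def min_row_tv_distance(net: BeliefNetwork, child: str, parent: str) -> float:
    """Smallest total-variation distance between the child's conditional rows
    across states of one parent (other parents fixed), minimized over the
    other parents' configurations — a lower bound on the parent's effect."""
    cpt = net.tables[child]
    axis = cpt.parents.index(parent)
    probs = np.moveaxis(cpt.probs, axis, 0)
    k = probs.shape[0]
    flat = probs.reshape(k, -1, probs.shape[-1])
    best = math.inf
    for j in range(flat.shape[1]):
        rows = flat[:, j, :]
        for a in range(k):
            for b in range(a + 1, k):
                best = min(best, 0.5 * float(np.abs(rows[a] - rows[b]).sum()))
    return best


# ---------------------------------------------------------------------------
# scenario configuration and sampling


@dataclass(frozen=True)
class SessionParams:
    """Ranges for behavior-mapping primitives of one space type."""

    n_sessions: int = 120  # ~10 units/type x 4 days x 3 daily windows
    n_responses: int = 118
    area_range_m2: tuple[float, float] = (40.0, 400.0)
    mean_groups: float = 2.0
    group_size_range: tuple[int, int] = (1, 6)
    target_congregate_mean: float = 0.5
    target_engagement_mean: float = 4.5
    time_spread: float = 0.3  # sd of the session-level index noise


_DEFAULT_SESSION_PARAMS = {
    "fitness_equipment": SessionParams(
        area_range_m2=(40.0, 200.0),
        mean_groups=2.0,
        group_size_range=(1, 5),
        target_congregate_mean=TARGET_CONGREGATE_MEANS["fitness_equipment"],
        target_engagement_mean=TARGET_ENGAGEMENT_MEANS["fitness_equipment"],
    ),
    "path": SessionParams(
        # a 2-3.5 m path segment of 25-90 m observed length
        area_range_m2=(80.0, 300.0),
        mean_groups=2.5,
        group_size_range=(1, 4),
        target_congregate_mean=TARGET_CONGREGATE_MEANS["path"],
        target_engagement_mean=TARGET_ENGAGEMENT_MEANS["path"],
    ),
    "sports_court": SessionParams(
        area_range_m2=(100.0, 700.0),
        mean_groups=1.8,
        group_size_range=(2, 14),
        target_congregate_mean=TARGET_CONGREGATE_MEANS["sports_court"],
        target_engagement_mean=TARGET_ENGAGEMENT_MEANS["sports_court"],
    ),
}


def default_session_params(space_type: str) -> SessionParams:
    try:
        return _DEFAULT_SESSION_PARAMS[space_type]
    except KeyError:
        raise ValueError(f"unknown space type {space_type!r}") from None


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic study condition for a space type."""

    space_type: str
    n_records: int = 2000
    missing_rate: float = 0.0
    seed: int = 0
    effect_strength: float = 1.0
    session_params: SessionParams | None = None

    def __post_init__(self) -> None:
        if self.space_type not in SPACE_TYPES:
            raise ValueError(f"unknown space type {self.space_type!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")

    def resolved_session_params(self) -> SessionParams:
        return self.session_params or default_session_params(self.space_type)


def sample_records(
    cfg: ScenarioConfig, net: BeliefNetwork | None = None
) -> Dataset:
    """Ancestral-sample ``n_records`` categorical records from the truth net.

    Missing cells are injected completely at random at ``missing_rate``.
    Unit ids are drawn uniformly from the space type's units.  Byte-identical
    output under identical configuration.
    """
    net = net or ground_truth_network(cfg.space_type, cfg.effect_strength)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_records
    order = net.structure.topological_order()
    samples: dict[str, np.ndarray] = {}
    for node in order:
        cpt = net.tables[node]
        if cpt.parents:
            idx = tuple(samples[p] for p in cpt.parents)
            rows = cpt.probs[idx]
        else:
            rows = np.broadcast_to(cpt.probs, (n, net.card(node)))
        u = rng.random(n)
        samples[node] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)

    specs = load_variable_specs()
    keep = [s for s in specs if s.name in net.tables]
    frame = pd.DataFrame(
        {
            s.name: pd.Categorical.from_codes(samples[s.name], list(s.states)).astype(object)
            for s in keep
        }
    )
    if cfg.missing_rate > 0:
        mask = rng.random(frame.shape) < cfg.missing_rate
        frame = frame.mask(pd.DataFrame(mask, columns=frame.columns), np.nan)
    units = [u.unit_id for u in load_units() if u.space_type == cfg.space_type]
    frame.insert(0, "unit_id", rng.choice(units, size=n))
    frame.insert(1, "weight", 1.0)
    return Dataset(keep, frame, provenance="synthetic")


def simulate_sessions(
    cfg: ScenarioConfig,
) -> tuple[list[CongregateSession], list[EngagementResponse]]:
    """Simulate behavior-mapping sessions and questionnaire responses.

    Congregate times are scaled so the session-level index has the
    configured per-type mean in expectation (before the 1-60 minute cap);
    questionnaire items are drawn around the configured engagement mean.
    """
    params = cfg.resolved_session_params()
    lo, hi = params.group_size_range
    if lo < 1 or hi < lo:
        raise ValueError("infeasible group size range")
    if params.area_range_m2[0] <= 1.0:
        raise ValueError("unit areas must exceed 1 m^2")
    rng = np.random.default_rng(_fingerprint_seed("sessions", cfg.space_type) ^ cfg.seed)
    units = [u.unit_id for u in load_units() if u.space_type == cfg.space_type]

    sessions: list[CongregateSession] = []
    for _ in range(params.n_sessions):
        s_area = float(rng.uniform(*params.area_range_m2))
        n_groups = 1 + int(rng.poisson(max(params.mean_groups - 1.0, 0.0)))
        sizes = rng.integers(lo, hi + 1, size=n_groups)
        n_present = int(sizes.sum())
        # Session index target: R = sum_g B_g^2 lnT_g / (N^2 log10 S).
        # Draw a mean-one noise factor per session, convert the targeted R
        # into a total ln-time budget, split it across groups with random
        # weights, and water-fill whatever exceeds the 60-min ceiling so the
        # cap introduces no downward bias in the session mean.
        sigma = params.time_spread
        noise = float(rng.lognormal(-0.5 * sigma**2, sigma))
        budget = (
            params.target_congregate_mean * noise * n_present**2 * math.log10(s_area)
        )
        w = rng.dirichlet(np.ones(n_groups))
        b2 = sizes.astype(float) ** 2
        ln_t = budget * w / b2
        cap = math.log(MAX_CONGREGATE_MINUTES)
        for _ in range(n_groups):
            over = ln_t > cap
            if not over.any():
                break
            excess = float((b2[over] * (ln_t[over] - cap)).sum())
            ln_t[over] = cap
            free = ~over
            if not free.any() or excess <= 0:
                break
            ln_t[free] += excess * w[free] / w[free].sum() / b2[free]
        ln_t = np.clip(ln_t, 0.0, cap)
        times = np.exp(ln_t)
        persons = [
            (int(b), float(t)) for b, t in zip(sizes, times) for _ in range(int(b))
        ]
        jitter = int(rng.integers(0, min(2, n_present) + 1))
        sessions.append(
            CongregateSession(
                unit_id=int(rng.choice(units)),
                area_m2=s_area,
                a_start=n_present - jitter,
                a_end=n_present + jitter,
                persons=tuple(persons),
            )
        )

    responses: list[EngagementResponse] = []
    m = params.target_engagement_mean
    for _ in range(params.n_responses):
        latent = rng.normal(m, 1.0)
        items = np.clip(np.rint(latent + rng.normal(0.0, 0.8, size=3)), 1, 7).astype(int)
        responses.append(
            EngagementResponse(int(rng.choice(units)), int(items[0]), int(items[1]), int(items[2]))
        )
    return sessions, responses
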