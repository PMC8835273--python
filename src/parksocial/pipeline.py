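"""End-to-end analysis driver and report writer.

Runs the whole chain once per space type — simulate (or load) observations,
compute interaction metrics, learn a belief network per space type under
edge constraints, run the mutual-information sensitivity analysis — and
writes the report bundle: selected networks (JSON), candidate ledgers and
CPT exports (CSV, percent rows), sensitivity rankings (CSV), the space-type
ranking summary (CSV) and a run log (JSON).  All randomness flows from one
top-level seed through named per-stage substreams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bbn import BeliefNetwork, EMSettings, posterior
from .domain import SPACE_TYPES, load_units, load_variable_specs
from .interaction import summarize_by_space_type
from .sensitivity import sensitivity_table
from .structure import (
    CandidateResult,
    EdgeConstraints,
    SearchSettings,
    SplitSpec,
    search_structures,
    split_dataset,
)
from .synth import ScenarioConfig, network_variables, sample_records, simulate_sessions
from . import synth

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "tier_constraints",
    "a_priori_constraints",
    "run_pipeline",
    "export_cpt_tables",
    "rank_space_types",
]

TARGETS = ("crowds_congregate", "engagement")


def _stage_seed(base_seed: int, *names: str) -> int:
    return (zlib.crc32("/".join(names).encode()) ^ base_seed) & 0x7FFFFFFF


def tier_constraints(space_type: str) -> EdgeConstraints:
    """Tier ordering only: spatial/individual -> activity -> interaction."""
    roles = {s.name: s.role for s in load_variable_specs()}
    variables = network_variables(space_type)
    tiers = (
        tuple(v for v in variables if roles[v] in ("spatial", "individual")),
        tuple(v for v in variables if roles[v] == "activity"),
        tuple(v for v in variables if roles[v] == "interaction"),
    )
    return EdgeConstraints(tier_order=tiers)


def a_priori_constraints(space_type: str) -> EdgeConstraints:
    """Draft priors: the mechanism edges of the space type, plus tiers."""
    tiers = tier_constraints(space_type).tier_order
    return EdgeConstraints(
        required_edges=synth._edges_for(space_type), tier_order=tiers
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full analysis run.

    Either supply per-space-type scenario configs (synthetic mode) or point
    ``dataset_paths`` at observation CSVs (survey mode) — exactly one of
    the two.
    """

    out_dir: Path
    seed: int = 0
    scenarios: tuple[ScenarioConfig, ...] | None = None
    dataset_paths: tuple[tuple[str, Path], ...] | None = None
    constraints_mode: str = "priors"  # or "tiers_only"
    split: SplitSpec = SplitSpec()
    em: EMSettings = EMSettings()
    search: SearchSettings = SearchSettings()

    def __post_init__(self) -> None:
        if (self.scenarios is None) == (self.dataset_paths is None):
            raise ValueError("provide exactly one of scenarios or dataset_paths")
        if self.constraints_mode not in ("priors", "tiers_only"):
            raise ValueError(f"unknown constraints mode {self.constraints_mode!r}")


@dataclass
class ReportBundle:
    out_dir: Path
    ranking: pd.DataFrame
    selected: dict[str, CandidateResult]
    sensitivity: dict[str, pd.DataFrame]
    log: dict


def export_cpt_tables(
    net: BeliefNetwork, targets: tuple[str, ...] = TARGETS, out_dir: Path | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per (target, direct parent): P(target level | parent state) in percent.

    Other parents are marginalized under the network's joint, so each table
    matches what a single-parent conditional readout displays; every row
    sums to 100.  A target with no parents yields an empty entry.
    """
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for target in targets:
        if target not in net.tables:
            continue
        parents = net.structure.parents(target)
        if not parents:
            out[(target, "")] = pd.DataFrame(
                index=pd.Index([], name="parent_state"), columns=net.states(target)
            )
            continue
        for parent in parents:
            rows = []
            for state in net.states(parent):
                rows.append(100.0 * posterior(net, target, {parent: state}))
            frame = pd.DataFrame(
                rows,
                index=pd.Index(net.states(parent), name=f"{parent}_state"),
                columns=net.states(target),
            )
            out[(target, parent)] = frame
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for (target, parent), frame in out.items():
            name = f"cpt_{target}__{parent or 'no_parents'}.csv"
            frame.to_csv(out_dir / name)
    return out


def rank_space_types(summary: pd.DataFrame) -> pd.DataFrame:
    """Attach descending ranks by mean congregate index and engagement.

    Ties keep input order (stable sort).
    """
    out = summary.copy()
    out["congregate_rank"] = (
        out["congregate_mean"].rank(ascending=False, method="first").astype(int)
    )
    out["engagement_rank"] = (
        out["engagement_mean"].rank(ascending=False, method="first").astype(int)
    )
    return out.sort_values("congregate_rank")


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute metrics -> discretization -> split -> search -> sensitivity
    -> export, once per space type."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    units = load_units()
    specs = load_variable_specs()

    if cfg.scenarios is not None:
        scenarios = {s.space_type: s for s in cfg.scenarios}
    else:
        scenarios = {}

    # -- interaction metrics and ranking (synthetic mode simulates sessions)
    all_sessions, all_responses = [], []
    for stype, scen in scenarios.items():
        scen_seeded = ScenarioConfig(
            space_type=scen.space_type,
            n_records=scen.n_records,
            missing_rate=scen.missing_rate,
            seed=_stage_seed(cfg.seed, "sessions", stype) ^ scen.seed,
            effect_strength=scen.effect_strength,
            session_params=scen.session_params,
        )
        sessions, responses = simulate_sessions(scen_seeded)
        all_sessions.extend(sessions)
        all_responses.extend(responses)
    ranking = pd.DataFrame()
    if all_sessions:
        ranking = rank_space_types(
            summarize_by_space_type(all_sessions, all_responses, units)
        )
        ranking.to_csv(out_dir / "space_type_ranking.csv")

    # -- per-space-type learning
    selected: dict[str, CandidateResult] = {}
    sens_frames: dict[str, pd.DataFrame] = {}
    log: dict = {"seed": cfg.seed, "space_types": {}}
    for stype in scenarios or dict(cfg.dataset_paths or ()):
        if cfg.scenarios is not None:
            scen = scenarios[stype]
            ds = sample_records(
                ScenarioConfig(
                    space_type=scen.space_type,
                    n_records=scen.n_records,
                    missing_rate=scen.missing_rate,
                    seed=_stage_seed(cfg.seed, "records", stype) ^ scen.seed,
                    effect_strength=scen.effect_strength,
                    session_params=scen.session_params,
                )
            )
        else:
            from .domain import Dataset

            path = dict(cfg.dataset_paths)[stype]
            ds = Dataset.read_csv(path, specs)
        constraints = (
            a_priori_constraints(stype)
            if cfg.constraints_mode == "priors"
            else tier_constraints(stype)
        )
        split = SplitSpec(
            test_fraction=cfg.split.test_fraction,
            seed=_stage_seed(cfg.seed, "split", stype),
            stratify_by=cfg.split.stratify_by,
        )
        train, test = split_dataset(ds, split)
        search = SearchSettings(
            n_candidates=cfg.search.n_candidates,
            max_parents=cfg.search.max_parents,
            mean_moves=cfg.search.mean_moves,
            rounds=cfg.search.rounds,
            seed=_stage_seed(cfg.seed, "search", stype),
        )
        em = EMSettings(
            pseudo_count=cfg.em.pseudo_count,
            tol=cfg.em.tol,
            max_iter=cfg.em.max_iter,
            seed=_stage_seed(cfg.seed, "em", stype),
        )
        best, ledger = search_structures(
            train, test, constraints, network_variables(stype), TARGETS, search, em
        )
        selected[stype] = best

        best.fitted.to_json(out_dir / f"network_{stype}.json")
        pd.DataFrame(
            [
                {
                    "n_edges": len(c.structure.edges),
                    "train_loglik": c.train_loglik,
                    **{
                        f"{t}_log_loss": m.log_loss
                        for t, m in c.metrics.items()
                    },
                    **{f"{t}_accuracy": m.accuracy for t, m in c.metrics.items()},
                    "edges": ";".join(f"{p}->{q}" for p, q in sorted(c.structure.edges)),
                }
                for c in ledger
            ]
        ).to_csv(out_dir / f"candidates_{stype}.csv", index=False)
        export_cpt_tables(best.fitted, TARGETS, out_dir / f"cpt_{stype}")

        frames = []
        for target in TARGETS:
            if target in best.fitted.tables:
                frames.append(sensitivity_table(best.fitted, target).to_frame())
        sens = pd.concat(frames, ignore_index=True)
        sens.to_csv(out_dir / f"sensitivity_{stype}.csv", index=False)
        sens_frames[stype] = sens

        log["space_types"][stype] = {
            "n_records": ds.n_records,
            "n_candidates_evaluated": len(ledger),
            "selected_edges": sorted(f"{p}->{q}" for p, q in best.structure.edges),
            "metrics": {
                t: {"log_loss": m.log_loss, "accuracy": m.accuracy}
                for t, m in best.metrics.items()
            },
        }

    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    return ReportBundle(
        out_dir=out_dir,
        ranking=ranking,
        selected=selected,
        sensitivity=sens_frames,
        log=log,
    )
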