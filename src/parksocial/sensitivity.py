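"""Mutual-information (entropy-reduction) sensitivity analysis.

For a target variable, every other network variable is ranked by the mutual
information between the two under the network's joint distribution — the
expected reduction in the target's entropy upon observing the variable.
Reported in bits and as a percentage of the target's entropy; both joints
and marginals come from exact inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bbn import BeliefNetwork, Evidence, marginal, posterior

__all__ = [
    "SensitivityEntry",
    "SensitivityReport",
    "entropy_bits",
    "mutual_information",
    "sensitivity_table",
]


@dataclass(frozen=True)
class SensitivityEntry:
    variable: str
    mi_bits: float
    percent_entropy_reduction: float


@dataclass
class SensitivityReport:
    target: str
    target_entropy_bits: float
    entries: list[SensitivityEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "target": self.target,
                    "variable": e.variable,
                    "mi_bits": e.mi_bits,
                    "percent_entropy_reduction": e.percent_entropy_reduction,
                }
                for e in self.entries
            ]
        )


def entropy_bits(dist: Sequence[float]) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 = 0."""
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1 or abs(p.sum() - 1.0) > 1e-8 or np.any(p < -1e-12):
        raise ValueError("input must be a normalized probability vector")
    pos = p[p > 0]
    return float(-(pos * np.log2(pos)).sum())


def mutual_information(
    net: BeliefNetwork,
    query: str,
    findings: str,
    evidence: Evidence | None = None,
) -> float:
    """MI between two network variables in bits, given optional evidence.

    ``I = sum_{q,f} p(q,f|e) log2[p(q,f|e) / (p(q|e) p(f|e))]``; symmetric
    in the two variables and nonnegative (clipped at 0 against roundoff).
    """
    if query == findings:
        raise ValueError("query and findings variables must differ")
    _, joint = marginal(net, [query, findings], evidence)
    pq = joint.sum(axis=1, keepdims=True)
    pf = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = np.ones_like(joint)
    ratio[mask] = joint[mask] / (pq @ pf)[mask]
    mi = float((joint[mask] * np.log2(ratio[mask])).sum())
    return max(mi, 0.0)


def sensitivity_table(
    net: BeliefNetwork, target: str, evidence: Evidence | None = None
) -> SensitivityReport:
    """Rank every other variable by MI with the target (descending).

    Percent entropy reduction is 100 * MI / H(target); if the target's
    marginal is degenerate (H = 0) every percentage is 0.
    """
    if target not in net.tables:
        raise ValueError(f"target {target!r} not in network")
    h_target = entropy_bits(posterior(net, target, evidence))
    entries = []
    for var in net.nodes:
        if var == target or (evidence and var in evidence):
            continue
        mi = mutual_information(net, target, var, evidence)
        pct = 100.0 * mi / h_target if h_target > 0 else 0.0
        entries.append(SensitivityEntry(var, mi, pct))
    entries.sort(key=lambda e: (-e.mi_bits, e.variable))
    return SensitivityReport(target=target, target_entropy_bits=h_target, entries=entries)
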