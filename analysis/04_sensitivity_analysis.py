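#!/usr/bin/env python
"""Rank influence factors by mutual information with the interaction targets.

Reads the selected networks from results/, computes the entropy-reduction
sensitivity table for crowds congregate and engagement in each space type,
and writes results/sensitivity_<space_type>.csv.
"""

from pathlib import Path

import pandas as pd

from parksocial.bbn import BeliefNetwork
from parksocial.domain import SPACE_TYPES
from parksocial.pipeline import TARGETS
from parksocial.sensitivity import sensitivity_table

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    for space_type in SPACE_TYPES:
        net = BeliefNetwork.from_json(ROOT / f"network_{space_type}.json")
        frames = []
        for target in TARGETS:
            report = sensitivity_table(net, target)
            frames.append(report.to_frame())
            top = report.entries[0]
            print(
                f"{space_type} / {target}: strongest factor {top.variable} "
                f"({top.mi_bits:.3f} bits, {top.percent_entropy_reduction:.1f}% "
                f"of H={report.target_entropy_bits:.3f} bits)"
            )
        pd.concat(frames, ignore_index=True).to_csv(
            ROOT / f"sensitivity_{space_type}.csv", index=False
        )


if __name__ == "__main__":
    main()
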