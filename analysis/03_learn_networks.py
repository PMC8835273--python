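#!/usr/bin/env python
"""Learn one belief network per space type from the simulated records.

For each space type: split the records 70/30, run the prior-constrained
candidate search with EM fitting, select by held-out log loss, and write the
selected network (JSON), the candidate ledger (CSV) and the percent CPT
exports for both interaction targets.
"""

from pathlib import Path

import pandas as pd

from parksocial.bbn import EMSettings
from parksocial.domain import SPACE_TYPES, Dataset, load_variable_specs
from parksocial.pipeline import TARGETS, a_priori_constraints, export_cpt_tables
from parksocial.structure import SearchSettings, SplitSpec, search_structures, split_dataset
from parksocial.synth import network_variables

SEED = 21
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    specs = load_variable_specs()
    for i, space_type in enumerate(SPACE_TYPES):
        ds = Dataset.read_csv(ROOT / "data" / f"records_{space_type}.csv", specs, "synthetic")
        train, test = split_dataset(ds, SplitSpec(0.3, seed=SEED + i))
        best, ledger = search_structures(
            train,
            test,
            a_priori_constraints(space_type),
            network_variables(space_type),
            TARGETS,
            SearchSettings(n_candidates=40, rounds=1, seed=SEED + i, selection_rule="log_loss"),
            EMSettings(pseudo_count=1.0, seed=SEED + i),
        )
        best.fitted.to_json(ROOT / f"network_{space_type}.json")
        pd.DataFrame(
            [
                {
                    "n_edges": len(c.structure.edges),
                    "train_loglik": c.train_loglik,
                    **{f"{t}_log_loss": m.log_loss for t, m in c.metrics.items()},
                    **{f"{t}_accuracy": m.accuracy for t, m in c.metrics.items()},
                }
                for c in ledger
            ]
        ).to_csv(ROOT / f"candidates_{space_type}.csv", index=False)
        export_cpt_tables(best.fitted, TARGETS, ROOT / f"cpt_{space_type}")
        print(f"{space_type}: {len(ledger)} candidates; selected {len(best.structure.edges)} edges")
        for t, m in best.metrics.items():
            print(f"  {t}: log loss {m.log_loss:.3f}, accuracy {m.accuracy:.1%}")


if __name__ == "__main__":
    main()
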