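#!/usr/bin/env python
"""Simulate the study's raw observations for all three space types.

Writes, under results/data/: behavior-mapping session tables (header +
long-format person rows), engagement questionnaire items, and the
categorical observation records sampled from the per-space-type
ground-truth networks used by the learning stages.
"""

from pathlib import Path

import pandas as pd

from parksocial.domain import SPACE_TYPES
from parksocial.interaction import sessions_to_frames
from parksocial.synth import ScenarioConfig, sample_records, simulate_sessions

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for space_type in SPACE_TYPES:
        cfg = ScenarioConfig(
            space_type, n_records=5000, missing_rate=0.02, seed=SEED, effect_strength=4.0
        )
        sessions, responses = simulate_sessions(cfg)
        head, persons = sessions_to_frames(sessions)
        head.to_csv(OUT / f"sessions_{space_type}.csv", index=False)
        persons.to_csv(OUT / f"session_persons_{space_type}.csv", index=False)
        pd.DataFrame(
            [
                {
                    "unit_id": r.unit_id,
                    "item_participation": r.item_participation,
                    "item_preference": r.item_preference,
                    "item_frequency": r.item_frequency,
                }
                for r in responses
            ]
        ).to_csv(OUT / f"engagement_{space_type}.csv", index=False)
        records = sample_records(cfg)
        records.to_csv(OUT / f"records_{space_type}.csv")
        print(
            f"{space_type}: {len(sessions)} sessions, {len(responses)} responses, "
            f"{records.n_records} records ({records.frame[records.variable_columns()].isna().to_numpy().mean():.1%} missing cells)"
        )


if __name__ == "__main__":
    main()
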