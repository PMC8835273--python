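#!/usr/bin/env python
"""Score social interaction per space type and rank the space types.

Reads the simulated sessions and questionnaires from results/data/, computes
the congregate index per session and the engagement score per respondent,
and writes the per-space-type summary with rankings to
results/space_type_ranking.csv.
"""

from pathlib import Path

import pandas as pd

from parksocial.domain import SPACE_TYPES, load_units
from parksocial.interaction import EngagementResponse, sessions_from_frames, summarize_by_space_type
from parksocial.pipeline import rank_space_types

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sessions, responses = [], []
    for space_type in SPACE_TYPES:
        head = pd.read_csv(ROOT / "data" / f"sessions_{space_type}.csv")
        persons = pd.read_csv(ROOT / "data" / f"session_persons_{space_type}.csv")
        sessions += sessions_from_frames(head, persons)
        eng = pd.read_csv(ROOT / "data" / f"engagement_{space_type}.csv")
        responses += [
            EngagementResponse(
                int(r.unit_id),
                int(r.item_participation),
                int(r.item_preference),
                int(r.item_frequency),
            )
            for r in eng.itertuples()
        ]
    summary = rank_space_types(summarize_by_space_type(sessions, responses, load_units()))
    summary.to_csv(ROOT / "space_type_ranking.csv")
    print(summary.round(3))
    best = summary.index[0]
    print(f"\nHighest mean congregate index: {best} "
          f"({summary.loc[best, 'congregate_mean']:.3f})")


if __name__ == "__main__":
    main()
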