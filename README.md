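# parksocial

Probabilistic analysis of how the built structure of community sports parks
shapes social interaction. Three parks are divided into 35 spatial study
units of three space types — fitness-equipment spaces, paths, and sports
courts — and two bespoke outcomes are measured per unit: a behavior-mapping
**crowds-congregate index** and a questionnaire **engagement-with-the-park
score**. A discrete **Bayesian belief network** (BBN) is learned per space
type to expose the influence mechanism *spatial factors → activity type →
social interaction*, and the influence factors are ranked by
mutual-information sensitivity. The package is for quantitative
urban-greenspace and public-health researchers who want this workflow as
reusable, tested code.

## The statistics at the core

**Crowds-congregate index.** For one observation session in a unit of area
S m² with N people present, person i in a congregate group of size B_i for
T_i minutes (1 ≤ T_i ≤ 60):

    R = Σᵢ (B_i / A) · ln T_i  /  (N · log₁₀ S),   A = (A_start + A_end) / 2

**Engagement score** is the mean of three 1–7 questionnaire items.

**Belief networks.** Each space type gets a DAG + CPTs over its spatial,
activity and individual-difference variables. Learning follows three steps:
a draft network from a-priori edges (with a tier ordering
spatial/individual → activity → interaction), random single-edge
add/remove/reverse candidate generation, EM parameter fitting on a 70/30
split, and held-out selection by per-target logarithmic loss / accuracy.
Inference is exact variable elimination; sensitivity is mutual information
I(target; variable) in bits and as percent entropy reduction.

The original field records are not deposited, so a synthetic-data module
generates sessions, questionnaires and categorical records from packaged
per-space-type ground-truth networks (CPTs seeded from the published
conditional-probability tables); every stage is exercised against known
ground truth. See `docs/methods.md` for assumptions and design choices.

## Worked example

Run the numbered analysis drivers from the repository root:

```sh
python analysis/01_simulate_observations.py
python analysis/02_interaction_metrics.py
python analysis/03_learn_networks.py
python analysis/04_sensitivity_analysis.py
```

Driver 02 prints the per-space-type interaction summary (outputs under
`results/`):

```
                   congregate_mean  ...  engagement_rank
space_type
sports_court                 0.518  ...                1
path                         0.485  ...                3
fitness_equipment            0.426  ...                2

Highest mean congregate index: sports_court (0.518)
```

i.e. sports courts congregate the most interaction per unit area (the
generator was configured with that ordering around means 0.550/0.503/0.426;
realized means sit slightly below where the 60-minute observation window
binds). Driver 03 then learns one
network per space type and reports held-out metrics, e.g.

```
fitness_equipment: 40 candidates; selected 14 edges
  crowds_congregate: log loss 0.988, accuracy 55.5%
  engagement: log loss 0.954, accuracy 53.0%
```

and driver 04 ranks the influence factors:

```
fitness_equipment / crowds_congregate: strongest factor physical_activity
  (0.118 bits, 6.9% of H=1.706 bits)
path / crowds_congregate: strongest factor visual_obstacles
sports_court / engagement: strongest factor crowds_congregate
  (0.177 bits, 24.6% of H=0.718 bits)
```

— observing whether physical activity happens removes the largest share of
uncertainty in the fitness-space congregate level, and sports-court
engagement is driven most by crowd congregation, exactly the mechanisms
built into the generators.

Library use mirrors the drivers:

```python
import parksocial as ps

cfg = ps.ScenarioConfig("fitness_equipment", n_records=5000, seed=0, effect_strength=4.0)
ds = ps.sample_records(cfg)
train, test = ps.split_dataset(ds, ps.SplitSpec(0.3, seed=0))
best, ledger = ps.search_structures(
    train, test, ps.tier_constraints("fitness_equipment"),
    ps.network_variables("fitness_equipment"),
    ("crowds_congregate", "engagement"),
    ps.SearchSettings(n_candidates=75, rounds=2, seed=0, selection_rule="log_loss"),
)
print(ps.sensitivity_table(best.fitted, "crowds_congregate").to_frame())
```

## Layout

```
src/parksocial/   library: domain, interaction, spatial, bbn, structure,
                  sensitivity, synth, pipeline (+ packaged JSON fixtures)
analysis/         numbered drivers (the command surface)
tests/            pytest suite incl. brute-force oracles
scripts/          acceptance.py
docs/methods.md   model, assumptions, design decisions, limitations
```
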