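"""Generate the synthetic national survey used by all downstream steps.

52 health districts on a lattice geography, ~18,000 participants with the
survey's skewed district sample sizes, four correlated cardiovascular
outcomes drawn from the joint spatial model, covariates at the survey's
marginal frequencies, two design-weight columns, and a district deprivation
(SAMPI) table.  Writes everything under results/sim/.
"""

from pathlib import Path

import numpy as np

from cvdmap import generator as gen
from cvdmap.spatial_graph import write_winbugs

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
SEED = 20120101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = gen.GeneratorConfig(J=52, K=4, include_sampi=True, seed=SEED)
    records, outcomes, truth = gen.generate_population(cfg)
    sampi = gen.make_district_sampi(cfg, np.random.default_rng([SEED, 91]))

    records.to_csv(OUT / "participants.csv", index=False)
    outcomes.to_csv(OUT / "outcomes_true.csv", index=False)
    sampi.to_csv(OUT / "district_sampi.csv", index=False)
    write_winbugs(cfg.graph, OUT / "adjacency.txt")
    truth.to_json(OUT / "ground_truth.json")

    sizes = records.groupby("district").size()
    print(f"simulated {len(records)} participants in {cfg.J} districts")
    print(f"district sizes: mean {sizes.mean():.0f}, median {sizes.median():.0f}, "
          f"range {sizes.min()}-{sizes.max()}")
    print("realised prevalences:", outcomes.mean().round(3).to_dict())
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
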