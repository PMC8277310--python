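#!/usr/bin/env python
"""Generate the synthetic study data.

Simulates the 34-participant intervention cohort (weeks 0/8/16, with each
participant's fixed behavior-change strategy) and the two reference pools
the health-space model is trained on, all from the shipped study tables.
Writes results/cohort/ and results/reference_pools/.
"""

import json
from pathlib import Path

import numpy as np

from nutrispace import load_defaults
from nutrispace.screening import HomaFormula, harmonize_panel
from nutrispace.synthetic import (CohortSpec, TrajectorySpec,
                                  generate_intervention_cohort,
                                  generate_reference_pool, write_cohort)

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = load_defaults()
    rng = np.random.default_rng(SEED)
    seed_cohort, seed_healthy, seed_mets = (int(s) for s in
                                            rng.integers(0, 2**31 - 1, 3))

    cohort = generate_intervention_cohort(
        CohortSpec.from_config(cfg, "intervention"),
        TrajectorySpec.from_config(cfg), n=34, seed=seed_cohort)
    visits = harmonize_panel(cohort.visits)
    homa = HomaFormula(**cfg["homa_ir"])
    visits["homa_ir"] = [homa(g, c) for g, c in
                         zip(visits["glucose"], visits["c_peptide"])]
    cohort = cohort.__class__(visits=visits, strategies=cohort.strategies)
    write_cohort(cohort, ROOT / "cohort",
                 spec_info={"group": "intervention", "n": 34}, seed=SEED)

    pools_dir = ROOT / "reference_pools"
    pools_dir.mkdir(parents=True, exist_ok=True)
    healthy = harmonize_panel(generate_reference_pool(
        CohortSpec.from_config(cfg, "healthy"), 400, seed_healthy))
    mets = harmonize_panel(generate_reference_pool(
        CohortSpec.from_config(cfg, "mets"), 100, seed_mets))
    healthy.to_csv(pools_dir / "healthy_pool.csv", index=False)
    mets.to_csv(pools_dir / "mets_pool.csv", index=False)
    (pools_dir / "seeds.json").write_text(json.dumps(
        {"seed": SEED, "cohort": seed_cohort, "healthy": seed_healthy,
         "mets": seed_mets}, indent=2))

    v = cohort.visits
    w0 = v[v.week == 0]
    print(f"cohort: {w0.shape[0]} participants x {v['week'].nunique()} visits")
    print(f"  baseline DHDI total {w0['dhdi_total'].mean():.1f} "
          f"(SD {w0['dhdi_total'].std():.1f})")
    sizes = {c: sum(c in s for s in cohort.strategies.values())
             for c in sorted({c for s in cohort.strategies.values() for c in s})}
    print(f"  strategy sizes per category: {sizes}")
    print(f"reference pools: healthy {len(healthy)}, mets {len(mets)}")


if __name__ == "__main__":
    main()
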