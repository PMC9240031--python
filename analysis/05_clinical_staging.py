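#!/usr/bin/env python
"""Stage the alteration sequence against clinical milestones.

Reruns the trajectory simulation with the Hoehn-Yahr milestones (HYS >= 2,
HYS >= 3) added as events, and again with the cognitive milestones (MCI,
dementia); structural events between adjacent milestones share a stage.
"""

from pathlib import Path

import pandas as pd

from ebmseq import alteration, staging
from ebmseq.progression import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260931


def main() -> None:
    w = alteration.read_weights(ROOT / "weights.csv")
    cohort = pd.read_csv(ROOT / "data" / "cohort.csv")
    for scheme_id in ("HYS", "COGNITION"):
        scheme = staging.build_clinical_events(cohort, scheme_id)
        staged = staging.stage_events(
            w, scheme, SimulationConfig(n_trajectories=10_000, seed=SEED)
        )
        path = ROOT / f"staged_sequence_{scheme_id.lower()}.csv"
        staging.write_staged(staged, path)
        counts = staged.stage_counts
        print(f"{scheme_id}: milestone indicator sums "
              f"{scheme.indicators.sum().to_dict()}; stage sizes {counts.to_dict()}")


if __name__ == "__main__":
    main()
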