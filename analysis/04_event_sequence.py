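#!/usr/bin/env python
"""Infer the population-level alteration sequence by trajectory simulation.

Simulates 10,000 monotone progression trajectories over the 110 events (the
production setting is one million; ten thousand is already limited by weight
noise rather than Monte-Carlo error at this cohort size) and extracts the
per-step modal sequence.
"""

from pathlib import Path

from ebmseq import alteration, atlas as atlas_mod, progression

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260930


def main() -> None:
    w = alteration.read_weights(ROOT / "weights.csv")
    atlas = atlas_mod.read_atlas(ROOT / "data" / "atlas.csv")
    cfg = progression.SimulationConfig(n_trajectories=10_000, seed=SEED)
    tc = progression.simulate(w, cfg)
    seq = progression.modal_sequence(tc)
    progression.write_counts(tc, ROOT / "trajectory_counts.csv")
    progression.write_sequence(seq, ROOT / "event_sequence.csv", atlas)
    tissue = atlas.set_index("region_id")["tissue"]
    first_20_wm = sum(tissue[e] == "WM" for e in seq.order[:20])
    print(f"modal sequence over {len(seq.order)} events "
          f"(mean modal frequency {seq.modal_freq.mean():.3f})")
    print(f"{first_20_wm}/20 of the earliest events are WM tracts")
    print("NOTE: at this cohort size the per-step distributions are nearly "
          "flat (see docs/methods.md); the pairwise census is the robust "
          "cross-tissue readout")


if __name__ == "__main__":
    main()
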