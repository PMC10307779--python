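#!/usr/bin/env python
"""Simulate the study cohort: 15 rats through reflex testing, oxycodone
place conditioning, extinction, sham/CCI surgery and post-surgery testing.

Writes the four tidy session CSVs plus a config echo under results/cohort/.
"""

from pathlib import Path

from ethopharm import io, synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = syn.default_config(seed=SEED)
    dataset = syn.generate_study(cfg)
    io.write_dataset(dataset, OUT)
    io.write_config_echo(cfg, OUT / "generator_config.yaml")
    print(f"cohort of {cfg.n_animals} animals (seed {SEED}) -> {OUT}")
    print(f"  reflex trials: {len(dataset.reflex_trials)} rows "
          f"({dataset.reflex_trials['day'].nunique()} test days)")
    print(f"  conditioning:  {len(dataset.conditioning)} rows (days 13-16, VEH+OXY)")
    print(f"  place tests:   {dataset.place_tests['day'].nunique()} test days "
          f"x 3 compartments")
    arms = dataset.animals["surgery_arm"].value_counts().to_dict()
    print(f"  surgery arms:  {arms}")


if __name__ == "__main__":
    main()
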