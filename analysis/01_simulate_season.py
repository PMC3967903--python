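#!/usr/bin/env python
"""Simulate one field season of the feeder-grid study system.

Generates the 45-feeder grid, the randomized-block sucrose schedule for
the treatment year, a marked population with territorial structure, and
the per-second detection stream, writing everything under
``results/season/``.  The ground-truth population table is kept so later
steps can check recovery against what was generated.
"""

from pathlib import Path

from feederdef import simdata

SEED = 2009
OUT = Path("results/season")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    grid = simdata.make_grid(seed=SEED)
    schedule = simdata.make_treatment_schedule(2009, seed=SEED,
                                               feeder_ids=grid["feeder_id"])
    pop = simdata.make_population(30, grid, 2009, seed=SEED)
    cfg = simdata.SimConfig(seed=SEED)
    stream = simdata.simulate_detection_stream(pop, grid, schedule, cfg)

    simdata.write_table(grid, OUT / "feeders.csv")
    simdata.write_table(schedule, OUT / "schedule.csv")
    simdata.write_table(pop, OUT / "population.csv")
    simdata.write_stream(stream, OUT / "detections.csv")

    n_high = (schedule["sucrose"] == "high").sum()
    print(f"grid: {len(grid)} feeders "
          f"({(grid['habitat'] == 'forest').sum()} forest, "
          f"{(grid['openness'] == 'open').sum()} open)")
    print(f"schedule: {schedule['week'].nunique()} treatment weeks, "
          f"{n_high} high-sucrose feeder-weeks")
    print(f"population: {len(pop)} individuals "
          f"({(pop['sex'] == 'M').sum()} males, "
          f"{(pop['age_class'] == 'adult').sum()} adults)")
    print(f"detections: {len(stream)} per-second readings "
          f"-> {OUT / 'detections.csv'}")


if __name__ == "__main__":
    main()
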