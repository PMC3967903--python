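#!/usr/bin/env python
"""Convert the simulated detection stream into feeder visits.

Applies the 21-second merge rule: consecutive readings of the same bird
at the same feeder less than 21 s apart belong to one visit.  Reports
the compression (readings per visit) and the visit-duration spread.
"""

from pathlib import Path

from feederdef import sessionize

IN = Path("results/season/detections.csv")
OUT = Path("results/season/visits.csv")


def main():
    records = sessionize.read_detections(IN)
    visits = sessionize.detections_to_visits(records, gap_threshold=21)
    sessionize.write_visits(visits, OUT)
    assert visits["n_readings"].sum() == len(records)
    q = visits["duration_s"].quantile([0.5, 0.9]).to_dict()
    print(f"{len(records)} readings -> {len(visits)} visits "
          f"({len(records) / len(visits):.1f} readings/visit)")
    print(f"visit duration: median {q[0.5]:.0f} s, 90th pct {q[0.9]:.0f} s")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
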