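#!/usr/bin/env python
"""Simulate the two observer cohorts on the 2AFC speed task.

Ten "EB-like" observers (duration-dominant, inverted use of the distance
cue: the "shorter = faster" heuristic applied to space) and ten "SC-like"
observers (duration-dominant but veridical, with some genuine speed
sensitivity) each complete the 432-trial design.  Writes
results/responses.csv and results/observers.csv.
"""

import argparse
from pathlib import Path

from speedcontours.config import PipelineConfig
from speedcontours.pipeline import simulate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    responses, observers = simulate_cohort(cfg)
    RESULTS.mkdir(exist_ok=True)
    responses.to_csv(RESULTS / "responses.csv", index=False)
    observers.to_csv(RESULTS / "observers.csv", index=False)
    by_group = responses.groupby("group")["subject_id"].nunique()
    print(f"simulated {len(responses)} trials from "
          f"{responses['subject_id'].nunique()} subjects "
          f"({', '.join(f'{g}: {n}' for g, n in by_group.items())})")
    rate = (responses["response"] == "faster").mean()
    print(f"overall 'faster' rate {rate:.3f} -> results/responses.csv")


if __name__ == "__main__":
    main()
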