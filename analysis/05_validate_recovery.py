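#!/usr/bin/env python
"""Planted-signal recovery and null false-flag validation study.

Twenty seeds: quarters of 20,000 cases with rate ratios 1, 5 and 10 planted
on distinct (drug, PT) pairs are pushed through the full pipeline and the
EBGM point estimate and four-method consensus are read off at the planted
pairs; twenty matched null quarters measure the fraction of (drug, PT)
combinations the consensus flags when nothing is planted.  Summary to
results/validation.json.
"""

import json
from pathlib import Path

import numpy as np

from pvsignal.pipeline import simulate_and_validate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = simulate_and_validate(repetitions=20, seed=0)
    print("planted-signal recovery (20 seeds, 20k cases each):")
    for r, res in report["planted"].items():
        est = np.array(res["ebgm"])
        print(f"  r={r:>4}: EBGM {est.mean():.2f} (range {est.min():.2f}-{est.max():.2f}), "
              f"within +-35% in {100 * res['within_35pct']:.0f}% of seeds, "
              f"consensus rate {100 * res['consensus_rate']:.0f}%")
    null_max = report["null"]["max_consensus_pair_fraction"]
    print(f"null universes: max consensus-flagged pair fraction "
          f"{100 * null_max:.3f}% (threshold: < 1%)")
    path = ROOT / "results" / "validation.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2) + "\n")
    print(f"full report -> {path}")


if __name__ == "__main__":
    main()
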