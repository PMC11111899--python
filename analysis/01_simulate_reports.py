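#!/usr/bin/env python
"""Generate the synthetic quarter of spontaneous reports used downstream.

Emulates a FAERS quarterly extract: 20,000 versioned case reports with
duplicates, role-coded drug entries, multiple PTs per case, demographics
with missingness, outcome codes and therapy/event dates.  Three
reporting-rate ratios (1, 5, 10) are planted on distinct (drug, PT) pairs as
ground truth; the r=10 pair (DRUG003 / PT0003) doubles as the liver-injury
analogue for the subgroup analysis.  Files are written in the '$'-delimited
ASCII dialect under scratch/ (they are bulky); the PT->SOC dictionary (341
PTs over 27 SOCs) goes to results/data/.
"""

from pathlib import Path

from pvsignal.simulate import SimConfig, generate_pt_dictionary, generate_quarter

ROOT = Path(__file__).resolve().parents[1]

STUDY = SimConfig(
    n_cases=20_000, n_drugs=60, n_pts=200, baseline_event_rate=0.1,
    planted_signals=((0, 0, 1.0), (1, 1, 5.0), (2, 2, 10.0)),
    duplicate_fraction=0.05, missing_demo_fraction=0.10, seed=2023,
)


def main() -> None:
    bundle = generate_quarter(STUDY)
    outdir = ROOT / "scratch" / "faers_synth"
    paths = bundle.write(outdir)
    print(f"wrote {len(paths)} tables to {outdir}")
    for name, frame in bundle.tables().items():
        print(f"  {name}: {len(frame):>7} rows")
    dictionary = generate_pt_dictionary(27, 341, seed=STUDY.seed)
    dict_path = ROOT / "results" / "data" / "pt_dictionary.tsv"
    dict_path.parent.mkdir(parents=True, exist_ok=True)
    dictionary.to_csv(dict_path, sep="\t", index=False)
    print(f"PT dictionary: {len(dictionary)} PTs over "
          f"{dictionary['soc'].nunique()} SOCs -> {dict_path}")
    print("planted signals (drug, pt, rate ratio):",
          ", ".join(f"(DRUG{d+1:03d}, PT{p+1:04d}, r={r:g})"
                    for d, p, r in STUDY.planted_signals))


if __name__ == "__main__":
    main()
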