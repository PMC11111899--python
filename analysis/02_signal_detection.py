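#!/usr/bin/env python
"""Run ingestion, deduplication and four-method signal detection.

Reads the synthetic quarter written by 01_simulate_reports.py (regenerating
it if absent), selects the target drug DRUG003 as primary suspect,
deduplicates per the highest-version/latest-receipt rule, scores every PT
with ROR, PRR, EBGM and the BCPNN information component, applies the
four-method consensus, and aggregates to system organ classes.  Outputs the
signal and SOC tables plus the run manifest under results/run/.
"""

import importlib.util
from pathlib import Path

from pvsignal.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]
spec = importlib.util.spec_from_file_location("step01", Path(__file__).parent / "01_simulate_reports.py")
step01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(step01)


def main() -> None:
    cfg = PipelineConfig(
        sim=step01.STUDY,
        target_variants=("DRUG003",),
        subgroup_target_pts=("PT0003",),
        dictionary_path=str(ROOT / "results" / "data" / "pt_dictionary.tsv")
        if (ROOT / "results" / "data" / "pt_dictionary.tsv").exists() else None,
        n_soc=27,
        seed=step01.STUDY.seed,
    )
    outdir = ROOT / "results" / "run"
    result = run_pipeline(cfg, outdir=outdir)
    s = result.summary
    print(f"reports read:        {s['reports_read']}")
    print(f"cases after dedup:   {s['cases_after_dedup']}")
    print(f"target-drug reports: {s['target_reports']}")
    print(f"(case, PT) units:    {s['case_pt_units']}")
    top = result.signal_table.head(8)
    cols = ["pt", "a", "ror", "prr", "ebgm", "ic", "ic_minus_2sd", "consensus"]
    print("\ntop signals by report count:")
    print(top[cols].to_string(index=False,
                              float_format=lambda v: f"{v:.2f}"))
    n_cons = int(result.signal_table["consensus"].sum())
    print(f"\nconsensus signals: {n_cons} PT(s)")
    print(f"outputs -> {outdir}")


if __name__ == "__main__":
    main()
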