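#!/usr/bin/env python
"""Genome-wide retention scoring of a complete excision knockdown against an
excision-competent control, from whole-cell DNA (old/new MAC mixture,
rho = 0.5): the apparent retention score distribution shifts to ~rho while
the control stays at zero, and essentially every covered IES is called
significantly retained. Score tables land under results/knockdown/ (the full
run, including genomes, goes to scratch/)."""

import shutil
from pathlib import Path

from iespipe.pipeline import run_pipeline, scenario_config

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
RUN = ROOT / "scratch" / "knockdown_run"
OUT = ROOT / "results" / "knockdown"


def main() -> None:
    summary = run_pipeline(scenario_config("knockdown", seed=SEED, outdir=str(RUN)))
    OUT.mkdir(parents=True, exist_ok=True)
    for f in RUN.glob("*.tsv"):
        shutil.copy2(f, OUT / f.name)
    shutil.copy2(RUN / "summary.json", OUT / "summary.json")

    print(f"{summary['n_ies']} IESs; coverage 30X, rho = 0.5")
    print(f"mean apparent IRS, knockdown:  {summary['mean_irs_case_r1']:.3f} "
          "(full retention diluted by old-MAC DNA)")
    print(f"mean apparent IRS, control:    {summary['mean_irs_control']:.3f}")
    print(f"significantly retained: {summary['n_significant'][0]} of "
          f"{summary['n_tested'][0]} tested (replicate 1)")
    print(f"replicate IRS Spearman rho: {summary['replicate_spearman']:.3f} "
          "(~0 expected here: with uniform full retention the replicate-to-"
          "replicate ranking is pure counting noise)")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
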