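#!/usr/bin/env python
"""Trial-level statistics: summaries, correlations, BLUEs, recovery.

Produces the summary table (mean, SD, range, CV per phase x treatment),
the feature-biomass Pearson correlation matrix, mixed-model BLUEs of every
genotype x treatment cell with Wald tests of the fixed terms, and the
parameter-recovery report against the generator's ground truth.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ryenue.config import load_config
from ryenue.pipeline import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/trial"))
    args = ap.parse_args()

    cfg = load_config(overrides={"seed": args.seed})
    run_pipeline(cfg, args.out, stages=("analyze",))

    summary = pd.read_csv(args.out / "summary.csv")
    ep = summary[summary.phase.isin(["EP-1", "EP-2"])]
    for resp in ("DM", "NUE"):
        block = ep[ep.response == resp]
        if block.empty:
            continue
        print(f"{resp} summary (phase, treatment, mean +/- SD, range, CV):")
        for _, r in block.iterrows():
            print(f"  {r.phase:5s} {r.treatment:>4} mM  "
                  f"{r['mean']:8.2f} +/- {r.sd:7.3f}  "
                  f"[{r['min']:.2f}, {r['max']:.2f}]  CV {r.cv:.2f}")

    corr = pd.read_csv(args.out / "correlations_r.csv").set_index("variable")
    print("Pearson r with FM / DM (experimental phases):")
    for feat in ("MPPA", "V", "V_lemnatec", "V_keygene"):
        if feat in corr.index:
            print(f"  {feat:11s} FM {corr.loc[feat, 'FM']:.3f}   DM {corr.loc[feat, 'DM']:.3f}")

    tests = pd.read_csv(args.out / "fixed_effect_tests.csv")
    dm_tests = tests[tests.response == "DM"]
    print("Wald tests for DM (term, phase, df, p):")
    for _, r in dm_tests.iterrows():
        print(f"  {r.term:20s} {r.phase:5s} df={r.df:3d}  p={r.pvalue:.2e}")

    rec = json.loads((args.out / "recovery.json").read_text())
    print("genotype-effect recovery (DM BLUEs vs truth, EP-1):")
    for trt, entry in rec["per_treatment"].items():
        print(f"  {trt} mM: Spearman {entry['spearman']:.3f}, "
              f"top-decile overlap {entry['top_decile_overlap']:.2f}")


if __name__ == "__main__":
    main()
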