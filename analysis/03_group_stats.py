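#!/usr/bin/env python
"""Group-level inference on the quantified responses.

Fits the stimulus × ROI × group mixed model with per-subject random
intercepts, runs Tukey-corrected faces−houses contrasts per group × ROI,
summarizes the orthogonal color-change task, and correlates neural
measures with SRS T-scores (Spearman).  Reads results/response_table.tsv
and results/subjects.tsv written by 02_quantify_cohort.py.
"""

import argparse
from pathlib import Path

import pandas as pd

from fpvs.design import make_design
from fpvs.simulate import behavior_table, cohort_specs
from fpvs.stats import (behavior_summary, contrast_table, correlate_srs,
                        fit_lmem, posthoc_contrasts)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    resp = pd.read_csv(args.out / "response_table.tsv", sep="\t")
    subjects = pd.read_csv(args.out / "subjects.tsv", sep="\t")
    resp = resp.merge(subjects[["subject", "group"]].drop_duplicates(),
                      on=["subject", "group"])

    res = fit_lmem(resp)
    res.anova.to_csv(args.out / "lmem_anova.tsv", sep="\t", index=False)
    cons = posthoc_contrasts(res)
    contrast_table(cons).to_csv(args.out / "contrasts.tsv", sep="\t",
                                index=False)

    print(f"LMEM ({res.n_obs} obs, {res.n_subjects} subjects, "
          f"denominator df {res.df_den:.0f}, method {res.df_method}):")
    print(res.anova.round(4).to_string(index=False))
    print("\nTukey-corrected faces−houses contrasts:")
    for c in cons:
        mark = "*" if c.significant else " "
        print(f"  {c.group:3s} {c.roi:3s}: {c.estimate_uv:+.2f} µV, "
              f"T({c.df:.0f}) = {c.t:+.2f}, p = {c.p_tukey:.4f} {mark}")

    # behavioral task (same cohort seed as the recordings)
    n_per_group = subjects.group.value_counts().iloc[0]
    specs, _ = cohort_specs(int(n_per_group), seed=args.seed,
                            design=make_design())
    beh = behavior_table(specs, seed=args.seed)
    summ = behavior_summary(beh)
    summ.to_csv(args.out / "behavior.tsv", sep="\t", index=False)
    print("\northogonal task (two-sided Welch t):")
    print(summ.round(4).to_string(index=False))

    if "srs_t" in subjects:
        cors = correlate_srs(resp, subjects)
        cors.to_csv(args.out / "srs_correlations.tsv", sep="\t", index=False)
        worst = cors.loc[cors.p.idxmin()]
        print(f"\nSpearman SRS correlations: {len(cors)} tests, "
              f"smallest p = {worst.p:.3f} "
              f"({worst.scope}/{worst.roi}/{worst.measure}, "
              f"rho = {worst.rho:+.2f}); no correction applied")


if __name__ == "__main__":
    main()
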