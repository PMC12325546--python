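#!/usr/bin/env python
"""Paired pre/post treatment statistics on the simulated cohorts: outlier
screens (Tukey, ROUT Q=1%, relationship check), paired relative changes,
mixed-effects ANOVA with location as random effect, and median +/- 95% CI
effect summaries.

Reads results/simulated/paired_*.csv; writes results/treatment_effects.csv
and results/lme_results.json.

Finding (seeded run): median reductions recover the generated effects within
a fraction of a percentage point, treatment terms are decisively significant
for every real effect and not for the control, and the screens flag
essentially nothing in these clean cohorts.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from myostiff import stats as st

ROOT = Path(__file__).resolve().parent.parent / "results"


def long_table(df: pd.DataFrame) -> pd.DataFrame:
    a = df.rename(columns={"E_pre_Pa": "E_Pa"})[["location_id", "E_Pa"]].assign(treatment="pre")
    b = df.rename(columns={"E_post_Pa": "E_Pa"})[["location_id", "E_Pa"]].assign(treatment="post")
    return pd.concat([a, b], ignore_index=True)


def main() -> None:
    warnings.filterwarnings("ignore")
    summary_rows, lme_out = [], {}
    for path in sorted((ROOT / "simulated").glob("paired_*.csv")):
        cond = path.stem.replace("paired_", "")
        df = pd.read_csv(path)
        pre = df.set_index("location_id")["E_pre_Pa"]
        post = df.set_index("location_id")["E_post_Pa"]
        pc = st.paired_changes(pre, post)

        # screens on the relative changes, then the pre/post relationship
        tuk = st.tukey_outliers(pc["rel_change"], ids=pc["location_id"])
        rout = st.rout_outliers(pc["rel_change"], ids=pc["location_id"])
        rel = st.relationship_screen(list(zip(pc["E_pre_Pa"], pc["E_post_Pa"])),
                                     ids=pc["location_id"])
        flagged = (set(tuk.flagged_ids) | set(rout.flagged_ids)) & set(rel.flagged_ids)
        kept = pc[~pc["location_id"].isin(flagged)]

        mci = st.median_ci(100.0 - kept["rel_change"])
        res = st.fit_lme(long_table(df[~df["location_id"].isin(flagged)]))
        p_treat = [f for f in res.fixed_effects if "treatment" in f["term"]][0]
        summary_rows.append({
            "condition": cond,
            "n": len(kept),
            "n_flagged": len(flagged),
            "median_reduction_pct": mci.median,
            "ci_low_pct": mci.ci_low,
            "ci_high_pct": mci.ci_high,
            "lme_treatment_p": p_treat["p_value"],
            "lme_adjusted_p": p_treat["adjusted_p"],
            "boxcox_lambda": res.transform_lambda,
        })
        lme_out[cond] = {"fixed_effects": p_treat, "n": res.n, "N": res.N,
                         "converged": res.converged}
        print(f"{cond:8s} median reduction {mci.median:6.2f}% "
              f"(95% CI {mci.ci_low:.2f}-{mci.ci_high:.2f}), "
              f"treatment p={p_treat['p_value']:.2e}, flagged={len(flagged)}")

    pd.DataFrame(summary_rows).to_csv(ROOT / "treatment_effects.csv", index=False)
    (ROOT / "lme_results.json").write_text(json.dumps(lme_out, indent=2))


if __name__ == "__main__":
    main()
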