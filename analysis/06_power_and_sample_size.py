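#!/usr/bin/env python
"""Sample-size conventions and seed-wise recovery of the imposed ΔpH.

Part 1 tabulates the paired normal-approximation sample size for the
hydrogen-ion effect (Δ[H+] = 1.03e-7 mol/L, pooled SD 1.39e-7 mol/L,
α = 0.05, β = 0.20) under one- and two-sided conventions.  Part 2 repeats
the cohort-level ΔpH analysis over 100 seeds to measure how often the
hierarchical estimate lands within 0.05 pH of the imposed 0.19.  Writes
results/sample_size.csv and results/delta_ph_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from biofilmq.stats import hierarchical_estimate, sample_size_paired
from biofilmq.synthetic import gen_ph_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    delta, sd = 1.03e-7, 1.39e-7
    rows = [{"convention": f"{sided}-sided",
             "n": sample_size_paired(delta, sd, sided=sided)}
            for sided in ("two", "one")]
    ss = pd.DataFrame(rows)
    ss.to_csv(OUT / "sample_size.csv", index=False)
    print("paired sample size for Δ[H+] = 1.03e-7, SD = 1.39e-7, "
          "α = 0.05, β = 0.20:")
    print(ss.to_string(index=False))
    print("note: no standard normal/t convention reproduces a paired N "
          "as low as 7 for these inputs.\n")

    recov = []
    for seed in range(100):
        df = gen_ph_cohort(seed=seed).query("timepoint_min == 10").rename(
            columns={"patient_id": "patient", "carrier_id": "biofilm",
                     "treatment": "group", "mean_ph": "value"})
        res = hierarchical_estimate(df, reference="NoARG")
        recov.append({"seed": seed, "estimate": res.difference,
                      "ci_low": res.ci_low, "ci_high": res.ci_high,
                      "within_005": abs(res.difference - 0.19) < 0.05,
                      "sign_agrees": np.sign(res.difference)
                      == np.sign(res.two_stage_difference)})
    rec = pd.DataFrame(recov)
    rec.to_csv(OUT / "delta_ph_recovery.csv", index=False)
    print(f"ΔpH recovery over 100 cohort seeds (imposed 0.19 at 10 min): "
          f"mean estimate {rec.estimate.mean():+.3f}, SD "
          f"{rec.estimate.std():.3f}; within ±0.05 of truth in "
          f"{int(rec.within_005.sum())}/100 seeds; estimator sign agreement "
          f"{int(rec.sign_agrees.sum())}/100")


if __name__ == "__main__":
    main()
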