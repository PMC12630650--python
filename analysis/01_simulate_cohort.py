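#!/usr/bin/env python
"""Generate the synthetic split-mouth cohort and record its ground truth.

Emulates the study layout — 10 patients, arginine/placebo sides allocated
by block randomisation (block size 2), duplicate pH biofilms per side with
9 FOVs each at 10 and 35 min of sucrose exposure, one FLBA biofilm per
lectin and side, and one paired ASV sample per side — at desk-scale image
geometry.  Truth tables go to results/cohort/; they are the reference every
later script compares its estimates against.
"""

import json
from pathlib import Path

from biofilmq.synthetic import gen_cohort, reduced_cohort_spec

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20250925


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = reduced_cohort_spec()
    cohort = gen_cohort(spec, seed=SEED)

    cohort.allocation.to_csv(OUT / "allocation.csv", index=False)
    cohort.ph_fovs.to_csv(OUT / "ph_fov_truth.csv", index=False)
    cohort.flba_truth.to_csv(OUT / "flba_truth.csv", index=False)
    cohort.asv_table.to_frame().to_csv(OUT / "asv_counts.csv", index=False)
    with open(OUT / "truth.json", "w") as fh:
        json.dump({"seed": SEED, "asv": cohort.asv_truth}, fh, indent=2)

    alloc = cohort.allocation.arg_side.value_counts().to_dict()
    print(f"cohort seed {SEED}: {len(cohort.allocation)} patients, "
          f"ARG side allocation {alloc}")
    print(f"pH truth rows: {len(cohort.ph_fovs)} "
          f"({cohort.ph_fovs.carrier_id.nunique()} biofilms)")
    print(f"FLBA truth rows: {len(cohort.flba_truth)}")
    print(f"ASV table: {cohort.asv_table.n_samples} samples x "
          f"{cohort.asv_table.n_asvs} ASVs; shifted taxa "
          f"{cohort.asv_truth['shifted_taxa']}")


if __name__ == "__main__":
    main()
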