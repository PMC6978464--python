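"""Generate the synthetic study cohort.

A paired two-condition cohort shaped like a deep-sedation fMRI study: 16
subjects scanned awake and deeply sedated, 234 regions x 190 timepoints per
scan, with the sedated condition generated at complexity grade 0.8 (slower,
more strongly community-coupled signals) and a serum-concentration-like
dose covariate for the sedated scans. Scans, metadata, and the generative
ground truth are written under scratch/cohort/ (raw scans are bulky; only
derived tables live under results/).
"""

import argparse
from pathlib import Path

import braincomplexity as bc

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("scratch/cohort"))
args = parser.parse_args()

spec = bc.SyntheticCohortSpec(seed=args.seed)
scans, meta, truth = bc.gen_cohort(spec)
bc.write_cohort(scans, meta, truth, args.out)

print(f"wrote {len(scans)} scans ({spec.n_regions} regions x "
      f"{spec.n_timepoints} timepoints) to {args.out}")
print(f"conditions: {spec.conditions}, grades: {spec.complexity_grade}")
print("ground-truth AR coefficients by condition:")
print(truth.groupby("condition")["ar_coefficient"].describe()[["mean", "std"]])
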