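"""Higher-order analysis: is there a single "overall complexity"?

Pools the per-scan profiles, correlates every metric against every other,
extracts the first principal component of the standardised metrics, and
tests whether the individual metrics and the component discriminate the
conditions and track the dose covariate. Tables are written under
results/cohort_report/.
"""

import argparse
from pathlib import Path

import pandas as pd

import braincomplexity as bc

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--profiles", type=Path, default=Path("results/profiles.csv"))
parser.add_argument("--out", type=Path, default=Path("results/cohort_report"))
args = parser.parse_args()

wide = bc.read_results(args.profiles)
result = bc.analyse_cohort(wide)
args.out.mkdir(parents=True, exist_ok=True)

result.metric_correlations.round(3).to_csv(args.out / "metric_correlations.csv")
result.pc1_loadings.rename("loading").round(4).to_csv(args.out / "pc1_loadings.csv")

rows = []
for name, test in result.omnibus_tests.items():
    rows.append({"metric": name, "test": "kruskal", "statistic": test["H"],
                 "p": test["p"], "pair": ""})
for name, pairs in result.pairwise_tests.items():
    for (a, b), test in pairs.items():
        rows.append({"metric": name, "test": "wilcoxon", "statistic": test["W"],
                     "p": test["p"], "pair": f"{a}-vs-{b}"})
for name, (r, p) in result.dose_correlations.items():
    rows.append({"metric": name, "test": "dose_pearson", "statistic": r, "p": p,
                 "pair": ""})
tests = pd.DataFrame(rows)
tests.to_csv(args.out / "tests.csv", index=False)

print(f"PC1 explains {result.pc1_variance_explained:.1%} of metric variance")
print("\nPC1 loadings:")
print(result.pc1_loadings.round(3).to_string())
print("\ncondition tests (Wilcoxon):")
print(tests[tests.test == "wilcoxon"].to_string(index=False))
print("\ndose correlations (sedated scans):")
print(tests[tests.test == "dose_pearson"].to_string(index=False))
print(f"\nwrote report to {args.out}")
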