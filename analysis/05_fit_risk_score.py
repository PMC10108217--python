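"""Distill the discovered signature into a linear risk score.

Fits the bidirectional stepwise logistic model on the training split's
signature labels (per-patient mean features during days 91-180) and
applies both the refitted score and the fixed published Composite Immune
Risk Score (threshold 2.50) to every patient with in-window data.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cirs import (PUBLISHED_MODEL, average_features, fit_score_model,
                  load_cohort, period_by_label, score_patient_period)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = load_cohort(args.results / "cohort" / "profiles.csv",
                     args.results / "cohort" / "outcomes.csv")
signature = pd.read_csv(args.results / "anchors" / "signature.csv")
period = period_by_label("d91_180")
out = args.results / "score"
out.mkdir(parents=True, exist_ok=True)

training = cohort.split("training")
feats = average_features(training, period).dropna()
labels = signature.set_index("patient_id")["carries"]
common = feats.index.intersection(labels.index)
model = fit_score_model(feats.loc[common], labels.reindex(common).to_numpy())

print("refitted score (stepwise AIC over the 20 profile features):")
for feature, coef in model.coefficients.items():
    print(f"  {feature:>16s}  {coef:+.4f}")
print(f"  threshold (Youden) {model.threshold:+.4f}")
with open(out / "fitted_model.json", "w") as fh:
    json.dump({"coefficients": model.coefficients, "intercept": model.intercept,
               "threshold": model.threshold, "provenance": model.provenance},
              fh, indent=1)

for name, m in [("fitted", model), ("published", PUBLISHED_MODEL)]:
    scores = score_patient_period(cohort, period, m)
    scores.to_csv(out / f"scores_{name}.csv", index=False, float_format="%.12g")
    print(f"{name} score: {len(scores)} patients scored, "
          f"{(scores['label'] == 'high').mean():.1%} high-risk")
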