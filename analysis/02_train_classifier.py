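"""Train and evaluate the behaviour classifier.

Runs preprocess -> feature extraction -> correlation-filtered forward
selection -> gradient-boosted-tree training on the labelled training set
from 01_simulate, then evaluates with a pooled 5-fold cross-validated
confusion matrix.  Small result tables (selected features with accuracy
contributions, confusion matrix, summary) land in results/classifier/.
"""

import sys
from pathlib import Path

from heatacc.pipeline import train_pipeline
from heatacc.synthetic import TRAINING_DIALECT

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    training = ROOT / "scratch" / "data" / "training_bursts.csv"
    if not training.exists():
        sys.exit("run analysis/01_simulate.py first")
    out = ROOT / "results" / "classifier"
    summary = train_pipeline(training, out, TRAINING_DIALECT, seed=seed)
    # the big feature matrix is intermediate, not a result table
    (out / "training_features.csv").unlink(missing_ok=True)
    lo, hi = summary["accuracy_ci"]
    print(f"cross-validated accuracy: {summary['accuracy']:.1%} "
          f"(95% CI {lo:.1%}-{hi:.1%}) on {summary['n_bursts']} bursts")
    print("selected features and accuracy contributions:")
    for feat, contrib in zip(summary["selected_features"], summary["contributions"]):
        print(f"  {feat}: {contrib:+.3f}")
    print(f"tables in {out}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
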