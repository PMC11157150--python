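"""Predict behaviours on the deployment and fit the heat-response models.

Applies the trained classifier to the unlabelled scenario bursts,
consolidates the 12 predicted behaviours into the 5 analysis categories,
joins blackglobe temperature from the weather series, and aggregates
afternoon (12:00-17:59 local) time-budget and mean-ODBA cells per
(blackglobe deg C, hour, month, individual).  For each behaviour a
penalized-spline mixed model estimates the proportion of time as a
function of blackglobe temperature and hour with individual random
intercepts; the same driver also fits the hot/cool-day diel models that
04_diel_comparison summarises.  Term tables and cells land in
results/analysis/.
"""

import sys
from pathlib import Path

from heatacc.pipeline import analyze_pipeline
from heatacc.synthetic import SCENARIO_DIALECT

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "data"
    model_dir = ROOT / "results" / "classifier"
    if not (data / "scenario_bursts.csv").exists():
        sys.exit("run analysis/01_simulate.py first")
    if not (model_dir / "model.json").exists():
        sys.exit("run analysis/02_train_classifier.py first")
    out = ROOT / "results" / "analysis"
    summary = analyze_pipeline(
        model_dir,
        data / "scenario_bursts.csv",
        data / "weather.csv",
        out,
        SCENARIO_DIALECT,
    )
    print(f"{summary['n_predictions']} bursts classified; "
          f"{summary['excluded_fraction']:.1%} excluded as rare behaviours")
    print(f"{summary['n_afternoon_cells']} afternoon budget cells, "
          f"{summary['n_odba_cells']} mean-ODBA cells (>=30 recordings)")
    print("blackglobe smooth p-values (afternoon proportions):")
    for behaviour, rep in summary["heat_models"].items():
        for term in rep["terms"]:
            if term["term"].startswith("s(blackglobe"):
                print(f"  {behaviour}: p = {term['p_value']:.4f} "
                      f"(edf {term['edf']:.2f})")
    print(f"term tables in {out}")


if __name__ == "__main__":
    main()
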