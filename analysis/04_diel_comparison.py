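"""Summarise the hot-day vs cool-day diel comparison.

Reads the diel model results produced by 03_heat_response (10 hottest vs
10 coolest days by daily maximum air temperature within October-December)
and writes a compact per-behaviour table: does the diel pattern differ
between hot and cool days (interaction smooth), does the 24-h mean differ
(intercept contrast), and by what percentage.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
ALPHA = 0.05


def main() -> None:
    summary_path = ROOT / "results" / "analysis" / "analyze_summary.json"
    if not summary_path.exists():
        sys.exit("run analysis/03_heat_response.py first")
    summary = json.loads(summary_path.read_text())
    rows = []
    for behaviour, extras in summary["diel_models"].items():
        rows.append(
            {
                "behaviour": behaviour,
                "diel_pattern_differs": extras["interaction_p"] < ALPHA,
                "interaction_p": round(extras["interaction_p"], 4),
                "mean_24h_differs": extras["intercept_contrast_p"] < ALPHA,
                "intercept_p": round(extras["intercept_contrast_p"], 4),
                "pct_difference_24h": round(extras["pct_difference_24h"], 1),
            }
        )
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "diel_summary.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
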