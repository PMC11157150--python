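"""Generate the synthetic study data.

Writes the deterministic fixture suite — a labelled training set of ~2,000
bursts across the 12 ethogram behaviours, a 2-individual 20-day hot-season
deployment (behaviour timeline plus raw collar bursts), the matching hourly
weather series and the ground-truth record of every planted parameter —
under scratch/data/.  Large raw files live under scratch/ on purpose; the
downstream drivers keep only small result tables under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from heatacc import synthetic

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    out = ROOT / "scratch" / "data"
    paths = synthetic.make_fixture_suite(out, seed=seed)
    timeline = pd.read_csv(paths["timeline"])
    print(f"wrote {len(paths)} files to {out}")
    print(f"training bursts: {sum(1 for _ in open(paths['training'])) - 1}")
    local = pd.to_datetime(timeline["timestamp"], utc=True) + pd.Timedelta(hours=2)
    print(f"scenario ticks:  {len(timeline)} "
          f"({timeline['individual_id'].nunique()} individuals, "
          f"{local.dt.date.nunique()} local days)")
    print("category mix:")
    print(timeline["category"].value_counts(normalize=True).round(3).to_string())


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
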