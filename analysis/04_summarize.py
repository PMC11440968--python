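"""Combine the rule and score screenings into one model-comparison table.

Reads the metrics JSONs from 02/03 and writes results/model_comparison.csv
with one row per model: counts, Se, Sp, ACC, MCC, CCR.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"
COLUMNS = ["tp", "fp", "tn", "fn", "se", "sp", "acc", "mcc", "ccr"]


def main():
    rows = []
    for name in ("rules_metrics.json", "scores_metrics.json"):
        payload = json.loads((RESULTS / name).read_text())
        for model, rep in payload["metrics"].items():
            if rep is None:
                continue
            rows.append({"model": model, **{c: rep[c] for c in COLUMNS}})
    table = pd.DataFrame(rows).set_index("model").sort_values("mcc", ascending=False)
    out = RESULTS / "model_comparison.csv"
    table.to_csv(out, lineterminator="\n")
    print(table.round(3).to_string())
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
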