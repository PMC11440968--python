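"""Screen the realistic cohort with every rule-of-thumb classifier.

Reads results/cohort_realistic.csv (run 01 first), classifies each record
with all eight rules, and writes the per-record verdicts plus per-rule
fractions and metrics.
"""

import json
from pathlib import Path

import pandas as pd

from bbbscreen import identity_column_map, load_dataset, screen, write_results
from bbbscreen.rules import available_rules

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    path = RESULTS / "cohort_realistic.csv"
    header = pd.read_csv(path, nrows=0).columns
    ds = load_dataset(path, column_map=identity_column_map(header))
    report = screen(ds, available_rules())

    write_results(ds, report.per_record, RESULTS / "rules_per_record.csv")
    payload = {
        "fractions": report.fractions,
        "metrics": {
            m: (rep.as_dict() if rep is not None else None)
            for m, rep in report.per_model.items()
        },
    }
    (RESULTS / "rules_metrics.json").write_text(json.dumps(payload, indent=2))

    for rule in available_rules():
        frac = report.fractions[rule]
        print(
            f"{rule:16s} positives CNS+: {frac['positives_cns_plus']:.2f}  "
            f"negatives CNS-: {frac['negatives_cns_minus']:.2f}  "
            f"indeterminate: {frac['indeterminate']}"
        )


if __name__ == "__main__":
    main()
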