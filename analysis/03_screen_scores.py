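"""Score the realistic cohort with the MPO models and logBB regressions.

CNS MPO (threshold > 4), CNS PET MPO (> 3), the synthetic-config BBB score
and the two Vilar logBB classifiers are applied to every record; per-record
scores and per-model metrics land in results/.
"""

import json
from pathlib import Path

import pandas as pd

from bbbscreen import (
    example_bbb_config,
    identity_column_map,
    load_dataset,
    screen,
    write_results,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
MODELS = ["cns_mpo", "cns_pet_mpo", "bbb_score", "vilar_eq6", "vilar_eq7"]


def main():
    path = RESULTS / "cohort_realistic.csv"
    header = pd.read_csv(path, nrows=0).columns
    ds = load_dataset(path, column_map=identity_column_map(header))

    config = example_bbb_config()
    config["cns_plus_threshold"] = 3.0  # of a 5-point synthetic scale
    report = screen(ds, MODELS, bbb_config=config)

    write_results(ds, report.per_record, RESULTS / "scores_per_record.csv")
    payload = {
        "fractions": report.fractions,
        "provenance": report.provenance,
        "metrics": {
            m: (rep.as_dict() if rep is not None else None)
            for m, rep in report.per_model.items()
        },
    }
    (RESULTS / "scores_metrics.json").write_text(json.dumps(payload, indent=2))

    for model in MODELS:
        rep = report.per_model[model]
        if rep is None:
            print(f"{model:12s} no determinate labeled predictions")
            continue
        print(
            f"{model:12s} Se {rep.se:.2f}  Sp {rep.sp:.2f}  "
            f"MCC {rep.mcc:.2f}  CCR {rep.ccr:.2f}"
        )


if __name__ == "__main__":
    main()
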