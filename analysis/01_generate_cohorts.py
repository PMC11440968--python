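"""Generate the synthetic screening cohorts used by the downstream analyses.

Writes two labeled 109/20 cohorts to results/: a clean-mode cohort
(separable by construction under the CNS MPO ranges) and a realistic-mode
cohort drawn from overlapping per-class normals.
"""

from pathlib import Path

from bbbscreen import GeneratorConfig, dataset_to_frame, generate

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    for mode in ("clean", "realistic"):
        ds = generate(GeneratorConfig(mode=mode, seed=SEED))
        path = OUT / f"cohort_{mode}.csv"
        dataset_to_frame(ds).to_csv(path, index=False, lineterminator="\n")
        n_pos = sum(1 for r in ds if r.label.value == "successful")
        print(f"{mode}: {len(ds)} records ({n_pos} successful) -> {path}")


if __name__ == "__main__":
    main()
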