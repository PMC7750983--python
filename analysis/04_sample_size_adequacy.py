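"""How many complete molar rows are needed for mean and SD of ratios?

Subsamples the synthetic sample without replacement at every N in
2..n-1 (10,000 pseudoreplicates per N) and reports the smallest N at
which 95% of pseudoreplicate means / SDs fall inside the full-sample
95% bootstrap intervals.
"""

import json
import pathlib

from molarcascade.data import (
    average_replicates,
    build_row_sizes,
    compute_ratios,
    read_measurement_table,
)
from molarcascade.sims import (
    adequacy_threshold,
    reference_intervals,
    sample_size_simulation,
)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 4


def main() -> None:
    table = read_measurement_table(OUT / "measurements.csv")
    collapsed = average_replicates(table)
    summary = {}
    for metric in ("length", "area"):
        ratios = compute_ratios(build_row_sizes(collapsed, metric=metric))
        reference = reference_intervals(ratios, n_boot=10_000, seed=SEED)
        result = sample_size_simulation(
            ratios, reference, reps=10_000, seed=SEED + 1
        )
        result.frame.to_csv(OUT / f"samplesize_{metric}.csv", index=False)
        adequacy = {
            f"{ratio}_{stat}": adequacy_threshold(result, ratio, stat)
            for ratio in ("r21", "r31")
            for stat in ("mean", "sd")
        }
        summary[metric] = adequacy
        print(f"[{metric}] smallest adequate N: {adequacy}")
    (OUT / "samplesize_adequacy.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
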