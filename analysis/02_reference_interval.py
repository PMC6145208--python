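"""Reference interval: per-CpG normal ranges from 156 synthetic fertile
reference methylomes, and how many loci remain callable.

Builds the empirical 95% interval (plus order statistics) at every locus,
summarises the interquartile-range distribution, and classifies each locus
by whether an aberrant call 0.2 beyond the interval is geometrically
possible. Writes a summary to results/reference_interval_summary.json;
the full per-locus table can be regenerated with `methval refint build`.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, default_config, parse_args

from methval import reference
from methval.simulate import gen_reference_population

T = 0.2
REPORTABLE_LOW = 0.052


def main() -> None:
    args = parse_args(__doc__)
    config = default_config(args.seed)

    population = gen_reference_population(config)
    table = reference.build_reference(population)
    table = reference.classify_detectability(table, T, REPORTABLE_LOW)

    iqr = reference.summarize_iqr(table)
    det = reference.detectability_summary(table)
    by_class = table["detectability"].value_counts().to_dict()

    summary = {
        "n_loci": det["n"],
        "n_reference_samples": config.n_reference_samples,
        "iqr_mode": iqr["mode"],
        "ci_width_lt_0.1_fraction": iqr["ci_width_lt_0.1_fraction"],
        "detectable_fraction": det["detectable_fraction"],
        "one_direction_fraction": det["one_direction_fraction"],
        "loci_by_class": {str(k): int(v) for k, v in by_class.items()},
        "t": T,
        "reportable_low": REPORTABLE_LOW,
    }
    with open(RESULTS / "reference_interval_summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)

    print(f"Reference intervals built at {det['n']} loci from "
          f"{config.n_reference_samples} reference methylomes.")
    print(f"IQR distribution mode: {iqr['mode']:.4f} "
          f"(tight, strongly unimodal per-CpG distributions).")
    print(f"95% intervals narrower than 0.1: "
          f"{100 * iqr['ci_width_lt_0.1_fraction']:.1f}% of loci.")
    print(f"Detectable at t = {T}: {100 * det['detectable_fraction']:.1f}% "
          f"of loci; of those, {100 * det['one_direction_fraction']:.1f}% "
          f"can change in one direction only.")
    print(f"Loci per class: {summary['loci_by_class']}")


if __name__ == "__main__":
    main()
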