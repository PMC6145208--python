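"""Reportable range: calibrate the array against WGBS on eight paired
synthetic samples.

For each sample we regress the WGBS methylation level on the array level
(y = a + b·x), solve for the measurements at which the fitted truth
reaches 0 and 1, and take the largest range covered by every sample.
Writes the per-sample fits (the analogue of a per-sample cut-off table)
to results/reportable_range.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, default_config, parse_args

from methval import concordance
from methval.report import probe_site_mapping, sample_truth
from methval.simulate import draw_locus_means, gen_paired_wgbs_array


def main() -> None:
    args = parse_args(__doc__)
    config = default_config(args.seed)
    means, sds = draw_locus_means(config)
    mapping = probe_site_mapping(config.n_loci)

    rows, fits = [], []
    for s in range(8):
        rng = np.random.default_rng([config.seed, 4, s])
        truth = sample_truth(means, sds, rng)
        wgbs, array = gen_paired_wgbs_array(truth, config, rng=rng)
        array_series = pd.Series(array, index=mapping["probe_id"].to_numpy())
        pairs = concordance.filter_comparable_loci(wgbs, array_series, mapping)
        fit = concordance.fit_reportable_range(pairs)
        fits.append(fit)
        rows.append(
            {"sample": s + 1, "n_loci": fit.n, "intercept": round(fit.a, 5),
             "slope": round(fit.b, 5), "adj_r2": round(fit.adj_r2, 4),
             "low_cutoff": round(fit.r_low, 4),
             "high_cutoff": round(fit.r_high, 4)}
        )

    table = pd.DataFrame(rows)
    low, high = concordance.aggregate_reportable_range(fits)
    table.to_csv(RESULTS / "reportable_range.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    print(f"\nLargest overlapping range across the eight samples: "
          f"[{low:.3f}, {high:.3f}]")
    print("Methylation levels below the lower cut-off are reported as "
          "'< low cut-off' rather than as exact values.")


if __name__ == "__main__":
    main()
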