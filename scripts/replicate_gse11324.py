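"""Replicate the real-data benchmark (GEO series GSE11324) — optional.

The published benchmark runs the triclustering on an estrogen-stimulated
MCF7 time course: 54675 Affymetrix probe sets x 3 replicates x 4 time
points (0, 3, 6, 12 h), with delta = 0.012382 and lambda = 1.2, reporting
115 triclusters, coverage 93.7412, average TQI 3.082684e-05 and SDB
0.4670856.

This script does NOT download or normalize the array data; supply a
preprocessed long-format TSV (gene_id, sample_id, time, value — e.g.
RMA-normalized expression exported from GEO) and it runs the same
configuration and compares the four summary statistics against the
published values with tolerance bands.  The outer masking loop draws random
values, so counts and scores vary run to run; the bands below are generous
for that reason, and this check is informational rather than a test gate.

Usage:
    python scripts/replicate_gse11324.py --input gse11324_long.tsv \
        --seed 0 --out replication.json
"""

import argparse
import json

import deltatrimax as dt
from deltatrimax.io import read_long_tsv

PUBLISHED = {
    "n_triclusters": 115,
    "coverage": 93.7412,
    "average_tqi": 3.082684e-05,
    "sdb": 0.4670856,
}
# relative tolerance bands; masking randomness and preprocessing choices
# both move these numbers
BANDS = {"n_triclusters": 0.25, "coverage": 0.10, "average_tqi": 0.50,
         "sdb": 0.50}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", required=True,
                        help="preprocessed long-format TSV of the series")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--delta", type=float, default=0.012382)
    parser.add_argument("--lam", type=float, default=1.2)
    parser.add_argument("--max-triclusters", type=int, default=200)
    parser.add_argument("--out", default="replication.json")
    args = parser.parse_args()

    tensor = read_long_tsv(args.input)
    params = dt.TrimaxParams(delta=args.delta, lam=args.lam,
                             max_triclusters=args.max_triclusters,
                             seed=args.seed)
    result = dt.delta_trimax(tensor, params)
    report = dt.quality_report(result.triclusters, tensor, r=100,
                               seed=args.seed)
    measured = {
        "n_triclusters": len(result.triclusters),
        "coverage": report.coverage,
        "average_tqi": report.average_tqi,
        "sdb": report.sdb,
    }
    comparison = {}
    for key, published in PUBLISHED.items():
        got = measured[key]
        band = BANDS[key]
        ok = abs(got - published) <= band * abs(published)
        comparison[key] = {"published": published, "measured": got,
                           "relative_band": band, "within_band": ok}
        print(f"{key}: measured {got:.6g} vs published {published:.6g} "
              f"({'within' if ok else 'OUTSIDE'} {band:.0%} band)")
    with open(args.out, "w") as fh:
        json.dump(comparison, fh, indent=1)


if __name__ == "__main__":
    main()
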