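"""Optional: full differential co-expression analysis on user-supplied data.

The published glioma case study compared 65 astrocytoma grade II against 30
oligodendroglioma grade II microarray profiles over the MSigDB canonical
pathway collection, with 10,000 permutations per gene set and a minimum
post-intersection set size of 20.  Those inputs (REMBRANDT expression data
and the MSigDB GMT file) must be obtained by the user; this script documents
and runs the same pipeline on whatever files are supplied:

  python scripts/real_data_analysis.py \
      --expr expression.tsv          # genes x samples, tab-delimited, header \
      --labels phenotypes.tsv        # two-column sample/label or CLS file \
      --gmt c2.cp.v4.0.symbols.gmt   # gene-set collection \
      [--annotation probes.tsv]      # probe -> symbol table if not collapsed \
      --out results.tsv

The output table lists each surviving gene set with its spectral
Jensen-Shannon statistic, permutation p-value, and BH-adjusted q-value.
Per-set follow-ups (gene rankings, single-gene differential expression, the
edge-difference matrix) are available through ``coexgraph analyze --set``.
"""

from __future__ import annotations

import argparse

from coexgraph import (
    AssociationConfig,
    analyze_collection,
    collapse_probes,
    read_annotation,
    read_expression,
    read_gmt,
    read_labels,
    write_results,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--expr", required=True)
    parser.add_argument("--labels", required=True)
    parser.add_argument("--gmt", required=True)
    parser.add_argument("--annotation", default=None)
    parser.add_argument("--nperm", type=int, default=10000)
    parser.add_argument("--min-size", type=int, default=20)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    expr = read_expression(args.expr, allow_duplicate_ids=args.annotation is not None)
    if args.annotation:
        expr = collapse_probes(expr, read_annotation(args.annotation))
    labels = read_labels(args.labels, sample_ids=expr.sample_ids)
    sets = read_gmt(args.gmt)

    results = analyze_collection(
        expr, labels, sets,
        config=AssociationConfig(),     # weighted, Spearman, 1 - FDR-adjusted p
        kind="spectral_js",
        B=args.nperm,
        min_size=args.min_size,
        seed=args.seed,
    )
    write_results(results, args.out)
    print(f"wrote {len(results)} gene-set results to {args.out}")


if __name__ == "__main__":
    main()
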