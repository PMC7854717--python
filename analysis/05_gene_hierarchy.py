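#!/usr/bin/env python
"""Gene commanding heights and each chamber's gene master regulator.

Scores every gene as GCH = (REC + 1) * exp(4 * mean rho^2 over all other
genes) in each chamber, ranks the chambers' hierarchies, and prints the
top-5 genes per chamber; rank 1 is the chamber's GMR. Also reports the
arithmetic mean GCH of each synthetic pathway per chamber.

Usage: python analysis/05_gene_hierarchy.py
       [--data results/data] [--out results/gch]
"""

import argparse
from pathlib import Path

import pandas as pd

from gfabric.cli import stage_gch
from gfabric.gch import pathway_mean_gch
from gfabric.io_model import read_gene_sets, write_table


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/gch"))
    parser.add_argument("--top-k", type=int, default=5)
    args = parser.parse_args()

    stage_gch(
        str(args.data / "expression.tsv"),
        args.out,
        gene_sets_path=None,
        partners_set=None,
        top_k=args.top_k,
    )

    top = pd.read_csv(args.out / "gch_top.tsv", sep="\t")
    print(f"\ntop {args.top_k} genes (highest GCH) per chamber:")
    print(top[["chamber", "rank", "gene", "rec", "mean_sq_cor", "gch"]]
          .to_string(index=False))

    sets = read_gene_sets(args.data / "synthetic_pathways.gmt")
    rows = []
    for chamber in ("LA", "RA", "LV", "RV"):
        table = pd.read_csv(args.out / f"gch_{chamber}.tsv", sep="\t")
        for name in sets.names():
            members, _ = sets.quantified(name, table["gene"])
            rows.append({"set": name, "chamber": chamber,
                         "mean_GCH": pathway_mean_gch(table, members)})
    means = pd.DataFrame(rows)
    write_table(means, args.out / "pathway_mean_gch.tsv")
    print("\nmean pathway GCH (LA):")
    print(means[means["chamber"] == "LA"].to_string(index=False))


if __name__ == "__main__":
    main()
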