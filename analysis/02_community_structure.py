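#!/usr/bin/env python
"""Beta-diversity structure of the donor/recipient cohort.

Replicate-averages the cohort, computes Bray-Curtis dissimilarities and
their principal-coordinate embedding, tests composition (PERMANOVA) and
dispersion (PERMDISP) between hosts, and compares the category-wise
dissimilarities (donor-donor, mouse-mouse, donor vs own/other recipients)
with Kruskal-Wallis + Dunn.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from hma_fidelity import (
    average_replicates,
    bray_curtis,
    build_pairing,
    compare_groups,
    extract_group_dissimilarities,
    load_metadata,
    load_taxon_table,
    pcoa,
    permanova,
    permdisp,
)
from hma_fidelity.beta import write_dist_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
    parser.add_argument("--permutations", type=int, default=999)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = load_taxon_table(args.datadir / "cohort_abundance.tsv", rank="genus")
    meta = load_metadata(args.datadir / "cohort_metadata.tsv")
    pairing = build_pairing(meta)
    averaged = average_replicates(table, meta)

    by_col = {m.sample_id: m for m in meta}
    for m in meta:
        if m.host == "mouse":
            by_col.setdefault(m.replicate_group, m)
    hosts = [by_col[c].host for c in averaged.samples]

    dist = bray_curtis(averaged)
    write_dist_matrix(dist, args.outdir / "bray_curtis.tsv")
    ordination = pcoa(dist)
    ordination.to_frame().to_csv(args.outdir / "pcoa.tsv", sep="\t",
                                 float_format="%.10g")

    manova = permanova(dist, hosts, n_perm=args.permutations, seed=args.seed)
    disp = permdisp(dist, hosts, n_perm=args.permutations, seed=args.seed)
    grouped = extract_group_dissimilarities(dist, meta, pairing)
    test = compare_groups(
        {k: v for k, v in grouped.categories.items() if len(v) >= 2},
        method="kruskal_dunn",
    )

    result = {
        "permanova": {"pseudo_F": manova.statistic, "r_squared": manova.r_squared,
                      "p_value": manova.p_value},
        "permdisp": {"pseudo_F": disp.statistic, "p_value": disp.p_value},
        "mean_dissimilarity": grouped.means(),
        "kruskal_dunn": {"H": test.statistic, "p_value": test.p_value},
        "pcoa_pc1_pc2_explained": [float(v) for v in
                                   ordination.proportion_explained[:2]],
    }
    with open(args.outdir / "community_structure.json", "w") as fh:
        json.dump(result, fh, indent=2, sort_keys=True)
    pd.DataFrame(
        [(c, v) for c, vals in grouped.categories.items() for v in vals],
        columns=["category", "dissimilarity"],
    ).to_csv(args.outdir / "grouped_dissimilarities.tsv", sep="\t", index=False)

    print(f"PERMANOVA (human vs mouse): F = {manova.statistic:.2f}, "
          f"R2 = {manova.r_squared:.2f}, p = {manova.p_value:.3g}")
    print(f"PERMDISP: F = {disp.statistic:.2f}, p = {disp.p_value:.3g}")
    means = grouped.means()
    print("mean Bray-Curtis: " + ", ".join(
        f"{k} = {v:.3f}" for k, v in sorted(means.items())))
    print(f"Kruskal-Wallis across categories: H = {test.statistic:.2f}, "
          f"p = {test.p_value:.3g}")


if __name__ == "__main__":
    main()
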