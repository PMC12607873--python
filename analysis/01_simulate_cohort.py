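#!/usr/bin/env python
"""Generate the synthetic cohorts every later analysis step consumes.

Writes a single-population donor/recipient cohort (6 donors, 3 replicate
mice per donor, paired T0/T2 timepoints, consortium spike-in at T2) and a
four-study strong-filter mega-analysis cohort, each with abundance tables,
metadata, and the hidden-truth sidecar.
"""

import argparse
from pathlib import Path

from hma_fidelity import default_truth, generate_cohort, generate_multi_study
from hma_fidelity.simulate import write_truth
from hma_fidelity.tables import write_metadata, write_taxon_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(default_truth(seed=args.seed), seed=args.seed)
    write_taxon_table(cohort.table, args.outdir / "cohort_abundance.tsv")
    write_metadata(cohort.meta, args.outdir / "cohort_metadata.tsv")
    write_truth(cohort.truth, args.outdir / "cohort_truth.tsv",
                args.outdir / "cohort_manifest.json", cohort.manifest)
    print(f"single cohort: {len(cohort.table.samples)} samples, "
          f"{len(cohort.table.taxa)} taxa, {len(cohort.pairing.pairs)} "
          f"donor-recipient pairs")

    ms = generate_multi_study(seed=args.seed)
    write_taxon_table(ms.table, args.outdir / "mega_abundance.tsv")
    write_metadata(ms.meta, args.outdir / "mega_metadata.tsv")
    for study_id, truth in ms.truths.items():
        write_truth(truth, args.outdir / f"mega_truth_{study_id}.tsv")
    print(f"mega-analysis: {len(ms.truths)} studies, "
          f"{len(ms.table.samples)} samples, {len(ms.pairing.pairs)} pairs")
    print(f"wrote cohort files under {args.outdir}")


if __name__ == "__main__":
    main()
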