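"""Replicate averaging, abundance filtering, and display transforms.

Mice seeded from the same donor stool are technical replicates of one
colonization event, not independent animals; averaging their profiles before
any between-group statistic avoids pseudo-replication.  The low-abundance
filter and the floored log transform serve the association/correlation
stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hma_fidelity.tables import SampleMeta, TaxonTable, renormalize


def average_replicates(table: TaxonTable, meta: list[SampleMeta]) -> TaxonTable:
    """Collapse each mouse replicate group to the arithmetic mean profile.

    Output columns are the replicate-group ids for mice and the original
    sample ids for humans (passed through unchanged).  The result is
    renormalized; means of normalized columns already sum to 100, so this is
    a guard rather than a rescaling.
    """
    by_id = {m.sample_id: m for m in meta}
    unknown = [s for s in table.samples if s not in by_id]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown}")

    group_hosts: dict[str, set[str]] = {}
    for s in table.samples:
        m = by_id[s]
        if m.host == "mouse":
            group_hosts.setdefault(m.replicate_group, set()).add(m.host)
        elif m.replicate_group:
            group_hosts.setdefault(m.replicate_group, set()).add(m.host)
    for g, hosts in group_hosts.items():
        if len(hosts) > 1:
            raise ValueError(f"replicate group {g!r} spans both host species")

    columns: dict[str, pd.Series] = {}
    order: list[str] = []
    for s in table.samples:
        m = by_id[s]
        if m.host == "human":
            columns[s] = table.data[s]
            order.append(s)
        else:
            g = m.replicate_group
            if g not in columns:
                members = [
                    t for t in table.samples
                    if by_id[t].host == "mouse" and by_id[t].replicate_group == g
                ]
                columns[g] = table.data[members].mean(axis=1)
                order.append(g)
    out = TaxonTable(pd.DataFrame({c: columns[c] for c in order}), rank=table.rank)
    return renormalize(out)


def filter_low_abundance(table: TaxonTable, min_ra_percent: float = 0.1) -> TaxonTable:
    """Drop taxa whose maximum relative abundance over samples is below the cutoff.

    A taxon is retained iff max RA >= ``min_ra_percent`` (so a taxon at
    exactly the cutoff stays).  The sample set is unchanged and no
    renormalization is applied: the filter feeds association and correlation
    stages, where dropping rare rows must not rescale the remaining ones.
    """
    if min_ra_percent < 0:
        raise ValueError("min_ra_percent must be >= 0")
    keep = table.data.max(axis=1) >= min_ra_percent
    out = table.copy()
    out.data = table.data.loc[keep]
    return out


def log_display(table: TaxonTable, floor: float = -3.0) -> pd.DataFrame:
    """log10 of percent RA for display, with zeros set to a fixed floor.

    Returns a plain DataFrame (not a TaxonTable: the values are no longer
    compositional).
    """
    values = table.values
    if (values < 0).any():
        raise ValueError("log_display requires non-negative abundances")
    positive = values > 0
    if positive.any():
        smallest = values[positive].min()
        if floor >= np.log10(smallest):
            raise ValueError(
                f"floor {floor} is not below log10 of the smallest positive "
                f"value ({np.log10(smallest):.3g})"
            )
    out = np.full_like(values, floor, dtype=float)
    out[positive] = np.log10(values[positive])
    return pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
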