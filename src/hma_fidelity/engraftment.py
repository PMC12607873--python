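"""Per-taxon engraftment statistics for donor-recipient cohorts.

Percent engraftment of a taxon is the fraction of donor-recipient pairs in
which the taxon, present in the donor stool, is also detected in the
recipient mouse group:

    percent_engraftment = 100 * n_pairs_engrafted / n_donors_with_taxon

A recipient group counts as carrying a taxon when any member mouse does (an
averaged profile preserves any positive value, so group presence is an OR
over replicates).  Taxa never seen in a donor are excluded: their
denominator is zero and engraftment is undefined for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from hma_fidelity.tables import PairingMap, TaxonTable

STRATA = ("high", "medium", "low", "unassigned")

ENGRAFTMENT_COLUMNS = (
    "n_donors_with_taxon",
    "n_pairs_engrafted",
    "percent_engraftment",
    "stratum",
    "study_id",
)


class EngraftmentTable(pd.DataFrame):
    """Per-taxon engraftment counts and percentages.

    A thin DataFrame subclass indexed by taxon with columns
    ``n_donors_with_taxon``, ``n_pairs_engrafted``, ``percent_engraftment``,
    ``stratum`` and ``study_id``.
    """

    @property
    def _constructor(self):
        return EngraftmentTable


def presence_matrix(table: TaxonTable, detection_threshold_percent: float = 0.0) -> pd.DataFrame:
    """Boolean taxa x samples matrix: present iff RA strictly above threshold."""
    if detection_threshold_percent < 0:
        raise ValueError("detection threshold must be >= 0")
    return table.data > detection_threshold_percent


def _group_presence(presence: pd.DataFrame, members) -> pd.Series:
    cols = [m for m in members if m in presence.columns]
    if not cols:
        raise ValueError(f"no member samples of {sorted(members)} found in matrix")
    return presence[cols].any(axis=1)


def percent_engraftment(
    presence: pd.DataFrame,
    pairing: PairingMap,
    study_id: str = "",
) -> EngraftmentTable:
    """Per-taxon engraftment over the donor-recipient pairs of a cohort.

    For each taxon: the denominator counts pairs whose donor carries the
    taxon, the numerator counts those where the recipient group carries it
    too.  Taxa carried by no donor are dropped.
    """
    if not pairing.pairs:
        raise ValueError("pairing contains no donor-recipient pairs")
    missing = [d for d, _ in pairing.pairs if d not in presence.columns]
    if missing:
        raise ValueError(f"donor samples absent from presence matrix: {missing}")

    n_donors = pd.Series(0, index=presence.index, dtype=int)
    n_engrafted = pd.Series(0, index=presence.index, dtype=int)
    for donor, group in pairing.pairs:
        donor_has = presence[donor]
        group_has = _group_presence(presence, pairing.recipient_group_members[group])
        n_donors += donor_has.astype(int)
        n_engrafted += (donor_has & group_has).astype(int)

    keep = n_donors > 0
    out = EngraftmentTable(
        {
            "n_donors_with_taxon": n_donors[keep],
            "n_pairs_engrafted": n_engrafted[keep],
            "percent_engraftment": 100.0 * n_engrafted[keep] / n_donors[keep],
            "stratum": "unassigned",
            "study_id": study_id,
        }
    )
    out.index.name = "taxon"
    return out


def filter_engrafters(table: EngraftmentTable, min_pairs: int = 5) -> EngraftmentTable:
    """Keep taxa engrafting in at least ``min_pairs`` donor-recipient pairs.

    The default of 5 keeps taxa engrafting in more than 4 pairs.
    """
    return table[table["n_pairs_engrafted"] >= min_pairs]


def _stratum(mean_pct: float) -> str:
    if mean_pct > 80.0:
        return "high"
    if mean_pct >= 60.0:
        return "medium"
    return "low"


def stratify_engrafters(tables: list[EngraftmentTable]) -> EngraftmentTable:
    """Average percent engraftment across studies and assign strata.

    High engrafters exceed 80% mean engraftment, low engrafters fall below
    60%, and the closed interval [60, 80] is medium — the unique assignment
    that partitions the percentage line.  A taxon with no defined value in
    any study is ``unassigned``.
    """
    if not tables:
        raise ValueError("need at least one per-study engraftment table")
    taxa = sorted(set().union(*(set(t.index) for t in tables)))
    means = []
    for taxon in taxa:
        vals = [
            float(t.loc[taxon, "percent_engraftment"]) for t in tables if taxon in t.index
        ]
        means.append(np.mean(vals) if vals else np.nan)
    means = pd.Series(means, index=taxa, name="percent_engraftment")
    strata = means.map(lambda m: "unassigned" if pd.isna(m) else _stratum(m))
    out = EngraftmentTable(
        {
            "n_donors_with_taxon": [
                int(sum(t.loc[tx, "n_donors_with_taxon"] for t in tables if tx in t.index))
                for tx in taxa
            ],
            "n_pairs_engrafted": [
                int(sum(t.loc[tx, "n_pairs_engrafted"] for t in tables if tx in t.index))
                for tx in taxa
            ],
            "percent_engraftment": means,
            "stratum": strata,
            "study_id": "pooled",
        }
    )
    out.index = pd.Index(taxa, name="taxon")
    return out


def donor_engraftment_fraction(presence: pd.DataFrame, pairing: PairingMap) -> pd.Series:
    """Per donor-recipient pair: percent of donor taxa found in the recipients.

    ``100 * |donor taxa also in recipient group| / |donor taxa|``, indexed by
    donor sample id (suffixed with the group id when a donor has several
    pairs).
    """
    if not pairing.pairs:
        raise ValueError("pairing contains no donor-recipient pairs")
    donors_seen = [d for d, _ in pairing.pairs]
    fractions = {}
    for donor, group in pairing.pairs:
        donor_taxa = presence[donor]
        n_donor = int(donor_taxa.sum())
        if n_donor == 0:
            raise ValueError(f"donor {donor!r} carries no taxa")
        group_has = _group_presence(presence, pairing.recipient_group_members[group])
        shared = int((donor_taxa & group_has).sum())
        key = donor if donors_seen.count(donor) == 1 else f"{donor}|{group}"
        fractions[key] = 100.0 * shared / n_donor
    return pd.Series(fractions, name="percent_donor_taxa_engrafted")


def engraftment_abundance_correlation(
    table: EngraftmentTable,
    mouse_table: TaxonTable,
) -> tuple[float, float, int]:
    """Pearson correlation between percent engraftment and mean recipient RA.

    Returns ``(r, p, n)`` over the taxa shared by the engraftment table and
    the recipient abundance table; requires at least 3 shared taxa.
    """
    mean_ra = mouse_table.data.mean(axis=1)
    shared = [t for t in table.index if t in mean_ra.index]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared taxa, got {len(shared)}")
    x = table.loc[shared, "percent_engraftment"].to_numpy(dtype=float)
    y = mean_ra.loc[shared].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(shared)


def write_engraftment_table(table: EngraftmentTable, path) -> None:
    out = table.reset_index()[
        ["taxon", "study_id", "n_donors_with_taxon", "n_pairs_engrafted",
         "percent_engraftment", "stratum"]
    ]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
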