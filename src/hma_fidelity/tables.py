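"""Taxon abundance tables, sample metadata, and donor-recipient pairing.

The canonical in-memory container is :class:`TaxonTable`, a taxa x samples
matrix of *percent* relative abundance (columns sum to 100 after
:func:`renormalize`).  Two on-disk dialects are read: a plain TSV whose first
column is ``taxon``, and a merged-profiler dialect whose first column is
``clade_name`` holding full rank-prefixed taxonomy strings
(``k__...|g__...|s__...``); only rows terminating at the requested rank are
kept and the terminal rank name becomes the taxon identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("species", "genus")
RANK_PREFIX = {"species": "s__", "genus": "g__"}

HOSTS = ("human", "mouse")
TIMEPOINTS = ("T0", "T2", "baseline", "SPF", "other")
ROUTES = ("HTR", "MTR", "none")

METADATA_COLUMNS = (
    "sample_id",
    "host",
    "donor_id",
    "timepoint",
    "study_id",
    "route",
    "replicate_group",
)

#: tolerance on column sums before a table is flagged for renormalization
SUM_TOL = 1e-6


@dataclass
class TaxonTable:
    """Taxa x samples matrix of percent relative abundance at one rank.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon identifier with one column per sample.
        Values are percent relative abundance (0-100 scale).
    rank:
        Taxonomic rank of the rows, ``"species"`` or ``"genus"``.
    needs_renormalization:
        True when at least one column does not sum to 100 within tolerance.
        Set automatically on construction; cleared by :func:`renormalize`.
    """

    data: pd.DataFrame
    rank: str
    needs_renormalization: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {self.rank!r}")
        df = self.data
        df.index = pd.Index([str(t).strip() for t in df.index], name="taxon")
        df.columns = pd.Index([str(s).strip() for s in df.columns])
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if (values < 0).any():
            raise ValueError("abundance values must be non-negative")
        self.data = df.astype(float)
        sums = values.sum(axis=0)
        if df.shape[1] and not np.allclose(sums, 100.0, atol=SUM_TOL, rtol=0):
            self.needs_renormalization = True

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "TaxonTable":
        return TaxonTable(self.data.copy(), self.rank, self.needs_renormalization)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations: host species, donor, timepoint, study, route."""

    sample_id: str
    host: str
    donor_id: str
    timepoint: str
    study_id: str
    route: str
    replicate_group: str

    def __post_init__(self) -> None:
        if self.host not in HOSTS:
            raise ValueError(f"host must be one of {HOSTS}, got {self.host!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if self.host == "human" and self.route != "none":
            raise ValueError(
                f"human sample {self.sample_id!r} must have route='none', "
                f"got {self.route!r}"
            )


@dataclass
class PairingMap:
    """Donor sample <-> recipient mouse-group pairing.

    ``pairs`` lists (donor_sample_id, recipient_group_id) tuples;
    ``recipient_group_members`` maps each recipient group to the mouse
    sample ids that were seeded from that donor stool.  A donor sample may
    sit in several pairs (e.g. one per timepoint); a recipient group sits in
    exactly one.
    """

    pairs: list[tuple[str, str]]
    recipient_group_members: dict[str, set[str]]

    def __post_init__(self) -> None:
        groups = [g for _, g in self.pairs]
        if len(groups) != len(set(groups)):
            raise ValueError("a recipient group may appear in exactly one pair")
        for _, g in self.pairs:
            members = self.recipient_group_members.get(g, set())
            if not members:
                raise ValueError(f"recipient group {g!r} has no member samples")

    @property
    def donor_of(self) -> dict[str, str]:
        return {g: d for d, g in self.pairs}


def _parse_metaphlan_rows(df: pd.DataFrame, rank: str) -> pd.DataFrame:
    prefix = RANK_PREFIX[rank]
    keep_idx: list[str] = []
    keep_rows: list[int] = []
    for i, clade in enumerate(df.index):
        clade = str(clade).strip()
        if "UNCLASSIFIED" in clade.upper():
            logger.info("dropping unclassified row %r", clade)
            continue
        terminal = clade.split("|")[-1]
        if not terminal.startswith(prefix):
            continue  # row terminates at another rank
        keep_idx.append(terminal[len(prefix):])
        keep_rows.append(i)
    out = df.iloc[keep_rows].copy()
    out.index = pd.Index(keep_idx, name="taxon")
    if out.index.has_duplicates:
        dup = sorted(out.index[out.index.duplicated()].unique())
        raise ValueError(
            f"duplicate taxa after extracting rank {rank!r}: {dup}"
        )
    return out


def load_taxon_table(path, dialect: str = "plain_tsv", rank: str = "species") -> TaxonTable:
    """Read an abundance TSV in either supported dialect.

    ``plain_tsv``: first column ``taxon``, remaining columns samples.
    ``metaphlan_merged``: first column ``clade_name`` with rank-prefixed
    taxonomy strings; only rows terminating at ``rank`` are retained.

    Raises on non-numeric cells (named by row and column) and on duplicate
    taxa after rank extraction.  Columns not summing to 100 merely set the
    ``needs_renormalization`` flag.
    """
    if dialect not in ("plain_tsv", "metaphlan_merged"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    if dialect == "metaphlan_merged":
        df = _parse_metaphlan_rows(df, rank)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            taxon = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric value at taxon {taxon!r}, sample {col!r}: "
                f"{df.loc[taxon, col]!r}"
            )
        numeric[col] = converted.fillna(0.0)
    table = TaxonTable(numeric, rank=rank)
    if table.needs_renormalization:
        logger.warning("column sums differ from 100; call renormalize()")
    return table


def write_taxon_table(table: TaxonTable, path) -> None:
    """Write a table in the plain TSV dialect (first column ``taxon``)."""
    out = table.data.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t", float_format="%.10g")


def load_metadata(path) -> list[SampleMeta]:
    """Read a sample-metadata TSV with the required header columns.

    Enforces the controlled vocabularies for host, timepoint, and route, and
    rejects duplicate sample ids.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    rows = [
        SampleMeta(**{c: str(row[c]).strip() for c in METADATA_COLUMNS})
        for _, row in df.iterrows()
    ]
    ids = [m.sample_id for m in rows]
    if len(ids) != len(set(ids)):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample_id in metadata: {dup}")
    return rows


def write_metadata(meta: list[SampleMeta], path) -> None:
    df = pd.DataFrame([{c: getattr(m, c) for c in METADATA_COLUMNS} for m in meta])
    df.to_csv(path, sep="\t", index=False)


def meta_by_id(meta: list[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in meta}


def build_pairing(meta: list[SampleMeta]) -> PairingMap:
    """Pair each donor sample with the recipient groups seeded from it.

    A mouse replicate group matches the human sample sharing its donor_id
    and timepoint.  Orphan mouse groups (no matching donor sample) are
    excluded with a warning.  Pairs are ordered by donor_id then timepoint.
    """
    humans = [m for m in meta if m.host == "human"]
    mice = [m for m in meta if m.host == "mouse"]
    if not humans or not mice:
        raise ValueError("pairing requires at least one human and one mouse sample")

    donor_lookup: dict[tuple[str, str], str] = {}
    for h in humans:
        donor_lookup[(h.donor_id, h.timepoint)] = h.sample_id

    groups: dict[str, list[SampleMeta]] = {}
    for m in mice:
        groups.setdefault(m.replicate_group, []).append(m)

    pairs: list[tuple[str, str]] = []
    members: dict[str, set[str]] = {}
    keyed: list[tuple[str, str, str, str]] = []
    for group_id, group_meta in groups.items():
        donor_ids = {m.donor_id for m in group_meta}
        timepoints = {m.timepoint for m in group_meta}
        if len(donor_ids) > 1 or len(timepoints) > 1:
            raise ValueError(
                f"replicate group {group_id!r} mixes donors or timepoints"
            )
        donor_id, tp = donor_ids.pop(), timepoints.pop()
        donor_sample = donor_lookup.get((donor_id, tp)) or donor_lookup.get(
            (donor_id, "T0")
        )
        if donor_sample is None:
            logger.warning(
                "excluding orphan mouse group %r: no donor sample for "
                "donor_id=%r", group_id, donor_id,
            )
            continue
        keyed.append((donor_id, tp, donor_sample, group_id))
        members[group_id] = {m.sample_id for m in group_meta}
    keyed.sort()
    pairs = [(d, g) for _, _, d, g in keyed]
    if not pairs:
        raise ValueError("no donor-recipient pairs could be formed")
    return PairingMap(pairs=pairs, recipient_group_members=members)


def renormalize(table: TaxonTable) -> TaxonTable:
    """Scale every sample column to sum exactly 100.

    All-zero columns are an error (a sample with no observed taxa cannot be
    renormalized).
    """
    sums = table.values.sum(axis=0)
    zero = np.asarray(sums) <= 0
    if zero.any():
        bad = [s for s, z in zip(table.samples, zero) if z]
        raise ValueError(f"cannot renormalize all-zero sample(s): {bad}")
    data = table.data * (100.0 / sums)
    return replace(table, data=data, needs_renormalization=False)


def merge_tables(tables: list[TaxonTable]) -> TaxonTable:
    """Union taxa across tables, filling missing taxa with 0.

    Required for cross-study comparisons; all inputs must share a rank and
    have disjoint sample sets.
    """
    if not tables:
        raise ValueError("no tables to merge")
    ranks = {t.rank for t in tables}
    if len(ranks) > 1:
        raise ValueError(f"cannot merge tables at different ranks: {sorted(ranks)}")
    merged = pd.concat([t.data for t in tables], axis=1).fillna(0.0)
    return TaxonTable(merged, rank=tables[0].rank)
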