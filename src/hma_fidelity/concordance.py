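"""Donor-recipient ecological-response concordance.

Three views of the same question — does the recipient community respond the
way the donor community did?

* delta-RA quadrant analysis: per-taxon change in percent relative
  abundance between two timepoints in donors versus recipients, with the
  fraction of taxa in each sign quadrant;
* route-of-exposure scatter: paired log abundances of taxa between two
  exposure routes, with consortium taxa flagged;
* cross-sample correlation matrices with Fisher z-transformed coefficients
  for group comparison (testing on z, reporting category means on r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hma_fidelity.preprocess import log_display
from hma_fidelity.tables import SampleMeta, TaxonTable, merge_tables

logger = logging.getLogger(__name__)

CLAMP = 1.0 - 1e-15

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")  # (+,+), (-,+), (-,-), (+,-)


@dataclass
class ConcordanceResult:
    """Paired donor/recipient per-taxon deltas with correlation and quadrants."""

    taxa: list[str]
    donor_delta: pd.Series
    recipient_delta: pd.Series
    pearson_r: float
    p_value: float
    quadrant_fractions: dict[str, float]


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations between sample RA vectors, with Fisher z."""

    ids: list[str]
    r: np.ndarray
    z: np.ndarray

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ids, columns=self.ids)


@dataclass
class GroupCorrelationSummary:
    """Category means of r (reporting) and z (testing) plus the omnibus test."""

    mean_r: dict[str, float]
    mean_z: dict[str, float]
    mean_r_within_study: dict[str, float]
    mean_r_cross_study: dict[str, float]
    test: object  # GroupComparisonResult on the z values


def fisher_z(r: float) -> float:
    """Fisher z-transformation, ``z = atanh(r)``, with clamping at |r| = 1.

    Correlations of exactly +/-1 (identical columns in a toy) are clamped to
    1 - 1e-15 with a warning rather than dropped, so pair counts survive.
    """
    r = float(r)
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) >= 1.0:
        warnings.warn(f"clamping |r| = {abs(r)} to {CLAMP} before Fisher z")
        r = np.sign(r) * CLAMP
    return float(np.arctanh(r))


def delta_ra(
    table: TaxonTable,
    meta: list[SampleMeta],
    from_tp: str = "T0",
    to_tp: str = "T2",
) -> pd.DataFrame:
    """Per-entity per-taxon change in percent RA between two timepoints.

    Entities are donors (human samples keyed by donor_id) or recipient
    groups (replicate-averaged mouse columns keyed by donor_id).  The input
    must be a replicate-averaged table: mouse columns named by replicate
    group.  Entities lacking a profile at either timepoint are excluded with
    a warning.  Returns a taxa x entity DataFrame; entity ids are
    ``host:donor_id``.
    """
    by_col: dict[str, SampleMeta] = {}
    group_meta: dict[str, SampleMeta] = {}
    for m in meta:
        by_col[m.sample_id] = m
        if m.host == "mouse" and m.replicate_group:
            group_meta.setdefault(m.replicate_group, m)

    profiles: dict[tuple[str, str], dict[str, str]] = {}
    for col in table.samples:
        m = by_col.get(col) or group_meta.get(col)
        if m is None:
            raise ValueError(f"column {col!r} matches no sample or replicate group")
        profiles.setdefault((m.host, m.donor_id), {})[m.timepoint] = col

    deltas = {}
    for (host, donor_id), tps in sorted(profiles.items()):
        if from_tp not in tps or to_tp not in tps:
            logger.warning(
                "excluding %s:%s — missing a %s or %s profile",
                host, donor_id, from_tp, to_tp,
            )
            continue
        deltas[f"{host}:{donor_id}"] = (
            table.data[tps[to_tp]] - table.data[tps[from_tp]]
        )
    return pd.DataFrame(deltas, index=table.data.index)


def delta_concordance(
    donor_delta: pd.Series,
    recipient_delta: pd.Series,
) -> ConcordanceResult:
    """Correlate per-taxon donor deltas with recipient deltas.

    Restricted to taxa present in both series' indices (callers restrict the
    indices to taxa observed in the respective hosts).  Pearson r keeps every
    overlapping taxon; the quadrant fractions use only taxa with both deltas
    nonzero — a point on an axis belongs to no quadrant.
    """
    taxa = [t for t in donor_delta.index if t in set(recipient_delta.index)]
    if len(taxa) < 3:
        raise ValueError(f"need >=3 overlapping taxa, got {len(taxa)}")
    x = donor_delta.loc[taxa].to_numpy(dtype=float)
    y = recipient_delta.loc[taxa].to_numpy(dtype=float)
    r, p = stats.pearsonr(x, y)

    both_nonzero = (x != 0) & (y != 0)
    n_q = both_nonzero.sum()
    fractions = dict.fromkeys(QUADRANTS, 0.0)
    if n_q:
        fractions["Q1"] = 100.0 * np.sum((x > 0) & (y > 0)) / n_q
        fractions["Q2"] = 100.0 * np.sum((x < 0) & (y > 0)) / n_q
        fractions["Q3"] = 100.0 * np.sum((x < 0) & (y < 0)) / n_q
        fractions["Q4"] = 100.0 * np.sum((x > 0) & (y < 0)) / n_q
    return ConcordanceResult(
        taxa=taxa,
        donor_delta=donor_delta.loc[taxa],
        recipient_delta=recipient_delta.loc[taxa],
        pearson_r=float(r),
        p_value=float(p),
        quadrant_fractions=fractions,
    )


def route_abundance_scatter(
    table_htr: TaxonTable,
    table_mtr: TaxonTable,
    consortium: list[str],
) -> tuple[pd.DataFrame, float]:
    """Paired log RA of shared taxa between two exposure routes.

    Each route table is reduced to its mean profile across samples; shared
    taxa get a log10 value per route (zeros floored at -3) and a consortium
    flag.  Returns the tidy table and the Pearson r on the log values.
    """
    shared = [t for t in table_htr.taxa if t in set(table_mtr.taxa)]
    if not shared:
        raise ValueError("the two route tables share no taxa")
    consortium_set = set(consortium)

    def mean_log(table: TaxonTable) -> pd.Series:
        mean = table.data.mean(axis=1).to_frame("mean")
        sub = TaxonTable(mean, rank=table.rank)
        return log_display(sub)["mean"]

    log_h = mean_log(table_htr).loc[shared]
    log_m = mean_log(table_mtr).loc[shared]
    out = pd.DataFrame(
        {
            "log_ra_htr": log_h,
            "log_ra_mtr": log_m,
            "is_consortium": [t in consortium_set for t in shared],
        }
    )
    out.index.name = "taxon"
    if len(shared) >= 3 and log_h.std() > 0 and log_m.std() > 0:
        r = float(stats.pearsonr(log_h, log_m)[0])
    else:
        r = float("nan")
    return out, r


def sample_correlation_matrix(tables: list[TaxonTable]) -> CorrelationMatrix:
    """Pairwise Pearson correlation between all sample RA vectors.

    Taxa are unioned across tables with zero fill, so vectors are comparable
    across studies; each pairwise correlation is then computed over that
    pair's union support (taxa present in at least one of the two samples).
    Zero-variance vectors yield undefined correlations, recorded as NaN with
    a warning.
    """
    merged = merge_tables(tables) if len(tables) > 1 else tables[0]
    ids = merged.samples
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    x = merged.values
    n = len(ids)
    # each pair is correlated over its union support: a taxon absent from
    # both samples says nothing about their agreement, and including it
    # would let unrelated studies' taxa inflate r through the zero fill
    present = x > 0
    r = np.ones((n, n))
    warned = False
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(n):
            for j in range(i + 1, n):
                mask = present[:, i] | present[:, j]
                xi, xj = x[mask, i], x[mask, j]
                if mask.sum() < 2 or xi.std() == 0 or xj.std() == 0:
                    r[i, j] = r[j, i] = np.nan
                    if not warned:
                        warnings.warn(
                            f"zero-variance sample vector in pair "
                            f"({ids[i]!r}, {ids[j]!r}); correlation NaN"
                        )
                        warned = True
                    continue
                r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    clamped = np.clip(r, -CLAMP, CLAMP)
    z = np.arctanh(clamped)
    return CorrelationMatrix(ids=ids, r=r, z=z)


def group_correlation_summary(
    corr: CorrelationMatrix,
    meta: list[SampleMeta],
    test_method: str = "anova_tukey",
) -> GroupCorrelationSummary:
    """Category means of correlations and the omnibus test on Fisher z.

    Categories: human_human, human_mouse, mouse_mouse, each unordered
    off-diagonal pair counted once.  Means are reported on untransformed r;
    the group comparison (default one-way ANOVA + Tukey HSD) runs on z,
    where the sampling distribution is approximately normal.  Ids may be
    sample ids or replicate-group ids (resolved through the metadata).
    Within- and cross-study means of r are reported alongside.
    """
    from hma_fidelity.beta import compare_groups

    by_col: dict[str, SampleMeta] = {}
    for m in meta:
        by_col.setdefault(m.sample_id, m)
        if m.host == "mouse" and m.replicate_group:
            by_col.setdefault(m.replicate_group, m)
    missing = [i for i in corr.ids if i not in by_col]
    if missing:
        raise ValueError(f"ids absent from metadata: {missing}")

    r_by_cat: dict[str, list[float]] = {}
    z_by_cat: dict[str, list[float]] = {}
    r_within: dict[str, list[float]] = {}
    r_cross: dict[str, list[float]] = {}
    n = len(corr.ids)
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = by_col[corr.ids[i]], by_col[corr.ids[j]]
            cat = "_".join(sorted([mi.host, mj.host]))
            cat = {"human_human": "human_human",
                   "human_mouse": "human_mouse",
                   "mouse_mouse": "mouse_mouse"}[cat]
            rij, zij = float(corr.r[i, j]), float(corr.z[i, j])
            if np.isnan(rij):
                continue
            r_by_cat.setdefault(cat, []).append(rij)
            z_by_cat.setdefault(cat, []).append(zij)
            scope = r_within if mi.study_id == mj.study_id else r_cross
            scope.setdefault(cat, []).append(rij)

    if len(r_by_cat) < 2:
        raise ValueError("need at least two populated categories")
    testable = {k: v for k, v in z_by_cat.items() if len(v) >= 2}
    test = compare_groups(testable, method=test_method) if len(testable) >= 2 else None
    return GroupCorrelationSummary(
        mean_r={k: float(np.mean(v)) for k, v in r_by_cat.items()},
        mean_z={k: float(np.mean(v)) for k, v in z_by_cat.items()},
        mean_r_within_study={k: float(np.mean(v)) for k, v in r_within.items()},
        mean_r_cross_study={k: float(np.mean(v)) for k, v in r_cross.items()},
        test=test,
    )
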