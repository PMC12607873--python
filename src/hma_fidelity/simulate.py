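"""Synthetic donor/recipient cohorts with a parametric host filter.

The generator emulates the statistical structure of a humanized-mouse
(HMA) experiment:

* **Donor communities** — per-taxon log-normal abundances with per-taxon
  occupancy, giving diverse human stool profiles.
* **Host filter** — each taxon a donor carries engrafts in that donor's
  mouse lineage with a taxon-specific probability, drawn *once per
  donor-taxon*: mice gavaged from one stool are technical replicates of a
  single colonization event, not independent trials.
* **Mouse fitness** — engrafted taxa are multiplied by a taxon-specific
  fitness factor shared by all mice (the murine gut favors the same taxa in
  every animal), plus per-mouse log-normal replicate noise.
* **Consortium spike-in** — a defined taxon list dosed into a community at a
  fixed total percentage, emulating administration of a cultured bacterial
  consortium between the T0 and T2 timepoints.

All randomness flows through explicit seeds; a cohort regenerates
byte-identically from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from hma_fidelity.tables import PairingMap, SampleMeta, TaxonTable, renormalize

# occupancy probability is a logistic function of the log-abundance location:
# abundant taxa are also prevalent ones
PREV_MU0 = -1.0
PREV_SCALE = 1.5

#: genera of a 30-strain therapeutic consortium, collapsed to genus rank;
#: the first five are consistently strong engrafters, the rest weak
CONSORTIUM_GENERA_HIGH = [
    "Lachnoclostridium", "Flavonifractor", "Alistipes", "Akkermansia",
    "Parabacteroides",
]
CONSORTIUM_GENERA_LOW = [
    "Collinsella", "Enterococcus", "Bifidobacterium", "Anaerostipes",
    "Faecalibacterium", "Lactobacillus",
]


@dataclass
class SyntheticTruth:
    """Hidden parameters of a synthetic cohort, kept for recovery tests."""

    engraftment_prob: pd.Series   # per-taxon colonization probability
    mouse_fitness: pd.Series      # per-taxon multiplicative factor in mice
    mu: pd.Series                 # per-taxon log-abundance location (donors)
    sigma: pd.Series              # per-taxon log-abundance scale (donors)
    noise_sd: float               # log-scale replicate noise between cage mates
    consortium_taxa: list[str]
    seed: int
    prevalence_override: pd.Series | None = None

    def __post_init__(self) -> None:
        taxa = self.mu.index
        for name, s in (("engraftment_prob", self.engraftment_prob),
                        ("mouse_fitness", self.mouse_fitness),
                        ("sigma", self.sigma)):
            if not s.index.equals(taxa):
                raise ValueError(f"{name} index does not match mu index")
        if ((self.engraftment_prob < 0) | (self.engraftment_prob > 1)).any():
            raise ValueError("engraftment probabilities must lie in [0, 1]")
        if (self.mouse_fitness < 0).any():
            raise ValueError("mouse fitness factors must be >= 0")
        missing = set(self.consortium_taxa) - set(taxa)
        if missing:
            raise ValueError(f"consortium taxa outside the pool: {sorted(missing)}")

    @property
    def taxon_pool(self) -> list[str]:
        return list(self.mu.index)

    @property
    def prevalence(self) -> pd.Series:
        """Per-taxon occupancy probability, derived from mu unless overridden."""
        derived = pd.Series(
            expit((self.mu.to_numpy(dtype=float) - PREV_MU0) / PREV_SCALE),
            index=self.mu.index,
        )
        if self.prevalence_override is not None:
            derived = self.prevalence_override.combine_first(derived)
        return derived.clip(0.0, 1.0)


def default_truth(n_taxa: int = 100, seed: int = 0, noise_sd: float = 0.3) -> SyntheticTruth:
    """Study-like default scenario.

    20 host-adapted "core" taxa: abundant and stable in donors, high
    engraftment probability (0.9), with a shared fitness reshaping in mice.
    A consortium of 11 genera with mixed engraftment.  The remaining taxa
    form the variable human flora: patchy occupancy, high between-donor
    variance, and a weak (5%) chance of crossing the host filter.
    """
    consortium = CONSORTIUM_GENERA_HIGH + CONSORTIUM_GENERA_LOW
    n_core = 20
    n_var = n_taxa - n_core - len(consortium)
    if n_var < 1:
        raise ValueError(f"n_taxa must exceed {n_core + len(consortium)}")
    rng = np.random.default_rng(seed)
    taxa = (
        [f"core_{i + 1:02d}" for i in range(n_core)]
        + consortium
        + [f"var_{i + 1:03d}" for i in range(n_var)]
    )
    mu = np.concatenate([
        rng.normal(2.0, 0.8, n_core),
        rng.normal(-1.0, 0.8, len(consortium)),
        rng.normal(-0.5, 1.0, n_var),
    ])
    sigma = np.concatenate([
        np.full(n_core, 0.6),
        np.full(len(consortium), 1.0),
        np.full(n_var, 1.8),
    ])
    prob = np.concatenate([
        np.full(n_core, 0.9),
        np.full(len(CONSORTIUM_GENERA_HIGH), 0.9),
        np.full(len(CONSORTIUM_GENERA_LOW), 0.3),
        np.full(n_var, 0.05),
    ])
    fitness = np.where(
        prob > 0.1, np.exp(rng.normal(0.0, 1.0, n_taxa)), 1.0
    )
    idx = pd.Index(taxa, name="taxon")
    return SyntheticTruth(
        engraftment_prob=pd.Series(prob, index=idx),
        mouse_fitness=pd.Series(fitness, index=idx),
        mu=pd.Series(mu, index=idx),
        sigma=pd.Series(sigma, index=idx),
        noise_sd=noise_sd,
        consortium_taxa=consortium,
        seed=seed,
    )


#: strong-filter scenario shape: a 20-taxon host-adapted core that dominates
#: human stool (log-location N(2.2, 1.2), within-population scale 0.5),
#: engrafts with probability 0.95 under a mild common fitness reshaping
#: (log-normal, sd 0.35), against a structureless variable flora
#: (log-location spread 1.2 between populations, scale 1.8 within) that
#: crosses the host filter with probability 0.02.
_SF_N_SHARED = 20
_SF_CORE_MU = (2.2, 1.2)
_SF_CORE_SIGMA = 0.5
_SF_CORE_PROB = 0.95
_SF_FITNESS_SD = 0.35
_SF_VAR_MU = (0.0, 1.2)
_SF_VAR_SIGMA = 1.8
_SF_VAR_PROB = 0.02


def _strong_filter_core(seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng([seed, 11])
    mu = rng.normal(*_SF_CORE_MU, _SF_N_SHARED)
    fitness = np.exp(rng.normal(0.0, _SF_FITNESS_SD, _SF_N_SHARED))
    return mu, fitness


def _strong_filter_truth_from_core(
    core_mu: np.ndarray,
    core_fitness: np.ndarray,
    n_taxa: int,
    seed: int,
    variable_rng: np.random.Generator,
    noise_sd: float,
) -> SyntheticTruth:
    n_shared = len(core_mu)
    n_var = n_taxa - n_shared
    if n_var < 1:
        raise ValueError(f"n_taxa must exceed {n_shared}")
    taxa = [f"shared_{i + 1:02d}" for i in range(n_shared)] + [
        f"var_{i + 1:03d}" for i in range(n_var)
    ]
    idx = pd.Index(taxa, name="taxon")
    mu = np.concatenate([core_mu, variable_rng.normal(*_SF_VAR_MU, n_var)])
    sigma = np.concatenate(
        [np.full(n_shared, _SF_CORE_SIGMA), np.full(n_var, _SF_VAR_SIGMA)]
    )
    prob = np.concatenate(
        [np.full(n_shared, _SF_CORE_PROB), np.full(n_var, _SF_VAR_PROB)]
    )
    fitness = np.concatenate([core_fitness, np.ones(n_var)])
    prevalence = pd.Series(
        np.concatenate([np.ones(n_shared), np.full(n_var, np.nan)]), index=idx
    ).dropna()
    return SyntheticTruth(
        engraftment_prob=pd.Series(prob, index=idx),
        mouse_fitness=pd.Series(fitness, index=idx),
        mu=pd.Series(mu, index=idx),
        sigma=pd.Series(sigma, index=idx),
        noise_sd=noise_sd,
        consortium_taxa=taxa[:5],
        seed=seed,
        prevalence_override=prevalence,
    )


def strong_filter_truth(n_taxa: int = 100, seed: int = 0, noise_sd: float = 0.2) -> SyntheticTruth:
    """Strong shared host filter scenario.

    A core of 20 universally carried, human-dominant taxa engrafts with
    probability 0.95 under a mild fitness reshaping common to all mice;
    everything else is variable human flora that crosses the filter with
    probability 0.02.  Mice from any donor therefore converge on the same
    murine-adapted community while donors stay diverse.
    """
    core_mu, core_fitness = _strong_filter_core(seed)
    return _strong_filter_truth_from_core(
        core_mu, core_fitness, n_taxa, seed,
        np.random.default_rng([seed, 13]), noise_sd,
    )


def _as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def generate_donor_panel(
    truth: SyntheticTruth,
    n_donors: int,
    timepoint: str = "T0",
    study_id: str = "synthetic",
    donor_prefix: str = "D",
    rng=None,
) -> tuple[TaxonTable, list[SampleMeta]]:
    """Draw diverse donor stool profiles.

    Per donor and taxon: occupancy ~ Bernoulli(prevalence), abundance
    ``exp(Normal(mu, sigma))`` for occupied taxa, then renormalization to
    percent.  A donor drawing an empty community (possible only under
    extreme parameters) is given its single most prevalent taxon so the
    column stays normalizable.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    prevalence = truth.prevalence.to_numpy(dtype=float)
    if not (prevalence > 0).any():
        raise ValueError("degenerate truth: all occupancy probabilities are zero")
    rng = _as_rng(truth.seed if rng is None else rng)
    n_taxa = len(truth.taxon_pool)
    mu = truth.mu.to_numpy(dtype=float)
    sigma = truth.sigma.to_numpy(dtype=float)

    cols = {}
    meta = []
    for i in range(n_donors):
        donor_id = f"{donor_prefix}{i + 1:02d}"
        occupied = rng.random(n_taxa) < prevalence
        abundance = np.exp(rng.normal(mu, np.maximum(sigma, 0.0)))
        column = np.where(occupied, abundance, 0.0)
        if column.sum() == 0:
            column[int(np.argmax(prevalence))] = 1.0
        sample_id = f"{donor_id}_{timepoint}"
        cols[sample_id] = column
        meta.append(SampleMeta(
            sample_id=sample_id, host="human", donor_id=donor_id,
            timepoint=timepoint, study_id=study_id, route="none",
            replicate_group="",
        ))
    table = TaxonTable(
        pd.DataFrame(cols, index=pd.Index(truth.taxon_pool, name="taxon")),
        rank="genus",
    )
    return renormalize(table), meta


def apply_host_filter(
    donors: TaxonTable,
    truth: SyntheticTruth,
    n_mice_per_donor: int,
    donor_meta: list[SampleMeta],
    route: str = "none",
    rng=None,
) -> tuple[TaxonTable, list[SampleMeta], PairingMap]:
    """Seed replicate mice from each donor column through the host filter.

    Engraftment of each donor-carried taxon is drawn once per donor (shared
    by the replicate mice); the engrafted abundance per mouse is the donor RA
    times the taxon's mouse fitness times log-normal replicate noise, then
    renormalized.
    """
    if n_mice_per_donor < 1:
        raise ValueError("n_mice_per_donor must be >= 1")
    rng = _as_rng(truth.seed + 1 if rng is None else rng)
    by_id = {m.sample_id: m for m in donor_meta}
    missing = [s for s in donors.samples if s not in by_id]
    if missing:
        raise ValueError(f"donor columns without metadata: {missing}")

    prob = truth.engraftment_prob.reindex(donors.data.index).fillna(0.0).to_numpy()
    fitness = truth.mouse_fitness.reindex(donors.data.index).fillna(1.0).to_numpy()

    cols = {}
    meta = []
    pairs = []
    members: dict[str, set[str]] = {}
    for donor_sample in donors.samples:
        dm = by_id[donor_sample]
        donor_ra = donors.data[donor_sample].to_numpy(dtype=float)
        carried = donor_ra > 0
        engrafts = carried & (rng.random(len(donor_ra)) < prob)
        if not engrafts.any():
            engrafts[int(np.argmax(donor_ra))] = True
        group = f"{dm.donor_id}_{dm.timepoint}_mice"
        members[group] = set()
        pairs.append((donor_sample, group))
        for j in range(n_mice_per_donor):
            noise = np.exp(rng.normal(0.0, truth.noise_sd, len(donor_ra)))
            column = np.where(engrafts, donor_ra * fitness * noise, 0.0)
            sample_id = f"{dm.donor_id}_{dm.timepoint}_m{j + 1}"
            cols[sample_id] = column
            members[group].add(sample_id)
            meta.append(SampleMeta(
                sample_id=sample_id, host="mouse", donor_id=dm.donor_id,
                timepoint=dm.timepoint, study_id=dm.study_id, route=route,
                replicate_group=group,
            ))
    table = TaxonTable(pd.DataFrame(cols, index=donors.data.index), rank=donors.rank)
    return renormalize(table), meta, PairingMap(pairs, members)


def spike_consortium(
    table: TaxonTable,
    truth: SyntheticTruth,
    dose_percent: float,
) -> TaxonTable:
    """Dose the consortium into every sample at a fixed total percentage.

    The existing community is scaled to ``100 - dose_percent`` and the dose
    is split across consortium taxa in fixed proportions (their relative
    donor-location weights), so each output column still sums to 100 and the
    consortium occupies exactly ``dose_percent`` plus whatever scaled-down
    abundance it already had.
    """
    if not truth.consortium_taxa:
        raise ValueError("truth has an empty consortium")
    if not 0 < dose_percent < 100:
        raise ValueError("dose_percent must lie strictly between 0 and 100")
    data = table.data.copy()
    for taxon in truth.consortium_taxa:
        if taxon not in data.index:
            data.loc[taxon] = 0.0
    weights = np.exp(truth.mu.loc[truth.consortium_taxa].to_numpy(dtype=float))
    weights = weights / weights.sum()
    scaled = renormalize(TaxonTable(data, rank=table.rank)).data * (
        (100.0 - dose_percent) / 100.0
    )
    add = pd.Series(dose_percent * weights, index=truth.consortium_taxa)
    scaled.loc[truth.consortium_taxa] = scaled.loc[truth.consortium_taxa].add(
        add, axis=0
    )
    return TaxonTable(scaled, rank=table.rank)


@dataclass
class Cohort:
    """A complete synthetic dataset: abundances, metadata, pairing, truth."""

    table: TaxonTable
    meta: list[SampleMeta]
    pairing: PairingMap
    truth: SyntheticTruth
    design: str
    manifest: dict = field(default_factory=dict)


def generate_cohort(
    truth: SyntheticTruth,
    n_donors: int = 6,
    n_mice: int = 3,
    design: str = "HTR",
    dose_percent: float = 5.0,
    seed: int | None = None,
    study_id: str = "synthetic",
    donor_prefix: str = "D",
) -> Cohort:
    """Generate a paired-timepoint donor/recipient cohort.

    HTR (human-treated route): donors sampled at T0, the T2 donor profile is
    the T0 profile spiked with the consortium, and separate mouse lineages
    are seeded from each timepoint's stool.  MTR (mouse-treated route): mice
    are seeded from the T0 donor stool and the T2 mouse profile is each T0
    mouse spiked directly.
    """
    if design not in ("HTR", "MTR"):
        raise ValueError(f"unknown design {design!r}; expected 'HTR' or 'MTR'")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    donors_t0, meta_h0 = generate_donor_panel(
        truth, n_donors, timepoint="T0", study_id=study_id,
        donor_prefix=donor_prefix, rng=rng,
    )
    tables = [donors_t0.data]
    meta = list(meta_h0)
    pairs: list[tuple[str, str]] = []
    members: dict[str, set[str]] = {}

    if design == "HTR":
        donors_t2 = spike_consortium(donors_t0, truth, dose_percent)
        rename = {s: s.replace("_T0", "_T2") for s in donors_t2.samples}
        donors_t2 = TaxonTable(
            donors_t2.data.rename(columns=rename), rank=donors_t2.rank
        )
        meta_h2 = [
            SampleMeta(
                sample_id=rename[m.sample_id], host="human", donor_id=m.donor_id,
                timepoint="T2", study_id=study_id, route="none", replicate_group="",
            )
            for m in meta_h0
        ]
        mice_t0, meta_m0, pairing_t0 = apply_host_filter(
            donors_t0, truth, n_mice, meta_h0, route="HTR", rng=rng
        )
        mice_t2, meta_m2, pairing_t2 = apply_host_filter(
            donors_t2, truth, n_mice, meta_h2, route="HTR", rng=rng
        )
        tables += [donors_t2.data, mice_t0.data, mice_t2.data]
        meta += meta_h2 + meta_m0 + meta_m2
        pairs = pairing_t0.pairs + pairing_t2.pairs
        members = {**pairing_t0.recipient_group_members,
                   **pairing_t2.recipient_group_members}
    else:  # MTR
        mice_t0, meta_m0, pairing_t0 = apply_host_filter(
            donors_t0, truth, n_mice, meta_h0, route="MTR", rng=rng
        )
        mice_t2 = spike_consortium(mice_t0, truth, dose_percent)
        rename = {s: s.replace("_T0_", "_T2_") for s in mice_t2.samples}
        mice_t2 = TaxonTable(mice_t2.data.rename(columns=rename), rank=mice_t2.rank)
        meta_m2 = [
            SampleMeta(
                sample_id=rename[m.sample_id], host="mouse", donor_id=m.donor_id,
                timepoint="T2", study_id=study_id, route="MTR",
                replicate_group=m.replicate_group.replace("_T0_", "_T2_"),
            )
            for m in meta_m0
        ]
        tables += [mice_t0.data, mice_t2.data]
        meta += meta_m0 + meta_m2
        pairs = list(pairing_t0.pairs)
        members = dict(pairing_t0.recipient_group_members)
        for (donor_sample, group) in pairing_t0.pairs:
            g2 = group.replace("_T0_", "_T2_")
            pairs.append((donor_sample, g2))
            members[g2] = {rename[s] for s in pairing_t0.recipient_group_members[group]}

    # consortium taxa may be added to some tables by the spike; align rows
    union = pd.concat(tables, axis=1).fillna(0.0)
    table = renormalize(TaxonTable(union, rank=donors_t0.rank))
    manifest = {
        "seed": int(seed),
        "design": design,
        "n_donors": int(n_donors),
        "n_mice_per_donor": int(n_mice),
        "dose_percent": float(dose_percent),
        "n_taxa": len(truth.taxon_pool),
        "study_id": study_id,
    }
    return Cohort(table=table, meta=meta, pairing=PairingMap(pairs, members),
                  truth=truth, design=design, manifest=manifest)


@dataclass
class MultiStudyCohort:
    """Several study cohorts sharing one host filter, merged for mega-analysis.

    The murine host filter (core taxa, engraftment probabilities, fitness) is
    identical across studies — it is a property of the recipient physiology —
    while each study's human population carries its own variable flora.
    """

    table: TaxonTable
    meta: list[SampleMeta]
    pairing: PairingMap
    truths: dict[str, SyntheticTruth]
    cohorts: dict[str, Cohort]
    manifest: dict = field(default_factory=dict)


def generate_multi_study(
    seed: int,
    n_studies: int = 4,
    n_donors: int = 6,
    n_mice: int = 3,
    n_taxa: int = 100,
    design: str = "HTR",
    dose_percent: float = 5.0,
    noise_sd: float = 0.2,
) -> MultiStudyCohort:
    """Strong-filter cohorts from several human populations.

    Each study draws its own variable human flora around the shared
    host-adapted core, emulating a mega-analysis across unrelated
    human cohorts whose recipient mice share a gut physiology.  Donor ids
    are prefixed per study (``S1D01`` ...), so merged tables, metadata and
    pairing stay collision-free.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    core_mu, core_fitness = _strong_filter_core(seed)
    tables = []
    meta: list[SampleMeta] = []
    pairs: list[tuple[str, str]] = []
    members: dict[str, set[str]] = {}
    truths: dict[str, SyntheticTruth] = {}
    cohorts: dict[str, Cohort] = {}
    for k in range(n_studies):
        study_id = f"S{k + 1}"
        truth = _strong_filter_truth_from_core(
            core_mu, core_fitness, n_taxa, seed,
            np.random.default_rng([seed, k, 7]), noise_sd,
        )
        cohort = generate_cohort(
            truth, n_donors=n_donors, n_mice=n_mice, design=design,
            dose_percent=dose_percent,
            seed=(seed * 1000003 + k + 1) % 2**31,
            study_id=study_id, donor_prefix=f"{study_id}D",
        )
        tables.append(cohort.table.data)
        meta += cohort.meta
        pairs += cohort.pairing.pairs
        members.update(cohort.pairing.recipient_group_members)
        truths[study_id] = truth
        cohorts[study_id] = cohort
    merged = renormalize(
        TaxonTable(pd.concat(tables, axis=1).fillna(0.0), rank="genus")
    )
    manifest = {
        "seed": int(seed),
        "n_studies": int(n_studies),
        "n_donors": int(n_donors),
        "n_mice_per_donor": int(n_mice),
        "design": design,
        "n_taxa": int(n_taxa),
    }
    return MultiStudyCohort(
        table=merged, meta=meta, pairing=PairingMap(pairs, members),
        truths=truths, cohorts=cohorts, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Truth sidecar IO
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, tsv_path, manifest_path=None, manifest: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "engraftment_prob": truth.engraftment_prob,
            "mouse_fitness": truth.mouse_fitness,
            "mu": truth.mu,
            "sigma": truth.sigma,
            "is_consortium": [t in set(truth.consortium_taxa) for t in truth.taxon_pool],
        }
    )
    df.index.name = "taxon"
    df.to_csv(tsv_path, sep="\t", float_format="%.12g")
    if manifest_path is not None:
        payload = {"seed": truth.seed, "noise_sd": truth.noise_sd}
        payload.update(manifest or {})
        with open(manifest_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_truth(tsv_path, seed: int, noise_sd: float) -> SyntheticTruth:
    df = pd.read_csv(tsv_path, sep="\t", index_col="taxon")
    return SyntheticTruth(
        engraftment_prob=df["engraftment_prob"],
        mouse_fitness=df["mouse_fitness"],
        mu=df["mu"],
        sigma=df["sigma"],
        noise_sd=noise_sd,
        consortium_taxa=df.index[df["is_consortium"]].tolist(),
        seed=seed,
    )
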