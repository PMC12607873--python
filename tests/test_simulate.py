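import json

import numpy as np
import pandas as pd
import pytest

from hma_fidelity.beta import bray_curtis, extract_group_dissimilarities
from hma_fidelity.engraftment import percent_engraftment, presence_matrix
from hma_fidelity.preprocess import average_replicates
from hma_fidelity.simulate import (
    SyntheticTruth,
    apply_host_filter,
    default_truth,
    generate_cohort,
    generate_donor_panel,
    generate_multi_study,
    load_truth,
    spike_consortium,
    strong_filter_truth,
    write_truth,
)


def flat_truth(n_taxa=10, prob=1.0, fitness=1.0, mu=2.0, sigma=0.0,
               noise_sd=0.0, seed=0, prevalence=1.0):
    idx = pd.Index([f"t{i:02d}" for i in range(n_taxa)], name="taxon")
    return SyntheticTruth(
        engraftment_prob=pd.Series(prob, index=idx, dtype=float),
        mouse_fitness=pd.Series(fitness, index=idx, dtype=float),
        mu=pd.Series(mu, index=idx, dtype=float),
        sigma=pd.Series(sigma, index=idx, dtype=float),
        noise_sd=noise_sd,
        consortium_taxa=[f"t{i:02d}" for i in range(3)],
        seed=seed,
        prevalence_override=pd.Series(prevalence, index=idx, dtype=float),
    )


class TestDonorPanel:
    def test_same_seed_identical(self):
        truth = default_truth(seed=3)
        t1, _ = generate_donor_panel(truth, 5)
        t2, _ = generate_donor_panel(truth, 5)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_noise_free_limit_identical_donors(self):
        truth = flat_truth(sigma=0.0, prevalence=1.0)
        table, _ = generate_donor_panel(truth, 4)
        np.testing.assert_allclose(
            table.values - table.values[:, :1], 0.0, atol=1e-9
        )

    def test_columns_sum_to_100(self):
        table, meta = generate_donor_panel(default_truth(seed=1), 6)
        np.testing.assert_allclose(table.values.sum(axis=0), 100.0, atol=1e-9)
        assert all(m.host == "human" for m in meta)

    def test_degenerate_truth_rejected(self):
        truth = flat_truth(prevalence=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            generate_donor_panel(truth, 2)


class TestHostFilter:
    def test_transparent_host_limit(self):
        truth = flat_truth(prob=1.0, fitness=1.0, sigma=0.3, noise_sd=0.0, seed=5)
        donors, meta = generate_donor_panel(truth, 3)
        mice, mmeta, pairing = apply_host_filter(donors, truth, 2, meta)
        for donor, group in pairing.pairs:
            for m in pairing.recipient_group_members[group]:
                np.testing.assert_allclose(
                    mice.data[m], donors.data[donor], atol=1e-9
                )
        # consequently donor-recipient dissimilarity is 0 and engraftment 100%
        avg = average_replicates(
            pd.concat([donors.data, mice.data], axis=1).pipe(
                lambda df: type(donors)(df, rank=donors.rank)
            ),
            meta + mmeta,
        )
        dist = bray_curtis(avg)
        grouped = extract_group_dissimilarities(dist, meta + mmeta, pairing)
        assert max(grouped.categories["donor_paired_recipient"]) < 1e-9
        etable = percent_engraftment(
            presence_matrix(type(donors)(
                pd.concat([donors.data, mice.data], axis=1), rank=donors.rank
            )), pairing,
        )
        assert (etable["percent_engraftment"] == 100.0).all()

    def test_extreme_filter_restricts_support(self):
        truth = flat_truth(n_taxa=30, prob=0.0, sigma=0.5, seed=2)
        truth.engraftment_prob.iloc[:5] = 1.0
        truth.mouse_fitness.iloc[:5] = 10.0
        donors, meta = generate_donor_panel(truth, 4)
        mice, _, _ = apply_host_filter(donors, truth, 3, meta)
        support = (mice.values > 0).any(axis=1)
        assert support[5:].sum() == 0

    def test_engraftment_draw_shared_by_cage_mates(self):
        truth = flat_truth(prob=0.5, sigma=0.5, noise_sd=0.1, seed=7)
        donors, meta = generate_donor_panel(truth, 5)
        mice, _, pairing = apply_host_filter(donors, truth, 4, meta)
        for _, group in pairing.pairs:
            members = sorted(pairing.recipient_group_members[group])
            presence = mice.data[members] > 0
            # a taxon engrafts in all cage mates or in none
            assert (presence.nunique(axis=1) == 1).all()

    def test_empirical_engraftment_frequency(self):
        truth = flat_truth(prob=0.7, sigma=0.5, seed=11)
        donors, meta = generate_donor_panel(truth, 200)
        mice, _, pairing = apply_host_filter(donors, truth, 1, meta)
        etable = percent_engraftment(
            presence_matrix(type(donors)(
                pd.concat([donors.data, mice.data], axis=1), rank=donors.rank
            )), pairing,
        )
        est = etable["percent_engraftment"].mean() / 100
        assert abs(est - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 200)


class TestSpikeConsortium:
    def test_small_dose_is_near_identity(self):
        truth = flat_truth(sigma=0.5, seed=1)
        donors, _ = generate_donor_panel(truth, 3)
        spiked = spike_consortium(donors, truth, 1e-9)
        np.testing.assert_allclose(spiked.values, donors.values, atol=1e-6)

    def test_dose_on_consortium_free_table(self):
        truth = flat_truth(n_taxa=6, sigma=0.5, seed=3)
        donors, _ = generate_donor_panel(truth, 2)
        # zero out the consortium rows and renormalize by hand
        data = donors.data.copy()
        data.loc[truth.consortium_taxa] = 0.0
        data = data * (100.0 / data.sum())
        table = type(donors)(data, rank=donors.rank)
        spiked = spike_consortium(table, truth, 50.0)
        consortium_share = spiked.data.loc[truth.consortium_taxa].sum()
        np.testing.assert_allclose(consortium_share, 50.0, atol=1e-9)
        np.testing.assert_allclose(spiked.values.sum(axis=0), 100.0, atol=1e-9)

    def test_dose_bounds_enforced(self):
        truth = flat_truth()
        donors, _ = generate_donor_panel(truth, 1)
        for dose in (0.0, 100.0, -1.0):
            with pytest.raises(ValueError):
                spike_consortium(donors, truth, dose)


class TestGenerateCohort:
    def test_htr_design_counts(self):
        cohort = generate_cohort(default_truth(seed=4), n_donors=6, n_mice=3)
        humans = [m for m in cohort.meta if m.host == "human"]
        groups = {m.replicate_group for m in cohort.meta if m.host == "mouse"}
        assert len(humans) == 12  # 6 donors x 2 timepoints
        assert len(groups) == 12
        assert len(cohort.pairing.pairs) == 12
        avg = average_replicates(cohort.table, cohort.meta)
        assert len(avg.samples) == 24

    def test_mtr_design_pairs_t2_mice_to_t0_donor(self):
        cohort = generate_cohort(default_truth(seed=4), n_donors=3, n_mice=2,
                                 design="MTR")
        donors = {d for d, _ in cohort.pairing.pairs}
        assert all(d.endswith("_T0") for d in donors)
        t2_groups = [g for _, g in cohort.pairing.pairs if "_T2_" in g]
        assert len(t2_groups) == 3

    def test_same_seed_reproducible(self):
        c1 = generate_cohort(default_truth(seed=9), n_donors=3, n_mice=2)
        c2 = generate_cohort(default_truth(seed=9), n_donors=3, n_mice=2)
        pd.testing.assert_frame_equal(c1.table.data, c2.table.data)
        assert c1.pairing.pairs == c2.pairing.pairs

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            generate_cohort(default_truth(seed=0), design="XXX")


class TestTruthSidecar:
    def test_round_trip(self, tmp_path):
        truth = strong_filter_truth(seed=8)
        tsv, manifest = tmp_path / "truth.tsv", tmp_path / "manifest.json"
        write_truth(truth, tsv, manifest, {"design": "HTR"})
        back = load_truth(tsv, seed=8, noise_sd=truth.noise_sd)
        pd.testing.assert_series_equal(
            back.engraftment_prob, truth.engraftment_prob, check_names=False
        )
        pd.testing.assert_series_equal(
            back.mouse_fitness, truth.mouse_fitness, check_names=False
        )
        assert back.consortium_taxa == truth.consortium_taxa
        assert json.loads(manifest.read_text())["design"] == "HTR"


class TestMultiStudy:
    def test_structure_and_uniqueness(self):
        ms = generate_multi_study(seed=2, n_studies=3, n_donors=4, n_mice=2)
        assert len(ms.truths) == 3
        samples = ms.table.samples
        assert len(samples) == len(set(samples))
        studies = {m.study_id for m in ms.meta}
        assert studies == {"S1", "S2", "S3"}
        assert len(ms.pairing.pairs) == 3 * 4 * 2  # studies x donors x timepoints
        np.testing.assert_allclose(ms.table.values.sum(axis=0), 100.0, atol=1e-9)

    def test_core_shared_variable_flora_differs(self):
        ms = generate_multi_study(seed=5, n_studies=2, n_donors=2, n_mice=1)
        t1, t2 = ms.truths["S1"], ms.truths["S2"]
        shared = [t for t in t1.taxon_pool if t.startswith("shared_")]
        variable = [t for t in t1.taxon_pool if t.startswith("var_")]
        pd.testing.assert_series_equal(t1.mu[shared], t2.mu[shared])
        pd.testing.assert_series_equal(t1.mouse_fitness[shared], t2.mouse_fitness[shared])
        assert not np.allclose(t1.mu[variable], t2.mu[variable])
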