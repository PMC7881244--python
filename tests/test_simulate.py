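import numpy as np
import pandas as pd
import pytest

from tmesig.signature import differential_expression
from tmesig.simulate import (
    simulate_abundance_table,
    simulate_bulk_cohort,
    simulate_linear_mixtures,
    simulate_response_cohort,
    simulate_sorted_populations,
)
from tmesig.survival import kruskal_wallis, logrank_test


class TestSortedPopulations:
    def test_same_seed_identical_distinct_seeds_differ(self):
        m1, _ = simulate_sorted_populations(n_genes=100, seed=3)
        m2, _ = simulate_sorted_populations(n_genes=100, seed=3)
        m3, _ = simulate_sorted_populations(n_genes=100, seed=4)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert not np.array_equal(m1.values, m3.values)

    def test_markers_have_planted_lfc_by_construction(self):
        mx, truth = simulate_sorted_populations(
            n_genes=200, effect_lfc=2.0, noise_sd=0.3, seed=1
        )
        labels = truth.population_labels
        for pop, markers in truth.marker_genes.items():
            own = mx.data.loc[sorted(markers), np.asarray(labels == pop)].mean(axis=1)
            other = mx.data.loc[sorted(markers), np.asarray(labels != pop)].mean(axis=1)
            # empirical means fluctuate around the planted |logFC| = 2
            assert np.all((own - other) > 1.5)

    def test_marker_overflow_rejected(self):
        with pytest.raises(ValueError, match="markers"):
            simulate_sorted_populations(n_genes=50, n_markers_per_pop=20, n_populations=3)

    def test_null_effect_gives_nominal_de_rate(self):
        # effect_lfc=0: DE at p<0.05 flags about 5% of genes (20 seeds)
        rates = []
        for seed in range(20):
            mx, truth = simulate_sorted_populations(
                n_populations=2, n_genes=400, effect_lfc=0.0, seed=seed
            )
            de = differential_expression(
                mx, truth.population_labels, "pop1", "pop2"
            )
            rates.append((de["p_value"] < 0.05).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02


class TestResponseCohort:
    def test_default_sizes_match_study_cohort(self):
        mx, truth = simulate_response_cohort(n_genes=50, n_signal_genes=10, seed=0)
        counts = truth.response_labels.value_counts()
        assert counts["responder"] == 9 and counts["nonresponder"] == 12

    def test_no_signal_genes_gives_empty_truth(self):
        _, truth = simulate_response_cohort(n_genes=50, n_signal_genes=0, seed=0)
        assert truth.marker_genes["response_signal"] == set()

    def test_planted_signs_recovered_by_de_direction(self):
        mx, truth = simulate_response_cohort(
            n_genes=400, n_signal_genes=40, effect_lfc=2.0, noise_sd=0.3, seed=2
        )
        de = differential_expression(
            mx, truth.response_labels, "responder", "nonresponder"
        ).set_index("gene_id")
        agree = [
            np.sign(de.loc[g, "log_fc"]) == s for g, s in truth.signal_signs.items()
        ]
        assert np.mean(agree) >= 0.95


class TestBulkCohort:
    def test_fractions_lie_on_the_simplex(self):
        _, _, truth = simulate_bulk_cohort(n_samples=40, n_genes=300, seed=0)
        F = truth.mixing_fractions.to_numpy()
        assert (F >= 0).all()
        np.testing.assert_allclose(F.sum(axis=1), 1.0, atol=1e-9)

    def test_determinism_and_annotation_consistency(self):
        m1, a1, t1 = simulate_bulk_cohort(n_samples=30, n_genes=300, seed=9)
        m2, a2, t2 = simulate_bulk_cohort(n_samples=30, n_genes=300, seed=9)
        np.testing.assert_array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(a1.table, a2.table)
        assert list(t1.subtype_labels) == list(t2.subtype_labels)

    def test_null_hazards_give_nominal_logrank_rate(self):
        # all subtype log-hazards zero: log-rank across planted subtypes
        # rejects at about the nominal 5% level (50 seeds)
        rej = 0
        for seed in range(50):
            _, ann, truth = simulate_bulk_cohort(
                k_subtypes=3, n_samples=90, n_genes=60, n_cell_types=2,
                markers_per_cell_type=10, signature_genes_per_subtype=5,
                seed=seed,
            )
            _, _, p = logrank_test(
                ann.column("time"), ann.column("event"), truth.subtype_labels
            )
            rej += p < 0.05
        assert abs(rej / 50 - 0.05) <= 0.07  # 2% band + binomial noise at 50 reps

    def test_inconsistent_spec_dimensions_rejected(self):
        with pytest.raises(ValueError, match="dirichlet_alpha"):
            simulate_bulk_cohort(
                k_subtypes=3, n_samples=10, n_genes=300,
                dirichlet_alpha=[[1.0, 1.0]], seed=0,
            )
        with pytest.raises(ValueError, match="per subtype"):
            simulate_bulk_cohort(
                k_subtypes=3, n_samples=10, n_genes=300,
                subtype_log_hazard=[0.0], seed=0,
            )


class TestLinearMixtures:
    def test_noiseless_mixture_is_exact_product(self):
        profiles = pd.DataFrame(
            [[10.0, 0.0], [0.0, 10.0], [5.0, 5.0]],
            index=["g1", "g2", "g3"], columns=["ct1", "ct2"],
        )
        bulk, fracs = simulate_linear_mixtures(profiles, n_samples=5, seed=1)
        np.testing.assert_allclose(
            bulk.to_numpy(), profiles.to_numpy() @ fracs.to_numpy().T, atol=1e-12
        )


class TestAbundanceTable:
    def test_columns_sum_to_one(self):
        labels = pd.Series([1, 1, 2, 2, 3, 3], index=[f"s{i}" for i in range(6)])
        tab, _ = simulate_abundance_table(20, labels, effect=2.0, seed=0)
        np.testing.assert_allclose(tab.sum(axis=0).to_numpy(), 1.0, atol=1e-9)

    def test_null_effect_gives_nominal_kw_rate(self):
        rates = []
        for seed in range(10):
            labels = pd.Series(np.repeat([1, 2, 3], 20))
            tab, _ = simulate_abundance_table(60, labels, effect=1.0, seed=seed)
            ps = [kruskal_wallis(tab.loc[t].to_numpy(), labels)[1] for t in tab.index]
            rates.append(np.mean(np.array(ps) < 0.05))
        assert abs(np.mean(rates) - 0.05) < 0.03

    def test_strong_effect_recovered_with_high_power(self):
        labels = pd.Series(np.repeat([1, 2, 3], 30))
        tab, enriched = simulate_abundance_table(40, labels, effect=4.0, seed=5)
        target = set().union(*enriched.values())
        hits = {
            t for t in tab.index
            if kruskal_wallis(tab.loc[t].to_numpy(), labels)[1] < 0.05
        }
        assert len(hits & target) / len(target) >= 0.9
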