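"""Generator contracts: determinism, planted correlations, planted hubs."""
import numpy as np
import pandas as pd
import pytest

from coexseed.datatypes import GROUP_SMA_I
from coexseed.ontology import term_kappa
from coexseed.qpcr import ddct_fold_change
from coexseed.seednet import rank_hubs
from coexseed.synthetic import (
    ConfigurationError,
    StudyConfig,
    generate_gene_sets,
    generate_interaction_network,
    generate_multi_platform_study,
    generate_qpcr_table,
)


class TestStudyGenerator:
    def test_same_seed_is_bit_identical(self):
        cfg = StudyConfig(n_genes=60, module_sizes=(15, 10), samples_per_group=4, seed=3)
        d1, t1 = generate_multi_platform_study(cfg)
        d2, t2 = generate_multi_platform_study(cfg)
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_series_equal(t1.module_of, t2.module_of)

    def test_probe_count_without_duplicates(self):
        cfg = StudyConfig(
            n_genes=80,
            module_sizes=(20,),
            samples_per_group=3,
            duplicate_probe_fraction=0.0,
            unannotated_fraction=0.0,
            seed=0,
        )
        datasets, _ = generate_multi_platform_study(cfg)
        assert all(d.values.shape[0] == 80 for d in datasets)

    def test_duplicate_and_unannotated_fractions(self):
        cfg = StudyConfig(
            n_genes=200,
            module_sizes=(30,),
            samples_per_group=3,
            duplicate_probe_fraction=0.2,
            unannotated_fraction=0.1,
            seed=1,
        )
        datasets, truth = generate_multi_platform_study(cfg)
        assert datasets[0].values.shape[0] == 200 + 40
        assert len(truth.annotated_genes) == 200 - 20
        assert len(truth.duplicated_genes) == 40

    def test_within_module_correlation_matches_target(self):
        cfg = StudyConfig(
            n_platforms=1,
            n_genes=80,
            module_sizes=(40,),
            module_trait_effect=0.0,
            within_module_cor=0.8,
            noise_sd=0.2,
            samples_per_group=60,
            duplicate_probe_fraction=0.0,
            unannotated_fraction=0.0,
            seed=5,
        )
        datasets, truth = generate_multi_platform_study(cfg)
        members = truth.module_of[truth.module_of == 1].index
        probes = [f"P{int(g[1:]):05d}" for g in members]
        C = np.corrcoef(datasets[0].values.loc[probes].to_numpy())
        mean_r = C[np.triu_indices_from(C, 1)].mean()
        assert 0.7 <= mean_r <= 0.9

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyConfig(n_genes=10, module_sizes=(8, 8))

    def test_trait_effect_is_monotone_in_module_trait_correlation(self):
        """The 95th percentile of null module-trait |r| over many seeds
        stays below the correlation produced by a planted effect."""
        from coexseed.membership import module_eigengene, module_trait_correlation
        from coexseed.datatypes import SEVERITY, ModuleAssignment

        def trait_abs_r(effect, seed):
            cfg = StudyConfig(
                n_platforms=1,
                n_genes=60,
                module_sizes=(20,),
                module_trait_effect=effect,
                n_trait_modules=1,
                samples_per_group=25,
                duplicate_probe_fraction=0.0,
                unannotated_fraction=0.0,
                seed=seed,
            )
            datasets, truth = generate_multi_platform_study(cfg)
            d = datasets[0]
            values = d.values.copy()
            values.index = d.annotation["symbol"]
            assignment = ModuleAssignment(truth.module_of)
            mes = module_eigengene(values, assignment)
            trait = d.groups.map(SEVERITY).astype(float)
            stats = module_trait_correlation(mes, trait)
            return float(stats.loc[stats["module"] == 1, "abs_r"].iloc[0])

        null = [trait_abs_r(0.0, s) for s in range(100)]
        planted = [trait_abs_r(1.0, s) for s in range(20)]
        assert np.quantile(null, 0.95) < np.mean(planted)


class TestGeneSets:
    def test_zero_overlap_terms_are_disjoint(self):
        universe = [f"g{i}" for i in range(200)]
        coll = generate_gene_sets(8, (10, 20), universe, overlap_level=0.0, seed=0)
        seen = set()
        for members in coll.terms.values():
            assert not (seen & members)
            seen |= members

    def test_full_coverage_annotates_every_gene(self):
        from coexseed.ontology import annotation_filter

        universe = [f"g{i}" for i in range(100)]
        coll = generate_gene_sets(6, (10, 25), universe, coverage=1.0, seed=2)
        assert annotation_filter(universe, coll) == universe

    def test_partial_coverage_count(self):
        from coexseed.ontology import annotation_filter

        universe = [f"g{i}" for i in range(200)]
        coll = generate_gene_sets(8, (10, 25), universe, coverage=0.7, seed=3)
        assert len(annotation_filter(universe, coll)) == 140

    def test_shared_members_give_positive_kappa(self):
        universe = [f"g{i}" for i in range(100)]
        a = frozenset(universe[:20])
        b = frozenset(universe[10:30])  # shares half of each
        assert term_kappa(a, b, universe) > 0

    def test_oversized_term_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gene_sets(3, (5, 50), [f"g{i}" for i in range(10)])

    def test_must_cover_guarantee(self):
        universe = [f"g{i}" for i in range(100)]
        vips = ["g90", "g91", "g92"]
        coll = generate_gene_sets(
            5, (5, 10), universe, coverage=0.3, seed=4, must_cover=vips
        )
        assert set(vips) <= coll.covered_genes()


class TestInteractionNetwork:
    def test_planted_hub_is_top_ranked(self):
        G, truth = generate_interaction_network(80, [30], seed=0)
        (top, deg), = rank_hubs(G, 1)
        assert top == truth["hubs"][0]
        assert deg == 30

    def test_unsigned_network_is_all_activation(self):
        G, _ = generate_interaction_network(40, [10], signed=False, seed=1)
        assert {d["sign"] for _, _, d in G.edges(data=True)} == {"activation"}

    def test_same_seed_same_edges(self):
        G1, _ = generate_interaction_network(50, [12, 15], seed=9)
        G2, _ = generate_interaction_network(50, [12, 15], seed=9)
        assert sorted(G1.edges(data="sign")) == sorted(G2.edges(data="sign"))

    def test_background_degrees_stay_low(self):
        G, truth = generate_interaction_network(100, [25, 25], seed=2)
        hub_set = set(truth["hubs"])
        background_max = max(d for v, d in G.degree() if v not in hub_set)
        assert background_max < 25


class TestCtGenerator:
    @pytest.mark.parametrize("fc", [1.0, 2.0])
    def test_noise_free_fold_change_is_exact(self, fc):
        ct = generate_qpcr_table(["gX"], {"gX": fc}, n_replicates=3, ct_noise_sd=0.0, seed=0)
        res = ddct_fold_change(ct, "gX")
        assert res.mean_fc == pytest.approx(fc, abs=1e-12)

    def test_noisy_fold_change_recovered_within_three_se(self):
        fcs = []
        for seed in range(30):
            ct = generate_qpcr_table(
                ["gX"], {"gX": 1.5}, n_replicates=5, ct_noise_sd=0.1, seed=seed
            )
            fcs.append(ddct_fold_change(ct, "gX").mean_fc)
        se = np.std(fcs, ddof=1) / np.sqrt(len(fcs))
        assert abs(np.mean(fcs) - 1.5) < 3 * se + 0.02  # small lognormal bias allowed

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_qpcr_table(["gX"], {"gX": 1.0}, n_replicates=1)
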