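"""Ground-truth generators: exact planted structure and reproducibility."""

import numpy as np
import pytest

from neurosim import InputError, SimConfig, generate_bundle, merge_catalogs
from neurosim.io_model import DiseaseGeneCatalog
from neurosim.synthetic_data import (gen_disease_catalog, gen_expression,
                                     gen_marker_catalog, gen_mutation_tables,
                                     gen_phenotype_scores)
from neurosim.region_expression import region_high_sets


class TestDiseaseCatalog:
    def test_planted_overlap_realized_exactly(self):
        cfg = SimConfig(seed=1, n_diseases=3, universe_size=60,
                        genes_per_disease=10,
                        planted_overlaps=[(0, 1, 5)])
        cat, truth = gen_disease_catalog(cfg)
        s = cat.gene_sets
        assert len(s["disease_00"] & s["disease_01"]) == 5
        assert len(s["disease_00"] & s["disease_02"]) == 0
        assert len(s["disease_01"] & s["disease_02"]) == 0
        assert all(len(v) == 10 for v in s.values())
        assert truth["overlaps"] == {("disease_00", "disease_01"): 5}

    def test_empty_overlap_list_gives_disjoint_sets(self):
        cfg = SimConfig(seed=2, n_diseases=4, universe_size=100,
                        genes_per_disease=10, planted_overlaps=[])
        cat, _ = gen_disease_catalog(cfg)
        sets = list(cat.gene_sets.values())
        for i in range(4):
            for j in range(i + 1, 4):
                assert not sets[i] & sets[j]

    def test_none_overlaps_draw_independently(self):
        cfg = SimConfig(seed=3, n_diseases=2, universe_size=50,
                        genes_per_disease=30, planted_overlaps=None)
        cat, truth = gen_disease_catalog(cfg)
        a, b = cat.gene_sets.values()
        # pigeonhole: two 30-sets from 50 genes must intersect
        assert len(a & b) >= 10
        assert truth["overlaps"] is None

    def test_infeasible_overlap_names_the_pair(self):
        cfg_kwargs = dict(seed=1, n_diseases=2, universe_size=60,
                          genes_per_disease=5)
        with pytest.raises(InputError, match=r"\(0, 1\)"):
            gen_disease_catalog(SimConfig(planted_overlaps=[(0, 1, 9)],
                                          **cfg_kwargs))

    def test_oversubscribed_disease_is_error(self):
        cfg = SimConfig(seed=1, n_diseases=3, universe_size=200,
                        genes_per_disease=10,
                        planted_overlaps=[(0, 1, 7), (0, 2, 7)])
        with pytest.raises(InputError, match="disease 0"):
            gen_disease_catalog(cfg)

    def test_default_config_is_paper_scale(self):
        cfg = SimConfig(seed=0)
        cat, truth = gen_disease_catalog(cfg)
        assert len(cat.diseases) == 20
        assert len(cat.universe) == 424
        for (a, b), o in truth["overlaps"].items():
            assert len(cat.gene_sets[a] & cat.gene_sets[b]) == o


class TestMarkerCatalog:
    def test_fraction_one_plants_whole_disease_set(self):
        cfg = SimConfig(seed=4, n_diseases=2, universe_size=100,
                        genes_per_disease=8, planted_overlaps=[],
                        n_contexts=3, markers_per_context=15,
                        planted_enrichment=[(0, 1, 1.0)])
        cat, _ = gen_disease_catalog(cfg)
        markers, truth = gen_marker_catalog(cfg, cat)
        assert cat.gene_sets["disease_00"] <= markers.marker_sets["ctx_01"]
        assert truth["planted"] == [("disease_00", "ctx_01", 8)]

    def test_default_25_contexts_filled_to_size(self):
        cfg = SimConfig(seed=5)
        cat, _ = gen_disease_catalog(cfg)
        markers, _ = gen_marker_catalog(cfg, cat)
        assert len(markers.contexts) == 25
        assert all(len(markers.marker_sets[c]) == 30 for c in markers.contexts)
        assert markers.background == frozenset().union(*markers.marker_sets.values())

    def test_infeasible_fraction_is_error(self):
        cfg = SimConfig(seed=4, n_diseases=2, universe_size=100,
                        genes_per_disease=50, planted_overlaps=[],
                        n_contexts=2, markers_per_context=10,
                        planted_enrichment=[(0, 0, 1.0)])
        cat, _ = gen_disease_catalog(cfg)
        with pytest.raises(InputError, match="markers"):
            gen_marker_catalog(cfg, cat)


class TestExpression:
    def test_planted_fold_recovered_through_region_calls(self):
        cfg = SimConfig(seed=6, n_genes_expr=300, noise_sd=0.1)
        study, truth = gen_expression(cfg)
        high = region_high_sets(study)
        want = {}
        for g, r, _ in truth["effects"]:
            want.setdefault(r, set()).add(g)
        assert {r: set(high.marker_sets[r]) for r in study.regions} == \
            {r: want.get(r, set()) for r in study.regions}

    def test_zero_noise_no_effect_flags_nothing(self):
        cfg = SimConfig(seed=7, n_genes_expr=50, noise_sd=0.0, region_effects=[])
        study, _ = gen_expression(cfg)
        high = region_high_sets(study)
        assert all(not s for s in high.marker_sets.values())

    def test_subthreshold_fold_not_flagged(self):
        cfg = SimConfig(seed=8, n_genes_expr=100, noise_sd=0.05,
                        region_effects=[(0, 0, 0.5)])
        study, _ = gen_expression(cfg)
        high = region_high_sets(study)
        assert study.genes[0] not in high.marker_sets["region_00"]


class TestPhenotypeScores:
    def test_zero_noise_scores_equal_scaled_proportion(self):
        cfg = SimConfig(seed=9, n_diseases=4, universe_size=100,
                        genes_per_disease=10, planted_overlaps=[(0, 1, 5)],
                        dmn_slope=1.0, dmn_noise_sd=0.0)
        cat, _ = gen_disease_catalog(cfg)
        table = gen_phenotype_scores(cfg, cat)
        assert table.scores("disease_00", "disease_01") == [pytest.approx(0.5)]
        assert table.scores("disease_02", "disease_03") == [pytest.approx(0.0)]

    def test_zero_slope_decouples_scores_from_similarity(self):
        # correlation of score with planted proportion centred on zero
        coefs = []
        for r in range(30):
            cfg = SimConfig(seed=40_000 + r, dmn_slope=0.0, dmn_noise_sd=0.01)
            cat, truth = gen_disease_catalog(cfg)
            table = gen_phenotype_scores(cfg, cat)
            props, scores = [], []
            for (a, b), o in truth["overlaps"].items():
                props.append(o / 20)
                scores.append(table.scores(a, b)[0])
            coefs.append(np.corrcoef(props, scores)[0, 1])
        assert abs(np.nanmean(coefs)) < 0.15

    def test_duplicate_matchings_average_to_the_planted_value(self):
        cfg = SimConfig(seed=10, n_diseases=3, universe_size=60,
                        genes_per_disease=10, planted_overlaps=[(0, 1, 4)],
                        dmn_slope=1.0, dmn_noise_sd=0.0, n_matchings=2)
        cat, _ = gen_disease_catalog(cfg)
        table = gen_phenotype_scores(cfg, cat)
        assert table.scores("disease_00", "disease_01") == [0.4, 0.4]


class TestMutationTables:
    def test_merged_records_reproduce_catalog_gene_sets(self):
        cfg = SimConfig(seed=11, n_diseases=5, universe_size=80,
                        genes_per_disease=8, planted_overlaps=[(0, 1, 3)])
        cat, _ = gen_disease_catalog(cfg)
        curated, clinvar = gen_mutation_tables(cfg, cat)
        merged, summary = merge_catalogs(curated, clinvar)
        rebuilt = DiseaseGeneCatalog.from_records(merged)
        assert {d: set(s) for d, s in rebuilt.gene_sets.items()} == \
            {d: set(s) for d, s in cat.gene_sets.items()}

    def test_default_scale_merge_has_shared_variants_and_mutation_overlap(self):
        cfg = SimConfig(seed=11)
        cat, _ = gen_disease_catalog(cfg)
        curated, clinvar = gen_mutation_tables(cfg, cat)
        _, summary = merge_catalogs(curated, clinvar)
        assert summary.n_mut_shared > 0
        # genes shared between diseases carry partially shared variants
        mut_cat = DiseaseGeneCatalog.from_records(curated, level="mutation")
        overlaps = [len(mut_cat.gene_sets["disease_00"]
                        & mut_cat.gene_sets["disease_01"])]
        assert max(overlaps) > 0


class TestReproducibility:
    def test_identical_config_gives_identical_bundle(self):
        cfg_a = SimConfig(seed=123, n_genes_expr=100)
        cfg_b = SimConfig(seed=123, n_genes_expr=100)
        b1, b2 = generate_bundle(cfg_a), generate_bundle(cfg_b)
        assert b1["catalog"].gene_sets == b2["catalog"].gene_sets
        assert b1["curated"] == b2["curated"]
        assert b1["clinvar"] == b2["clinvar"]
        assert b1["markers"].marker_sets == b2["markers"].marker_sets
        assert np.array_equal(b1["expression"].values, b2["expression"].values)
        assert b1["phenotype"].entries == b2["phenotype"].entries

    def test_substreams_are_independent_of_call_order(self):
        cfg = SimConfig(seed=77, n_genes_expr=100)
        study_first, _ = gen_expression(cfg)
        cat, _ = gen_disease_catalog(cfg)
        study_second, _ = gen_expression(cfg)
        assert np.array_equal(study_first.values, study_second.values)
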