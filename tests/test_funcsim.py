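import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gofunsim import (
    ICTable,
    SimilarityEngine,
    SyntheticSpec,
    direct_funcsim,
    enumerate_measures,
    funcsim,
    measure_by_label,
    pairwise_funcsim,
    random_annotations,
    random_dag,
    similarity_matrix,
)
from gofunsim.funcsim import FuncSimError

TOL = 1e-4


class TestPairwiseAggregation:
    MATRIX = [[0.8], [0.4]]  # T_p = {t1, t2} vs T_q = {u1}

    def test_avg_and_max(self):
        assert pairwise_funcsim(self.MATRIX, "avg") == pytest.approx(0.6)
        assert pairwise_funcsim(self.MATRIX, "max") == pytest.approx(0.8)

    def test_abm(self):
        # row maxima 0.8, 0.4; column maximum 0.8 -> (0.8+0.4+0.8)/3
        assert pairwise_funcsim(self.MATRIX, "abm") == pytest.approx(0.66667, abs=TOL)

    def test_bma(self):
        assert pairwise_funcsim(self.MATRIX, "bma") == pytest.approx(0.7)

    def test_empty_matrix_rejected(self):
        with pytest.raises(FuncSimError):
            pairwise_funcsim(np.zeros((0, 2)), "avg")

    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            elements=st.floats(0, 1),
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_ordering_invariants(self, m):
        avg = pairwise_funcsim(m, "avg")
        mx = pairwise_funcsim(m, "max")
        abm = pairwise_funcsim(m, "abm")
        bma = pairwise_funcsim(m, "bma")
        assert mx + 1e-9 >= abm >= avg - 1e-9
        assert mx + 1e-9 >= bma
        if m.shape[0] == m.shape[1]:
            assert abm == pytest.approx(bma)


class TestDirectMeasures:
    @pytest.mark.parametrize(
        "measure,expected",
        [
            ("simgic", 0.21799),
            ("simdic", 0.35794),
            ("simuic", 0.21799),
            ("simui", 0.5),
        ],
    )
    def test_p1_p3_values(self, f1_ann, f1_ic, measure, expected):
        score = direct_funcsim(
            f1_ann.extended["p1"], f1_ann.extended["p3"], f1_ic, measure
        )
        assert score == pytest.approx(expected, abs=TOL)

    def test_self_similarity_is_one(self, f1_ann, f1_ic):
        ext = f1_ann.extended["p1"]
        for measure in ("simgic", "simdic", "simuic", "simui"):
            assert direct_funcsim(ext, ext, f1_ic, measure) == pytest.approx(1.0)

    def test_all_zero_ic_defined_as_zero(self):
        zeros = ICTable("zhang", {"R": 0.0, "A": 0.0})
        a, b = frozenset({"R"}), frozenset({"R", "A"})
        assert direct_funcsim(a, b, zeros, "simgic") == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_simui_equals_simgic_under_all_ones_ic(self, seed):
        spec = SyntheticSpec(n_terms=25, n_proteins=20, seed=seed)
        dag = random_dag(spec)
        ann, _ = random_annotations(dag, spec)
        ones = ICTable("zhang", {t: 1.0 for t in dag.terms})
        proteins = ann.proteins[:8]
        for i in range(len(proteins)):
            for j in range(i + 1, len(proteins)):
                a = ann.extended[proteins[i]]
                b = ann.extended[proteins[j]]
                assert direct_funcsim(a, b, None, "simui") == pytest.approx(
                    direct_funcsim(a, b, ones, "simgic")
                )


class TestMeasureGrid:
    def test_exactly_57_unique_labels(self):
        configs = enumerate_measures()
        assert len(configs) == 57
        assert len({c.label for c in configs}) == 57

    def test_expected_labels_present(self):
        labels = {c.label for c in enumerate_measures()}
        assert {"XRBMA", "ZGIC", "WAvg", "UUIC", "SimUI", "SAvg", "LiABM"} <= labels

    def test_simui_has_no_family(self):
        simui = measure_by_label("SimUI")
        assert simui.family is None and not simui.is_pairwise

    def test_pairwise_vs_direct_partition(self):
        configs = enumerate_measures()
        pairwise = [c for c in configs if c.is_pairwise]
        direct = [c for c in configs if not c.is_pairwise]
        assert len(pairwise) == 44 and len(direct) == 13
        assert all(c.termsim_model for c in pairwise)
        assert all(c.termsim_model is None for c in direct)

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(FuncSimError, match="XRBMA"):
            measure_by_label("BOGUS")


class TestFuncsim:
    def test_ravg_on_singleton_sets(self, f1_dag, f1_ann, f1_ic):
        # p1 direct {C}, p3 direct {B}: 1x1 matrix, resnik(C,B) = IC(B)
        score = funcsim(
            f1_ann, "p1", "p3", measure_by_label("RAvg"), f1_dag, ic=f1_ic
        )
        assert score == pytest.approx(0.51083, abs=TOL)

    def test_agic_is_annotation_simgic(self, f1_dag, f1_ann, f1_ic):
        config = measure_by_label("AGIC")
        assert config.family == "annotation" and config.functional == "simgic"
        score = funcsim(f1_ann, "p1", "p3", config, f1_dag, ic=f1_ic)
        assert score == pytest.approx(0.21799, abs=TOL)

    def test_unannotated_protein_raises(self, f1_dag, f1_ann, f1_ic):
        from gofunsim.annotation import AnnotationError

        with pytest.raises(AnnotationError, match="ghost"):
            funcsim(f1_ann, "p1", "ghost", measure_by_label("AGIC"), f1_dag, f1_ic)

    def test_engine_symmetry_and_identity_across_grid(self, f1_dag, f1_ann):
        engine = SimilarityEngine(f1_dag, f1_ann)
        for config in enumerate_measures():
            ab = engine.score("p1", "p5", config)
            ba = engine.score("p5", "p1", config)
            assert ab == pytest.approx(ba)
            if config.normalized:
                assert 0.0 <= ab <= 1.0 + 1e-12
            self_score = engine.score("p4", "p4", config)
            if config.self_identity:
                assert self_score == pytest.approx(1.0)
            elif config.normalized:
                assert self_score <= 1.0 + 1e-12

    def test_similarity_matrix_symmetric_unit_diagonal(self, f1_dag, f1_ann):
        proteins = ["p1", "p3", "p5"]
        df = similarity_matrix(proteins, measure_by_label("AGIC"), f1_dag, f1_ann)
        m = df.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)

    def test_extended_termset_option(self, f1_dag, f1_ann):
        engine = SimilarityEngine(f1_dag, f1_ann, termset="extended")
        direct_engine = SimilarityEngine(f1_dag, f1_ann)
        cfg = measure_by_label("LAvg")
        # extended sets include shared ancestors, raising the average
        assert engine.score("p1", "p3", cfg) != pytest.approx(
            direct_engine.score("p1", "p3", cfg)
        )
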