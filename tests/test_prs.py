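"""PRS evaluation against a naive double-loop oracle, weight-file round
trips, and the structural templates."""

import numpy as np
import pytest

from nnprs.prs import (
    GenotypeMatrix,
    InteractionTerm,
    PRSDefinition,
    PRSParseError,
    evaluate_prs,
    load_prs_definition,
    make_template_prs,
    read_genotypes,
    template_block_snps,
    write_genotypes,
    write_prs_definition,
)


def _prs_oracle(values, prs):
    """Score every sample with explicit loops."""
    out = []
    for row in values:
        s = prs.intercept
        for i, w in enumerate(prs.additive_weights):
            s += w * row[i]
        for t in prs.interactions:
            ga, gb = row[t.index_a], row[t.index_b]
            if t.mode == "product":
                s += t.weight * ga * gb
            elif round(ga) == t.required_state_a and round(gb) == t.required_state_b:
                s += t.weight
        out.append(s)
    return np.array(out)


def _geno(values, snp_ids=None):
    values = np.asarray(values, dtype=float)
    ids = snp_ids or [f"s{i}" for i in range(values.shape[1])]
    return GenotypeMatrix(values=values, snp_ids=ids, effect_alleles=["A"] * len(ids))


class TestEvaluatePrs:
    def test_all_zero_genotypes_score_zero(self):
        prs = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.array([1.0, 2.0]))
        assert evaluate_prs(_geno(np.zeros((4, 2))), prs).tolist() == [0.0] * 4

    def test_hand_weighted_sum(self):
        prs = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.array([1.0, 2.0]))
        assert evaluate_prs(_geno([[1.0, 2.0]]), prs)[0] == pytest.approx(5.0)

    def test_state_indicator_enumeration(self):
        """Brute force over all 9 genotype pairs: only (1,1) earns the weight."""
        term = InteractionTerm(0, 1, "state_indicator", 3.0, 1, 1)
        prs = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.zeros(2), [term])
        grid = np.array([[a, b] for a in (0, 1, 2) for b in (0, 1, 2)], dtype=float)
        scores = evaluate_prs(_geno(grid), prs)
        expected = [3.0 if (a, b) == (1, 1) else 0.0 for a in (0, 1, 2) for b in (0, 1, 2)]
        assert scores.tolist() == expected

    def test_matches_double_loop_oracle(self, rng):
        for trial in range(10):
            prs = PRSDefinition(
                "p", [f"s{i}" for i in range(5)], list("ACGTA"),
                rng.normal(size=5),
                [
                    InteractionTerm(0, 3, "product", rng.normal()),
                    InteractionTerm(1, 4, "state_indicator", rng.normal(), 2, 1),
                ],
                intercept=float(rng.normal()),
            )
            g = _geno(rng.integers(0, 3, size=(5, 5)).astype(float))
            np.testing.assert_allclose(
                evaluate_prs(g, prs), _prs_oracle(g.values, prs), atol=1e-12
            )

    def test_column_permutation_invariance(self, rng):
        prs = make_template_prs("T1D10-like", seed=1)
        values = rng.integers(0, 3, size=(20, 10)).astype(float)
        g = GenotypeMatrix(values=values, snp_ids=list(prs.snp_ids),
                           effect_alleles=list(prs.effect_alleles))
        perm = rng.permutation(10)
        g_perm = GenotypeMatrix(values=values[:, perm],
                                snp_ids=[prs.snp_ids[i] for i in perm],
                                effect_alleles=[prs.effect_alleles[i] for i in perm])
        np.testing.assert_allclose(evaluate_prs(g, prs), evaluate_prs(g_perm, prs))

    def test_fractional_dosage_rounds_for_indicator(self):
        term = InteractionTerm(0, 1, "state_indicator", 5.0, 1, 2)
        prs = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.zeros(2), [term])
        scores = evaluate_prs(_geno([[0.9, 1.8], [0.4, 1.8]]), prs)
        assert scores.tolist() == [5.0, 0.0]

    def test_missing_snp_raises_with_name(self):
        prs = PRSDefinition("p", ["s0", "absent"], ["A", "C"], np.ones(2))
        with pytest.raises(KeyError, match="absent"):
            evaluate_prs(_geno(np.zeros((1, 2)), ["s0", "other"]), prs)

    def test_out_of_range_genotype_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            _geno([[3.0, 0.0]])

    def test_removing_indicator_changes_only_firing_samples(self):
        term = InteractionTerm(0, 1, "state_indicator", 2.0, 1, 1)
        prs = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.array([0.5, 0.5]), [term])
        bare = PRSDefinition("p", ["s0", "s1"], ["A", "C"], np.array([0.5, 0.5]))
        g = _geno([[1, 1], [1, 2], [0, 0], [1, 1]])
        diff = evaluate_prs(g, prs) - evaluate_prs(g, bare)
        assert diff.tolist() == [2.0, 0.0, 0.0, 2.0]


class TestWeightFiles:
    def test_roundtrip_67_snps_with_interactions(self, tmp_path):
        prs = make_template_prs("T1D67-like", seed=5)
        assert len(prs.interactions) == 10
        path = tmp_path / "t1d67.prs"
        write_prs_definition(prs, path)
        back = load_prs_definition(path)
        assert back.snp_ids == prs.snp_ids
        assert back.effect_alleles == prs.effect_alleles
        np.testing.assert_array_equal(back.additive_weights, prs.additive_weights)
        assert back.interactions == prs.interactions
        assert back.intercept == prs.intercept

    def test_unknown_snp_in_interaction_errors_with_line(self, tmp_path):
        path = tmp_path / "bad.prs"
        path.write_text("#bad\nA\ts0\tA\t1.0\nA\ts1\tC\t1.0\nI\ts0\tzz\tproduct\t.\t.\t2.0\n")
        with pytest.raises(PRSParseError, match=r":4.*zz"):
            load_prs_definition(path)

    def test_bad_mode_and_state_rejected(self, tmp_path):
        path = tmp_path / "bad2.prs"
        path.write_text("A\ts0\tA\t1.0\nA\ts1\tC\t1.0\nI\ts0\ts1\tmagic\t.\t.\t2.0\n")
        with pytest.raises(PRSParseError, match="magic"):
            load_prs_definition(path)
        path.write_text("A\ts0\tA\t1.0\nA\ts1\tC\t1.0\nI\ts0\ts1\tstate_indicator\t7\t1\t2.0\n")
        with pytest.raises(PRSParseError):
            load_prs_definition(path)

    def test_purely_additive_file_matches_dot_product(self, tmp_path, rng):
        prs = PRSDefinition("add", ["a", "b", "c"], list("ACG"), np.array([0.1, 0.2, 0.3]))
        path = tmp_path / "add.prs"
        write_prs_definition(prs, path)
        back = load_prs_definition(path)
        g = rng.integers(0, 3, size=(6, 3)).astype(float)
        np.testing.assert_allclose(
            evaluate_prs(_geno(g, ["a", "b", "c"]), back), g @ prs.additive_weights
        )


class TestTemplates:
    @pytest.mark.parametrize(
        "name,n_snps,n_terms",
        [("T1D10-like", 10, 1), ("T1D30-like", 30, 1),
         ("T1D67-like", 67, 10), ("CD42-like", 42, 6)],
    )
    def test_structure(self, name, n_snps, n_terms):
        prs = make_template_prs(name, seed=0)
        assert prs.n_snps == n_snps
        assert len(prs.interactions) == n_terms
        block = template_block_snps(name)
        block_idx = {prs.snp_ids.index(s) for s in block}
        for t in prs.interactions:
            assert t.mode == "state_indicator"
            assert {t.index_a, t.index_b} <= block_idx

    def test_same_seed_identical_different_seed_not(self):
        a, b = make_template_prs("CD42-like", 9), make_template_prs("CD42-like", 9)
        assert a.interactions == b.interactions
        np.testing.assert_array_equal(a.additive_weights, b.additive_weights)
        c = make_template_prs("CD42-like", 10)
        assert not np.array_equal(a.additive_weights, c.additive_weights)

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="unknown template"):
            make_template_prs("T2D99-like", 0)


class TestGenotypeIO:
    def test_delimited_roundtrip_with_missing(self, tmp_path):
        values = np.array([[0.0, 1.0], [2.0, 0.0]])
        mask = np.array([[False, False], [False, True]])
        g = GenotypeMatrix(values=values, snp_ids=["s0", "s1"],
                           effect_alleles=["A", "C"], missing_mask=mask)
        path = tmp_path / "g.tsv"
        write_genotypes(g, path)
        back = read_genotypes(path)
        np.testing.assert_array_equal(back.values, values * ~mask)
        np.testing.assert_array_equal(back.missing_mask, mask)
        assert back.snp_ids == ["s0", "s1"]

    def test_plink_raw_layout(self, tmp_path):
        path = tmp_path / "g.raw"
        path.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_C\n"
            "f1 i1 0 0 1 -9 2 NA\n"
            "f2 i2 0 0 2 -9 0 1\n"
        )
        g = read_genotypes(path)
        assert g.snp_ids == ["rs1", "rs2"]
        assert g.effect_alleles == ["A", "C"]
        np.testing.assert_array_equal(g.values, [[2.0, 0.0], [0.0, 1.0]])
        assert g.missing_mask[0, 1] and not g.missing_mask[0, 0]
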