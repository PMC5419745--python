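import numpy as np
import pytest
from scipy.linalg import expm

from idpevo import phylo_asr as pa
from idpevo import synthetic_data as sd

from conftest import (
    balanced_newick,
    brute_force_marginal,
    brute_force_site_likelihood,
)


class TestAlignmentHygiene:
    def test_mask_below_threshold(self):
        aln = pa.Alignment(["a", "b"], ["PE", "QE"], confidence=[0.9, 0.4])
        out = pa.mask_low_confidence(aln, 0.5)
        assert out.rows == ["PX", "QX"]

    def test_mask_threshold_zero_is_identity(self):
        aln = pa.Alignment(["a", "b"], ["PE", "QE"], confidence=[0.9, 0.4])
        out = pa.mask_low_confidence(aln, 0.0)
        assert out.rows == aln.rows

    def test_mask_strict_less_than(self):
        aln = pa.Alignment(["a"], ["PEW"], confidence=[0.49, 0.5, 0.51])
        out = pa.mask_low_confidence(aln, 0.5)
        assert out.rows == ["XEW"]

    def test_mask_leaves_gaps_untouched(self):
        aln = pa.Alignment(["a", "b"], ["P-", "Q-"], confidence=[0.1, 0.1])
        out = pa.mask_low_confidence(aln, 0.5)
        assert out.rows == ["X-", "X-"]

    def test_mask_requires_confidence(self):
        aln = pa.Alignment(["a"], ["PE"])
        with pytest.raises(ValueError, match="confidence"):
            pa.mask_low_confidence(aln, 0.5)

    def test_strip_removes_95pct_gap_column(self):
        rows = ["A" + "A" for _ in range(1)] + ["-A" for _ in range(19)]
        aln = pa.Alignment([f"s{i}" for i in range(20)], rows)
        out, cmap = pa.strip_gappy_columns(aln, 0.95)
        assert out.n_cols == 1 and list(cmap) == [1]

    def test_strip_no_gaps_identity(self):
        aln = pa.Alignment(["a", "b"], ["PEW", "QEW"])
        out, cmap = pa.strip_gappy_columns(aln, 0.95)
        assert out.rows == aln.rows
        assert list(cmap) == [0, 1, 2]

    def test_strip_counts_fractions(self):
        # columns with 2/4, 3/4, 4/4 gaps: only the all-gap column removed
        rows = ["AA-", "A--", "---", "---"]
        aln = pa.Alignment(["a", "b", "c", "d"], rows)
        out, cmap = pa.strip_gappy_columns(aln, 0.95)
        assert out.n_cols == 2 and list(cmap) == [0, 1]

    def test_strip_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            pa.strip_gappy_columns(pa.Alignment([], []), 0.95)

    def test_fasta_roundtrip(self, tmp_path):
        aln = pa.Alignment(["a", "b"], ["PE-X", "QEWW"])
        aln.to_fasta(tmp_path / "x.fasta")
        back = pa.Alignment.from_fasta(tmp_path / "x.fasta")
        assert back.ids == aln.ids and back.rows == aln.rows


class TestRateMatrix:
    def test_uniform_model_equal_offdiagonals(self):
        Q = pa.build_rate_matrix(pa.SubstitutionModel.poisson())
        off = Q[~np.eye(20, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_row_sums_zero_and_unit_rate(self, jtt_model):
        Q = pa.build_rate_matrix(jtt_model)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert np.isclose(-np.dot(jtt_model.frequencies, np.diag(Q)), 1.0)

    def test_uniform_model_closed_form_transition(self):
        # equal-rates model: P_ii(t) = 1/20 + (19/20) exp(-20 t / 19)
        model = pa.SubstitutionModel.poisson()
        kern = pa.TransitionKernel(model)
        for t in (0.0, 0.1, 0.7, 2.0):
            P = kern.probability_matrix(t)
            expected = 1.0 / 20 + (19.0 / 20) * np.exp(-20.0 * t / 19.0)
            assert np.allclose(np.diag(P), expected, atol=1e-12)

    def test_kernel_matches_expm(self, jtt_model):
        Q = pa.build_rate_matrix(jtt_model)
        kern = pa.TransitionKernel(jtt_model)
        assert np.allclose(kern.probability_matrix(0.37), expm(0.37 * Q), atol=1e-10)

    def test_asymmetric_exchangeabilities_rejected(self):
        S = np.ones((20, 20))
        S[0, 1] = 2.0
        with pytest.raises(ValueError, match="symmetric"):
            pa.SubstitutionModel(S, np.full(20, 0.05))

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.7])
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_discrete_gamma_mean_one(self, alpha, k):
        rates = pa.discrete_gamma_rates(alpha, k)
        assert np.isclose(rates.mean(), 1.0, atol=1e-12)
        assert np.all(np.diff(rates) > 0)

    def test_invariant_class_keeps_unit_mean(self):
        model = pa.SubstitutionModel.jtt(alpha=0.8, k=4, p_inv=0.25)
        rates, probs = model.rate_categories()
        assert rates[0] == 0.0 and np.isclose(probs.sum(), 1.0)
        assert np.isclose(np.dot(rates, probs), 1.0)


class TestSiteLikelihood:
    def test_single_leaf_is_log_pi(self, jtt_model):
        tree = pa.Phylogeny.from_newick("(A:0.0)root;")
        aln = pa.Alignment(["A"], ["W"])
        ll = pa.site_log_likelihood(aln, tree, jtt_model)
        w = pa.AMINO_ACIDS.index("W")
        assert np.isclose(ll[0], np.log(jtt_model.frequencies[w]))

    def test_three_leaf_matches_enumeration(self, three_leaf_tree):
        model = pa.SubstitutionModel.jtt(alpha=0.7, k=3, p_inv=0.1)
        aln = pa.Alignment(["A", "B", "C"], ["L", "M", "-"])
        ll = pa.site_log_likelihood(aln, three_leaf_tree, model)
        ref = brute_force_site_likelihood(aln, three_leaf_tree, model)
        assert np.isclose(ll[0], ref[0], rtol=1e-10)

    def test_zero_branch_lengths(self):
        model = pa.SubstitutionModel.jtt(k=1)
        tree = pa.Phylogeny.from_newick("((A:0,B:0)ab:0,C:0)root;")
        same = pa.Alignment(["A", "B", "C"], ["L", "L", "L"])
        ll = pa.site_log_likelihood(same, tree, model)
        l_idx = pa.AMINO_ACIDS.index("L")
        assert np.isclose(ll[0], np.log(model.frequencies[l_idx]))
        diff = pa.Alignment(["A", "B", "C"], ["L", "M", "L"])
        assert pa.site_log_likelihood(diff, tree, model)[0] == -np.inf

    def test_leaf_row_mismatch_errors(self, three_leaf_tree, jtt_model):
        aln = pa.Alignment(["A", "B", "Z"], ["L", "M", "W"])
        with pytest.raises(ValueError, match="mismatch"):
            pa.site_log_likelihood(aln, three_leaf_tree, jtt_model)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_small_trees_match_enumeration(self, seed):
        # random topology (3 or 4 leaves), random model, vs exhaustive sum
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(3, 5))
        bl = lambda: rng.uniform(0.01, 1.2)
        if n_leaves == 3:
            nwk = f"((A:{bl()},B:{bl()})ab:{bl()},C:{bl()})root;"
            ids = ["A", "B", "C"]
        else:
            nwk = (
                f"((A:{bl()},B:{bl()})ab:{bl()},"
                f"(C:{bl()},D:{bl()})cd:{bl()})root;"
            )
            ids = ["A", "B", "C", "D"]
        tree = pa.Phylogeny.from_newick(nwk)
        model = pa.SubstitutionModel.jtt(
            alpha=float(rng.uniform(0.3, 3.0)),
            k=int(rng.integers(1, 4)),
            p_inv=float(rng.uniform(0.0, 0.4)),
        )
        chars = list(pa.AMINO_ACIDS) + ["-", "X"]
        aln = pa.Alignment(ids, [rng.choice(chars) for _ in ids])
        ll = pa.site_log_likelihood(aln, tree, model)
        ref = brute_force_site_likelihood(aln, tree, model)
        assert np.isclose(ll[0], ref[0], rtol=1e-10)

    def test_child_order_invariance(self, jtt_model):
        a = pa.Phylogeny.from_newick("((A:0.3,B:0.5)ab:0.2,C:0.4)root;")
        b = pa.Phylogeny.from_newick("(C:0.4,(B:0.5,A:0.3)ab:0.2)root;")
        aln = pa.Alignment(["A", "B", "C"], ["LW", "MW", "MV"])
        lla = pa.site_log_likelihood(aln, a, jtt_model)
        llb = pa.site_log_likelihood(aln, b, jtt_model)
        assert np.allclose(lla, llb, rtol=1e-12)

    def test_reroot_invariance_along_branch(self, jtt_model):
        # reversible model: moving the root along the ab branch is neutral
        a = pa.Phylogeny.from_newick("((A:0.3,B:0.5)ab:0.2,C:0.4)root;")
        b = pa.Phylogeny.from_newick("((A:0.3,B:0.5)ab:0.05,C:0.55)root;")
        aln = pa.Alignment(["A", "B", "C"], ["LW", "MW", "MV"])
        lla = pa.site_log_likelihood(aln, a, jtt_model)
        llb = pa.site_log_likelihood(aln, b, jtt_model)
        assert np.allclose(lla, llb, rtol=1e-9)


class TestMarginalAncestral:
    def test_long_branch_posterior_approaches_prior(self):
        model = pa.SubstitutionModel.jtt(k=1)
        tree = pa.Phylogeny.from_newick("((A:60.0,B:60.0)ab:60.0,C:60.0)root;")
        aln = pa.Alignment(["A", "B", "C"], ["L", "L", "L"])
        post = pa.marginal_ancestral(aln, tree, model, "ab")
        assert np.allclose(post.probabilities[0], model.frequencies, atol=1e-6)

    def test_matches_enumeration(self, three_leaf_tree):
        model = pa.SubstitutionModel.jtt(alpha=0.9, k=2, p_inv=0.15)
        aln = pa.Alignment(["A", "B", "C"], ["L", "M", "V"])
        post = pa.marginal_ancestral(aln, three_leaf_tree, model, "ab")
        ref = brute_force_marginal(aln, three_leaf_tree, model, "ab")
        assert np.allclose(post.probabilities[0], ref, atol=1e-12)

    def test_posterior_rows_sum_to_one(self, sixteen_leaf_tree, jtt_model):
        aln, _ = sd.simulate_msa(sixteen_leaf_tree, jtt_model, 50, seed=5)
        for label in ("root", sixteen_leaf_tree.root.children[0].label):
            post = pa.marginal_ancestral(aln, sixteen_leaf_tree, jtt_model, label)
            assert np.allclose(post.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_leaf_posterior_is_point_mass(self, three_leaf_tree, jtt_model):
        aln = pa.Alignment(["A", "B", "C"], ["L", "M", "V"])
        post = pa.marginal_ancestral(aln, three_leaf_tree, jtt_model, "A")
        l_idx = pa.AMINO_ACIDS.index("L")
        assert np.isclose(post.probabilities[0, l_idx], 1.0)

    def test_unknown_node_errors(self, three_leaf_tree, jtt_model):
        aln = pa.Alignment(["A", "B", "C"], ["L", "M", "V"])
        with pytest.raises(KeyError):
            pa.marginal_ancestral(aln, three_leaf_tree, jtt_model, "nope")

    def test_root_recovery_simulated_16_leaves(self, sixteen_leaf_tree, jtt_model):
        aln, nodes = sd.simulate_msa(sixteen_leaf_tree, jtt_model, 200, seed=42)
        post = pa.marginal_ancestral(aln, sixteen_leaf_tree, jtt_model, "root")
        ml = post.ml_sequence()
        truth = nodes["root"]
        accuracy = np.mean([a == b for a, b in zip(ml, truth)])
        assert accuracy >= 0.90

    def test_true_residue_probability_grows_with_shorter_branches(self, jtt_model):
        means = []
        for bl in (0.4, 0.1, 0.02):
            tree = pa.Phylogeny.from_newick(balanced_newick(8, bl))
            aln, nodes = sd.simulate_msa(tree, jtt_model, 300, seed=9)
            post = pa.marginal_ancestral(aln, tree, jtt_model, "root")
            truth_idx = [pa.AMINO_ACIDS.index(c) for c in nodes["root"]]
            means.append(
                np.mean([post.probabilities[s, i] for s, i in enumerate(truth_idx)])
            )
        assert means[0] < means[1] < means[2]


class TestMLSequence:
    def _posterior(self, probs):
        row = np.asarray(probs, dtype=float)
        return pa.AncestralPosterior("n", row[None, :] / row.sum())

    def test_flagged_site_alternative_order(self):
        probs = np.full(20, (1 - 0.19 - 0.16 - 0.15 - 0.13) / 16)
        for res, p in (("I", 0.19), ("V", 0.16), ("T", 0.15), ("M", 0.13)):
            probs[pa.AMINO_ACIDS.index(res)] = p
        post = self._posterior(probs)
        seq, flagged = pa.ml_sequence_with_alternatives(post, 0.7)
        assert seq == "I"
        assert [a for a, _ in flagged[0].alternatives[:3]] == ["V", "T", "M"]

    def test_certain_site_not_flagged(self):
        probs = np.zeros(20)
        probs[pa.AMINO_ACIDS.index("W")] = 1.0
        post = pa.AncestralPosterior("n", probs[None, :])
        seq, flagged = pa.ml_sequence_with_alternatives(post, 0.7)
        assert seq == "W" and flagged == []

    def test_exact_tie_alphabetical(self):
        probs = np.zeros(20)
        probs[pa.AMINO_ACIDS.index("W")] = 0.5
        probs[pa.AMINO_ACIDS.index("C")] = 0.5
        post = pa.AncestralPosterior("n", probs[None, :])
        seq, flagged = pa.ml_sequence_with_alternatives(post, 0.7)
        assert seq == "C"  # C before W alphabetically
        assert flagged[0].alternatives[0][0] == "W"


class TestIndelReconstruction:
    def test_no_gaps_all_present(self, three_leaf_tree):
        aln = pa.Alignment(["A", "B", "C"], ["LW", "MW", "VW"])
        states = pa.reconstruct_indels(aln, three_leaf_tree)
        for arr in states.values():
            assert arr.all()

    def test_all_gap_column_absent_everywhere(self, three_leaf_tree):
        aln = pa.Alignment(["A", "B", "C"], ["-L", "-M", "-V"])
        states = pa.reconstruct_indels(aln, three_leaf_tree)
        for arr in states.values():
            assert not arr[0] and arr[1]

    def test_fitch_by_hand_four_leaves(self):
        tree = pa.Phylogeny.from_newick(
            "((A:0.1,B:0.1)ab:0.1,(C:0.1,D:0.1)cd:0.1)root;"
        )
        aln = pa.Alignment(["A", "B", "C", "D"], ["-", "L", "L", "L"])
        states = pa.reconstruct_indels(aln, tree)
        assert states["root"][0] and states["ab"][0] and states["cd"][0]
        assert not states["A"][0]

    def test_x_counts_as_present(self, three_leaf_tree):
        aln = pa.Alignment(["A", "B", "C"], ["X", "X", "X"])
        states = pa.reconstruct_indels(aln, three_leaf_tree)
        assert states["root"][0]


class TestOptimizeShape:
    def test_recovers_simulated_alpha(self, sixteen_leaf_tree):
        truth = pa.SubstitutionModel.jtt(alpha=0.5, k=4)
        aln, _ = sd.simulate_msa(sixteen_leaf_tree, truth, 1000, seed=7)
        start = pa.SubstitutionModel.jtt(alpha=1.0, k=4)
        fit = pa.optimize_shape(aln, sixteen_leaf_tree, start)
        assert abs(fit.alpha - 0.5) / 0.5 < 0.25

    def test_k1_rejected(self, three_leaf_tree):
        aln = pa.Alignment(["A", "B", "C"], ["L", "M", "V"])
        with pytest.raises(ValueError, match="k >= 2"):
            pa.optimize_shape(aln, three_leaf_tree, pa.SubstitutionModel.jtt(k=1))

    def test_optimum_beats_neighbours(self, sixteen_leaf_tree):
        truth = pa.SubstitutionModel.jtt(alpha=0.8, k=4)
        aln, _ = sd.simulate_msa(sixteen_leaf_tree, truth, 300, seed=3)
        fit = pa.optimize_shape(aln, sixteen_leaf_tree, truth)
        ll_best = pa.total_log_likelihood(aln, sixteen_leaf_tree, fit)
        for factor in (0.5, 2.0):
            ll = pa.total_log_likelihood(
                aln, sixteen_leaf_tree, fit.with_alpha(fit.alpha * factor)
            )
            assert ll_best >= ll
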