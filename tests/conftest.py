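import numpy as np
import pytest

from idpevo import phylo_asr as pa


def balanced_newick(n_leaves: int, branch_length: float) -> str:
    """Fully balanced rooted tree with uniform branch lengths."""
    items = [f"L{i}:{branch_length}" for i in range(n_leaves)]
    while len(items) > 1:
        items = [
            f"({a},{b}):{branch_length}" for a, b in zip(items[::2], items[1::2])
        ]
    return items[0].rsplit(":", 1)[0] + "root;"


@pytest.fixture(scope="session")
def jtt_model():
    return pa.SubstitutionModel.jtt(alpha=1.0, k=4)


@pytest.fixture(scope="session")
def three_leaf_tree():
    return pa.Phylogeny.from_newick("((A:0.3,B:0.5)ab:0.2,C:0.4)root;")


@pytest.fixture(scope="session")
def sixteen_leaf_tree():
    return pa.Phylogeny.from_newick(balanced_newick(16, 0.05))


def brute_force_site_likelihood(aln, tree, model):
    """Exhaustive enumeration over all internal-state assignments.

    Independent oracle: transition matrices via scipy.linalg.expm, the
    sum runs over every combination of internal node states.
    """
    from itertools import product

    from scipy.linalg import expm

    from idpevo.phylo_asr import AMINO_ACIDS
    from idpevo.phylo_asr.model import build_rate_matrix

    Q = build_rate_matrix(model)
    pi = model.frequencies
    rates, probs = model.rate_categories()
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    internals = tree.internal_nodes
    leaves = tree.leaves
    n_sites = aln.n_cols
    out = np.zeros(n_sites)
    for site in range(n_sites):
        lik = 0.0
        for rate, p_cat in zip(rates, probs):
            P = {
                node.label: expm(Q * node.length * rate)
                for node in tree.preorder()
                if node.parent is not None
            }
            cat_lik = 0.0
            for assignment in product(range(20), repeat=len(internals)):
                states = {n.label: s for n, s in zip(internals, assignment)}
                term = pi[states[tree.root.label]]
                for node in tree.preorder():
                    if node.parent is None:
                        continue
                    parent_state = states[node.parent.label]
                    if node.is_leaf:
                        ch = aln.row(node.label)[site]
                        if ch in ("-", "X"):
                            term *= 1.0
                        else:
                            term *= P[node.label][parent_state, idx[ch]]
                    else:
                        term *= P[node.label][parent_state, states[node.label]]
                cat_lik += term
            lik += p_cat * cat_lik
        out[site] = np.log(lik) if lik > 0 else -np.inf
    return out


def brute_force_marginal(aln, tree, model, node_label, site=0):
    """Posterior over states at one internal node by enumeration."""
    from itertools import product

    from scipy.linalg import expm

    from idpevo.phylo_asr import AMINO_ACIDS
    from idpevo.phylo_asr.model import build_rate_matrix

    Q = build_rate_matrix(model)
    pi = model.frequencies
    rates, probs = model.rate_categories()
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    internals = tree.internal_nodes
    post = np.zeros(20)
    for rate, p_cat in zip(rates, probs):
        P = {
            node.label: expm(Q * node.length * rate)
            for node in tree.preorder()
            if node.parent is not None
        }
        for assignment in product(range(20), repeat=len(internals)):
            states = {n.label: s for n, s in zip(internals, assignment)}
            term = p_cat * pi[states[tree.root.label]]
            for node in tree.preorder():
                if node.parent is None:
                    continue
                parent_state = states[node.parent.label]
                if node.is_leaf:
                    ch = aln.row(node.label)[site]
                    if ch not in ("-", "X"):
                        term *= P[node.label][parent_state, idx[ch]]
                else:
                    term *= P[node.label][parent_state, states[node.label]]
            post[states[node_label]] += term
    return post / post.sum()
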