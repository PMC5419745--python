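"""Felsenstein pruning, marginal ancestral reconstruction and indel parsimony.

Gaps (``-``) and masked residues (``X``) enter the residue likelihood as
missing data (all-ones conditional vectors); indel placement is handled
separately by binary Fitch parsimony (:func:`reconstruct_indels`).

All per-site computations carry per-node log scaling factors so deep or
long trees do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from ._jtt import AMINO_ACIDS
from .alignment import GAP, MASK, Alignment
from .model import N_STATES, SubstitutionModel, TransitionKernel
from .tree import Phylogeny, TreeNode

_STATE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _leaf_conditionals(row: str) -> np.ndarray:
    """(n_sites, 20) indicator matrix; gap/X rows are all ones."""
    L = np.zeros((len(row), N_STATES))
    for s, ch in enumerate(row):
        if ch in (GAP, MASK):
            L[s, :] = 1.0
        else:
            L[s, _STATE_INDEX[ch]] = 1.0
    return L


def _check_leaves(aln: Alignment, tree: Phylogeny) -> None:
    leaf_labels = {leaf.label for leaf in tree.leaves}
    if leaf_labels != set(aln.ids):
        missing = leaf_labels - set(aln.ids)
        extra = set(aln.ids) - leaf_labels
        raise ValueError(
            f"leaf/row mismatch: tree leaves without rows {sorted(missing)}, "
            f"rows without leaves {sorted(extra)}"
        )


class _CategoryPass:
    """Up (and optionally down) pass conditionals for one rate category."""

    def __init__(
        self,
        aln: Alignment,
        tree: Phylogeny,
        kernel: TransitionKernel,
        rate: float,
    ):
        self.tree = tree
        self.pi = kernel.model.frequencies
        n_sites = aln.n_cols
        eye = np.eye(N_STATES)
        self.P: dict[str, np.ndarray] = {}  # branch transition matrix per node
        self.up: dict[str, np.ndarray] = {}  # scaled subtree conditionals
        self.up_scale: dict[str, np.ndarray] = {}  # per-site log scalers
        for node in tree.postorder():
            if node is not tree.root:
                t = node.length * rate
                self.P[node.label] = eye if t == 0.0 else kernel.probability_matrix(t)
            if node.is_leaf:
                self.up[node.label] = _leaf_conditionals(aln.row(node.label))
                self.up_scale[node.label] = np.zeros(n_sites)
            else:
                L = np.ones((n_sites, N_STATES))
                scale = np.zeros(n_sites)
                for child in node.children:
                    L = L * (self.up[child.label] @ self.P[child.label].T)
                    scale = scale + self.up_scale[child.label]
                m = L.max(axis=1)
                nonzero = m > 0
                L[nonzero] /= m[nonzero, None]
                with np.errstate(divide="ignore"):
                    scale = scale + np.where(nonzero, np.log(np.maximum(m, 1e-300)), -np.inf)
                self.up[node.label] = L
                self.up_scale[node.label] = scale
        self._down: dict[str, np.ndarray] | None = None
        self._down_scale: dict[str, np.ndarray] | None = None

    def site_log_likelihood(self) -> np.ndarray:
        root = self.tree.root.label
        with np.errstate(divide="ignore"):
            return np.log(self.up[root] @ self.pi) + self.up_scale[root]

    def _run_down(self) -> None:
        if self._down is not None:
            return
        tree = self.tree
        n_sites = next(iter(self.up.values())).shape[0]
        down = {tree.root.label: np.tile(self.pi, (n_sites, 1))}
        down_scale = {tree.root.label: np.zeros(n_sites)}
        for node in tree.preorder():
            for child in node.children:
                H = down[node.label].copy()
                scale = down_scale[node.label].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    H *= self.up[sib.label] @ self.P[sib.label].T
                    scale += self.up_scale[sib.label]
                G = H @ self.P[child.label]
                m = G.max(axis=1)
                nonzero = m > 0
                G[nonzero] /= m[nonzero, None]
                with np.errstate(divide="ignore"):
                    scale = scale + np.where(
                        nonzero, np.log(np.maximum(m, 1e-300)), -np.inf
                    )
                down[child.label] = G
                down_scale[child.label] = scale
        self._down = down
        self._down_scale = down_scale

    def joint_at_node(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Scaled ``P(data, state at node)`` and its per-site log scaler."""
        self._run_down()
        J = self.up[label] * self._down[label]
        return J, self.up_scale[label] + self._down_scale[label]


def _category_passes(
    aln: Alignment, tree: Phylogeny, model: SubstitutionModel
) -> tuple[list[_CategoryPass], np.ndarray]:
    _check_leaves(aln, tree)
    kernel = TransitionKernel(model)
    rates, probs = model.rate_categories()
    return [_CategoryPass(aln, tree, kernel, r) for r in rates], probs


def site_log_likelihood(
    aln: Alignment, tree: Phylogeny, model: SubstitutionModel
) -> np.ndarray:
    """Per-site log-likelihoods by the pruning algorithm.

    Each site's likelihood is the rate-category-probability-weighted sum
    (the invariant class, if any, is an extra zero-rate category) of the
    frequency-weighted root conditionals.
    """
    passes, probs = _category_passes(aln, tree, model)
    per_cat = np.stack([p.site_log_likelihood() for p in passes])  # (k, sites)
    with np.errstate(divide="ignore"):
        terms = per_cat + np.log(probs)[:, None]
    mx = terms.max(axis=0)
    out = np.where(
        np.isfinite(mx),
        mx + np.log(np.exp(terms - np.where(np.isfinite(mx), mx, 0.0)).sum(axis=0)),
        -np.inf,
    )
    return out


def total_log_likelihood(
    aln: Alignment, tree: Phylogeny, model: SubstitutionModel
) -> float:
    return float(site_log_likelihood(aln, tree, model).sum())


@dataclass
class SiteAlternatives:
    """Flagged site: maximum-likelihood residue plus runners-up."""

    site: int  # 0-based column index
    ml_residue: str
    ml_prob: float
    alternatives: list[tuple[str, float]]  # ordered 2nd, 3rd, ... residues


@dataclass
class AncestralPosterior:
    """Per-site posterior state probabilities at one node.

    Attributes
    ----------
    node
        Node label.
    probabilities
        (n_sites, 20) array; every row sums to 1.
    presence
        Optional per-column residue presence (True) / absence (False)
        from indel reconstruction.
    """

    node: str
    probabilities: np.ndarray
    presence: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.probabilities.shape[0]

    @property
    def ml_probabilities(self) -> np.ndarray:
        return self.probabilities.max(axis=1)

    def ml_sequence(self) -> str:
        seq, _ = ml_sequence_with_alternatives(self, threshold=1.0)
        return seq

    def to_dataframe(self, alt_threshold: float = 0.7):
        import pandas as pd

        seq, flagged = ml_sequence_with_alternatives(self, alt_threshold)
        flagged_sites = {f.site for f in flagged}
        df = pd.DataFrame(self.probabilities, columns=list(AMINO_ACIDS))
        df.insert(0, "node", self.node)
        df.insert(1, "site", np.arange(self.n_sites))
        df["ml_residue"] = list(seq)
        df["ml_prob"] = self.ml_probabilities
        df["flagged"] = [s in flagged_sites for s in range(self.n_sites)]
        if self.presence is not None:
            df["present"] = self.presence
        return df


def marginal_ancestral(
    aln: Alignment,
    tree: Phylogeny,
    model: SubstitutionModel,
    node: str,
) -> AncestralPosterior:
    """Marginal posterior state probabilities at ``node``.

    Combines an up (subtree conditional) and a down (outside
    conditional) pass per rate category; categories are weighted by
    their posterior probability per site.
    """
    if node not in tree:
        raise KeyError(f"node {node!r} not in tree")
    passes, probs = _category_passes(aln, tree, model)
    joints, log_tot = [], []
    for cp, p in zip(passes, probs):
        J, scale = cp.joint_at_node(node)
        tot = J.sum(axis=1)
        with np.errstate(divide="ignore"):
            log_tot.append(np.log(p) + np.log(np.maximum(tot, 1e-300)) + scale)
        joints.append(J / np.maximum(tot, 1e-300)[:, None])
    log_tot = np.stack(log_tot)  # (k, sites)
    w = np.exp(log_tot - log_tot.max(axis=0))
    w /= w.sum(axis=0)
    post = np.einsum("ks,ksa->sa", w, np.stack(joints))
    post /= post.sum(axis=1, keepdims=True)
    return AncestralPosterior(node, post)


def ml_sequence_with_alternatives(
    post: AncestralPosterior, threshold: float
) -> tuple[str, list[SiteAlternatives]]:
    """ML sequence plus alternative residues for low-probability sites.

    Sites whose ML probability is strictly below ``threshold`` are
    flagged with their 2nd, 3rd, ... most probable residues.  Ties are
    broken alphabetically by one-letter code.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    letters = list(AMINO_ACIDS)
    seq = []
    flagged = []
    for s in range(post.n_sites):
        ranked = sorted(
            zip(letters, post.probabilities[s]), key=lambda t: (-t[1], t[0])
        )
        ml_res, ml_p = ranked[0]
        seq.append(ml_res)
        if ml_p < threshold:
            alts = [(res, float(p)) for res, p in ranked[1:] if p > 0.0]
            flagged.append(SiteAlternatives(s, ml_res, float(ml_p), alts))
    return "".join(seq), flagged


_ABSENT, _PRESENT, _EITHER = 1, 2, 3


def reconstruct_indels(aln: Alignment, tree: Phylogeny) -> dict[str, np.ndarray]:
    """Fitch parsimony on per-column residue presence/absence.

    ``X`` counts as a (masked) residue, i.e. present.  Ties at the root
    and unresolved internal states resolve toward "present".

    Returns a mapping from node label to a boolean presence vector
    (True = residue present at that column).
    """
    _check_leaves(aln, tree)
    n_cols = aln.n_cols
    sets: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            row = np.array(list(aln.row(node.label)))
            sets[node.label] = np.where(row == GAP, _ABSENT, _PRESENT).astype(np.int8)
        else:
            masks = [sets[c.label] for c in node.children]
            inter = masks[0].copy()
            union = masks[0].copy()
            for m in masks[1:]:
                inter &= m
                union |= m
            sets[node.label] = np.where(inter > 0, inter, union).astype(np.int8)
    states: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        mask = sets[node.label]
        if node.parent is None:
            state = (mask & _PRESENT) > 0  # root tie -> present
        else:
            parent_bit = np.where(states[node.parent.label], _PRESENT, _ABSENT)
            keep_parent = (mask & parent_bit) > 0
            own = (mask & _PRESENT) > 0
            state = np.where(keep_parent, states[node.parent.label], own)
        states[node.label] = state.astype(bool)
        del mask
    _ = n_cols
    return states


def optimize_shape(
    aln: Alignment,
    tree: Phylogeny,
    model: SubstitutionModel,
    fit_pinv: bool = False,
    alpha_bounds: tuple[float, float] = (0.02, 50.0),
) -> SubstitutionModel:
    """Fit the gamma shape (and optionally ``p_inv``) by maximum likelihood.

    One-dimensional bounded search on ``alpha`` (tolerance 1e-4); with
    ``fit_pinv`` a Nelder-Mead search on ``(log alpha, p_inv)``.
    Returns a copy of ``model`` with the fitted values.
    """
    if model.k < 2:
        raise ValueError("shape optimisation requires k >= 2 rate categories")

    def negll_alpha(alpha: float, p_inv: float) -> float:
        ll = total_log_likelihood(aln, tree, model.with_alpha(alpha, p_inv))
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite likelihood during optimisation")
        return -ll

    if not fit_pinv:
        res = minimize_scalar(
            negll_alpha,
            bounds=alpha_bounds,
            args=(model.p_inv,),
            method="bounded",
            options={"xatol": 1e-4},
        )
        return model.with_alpha(float(res.x))

    def negll(theta: np.ndarray) -> float:
        alpha = float(np.exp(theta[0]))
        p_inv = float(np.clip(theta[1], 0.0, 0.95))
        alpha = float(np.clip(alpha, *alpha_bounds))
        return negll_alpha(alpha, p_inv)

    res = minimize(
        negll,
        x0=np.array([np.log(model.alpha), max(model.p_inv, 0.05)]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6},
    )
    alpha = float(np.clip(np.exp(res.x[0]), *alpha_bounds))
    p_inv = float(np.clip(res.x[1], 0.0, 0.95))
    return model.with_alpha(alpha, p_inv)
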