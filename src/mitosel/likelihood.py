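"""Felsenstein pruning, site pattern handling and branch-length fitting.

The engine is alphabet-agnostic: leaves are integer state indices (-1 =
missing, marginalised over), models supply transition matrices, and rate
heterogeneity enters as a weighted mixture over per-category likelihoods
(invariant class = rate 0).  Per-pattern rescaling keeps long alignments in
range; it can be switched off to verify the bookkeeping on short ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .alignment import Alignment
from .models import RateHeterogeneity, SubstitutionModel
from .trees import PhyloTree

_LENGTH_LO, _LENGTH_HI = 1e-8, 50.0


class LikelihoodError(ValueError):
    pass


# -- leaf states and site patterns -----------------------------------------

def leaf_state_matrix(alignment: Alignment, model: SubstitutionModel,
                      leaf_names: list[str]) -> np.ndarray:
    """(n_leaves, n_sites) integer states in model order; -1 = missing.

    For codon models the alignment is in-frame nucleotide; each triplet maps
    to a sense-codon index, anything else (gap, ambiguity, stop) to missing.
    """
    missing_names = set(leaf_names) - set(alignment.names)
    if missing_names:
        raise LikelihoodError(
            f"alignment lacks taxa present in tree: {sorted(missing_names)}")
    state_len = len(model.states[0])
    if state_len == 1:
        index = {s: i for i, s in enumerate(model.states)}
        out = np.full((len(leaf_names), alignment.n_columns), -1, dtype=np.intp)
        for r, name in enumerate(leaf_names):
            row = alignment.row(name)
            for c, ch in enumerate(row):
                out[r, c] = index.get(ch, -1)
        return out
    if state_len != 3:
        raise LikelihoodError("unsupported state width")
    if alignment.n_columns % 3:
        raise LikelihoodError("codon model needs length divisible by 3")
    index = {s: i for i, s in enumerate(model.states)}
    n_sites = alignment.n_columns // 3
    out = np.full((len(leaf_names), n_sites), -1, dtype=np.intp)
    for r, name in enumerate(leaf_names):
        seq = alignment.sequence(name)
        for c in range(n_sites):
            out[r, c] = index.get(seq[3 * c: 3 * c + 3], -1)
    return out


def compress_patterns(leaf_states: np.ndarray):
    """Unique site patterns, their weights, and the site->pattern map."""
    patterns, inverse, counts = np.unique(
        leaf_states, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts.astype(float), inverse


# -- pruning ---------------------------------------------------------------

@dataclass
class _Workspace:
    """Pre-resolved tree arrays shared by all per-category pruning passes."""
    tree: PhyloTree
    leaf_row: dict[int, int]       # tree node -> row in leaf-state matrix

    @classmethod
    def build(cls, tree: PhyloTree, leaf_names: list[str]) -> "_Workspace":
        order = {name: i for i, name in enumerate(leaf_names)}
        leaf_row = {}
        for node in tree.leaves:
            label = tree.labels[node]
            if label not in order:
                raise LikelihoodError(f"tree leaf {label!r} not in alignment")
            leaf_row[node] = order[label]
        return cls(tree, leaf_row)


def pattern_likelihoods(tree: PhyloTree, patterns: np.ndarray,
                        P: dict[int, np.ndarray], pi: np.ndarray,
                        ws: _Workspace, scale: bool = True):
    """Per-pattern likelihood under fixed per-branch transition matrices.

    ``P[node]`` is the matrix on the branch above ``node``.  Returns
    ``(lik, log_scale)`` with the true per-pattern likelihood equal to
    ``lik * exp(log_scale)``.
    """
    npat = patterns.shape[1]
    S = len(pi)
    messages: dict[int, np.ndarray] = {}
    log_scale = np.zeros(npat)
    for node in tree.postorder:
        node = int(node)
        if tree.is_leaf(node):
            states = patterns[ws.leaf_row[node]]
            msg = np.ones((npat, S))
            known = states >= 0
            msg[known] = P[node][:, states[known]].T
            messages[node] = msg
        else:
            partial = messages[tree.children[node][0]].copy()
            for child in tree.children[node][1:]:
                partial *= messages[child]
            for child in tree.children[node]:
                del messages[child]
            if node == tree.root:
                lik = partial @ pi
                return lik, log_scale
            if scale:
                m = partial.max(axis=1)
                m[m == 0] = 1.0
                partial /= m[:, None]
                log_scale += np.log(m)
            messages[node] = partial @ P[node].T
    raise AssertionError("root never reached")  # pragma: no cover


def _transition_matrices(tree: PhyloTree, model: SubstitutionModel,
                         rate: float) -> dict[int, np.ndarray]:
    P = {}
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        P[node] = model.transition_matrix(float(tree.branch_length[node]), rate)
    return P


def site_log_likelihoods(tree: PhyloTree, alignment: Alignment,
                         model: SubstitutionModel, scale: bool = True
                         ) -> np.ndarray:
    """Per-site log-likelihood with the model's +I+G mixture."""
    leaf_names = tree.leaf_labels
    states = leaf_state_matrix(alignment, model, leaf_names)
    patterns, _, inverse = compress_patterns(states)
    ws = _Workspace.build(tree, leaf_names)
    rates, weights = model.heterogeneity.rates_and_weights()
    total = np.zeros(patterns.shape[1])
    log_shift = None
    parts = []
    for rate, w in zip(rates, weights):
        P = _transition_matrices(tree, model, rate)
        lik, log_scale = pattern_likelihoods(tree, patterns, P, model.pi, ws,
                                             scale=scale)
        parts.append((w, lik, log_scale))
    log_shift = np.max([ls for _, _, ls in parts], axis=0)
    for w, lik, log_scale in parts:
        total += w * lik * np.exp(log_scale - log_shift)
    with np.errstate(divide="ignore"):
        logs = np.log(total) + log_shift
    if np.any(~np.isfinite(logs)):
        bad = int(np.flatnonzero(~np.isfinite(logs[inverse]))[0])
        raise LikelihoodError(f"non-finite site likelihood at site {bad}")
    return logs[inverse]


def log_likelihood(tree: PhyloTree, alignment: Alignment,
                   model: SubstitutionModel, scale: bool = True) -> float:
    return float(site_log_likelihoods(tree, alignment, model, scale).sum())


# -- branch-length optimisation --------------------------------------------

def _p_distance_scale(states: np.ndarray) -> float:
    """Crude tree-depth scale: half the mean pairwise mismatch fraction."""
    n = states.shape[0]
    if n < 2:
        return 0.1
    total, count = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            ok = (states[i] >= 0) & (states[j] >= 0)
            if ok.any():
                total += np.mean(states[i][ok] != states[j][ok])
                count += 1
    p = total / max(count, 1)
    return max(p / 2.0, 0.01)


def optimize_branch_lengths(tree: PhyloTree, alignment: Alignment,
                            model: SubstitutionModel,
                            optimize_alpha: bool = False,
                            multistart: bool = True,
                            tol: float = 1e-6):
    """ML branch lengths on a fixed topology (optionally also gamma shape).

    Returns ``(fitted_tree, lnL, model)`` — the model is re-returned because
    ``optimize_alpha`` replaces its heterogeneity.  Quasi-Newton on log
    lengths, bounds [1e-8, 50], multi-starts at {0.1, 1.0} x a p-distance
    heuristic.
    """
    leaf_names = tree.leaf_labels
    states = leaf_state_matrix(alignment, model, leaf_names)
    patterns, weights_pat, _ = compress_patterns(states)
    ws = _Workspace.build(tree, leaf_names)
    edges = [n for n in range(tree.n_nodes) if n != tree.root]
    het = model.heterogeneity

    def unpack(x):
        lengths = np.exp(x[: len(edges)])
        m = model
        if optimize_alpha:
            m = model.with_heterogeneity(RateHeterogeneity(
                het.p_invariant, float(np.exp(x[-1])), het.k))
        return lengths, m

    def negloglik(x):
        lengths, m = unpack(x)
        work = tree.copy()
        for e, t in zip(edges, lengths):
            work.branch_length[e] = t
        rates, wts = m.heterogeneity.rates_and_weights()
        total = None
        parts = []
        for rate, w in zip(rates, wts):
            P = _transition_matrices(work, m, rate)
            lik, log_scale = pattern_likelihoods(work, patterns, P, m.pi, ws)
            parts.append((w, lik, log_scale))
        shift = np.max([ls for _, _, ls in parts], axis=0)
        total = sum(w * lik * np.exp(ls - shift) for w, lik, ls in parts)
        with np.errstate(divide="ignore"):
            lnl = np.dot(weights_pat, np.log(total) + shift)
        return 1e12 if not np.isfinite(lnl) else -lnl

    scale0 = _p_distance_scale(states)
    starts = [scale0, 0.1 * scale0] if multistart else [scale0]
    lo, hi = np.log(_LENGTH_LO), np.log(_LENGTH_HI)
    best = None
    for s in starts:
        x0 = np.full(len(edges), np.log(np.clip(s, _LENGTH_LO, _LENGTH_HI)))
        if optimize_alpha:
            a0 = het.alpha if het.alpha else 1.0
            x0 = np.append(x0, np.log(a0))
        bounds = [(lo, hi)] * len(edges)
        if optimize_alpha:
            bounds.append((np.log(0.02), np.log(100.0)))
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise LikelihoodError("branch-length optimisation failed to find a "
                              "finite likelihood")
    lengths, fitted_model = unpack(best.x)
    fitted = tree.copy()
    for e, t in zip(edges, lengths):
        # below ~1e-5 expected substitutions/site a branch is numerically zero
        fitted.branch_length[e] = 0.0 if t <= 1e-5 else t
    lnl = -negloglik(best.x)
    return fitted, lnl, fitted_model
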