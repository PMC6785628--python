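"""Brute-force likelihood and ancestral posteriors by explicit enumeration.

These functions sum over every joint assignment of states to internal nodes
(S^m terms) and exist purely as independent oracles for the pruning and
two-pass reconstruction code: they share no machinery with it beyond the tree
container and transition matrices.  Exponential cost — small trees only.
"""
from __future__ import annotations


import numpy as np

from .models import SubstitutionModel
from .trees import PhyloTree


def _per_category(tree: PhyloTree, leaf_states: dict[int, int],
                  model: SubstitutionModel, rate: float):
    """(likelihood, per-internal-node unnormalised posteriors) at one rate.

    Every joint internal-state assignment is visited explicitly; the sweep is
    merely numpy-vectorised (one probability per assignment, gathered from the
    transition matrices), not factorised the way pruning is.
    """
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    pos = {n: i for i, n in enumerate(internal)}
    S = model.n_states
    P = {n: model.transition_matrix(float(tree.branch_length[n]), rate)
         for n in range(tree.n_nodes) if n != tree.root}
    # (m, S^m) matrix: one column per joint assignment of the m internal nodes
    m = len(internal)
    assign = np.stack(np.meshgrid(*([np.arange(S, dtype=np.intp)] * m),
                                  indexing="ij")).reshape(m, -1)
    prob = model.pi[assign[pos[tree.root]]].astype(float)
    for node in range(tree.n_nodes):
        if node == tree.root:
            continue
        parent_states = assign[pos[int(tree.parent[node])]]
        if tree.is_leaf(node):
            s_child = leaf_states[node]
            if s_child < 0:           # missing leaf: marginalise
                continue
            prob *= P[node][parent_states, s_child]
        else:
            prob *= P[node][parent_states, assign[pos[node]]]
    total = float(prob.sum())
    post = {n: np.bincount(assign[pos[n]], weights=prob, minlength=S)
            for n in internal}
    return total, post


def _leaf_states(tree: PhyloTree, site_states: np.ndarray,
                 leaf_names: list[str]) -> dict[int, int]:
    order = {name: i for i, name in enumerate(leaf_names)}
    return {node: int(site_states[order[tree.labels[node]]])
            for node in tree.leaves}


def enum_site_log_likelihoods(tree: PhyloTree, leaf_state_matrix: np.ndarray,
                              leaf_names: list[str],
                              model: SubstitutionModel) -> np.ndarray:
    """Per-site log-likelihood by exhaustive enumeration (+I+G mixture)."""
    rates, weights = model.heterogeneity.rates_and_weights()
    n_sites = leaf_state_matrix.shape[1]
    out = np.empty(n_sites)
    for s in range(n_sites):
        states = _leaf_states(tree, leaf_state_matrix[:, s], leaf_names)
        lik = 0.0
        for rate, w in zip(rates, weights):
            l_c, _ = _per_category(tree, states, model, rate)
            lik += w * l_c
        out[s] = np.log(lik)
    return out


def mc_pair_pattern_frequencies(tree: PhyloTree, recon, pair: tuple[int, int],
                                site: int, n_draws: int,
                                rng: np.random.Generator):
    """Monte-Carlo estimate of (P_parallel, P_convergent) at one site.

    Draws a rate category from the site's category posterior, the two parent
    states from their subtree-exclusive posteriors, and a derived state per
    branch from the transition matrix — then counts parallel / convergent
    endpoint patterns.  Independent oracle for the closed-form per-site pair
    probabilities.
    """
    from .convergence import _exclusive_parent_posterior

    b1, b2 = pair
    t1 = float(tree.branch_length[b1])
    t2 = float(tree.branch_length[b2])
    cats = rng.choice(len(recon.cat_rates), size=n_draws,
                      p=recon.cat_weights[site])
    n_par = n_conv = 0
    for ci in np.unique(cats):
        n_c = int((cats == ci).sum())
        rate = recon.cat_rates[ci]
        P1 = recon.model.transition_matrix(t1, rate)
        P2 = recon.model.transition_matrix(t2, rate)
        q1 = _exclusive_parent_posterior(recon, int(tree.parent[b1]), b1,
                                         ci, P1)[site]
        q2 = _exclusive_parent_posterior(recon, int(tree.parent[b2]), b2,
                                         ci, P2)[site]
        a1 = rng.choice(len(q1), size=n_c, p=q1)
        a2 = rng.choice(len(q2), size=n_c, p=q2)
        u1 = rng.random(n_c)
        u2 = rng.random(n_c)
        x1 = (u1[:, None] > P1.cumsum(axis=1)[a1]).sum(axis=1)
        x2 = (u2[:, None] > P2.cumsum(axis=1)[a2]).sum(axis=1)
        same_derived = x1 == x2
        changed = (x1 != a1) & (x2 != a2)
        n_par += int((same_derived & changed & (a1 == a2)).sum())
        n_conv += int((same_derived & changed & (a1 != a2)
                       & (x1 != a2) & (x2 != a1)).sum())
    return n_par / n_draws, n_conv / n_draws


def enum_marginal_posteriors(tree: PhyloTree, leaf_state_matrix: np.ndarray,
                             leaf_names: list[str], model: SubstitutionModel
                             ) -> dict[int, np.ndarray]:
    """Per internal node: (n_sites, S) marginal posteriors by enumeration."""
    rates, weights = model.heterogeneity.rates_and_weights()
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]
    n_sites = leaf_state_matrix.shape[1]
    out = {n: np.zeros((n_sites, model.n_states)) for n in internal}
    for s in range(n_sites):
        states = _leaf_states(tree, leaf_state_matrix[:, s], leaf_names)
        num = {n: np.zeros(model.n_states) for n in internal}
        denom = 0.0
        for rate, w in zip(rates, weights):
            l_c, post = _per_category(tree, states, model, rate)
            denom += w * l_c
            for n in internal:
                num[n] += w * post[n]
        for n in internal:
            out[n][s] = num[n] / denom
    return out
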