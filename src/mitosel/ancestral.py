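"""Marginal empirical-Bayes ancestral amino-acid reconstruction.

Posteriors at each internal node come from a two-pass (tipward partials,
rootward messages) computation at fixed branch lengths and model parameters,
with the gamma rate mixture marginalised.  Per-rate-category posteriors and
the per-site category weights are retained because the convergence test
conditions on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .likelihood import (LikelihoodError, _Workspace, compress_patterns,
                         leaf_state_matrix)
from .models import SubstitutionModel
from .trees import PhyloTree



@dataclass
class AncestralReconstruction:
    tree: PhyloTree
    model: SubstitutionModel
    n_sites: int
    site_numbers: np.ndarray                    # 1-based, reference if known
    #: node -> (n_sites, S) mixture-marginal posterior
    posterior: dict[int, np.ndarray] = field(repr=False)
    #: node -> (n_cats, n_sites, S) posterior conditional on rate category
    cat_posterior: dict[int, np.ndarray] = field(repr=False)
    #: (n_sites, n_cats) posterior weight of each rate category
    cat_weights: np.ndarray = field(repr=False)
    cat_rates: np.ndarray = field(repr=False)
    map_state: dict[int, np.ndarray] = field(repr=False)   # state indices
    map_posterior: dict[int, np.ndarray] = field(repr=False)
    #: node -> (n_cats, n_sites, S) scaled tipward partial likelihoods (all
    #: nodes); lets downstream code form subtree-exclusive posteriors
    cat_partial: dict[int, np.ndarray] = field(repr=False, default=None)
    n_map_ties: int = 0

    def map_residue(self, node: int, site: int) -> str:
        return self.model.states[self.map_state[node][site]]

    def to_table(self):
        """Flat per-(node, site) records of MAP states ('rst-like' export)."""
        import pandas as pd
        rows = []
        for node in sorted(self.posterior):
            for s in range(self.n_sites):
                rows.append({
                    "node": node,
                    "site": int(self.site_numbers[s]),
                    "map_state": self.map_residue(node, s),
                    "posterior": float(self.map_posterior[node][s]),
                })
        return pd.DataFrame(rows)


def _map_with_alpha_ties(post: np.ndarray, alpha_rank: np.ndarray):
    """Row-wise argmax; near-ties (1e-12) resolved alphabetically."""
    best = post.max(axis=1, keepdims=True)
    tied = post >= best - 1e-12
    n_ties = int((tied.sum(axis=1) > 1).sum())
    rank = np.where(tied, alpha_rank[None, :], np.iinfo(np.int64).max)
    states = rank.argmin(axis=1)
    return states.astype(np.intp), n_ties


def marginal_reconstruction(tree: PhyloTree, aa_alignment: Alignment,
                            model: SubstitutionModel) -> AncestralReconstruction:
    """Empirical-Bayes marginal posteriors at every internal node."""
    if not np.all(np.isfinite(tree.branch_length)):
        raise LikelihoodError("tree has non-finite branch lengths; fit them "
                              "before reconstructing")
    leaf_names = tree.leaf_labels
    states = leaf_state_matrix(aa_alignment, model, leaf_names)
    patterns, _, inverse = compress_patterns(states)
    ws = _Workspace.build(tree, leaf_names)
    npat = patterns.shape[1]
    S = model.n_states
    rates, weights = model.heterogeneity.rates_and_weights()
    internal = [n for n in range(tree.n_nodes) if not tree.is_leaf(n)]

    cat_post = {n: np.empty((len(rates), npat, S)) for n in internal}
    cat_partial = {n: np.empty((len(rates), npat, S))
                   for n in range(tree.n_nodes)}
    cat_lik = np.empty((len(rates), npat))       # w_c * L_c, up to shared scale
    log_scale_by_cat = []

    for ci, (rate, w) in enumerate(zip(rates, weights)):
        P = {n: model.transition_matrix(float(tree.branch_length[n]), rate)
             for n in range(tree.n_nodes) if n != tree.root}
        # tipward pass: scaled partials and edge messages
        partial: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        log_scale = np.zeros(npat)
        for node in tree.postorder:
            node = int(node)
            if tree.is_leaf(node):
                st = patterns[ws.leaf_row[node]]
                part = np.zeros((npat, S))
                known = st >= 0
                part[known, st[known]] = 1.0
                part[~known] = 1.0
            else:
                part = np.ones((npat, S))
                for child in tree.children[node]:
                    part *= msg[child]
                m = part.max(axis=1)
                m[m == 0] = 1.0
                part /= m[:, None]
                log_scale += np.log(m)
            partial[node] = part
            cat_partial[node][ci] = part
            if node != tree.root:
                msg[node] = part @ P[node].T
        # rootward pass
        up: dict[int, np.ndarray] = {tree.root: np.tile(model.pi, (npat, 1))}
        for node in tree.postorder[::-1]:
            node = int(node)
            if tree.is_leaf(node):
                continue
            for child in tree.children[node]:
                above = up[node].copy()
                for sib in tree.children[node]:
                    if sib != child:
                        above *= msg[sib]
                up[child] = above @ P[child]
        lik = (partial[tree.root] * up[tree.root]).sum(axis=1)
        cat_lik[ci] = w * lik
        log_scale_by_cat.append(log_scale)
        for n in internal:
            num = partial[n] * up[n]
            tot = num.sum(axis=1, keepdims=True)
            tot[tot == 0] = 1.0
            cat_post[n][ci] = num / tot

    # category weights need the true (unscaled) relative likelihoods
    log_scale_by_cat = np.array(log_scale_by_cat)         # (ncat, npat)
    shift = log_scale_by_cat.max(axis=0)
    scaled = cat_lik * np.exp(log_scale_by_cat - shift)
    denom = scaled.sum(axis=0)
    if np.any(denom <= 0):
        bad = int(np.flatnonzero(denom[inverse] <= 0)[0])
        raise LikelihoodError(f"zero likelihood at site {bad}")
    cat_w_pat = (scaled / denom).T                        # (npat, ncat)

    # deterministic MAP tie-break: alphabetically first state wins
    alpha_rank = np.argsort(np.argsort(model.states))
    posterior, cat_posterior, map_state, map_post = {}, {}, {}, {}
    ties = 0
    for n in internal:
        mixed_pat = np.einsum("pc,cps->ps", cat_w_pat, cat_post[n])
        mixed = mixed_pat[inverse]
        posterior[n] = mixed
        cat_posterior[n] = cat_post[n][:, inverse, :]
        st, t = _map_with_alpha_ties(mixed, alpha_rank)
        map_state[n] = st
        map_post[n] = mixed[np.arange(len(st)), st]
        ties += t

    n_sites = states.shape[1]
    if aa_alignment.reference_map is not None:
        site_numbers = aa_alignment.reference_map.copy()
    else:
        site_numbers = np.arange(1, n_sites + 1)
    return AncestralReconstruction(
        tree=tree, model=model, n_sites=n_sites, site_numbers=site_numbers,
        posterior=posterior, cat_posterior=cat_posterior,
        cat_weights=cat_w_pat[inverse], cat_rates=rates,
        cat_partial={n: a[:, inverse, :] for n, a in cat_partial.items()},
        map_state=map_state, map_posterior=map_post, n_map_ties=ties)


# -- per-branch substitutions ----------------------------------------------

@dataclass(frozen=True)
class BranchSubstitution:
    branch: int                  # node index below the branch
    site: int                    # 1-based (reference numbering when known)
    parent_state: str
    child_state: str
    parent_posterior: float
    child_posterior: float       # 1.0 at leaves
    low_confidence: bool = False

    @property
    def notation(self) -> str:
        return f"{self.parent_state}{self.site}{self.child_state}"


@dataclass
class SubstitutionScan:
    substitutions: list[BranchSubstitution]
    n_skipped_missing: int

    def on_branch(self, branch: int) -> list[BranchSubstitution]:
        return [s for s in self.substitutions if s.branch == branch]


def branch_substitutions(recon: AncestralReconstruction, tree: PhyloTree,
                         aa_alignment: Alignment,
                         p_min: float = 0.7) -> SubstitutionScan:
    """MAP(parent) vs child comparison on every branch and site.

    Child state is the observed residue at leaves (missing ones are skipped
    and tallied) and the MAP state at internal nodes.  Either endpoint's MAP
    posterior below ``p_min`` flags the record low-confidence; it is retained.
    """
    state_index = {s: i for i, s in enumerate(recon.model.states)}
    leaf_names = tree.leaf_labels
    states = leaf_state_matrix(aa_alignment, recon.model, leaf_names)
    order = {name: i for i, name in enumerate(leaf_names)}
    out: list[BranchSubstitution] = []
    skipped = 0
    for node in range(tree.n_nodes):
        parent = int(tree.parent[node])
        if parent < 0:
            continue
        p_map = recon.map_state[parent]
        p_post = recon.map_posterior[parent]
        if tree.is_leaf(node):
            child_states = states[order[tree.labels[node]]]
            child_post = np.ones(recon.n_sites)
        else:
            child_states = recon.map_state[node]
            child_post = recon.map_posterior[node]
        for s in range(recon.n_sites):
            cs = int(child_states[s])
            if cs < 0:
                skipped += 1
                continue
            ps = int(p_map[s])
            if ps == cs:
                continue
            out.append(BranchSubstitution(
                branch=node, site=int(recon.site_numbers[s]),
                parent_state=recon.model.states[ps],
                child_state=recon.model.states[cs],
                parent_posterior=float(p_post[s]),
                child_posterior=float(child_post[s]),
                low_confidence=(p_post[s] < p_min or child_post[s] < p_min)))
    return SubstitutionScan(out, skipped)
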