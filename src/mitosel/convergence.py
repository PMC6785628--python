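"""Convergent/parallel substitution detection and significance testing.

Two branches share a *parallel* change at a site when the same ancestral
residue gave rise to the same derived residue on both; a *convergent* change
when different ancestral residues arrived at the same derived residue (which
must differ from both ancestors — if it equals one of them, only one branch
actually changed).  Significance follows the expected-count approach: under
the fitted substitution model each site contributes a small probability of
showing a parallel (or convergent) pattern on a given branch pair, the number
of such sites is a sum of independent Bernoullis (Poisson-binomial), and the
p-value is the upper tail of that distribution at the observed count.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ancestral import AncestralReconstruction, BranchSubstitution
from .trees import PhyloTree

PARALLEL, CONVERGENT, NONE = "parallel", "convergent", "none"


class ConvergenceError(ValueError):
    pass


@dataclass(frozen=True)
class ConvergenceEvent:
    gene: str | None
    site: int
    branches: tuple[int, int]
    ancestral: tuple[str, str]
    derived: str
    type: str                         # parallel | convergent

    @property
    def notation(self) -> str:
        a1, a2 = self.ancestral
        anc = a1 if a1 == a2 else f"{a1}/{a2}"
        return f"{anc}{self.site}{self.derived}"


@dataclass
class PairTestResult:
    branches: tuple[int, int]
    n_parallel: int
    n_convergent: int
    expected_parallel: float
    expected_convergent: float
    p_parallel: float
    p_convergent: float

    @property
    def stars_parallel(self) -> str:
        return significance_stars(self.p_parallel)

    @property
    def stars_convergent(self) -> str:
        return significance_stars(self.p_convergent)


def significance_stars(p: float) -> str:
    """The usual bands: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# -- event classification --------------------------------------------------

def classify_change_pair(sub1: BranchSubstitution,
                         sub2: BranchSubstitution) -> str:
    """Parallel / convergent / none for two same-site substitutions."""
    if sub1.site != sub2.site:
        raise ConvergenceError("substitutions are at different sites")
    if sub1.child_state != sub2.child_state:
        return NONE
    d = sub1.child_state
    a1, a2 = sub1.parent_state, sub2.parent_state
    if a1 == a2:
        return PARALLEL if d != a1 else NONE
    if d in (a1, a2):
        return NONE
    return CONVERGENT


def scan_branch_pairs(recon: AncestralReconstruction, tree: PhyloTree,
                      focal_branches: list[int],
                      substitutions: list[BranchSubstitution],
                      gene: str | None = None
                      ) -> dict[tuple[int, int], list[ConvergenceEvent]]:
    """All convergent/parallel events for every unordered non-nested pair."""
    focal = sorted(set(int(b) for b in focal_branches))
    if len(focal) < 2:
        raise ConvergenceError("need at least two focal branches to compare")
    by_branch: dict[int, dict[int, BranchSubstitution]] = {b: {} for b in focal}
    for sub in substitutions:
        if sub.branch in by_branch:
            by_branch[sub.branch][sub.site] = sub
    out: dict[tuple[int, int], list[ConvergenceEvent]] = {}
    for b1, b2 in combinations(focal, 2):
        if tree.on_same_path(b1, b2):
            import warnings
            warnings.warn(f"branches {b1} and {b2} lie on one root-to-tip "
                          "path; changes are not independent — pair skipped",
                          stacklevel=2)
            continue
        events = []
        shared_sites = sorted(set(by_branch[b1]) & set(by_branch[b2]))
        for site in shared_sites:
            s1, s2 = by_branch[b1][site], by_branch[b2][site]
            kind = classify_change_pair(s1, s2)
            if kind != NONE:
                events.append(ConvergenceEvent(
                    gene=gene, site=site, branches=(b1, b2),
                    ancestral=(s1.parent_state, s2.parent_state),
                    derived=s1.child_state, type=kind))
        out[(b1, b2)] = events
    return out


# -- per-site pattern probabilities ----------------------------------------

def _exclusive_parent_posterior(recon: AncestralReconstruction, parent: int,
                                branch: int, cat: int,
                                P: np.ndarray) -> np.ndarray:
    """Parent-state posterior with the focal subtree's evidence removed.

    The inclusive per-category posterior factorises as (rootward message x
    product of child messages); dividing out the focal child's message
    ``partial_child @ P.T`` leaves the posterior given all other data.
    """
    q_incl = recon.cat_posterior[parent][cat]
    msg = recon.cat_partial[branch][cat] @ P.T
    with np.errstate(divide="ignore", invalid="ignore"):
        q = q_incl / msg
    q[~np.isfinite(q)] = 0.0
    tot = q.sum(axis=1, keepdims=True)
    tot[tot <= 0] = 1.0
    return q / tot

def per_site_pair_probabilities(tree: PhyloTree, recon: AncestralReconstruction,
                                pair: tuple[int, int]) -> np.ndarray:
    """(n_sites, 2) probabilities of a parallel / convergent pattern.

    For branch lengths t1, t2, parent-state posteriors q1, q2 and transition
    matrices P1, P2 (per rate category c, weighted by the category's
    posterior):

        P_par  = sum_a q1(a) q2(a) sum_{x != a} P1[a,x] P2[a,x]
        P_conv = sum_{a1 != a2} q1(a1) q2(a2) sum_{x not in {a1,a2}}
                 P1[a1,x] P2[a2,x]

    Each parent posterior *excludes* the evidence from its own focal subtree
    (the message up the focal branch is divided out).  With the inclusive
    posterior the derived state would be counted twice — once inside q and
    once in P(a -> x) — inflating the expected counts and making the test
    anticonservative; the exclusive form is what the Bernoulli factorisation
    above actually assumes.
    """
    b1, b2 = pair
    if tree.on_same_path(b1, b2):
        raise ConvergenceError(f"branches {b1} and {b2} are nested")
    model = recon.model
    t1 = float(tree.branch_length[b1])
    t2 = float(tree.branch_length[b2])
    par1, par2 = int(tree.parent[b1]), int(tree.parent[b2])
    n_sites = recon.n_sites
    out = np.zeros((n_sites, 2))
    for ci, rate in enumerate(recon.cat_rates):
        w = recon.cat_weights[:, ci]
        P1 = model.transition_matrix(t1, rate)
        P2 = model.transition_matrix(t2, rate)
        q1 = _exclusive_parent_posterior(recon, par1, b1, ci, P1)
        q2 = _exclusive_parent_posterior(recon, par2, b2, ci, P2)
        # parallel: same ancestor a, same derived x != a on both branches
        m = (P1 * P2).sum(axis=1) - np.diag(P1) * np.diag(P2)
        out[:, 0] += w * ((q1 * q2) @ m)
        # convergent: ancestors a1 != a2, derived x outside {a1, a2}
        C = P1 @ P2.T
        C -= np.outer(np.diag(P1), np.ones(model.n_states)) * P2.T
        C -= P1 * np.diag(P2)[None, :]
        bilinear = np.einsum("sa,ab,sb->s", q1, C, q2)
        diag_part = (q1 * q2) @ np.diag(C)
        out[:, 1] += w * (bilinear - diag_part)
    return np.clip(out, 0.0, 1.0)


# -- significance ----------------------------------------------------------

def poisson_binomial_tail(n: int, probs: np.ndarray) -> tuple[float, float]:
    """(P(N >= n), P(N = n)) for N a sum of independent Bernoulli(probs).

    Exact dynamic-programming convolution truncated at n successes.
    """
    probs = np.asarray(probs, dtype=float)
    # dist[k] = P(exactly k successes so far), overflow absorbs >= n
    dist = np.zeros(n + 1)
    dist[0] = 1.0
    overflow = 0.0
    for p in probs:
        overflow += dist[n] * p
        dist[1:] = dist[1:] * (1.0 - p) + dist[:-1] * p
        dist[0] *= 1.0 - p
    p_eq = float(dist[n])
    p_ge = float(dist[n] + overflow)
    return min(p_ge, 1.0), p_eq


def convergence_significance(observed_n: int, per_site_probs: np.ndarray,
                             method: str = "auto", adjust: str | None = None,
                             rng: np.random.Generator | None = None) -> float:
    """Upper-tail p-value P(N >= observed) for a convergence/parallel count.

    Exact Poisson-binomial for <= 10,000 sites, Poisson approximation with
    mean E = sum(probs) beyond that (or on request).  ``adjust`` options:
    ``mid`` (mid-p: half the point mass) and ``randomized`` (uniform smear,
    exactly U(0,1) under the null; needs ``rng``).
    """
    probs = np.asarray(per_site_probs, dtype=float)
    if observed_n < 0:
        raise ConvergenceError("observed count cannot be negative")
    if observed_n > probs.size:
        raise ConvergenceError(
            f"observed count {observed_n} exceeds {probs.size} sites")
    if np.any((probs < 0) | (probs > 1)):
        raise ConvergenceError("per-site probabilities must lie in [0, 1]")
    if observed_n == 0:
        p_ge, p_eq = 1.0, float(np.prod(1.0 - probs))
    elif method == "poisson" or (method == "auto" and probs.size > 10_000):
        from scipy.stats import poisson
        E = float(probs.sum())
        p_ge = float(poisson.sf(observed_n - 1, E))
        p_eq = float(poisson.pmf(observed_n, E))
    else:
        p_ge, p_eq = poisson_binomial_tail(observed_n, probs)
    if adjust is None:
        return p_ge
    if adjust == "mid":
        return p_ge - 0.5 * p_eq
    if adjust == "randomized":
        if rng is None:
            raise ConvergenceError("randomized adjustment needs an rng")
        return p_ge - float(rng.uniform()) * p_eq
    raise ConvergenceError(f"unknown adjustment {adjust!r}")


def branch_pair_test(recon: AncestralReconstruction, tree: PhyloTree,
                     pair: tuple[int, int],
                     events: list[ConvergenceEvent],
                     adjust: str | None = None,
                     rng: np.random.Generator | None = None) -> PairTestResult:
    """Observed vs expected parallel/convergent counts for one branch pair."""
    probs = per_site_pair_probabilities(tree, recon, pair)
    n_par = sum(1 for e in events if e.type == PARALLEL)
    n_conv = sum(1 for e in events if e.type == CONVERGENT)
    return PairTestResult(
        branches=pair, n_parallel=n_par, n_convergent=n_conv,
        expected_parallel=float(probs[:, 0].sum()),
        expected_convergent=float(probs[:, 1].sum()),
        p_parallel=convergence_significance(n_par, probs[:, 0],
                                            adjust=adjust, rng=rng),
        p_convergent=convergence_significance(n_conv, probs[:, 1],
                                              adjust=adjust, rng=rng))
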