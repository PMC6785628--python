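"""GY94-style codon models and the two gene-level selection tests.

Implements the one-ratio model (a single dN/dS ratio omega shared by all
branches and sites) and branch-site Model A with its fixed-omega2 null, the
chi-square likelihood-ratio test between them, and naive-empirical-Bayes
per-site class posteriors.  Substitutions touching more than one codon
position have rate zero; single-position changes are scaled by kappa for
transitions and by omega when they alter the amino acid, with synonymy defined
by the vertebrate mitochondrial code.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import Alignment
from .code_tables import NT_INDEX, VERTEBRATE_MT, GeneticCode, genetic_code
from .likelihood import (_Workspace, compress_patterns, leaf_state_matrix,
                         pattern_likelihoods)
from .models import SubstitutionModel, UNIFORM_RATES
from .trees import PhyloTree

_T_LO, _T_HI = 1e-8, 50.0


class SelectionError(ValueError):
    pass


# -- codon frequencies -----------------------------------------------------

def codon_frequencies(alignment: Alignment, mode: str = "F3x4",
                      code: GeneticCode | None = None) -> np.ndarray:
    """Equilibrium sense-codon frequencies (F3x4 default, F1x4, equal)."""
    code = code or genetic_code(VERTEBRATE_MT)
    n = code.n_codons
    mode = mode.upper()
    if mode == "EQUAL":
        return np.full(n, 1.0 / n)
    counts = np.zeros((3, 4))
    for name in alignment.names:
        seq = alignment.sequence(name)
        for i, ch in enumerate(seq):
            j = NT_INDEX.get(ch)
            if j is not None:
                counts[i % 3, j] += 1
    counts += 0.5                      # pseudocount guards empty positions
    if mode == "F1X4":
        f = counts.sum(axis=0)
        counts = np.tile(f, (3, 1))
    elif mode != "F3X4":
        raise SelectionError(f"unknown frequency mode {mode!r}")
    counts /= counts.sum(axis=1, keepdims=True)
    pi = np.array([counts[0, NT_INDEX[c[0]]]
                   * counts[1, NT_INDEX[c[1]]]
                   * counts[2, NT_INDEX[c[2]]] for c in code.codons])
    return pi / pi.sum()


# -- rate matrices ---------------------------------------------------------

def codon_generator(kappa: float, omega: float, pi: np.ndarray,
                    code: GeneticCode | None = None, scale: bool = True):
    """GY94 generator; if ``scale`` normalise to mean rate 1, else return
    ``(Q, mu)`` with mu the equilibrium mean rate of the unscaled matrix."""
    code = code or genetic_code(VERTEBRATE_MT)
    if kappa <= 0 or omega < 0:
        raise SelectionError("kappa must be > 0 and omega >= 0")
    ii, jj, ts, nonsyn = code.single_change_pairs()
    n = code.n_codons
    Q = np.zeros((n, n))
    rate = pi[jj] * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    Q[ii, jj] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if scale:
        return Q / mu
    return Q, mu


def codon_rate_matrix(kappa: float, omega: float, pi: np.ndarray,
                      code: GeneticCode | None = None) -> np.ndarray:
    """Mean-rate-1 GY94 generator (time in expected substitutions/codon)."""
    return codon_generator(kappa, omega, pi, code, scale=True)


def codon_model(kappa: float, omega: float, pi: np.ndarray,
                code: GeneticCode | None = None) -> SubstitutionModel:
    code = code or genetic_code(VERTEBRATE_MT)
    Q = codon_rate_matrix(kappa, omega, pi, code)
    return SubstitutionModel(list(code.codons), Q, pi, UNIFORM_RATES,
                             name=f"GY94(kappa={kappa:g},omega={omega:g})")


# -- fit results -----------------------------------------------------------

@dataclass
class OneRatioFit:
    kappa: float
    omega: float
    pi: np.ndarray
    tree: PhyloTree
    lnl: float
    freq_mode: str
    degenerate: bool = False
    n_evaluations: int = 0


@dataclass
class BranchSiteFit:
    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float
    pi: np.ndarray
    tree: PhyloTree
    lnl: float
    foreground: tuple[int, ...]
    null: bool
    converged: bool
    freq_mode: str
    site_class_likelihoods: np.ndarray = field(repr=False)  # (n_sites, 4)
    n_starts: int = 0

    @property
    def p2a(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = 1.0 - self.p0 - self.p1
        return rest * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


# -- shared fitting machinery ----------------------------------------------

class _CodonEngine:
    """Pattern-compressed codon likelihood with cached eigendecompositions."""

    def __init__(self, tree: PhyloTree, alignment: Alignment,
                 pi: np.ndarray, code: GeneticCode):
        self.tree = tree
        self.code = code
        self.pi = np.clip(pi, 1e-10, None)
        self.pi /= self.pi.sum()
        self.sq = np.sqrt(self.pi)
        leaf_names = tree.leaf_labels
        probe = codon_model(2.0, 1.0, self.pi, code)
        states = leaf_state_matrix(alignment, probe, leaf_names)
        self.states = states
        self.patterns, self.pat_weights, self.inverse = compress_patterns(states)
        self.ws = _Workspace.build(tree, leaf_names)
        self.edges = [n for n in range(tree.n_nodes) if n != tree.root]
        self.n_sites = states.shape[1]
        self.evals = 0
        self._eig_cache: dict[tuple[float, float], tuple] = {}

    def eig(self, kappa: float, omega: float):
        key = (round(kappa, 12), round(omega, 12))
        hit = self._eig_cache.get(key)
        if hit is not None:
            return hit
        Q, mu = codon_generator(kappa, omega, self.pi, self.code, scale=False)
        sym = (self.sq[:, None] * Q) / self.sq[None, :]
        lam, U = linalg.eigh((sym + sym.T) / 2.0)
        R = U / self.sq[:, None]
        L = U.T * self.sq[None, :]
        out = (lam, R, L, mu)
        if len(self._eig_cache) > 64:
            self._eig_cache.clear()
        self._eig_cache[key] = out
        return out

    def P(self, eig, t: float) -> np.ndarray:
        lam, R, L, _ = eig
        P = (R * np.exp(lam * t)) @ L
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def class_pattern_likelihoods(self, P_by_node: dict[int, np.ndarray]):
        return pattern_likelihoods(self.tree, self.patterns, P_by_node,
                                   self.pi, self.ws, scale=True)

    def has_variation(self) -> bool:
        obs = self.states
        for col in obs.T:
            known = col[col >= 0]
            if known.size and np.any(known != known[0]):
                return True
        return False


def _set_lengths(tree: PhyloTree, edges, lengths) -> PhyloTree:
    out = tree.copy()
    for e, t in zip(edges, lengths):
        out.branch_length[e] = t
    return out


# -- one-ratio model (M0) --------------------------------------------------

def fit_one_ratio(tree: PhyloTree, alignment: Alignment,
                  freq_mode: str = "F3x4", code_id: int = VERTEBRATE_MT,
                  tol: float = 1e-6) -> OneRatioFit:
    """Jointly fit kappa, a single omega, and all branch lengths by ML."""
    code = genetic_code(code_id)
    pi = codon_frequencies(alignment, freq_mode, code)
    eng = _CodonEngine(tree, alignment, pi, code)
    if not eng.has_variation():
        fitted = _set_lengths(tree, eng.edges, np.zeros(len(eng.edges)))
        P = {e: np.eye(code.n_codons) for e in eng.edges}
        lik, ls = eng.class_pattern_likelihoods(P)
        lnl = float(np.dot(eng.pat_weights, np.log(lik) + ls))
        return OneRatioFit(np.nan, np.nan, eng.pi, fitted, lnl, freq_mode,
                           degenerate=True)

    edges = eng.edges

    def negloglik(x):
        eng.evals += 1
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        lengths = np.exp(x[2:])
        eig = eng.eig(kappa, omega)
        mu = eig[3]
        P = {e: eng.P(eig, t * 1.0 / mu) for e, t in zip(edges, lengths)}
        lik, ls = eng.class_pattern_likelihoods(P)
        with np.errstate(divide="ignore"):
            lnl = np.dot(eng.pat_weights, np.log(lik) + ls)
        return 1e12 if not np.isfinite(lnl) else -lnl

    from .likelihood import _p_distance_scale
    t0 = _p_distance_scale(eng.states)
    lo, hi = np.log(_T_LO), np.log(_T_HI)
    bounds = [(np.log(0.05), np.log(100.0)), (np.log(1e-4), np.log(40.0))]
    bounds += [(lo, hi)] * len(edges)
    best = None
    for tscale in (t0, 0.1 * t0):
        x0 = np.concatenate([[np.log(2.0), np.log(0.4)],
                             np.full(len(edges),
                                     np.log(np.clip(tscale, _T_LO, _T_HI)))])
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    fitted = _set_lengths(tree, edges, np.exp(best.x[2:]))
    return OneRatioFit(kappa, omega, eng.pi, fitted, -float(best.fun),
                       freq_mode, degenerate=False, n_evaluations=eng.evals)


# -- branch-site Model A ---------------------------------------------------

def _branch_site_class_liks(eng: _CodonEngine, fg: set[int], kappa, p0, p1,
                            omega0, omega2, lengths):
    """Per-pattern likelihood for each of the 4 Model A site classes.

    All class matrices share one scale: the proportion-weighted mean rate of
    the background process, so a branch length is the expected number of
    substitutions per codon for a background-average site.
    """
    eig0 = eng.eig(kappa, omega0)
    eig1 = eng.eig(kappa, 1.0)
    eig2 = eng.eig(kappa, omega2)
    rest = 1.0 - p0 - p1
    p2a = rest * p0 / (p0 + p1)
    p2b = rest * p1 / (p0 + p1)
    mu = (p0 + p2a) * eig0[3] + (p1 + p2b) * eig1[3]
    P0, P1, P2 = {}, {}, {}
    for e, t in zip(eng.edges, lengths):
        tau = t / mu
        P0[e] = eng.P(eig0, tau)
        P1[e] = eng.P(eig1, tau)
        P2[e] = eng.P(eig2, tau) if e in fg else None
    class_liks, class_scales = [], []
    # classes: (background eig-P, foreground eig-P)
    for bg, fg_P in ((P0, P0), (P1, P1), (P0, P2), (P1, P2)):
        P = {e: (fg_P[e] if (e in fg and fg_P[e] is not None) else bg[e])
             for e in eng.edges}
        lik, ls = eng.class_pattern_likelihoods(P)
        class_liks.append(lik)
        class_scales.append(ls)
    props = np.array([p0, p1, p2a, p2b])
    return np.array(class_liks), np.array(class_scales), props


def _mix_lnl(class_liks, class_scales, props, pat_weights):
    shift = class_scales.max(axis=0)
    mixed = np.einsum("c,cp->p", props,
                      class_liks * np.exp(class_scales - shift))
    with np.errstate(divide="ignore"):
        lnl = np.dot(pat_weights, np.log(mixed) + shift)
    return lnl


def fit_branch_site(tree: PhyloTree, alignment: Alignment,
                    foreground: list[int] | None = None, null: bool = False,
                    share_lengths: bool = False, freq_mode: str = "F3x4",
                    code_id: int = VERTEBRATE_MT, tol: float = 1e-6,
                    init: OneRatioFit | None = None,
                    warm: "BranchSiteFit | None" = None) -> BranchSiteFit:
    """Fit branch-site Model A (or its omega2=1 null) on foreground branches.

    ``foreground`` are node indices whose parent branch is foreground; when
    omitted the tree's ``#k`` tags are used.  By default branch lengths are
    re-optimised jointly with the model; ``share_lengths`` keeps them fixed at
    a one-ratio prefit (``init``), which is much faster.  ``warm`` adds extra
    optimizer starts at another fit's solution — seeding the alternative from
    the null guards against the boundary local optima this likelihood surface
    is known for.
    """
    code = genetic_code(code_id)
    if foreground is None:
        foreground = tree.foreground_nodes()
    fg = {int(f) for f in foreground}
    if not fg:
        raise SelectionError("no foreground branches given or tagged")
    bad = fg - set(range(tree.n_nodes))
    if bad or tree.root in fg:
        raise SelectionError(f"invalid foreground branches: {sorted(bad)}")

    if init is None:
        init = fit_one_ratio(tree, alignment, freq_mode, code_id, tol=tol)
    pi = init.pi
    eng = _CodonEngine(tree, alignment, pi, code)
    edges = eng.edges
    base_lengths = np.array([init.tree.branch_length[e] for e in edges])
    base_lengths = np.clip(base_lengths, _T_LO, _T_HI)
    kappa0 = init.kappa if np.isfinite(init.kappa) else 2.0
    w0_init = min(max(init.omega if np.isfinite(init.omega) else 0.3, 0.01),
                  0.9)

    free_lengths = not share_lengths

    def unpack(x):
        kappa = np.exp(x[0])
        a0, a1 = x[1], x[2]
        m = max(a0, a1, 0.0)
        z = np.exp(a0 - m) + np.exp(a1 - m) + np.exp(-m)
        p0 = np.exp(a0 - m) / z
        p1 = np.exp(a1 - m) / z
        omega0 = 1.0 / (1.0 + np.exp(-x[3]))
        omega2 = 1.0 if null else 1.0 + np.exp(x[4])
        lengths = np.exp(x[5 if not null else 4:]) if free_lengths \
            else base_lengths
        return kappa, p0, p1, omega0, omega2, lengths

    def negloglik(x):
        eng.evals += 1
        kappa, p0, p1, omega0, omega2, lengths = unpack(x)
        try:
            cl, cs, props = _branch_site_class_liks(
                eng, fg, kappa, p0, p1, omega0, omega2, lengths)
        except (ValueError, linalg.LinAlgError):
            return 1e12
        lnl = _mix_lnl(cl, cs, props, eng.pat_weights)
        return 1e12 if not np.isfinite(lnl) else -lnl

    def pack(kappa, p0, p1, omega0, omega2):
        p2 = max(1.0 - p0 - p1, 1e-9)
        a0 = np.log(p0 / p2)
        a1 = np.log(p1 / p2)
        x = [np.log(kappa), a0, a1,
             np.log(omega0 / (1.0 - omega0))]
        if not null:
            x.append(np.log(max(omega2 - 1.0, 1e-8)))
        if free_lengths:
            x.extend(np.log(base_lengths))
        return np.array(x)

    starts = []
    for p2 in (0.05, 0.2):
        p0s = (1.0 - p2) * 0.7
        p1s = (1.0 - p2) * 0.3
        if null:
            starts.append(pack(kappa0, p0s, p1s, w0_init, 1.0))
        else:
            for w2 in (1.5, 5.0):
                starts.append(pack(kappa0, p0s, p1s, w0_init, w2))
    if warm is not None:
        p0w = min(max(warm.p0, 1e-7), 1 - 2e-7)
        p1w = min(max(warm.p1, 1e-7), 1 - p0w - 1e-7)
        w0w = min(max(warm.omega0, 1e-5), 1 - 1e-5)
        for w2 in ((1.0,) if null else (1.0 + 1e-8, 3.0)):
            starts.append(pack(warm.kappa, p0w, p1w, w0w, w2))

    bounds = [(np.log(0.05), np.log(100.0)), (-25.0, 25.0), (-25.0, 25.0),
              (-12.0, 12.0)]
    if not null:
        bounds.append((np.log(1e-9), np.log(999.0)))
    if free_lengths:
        bounds += [(np.log(_T_LO), np.log(_T_HI))] * len(edges)

    best = None
    for x0 in starts:
        res = minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxiter": 1000})
        if best is None or res.fun < best.fun:
            best = res
    kappa, p0, p1, omega0, omega2, lengths = unpack(best.x)
    fitted = _set_lengths(tree, edges, lengths)
    cl, cs, props = _branch_site_class_liks(eng, fg, kappa, p0, p1,
                                            omega0, omega2, lengths)
    # expand per-pattern class likelihoods (log scale folded in) to sites
    shift = cs.max(axis=0)
    site_cl = (cl * np.exp(cs - shift))[:, eng.inverse].T
    lnl = -float(best.fun)
    return BranchSiteFit(
        kappa=float(kappa), p0=float(p0), p1=float(p1),
        omega0=float(omega0), omega2=float(omega2), pi=eng.pi, tree=fitted,
        lnl=lnl, foreground=tuple(sorted(fg)), null=null,
        converged=bool(np.isfinite(best.fun) and best.fun < 1e12),
        freq_mode=freq_mode, site_class_likelihoods=site_cl,
        n_starts=len(starts))


def branch_site_test(tree: PhyloTree, alignment: Alignment,
                     foreground: list[int] | None = None,
                     share_lengths: bool = False, freq_mode: str = "F3x4",
                     code_id: int = VERTEBRATE_MT,
                     init: OneRatioFit | None = None):
    """Null and alternative Model A fits plus the df=1 LRT.

    Returns ``(null_fit, alt_fit, LRTResult)``.  The alternative is warm-
    started from the null optimum in addition to the grid of multi-starts.
    """
    if init is None:
        init = fit_one_ratio(tree, alignment, freq_mode, code_id)
    null = fit_branch_site(tree, alignment, foreground, null=True,
                           share_lengths=share_lengths, freq_mode=freq_mode,
                           code_id=code_id, init=init)
    alt = fit_branch_site(tree, alignment, foreground, null=False,
                          share_lengths=share_lengths, freq_mode=freq_mode,
                          code_id=code_id, init=init, warm=null)
    return null, alt, likelihood_ratio_test(null.lnl, alt.lnl, df=1)


# -- LRT and posteriors ----------------------------------------------------

def likelihood_ratio_test(lnl_null: float, lnl_alt: float, df: int = 1,
                          mixture: bool = False) -> LRTResult:
    """2*(lnL_alt - lnL_null) against chi2_df (optionally the 50:50
    chi2_0:chi2_1 boundary mixture); negative differences clamp to 0."""
    if df < 1:
        raise SelectionError("df must be >= 1")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    if mixture and df == 1:
        p = 0.5 * chi2.sf(stat, 1) if stat > 0 else 1.0
    else:
        p = chi2.sf(stat, df) if stat > 0 else 1.0
    return LRTResult(statistic=stat, df=df, p_value=float(min(1.0, p)))


def site_class_posteriors(fit: BranchSiteFit) -> np.ndarray:
    """(n_sites, 4) NEB posterior over classes {0, 1, 2a, 2b}."""
    if not fit.converged:
        raise SelectionError("refusing posteriors from an unconverged fit; "
                             "inspect the optimizer diagnostics")
    num = fit.site_class_likelihoods * fit.proportions[None, :]
    return num / num.sum(axis=1, keepdims=True)


def positively_selected_sites(fit: BranchSiteFit,
                              threshold: float = 0.95) -> np.ndarray:
    """Site indices with P(class 2a) + P(class 2b) >= threshold."""
    post = site_class_posteriors(fit)
    return np.flatnonzero(post[:, 2] + post[:, 3] >= threshold)
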