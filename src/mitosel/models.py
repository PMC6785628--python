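"""Continuous-time substitution models and among-site rate heterogeneity.

Models are held as a scaled generator Q (mean rate 1 at equilibrium) plus
equilibrium frequencies and an optional +I+G mixture.  Transition matrices for
time-reversible models come from a cached eigendecomposition of the
pi^{1/2}-symmetrised generator, with a scipy ``expm`` fallback otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import linalg
from scipy.stats import gamma as gamma_dist

from .code_tables import AMINO_ACIDS, NUCLEOTIDES


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-one discrete-gamma category rates (equal weights, bin means).

    The gamma(alpha, mean 1) density is cut at its k-quantiles and each
    category rate is the conditional mean of its bin, the common discretisation
    in codon/ML software.  Rates are renormalised so their average is exactly 1.
    """
    if not alpha > 0:
        raise ValueError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X in bin] via the incomplete-gamma identity: a*scale*F_{a+1}(x)
    mass = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(mass)
    if not np.all(np.isfinite(rates)) or rates.sum() <= 0:
        # extreme alpha (rate homogeneity limit): collapse to equal rates
        return np.ones(k)
    return rates / rates.mean()


@dataclass(frozen=True)
class RateHeterogeneity:
    """+I+G among-site rate mixture.

    ``p_invariant`` is the weight of a rate-0 class; the remaining mass is
    split equally over ``k`` discrete-gamma categories with shape ``alpha``.
    """

    p_invariant: float = 0.0
    alpha: float | None = None
    k: int = 4

    def __post_init__(self):
        if not 0.0 <= self.p_invariant < 1.0:
            raise ValueError("p_invariant must be in [0, 1)")

    def rates_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.k)
        weights = np.full(len(rates), (1.0 - self.p_invariant) / len(rates))
        if self.p_invariant > 0:
            rates = np.concatenate([[0.0], rates])
            weights = np.concatenate([[self.p_invariant], weights])
        return rates, weights


UNIFORM_RATES = RateHeterogeneity()


class SubstitutionModel:
    """A scaled generator over a finite state alphabet, with rate mixture."""

    def __init__(self, states: str | list[str], Q: np.ndarray, pi: np.ndarray,
                 heterogeneity: RateHeterogeneity = UNIFORM_RATES,
                 name: str = "custom"):
        Q = np.asarray(Q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        n = len(states)
        if Q.shape != (n, n) or pi.shape != (n,):
            raise ValueError("inconsistent model dimensions")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("generator rows must sum to 0")
        if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must be a probability vector")
        self.states = list(states)
        self.pi = pi / pi.sum()
        # normalise to one expected substitution per unit time at equilibrium
        mu = -float(np.dot(self.pi, np.diag(Q)))
        if mu <= 0:
            raise ValueError("degenerate generator (zero total rate)")
        self.Q = Q / mu
        self.heterogeneity = heterogeneity
        self.name = name
        self._eig = None
        self._reversible = np.allclose(
            self.pi[:, None] * self.Q, (self.pi[:, None] * self.Q).T, atol=1e-10
        )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def with_heterogeneity(self, het: RateHeterogeneity) -> "SubstitutionModel":
        return SubstitutionModel(self.states, self.Q, self.pi, het, self.name)

    def _eigendecomposition(self):
        if self._eig is None:
            sq = np.sqrt(self.pi)
            sym = (sq[:, None] * self.Q) / sq[None, :]
            lam, U = linalg.eigh((sym + sym.T) / 2.0)
            # columns of R / rows of L map eigen-space <-> state space
            R = U / sq[:, None]
            L = U.T * sq[None, :]
            self._eig = (lam, R, L)
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("time must be nonnegative")
        tau = t * rate
        if tau == 0.0:
            return np.eye(self.n_states)
        if self._reversible and np.all(self.pi > 0):
            lam, R, L = self._eigendecomposition()
            P = (R * np.exp(lam * tau)) @ L
        else:
            P = linalg.expm(self.Q * tau)
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)


# -- JSON model configs ----------------------------------------------------

def model_config(model: SubstitutionModel) -> dict:
    """JSON-serialisable description (name, parameters, I, alpha, k)."""
    het = model.heterogeneity
    cfg = {"name": model.name, "p_invariant": het.p_invariant,
           "alpha": het.alpha, "k": het.k}
    if model.n_states == 4:
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        s = model.Q / model.pi[None, :]
        cfg["exchangeabilities"] = [float(s[i, j]) for i, j in pairs]
        cfg["frequencies"] = [float(x) for x in model.pi]
    return cfg


def model_from_config(cfg: dict) -> SubstitutionModel:
    """Rebuild a model from :func:`model_config` output (or a hand-written
    config naming an empirical amino-acid model)."""
    het = RateHeterogeneity(cfg.get("p_invariant", 0.0), cfg.get("alpha"),
                            cfg.get("k", 4))
    name = cfg["name"].lower()
    if name in {"mtmam", "mtrev24"}:
        return aa_model(name, het)
    if "exchangeabilities" in cfg:
        return gtr_model(cfg["exchangeabilities"], cfg["frequencies"], het,
                         cfg["name"])
    if name.startswith("jc"):
        return jc_model(int(name[2:] or 4), het)
    raise ValueError(f"cannot rebuild model from config {cfg!r}")


# -- nucleotide models -----------------------------------------------------

def _gtr_generator(exch6, pi):
    """GTR generator from 6 exchangeabilities in order AC,AG,AT,CG,CT,GT."""
    s = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for val, (i, j) in zip(exch6, pairs):
        s[i, j] = s[j, i] = val
    Q = s * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def gtr_model(exch6, pi, heterogeneity=UNIFORM_RATES, name="GTR") -> SubstitutionModel:
    pi = np.asarray(pi, dtype=float)
    return SubstitutionModel(NUCLEOTIDES, _gtr_generator(np.asarray(exch6, float), pi),
                             pi, heterogeneity, name)


def jc_model(n_states: int = 4, heterogeneity=UNIFORM_RATES) -> SubstitutionModel:
    """Equal-rate, equal-frequency model on any alphabet size (JC69 for n=4)."""
    states = NUCLEOTIDES if n_states == 4 else [str(i) for i in range(n_states)]
    if n_states == 20:
        states = AMINO_ACIDS
    Q = np.ones((n_states, n_states))
    np.fill_diagonal(Q, 1 - n_states)
    pi = np.full(n_states, 1.0 / n_states)
    return SubstitutionModel(states, Q, pi, heterogeneity, name=f"JC{n_states}")


def trn_model(kappa1, kappa2, pi, heterogeneity=UNIFORM_RATES) -> SubstitutionModel:
    """TrN93: one transversion rate, separate A<->G and C<->T transition rates.

    Implemented as a constrained GTR parameterisation.
    """
    return gtr_model([1.0, kappa1, 1.0, 1.0, kappa2, 1.0], pi, heterogeneity, "TrN")


def tvm_model(exch_tv4, kappa, pi, heterogeneity=UNIFORM_RATES) -> SubstitutionModel:
    """TVM: four free transversion exchangeabilities, equal transition rates.

    ``exch_tv4`` orders the transversions (AC, AT, CG, GT); both transitions
    (AG, CT) share ``kappa``.  Constrained-GTR parameterisation.
    """
    a, b, c, d = exch_tv4
    return gtr_model([a, kappa, b, c, kappa, d], pi, heterogeneity, "TVM")


def hky_model(kappa, pi, heterogeneity=UNIFORM_RATES) -> SubstitutionModel:
    return gtr_model([1.0, kappa, 1.0, 1.0, kappa, 1.0], pi, heterogeneity, "HKY")


# -- empirical amino-acid models -------------------------------------------

def _load_aa_table(filename: str):
    text = resources.files("mitosel.data").joinpath(filename).read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if len(rows) != 20:
        raise ValueError(f"malformed amino-acid model table {filename}")
    S = np.zeros((20, 20))
    for i, ln in enumerate(rows[:19], start=1):
        vals = [float(x) for x in ln.split()]
        S[i, : len(vals)] = vals
    S = S + S.T
    pi = np.array([float(x) for x in rows[19].split()])
    return S, pi / pi.sum()


def aa_model(name: str = "mtmam",
             heterogeneity: RateHeterogeneity = UNIFORM_RATES,
             pi: np.ndarray | None = None) -> SubstitutionModel:
    """Empirical amino-acid model (``mtmam`` default, ``mtrev24`` selectable)."""
    key = name.lower()
    if key not in {"mtmam", "mtrev24"}:
        raise ValueError(f"unknown amino-acid model {name!r}")
    S, pi_model = _load_aa_table(f"{key}.tsv")
    pi = pi_model if pi is None else np.asarray(pi, dtype=float)
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return SubstitutionModel(AMINO_ACIDS, Q, pi, heterogeneity, name=key)
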