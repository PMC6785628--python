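"""Synthetic data with recorded ground truth.

Codon alignments are evolved on a tree by exact stochastic (Gillespie)
simulation along every branch, so the truth object carries the complete
ordered substitution history per branch and site — the currency the
convergence machinery is calibrated against.  Amino-acid alignments for
reconstruction/convergence null studies use endpoint sampling (histories are
not needed there, only true node states).

One integer seed drives a hierarchy of named independent streams (per gene,
per branch), so a fixture is stable under config edits that do not touch a
stream.
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alignment import Alignment
from .code_tables import VERTEBRATE_MT, GeneticCode, genetic_code
from .codon_selection import codon_generator
from .models import SubstitutionModel
from .trees import PhyloTree


class SimulationError(ValueError):
    pass


#: canonical six-taxon study tree for simulation experiments: three cherries,
#: with one long terminal branch (the focal "deep-sea" lineage) tagged as
#: foreground — mitochondrial-gene-scale divergences (tree length ~1.9
#: substitutions/codon)
STUDY_TREE_6 = "((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1,(e:0.2,f#1:0.5):0.1);"


def stream(seed: int, *names) -> np.random.Generator:
    """Named independent random stream derived from one master seed."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


# -- regimes ---------------------------------------------------------------

@dataclass(frozen=True)
class M0Regime:
    """Single dN/dS ratio on all branches and sites."""
    kappa: float = 2.0
    omega: float = 0.2
    name: str = "M0"


@dataclass(frozen=True)
class BranchSiteRegime:
    """Model A: classes {0: omega0, 1: neutral, 2a/2b: omega2 on foreground}.

    Defaults put 20% of sites in the foreground-selected classes — the kind
    of moderately widespread episodic signal the branch-site test is built
    to detect on a single lineage.
    """
    kappa: float = 2.0
    p0: float = 0.6
    p1: float = 0.2
    omega0: float = 0.2
    omega2: float = 4.0
    name: str = "branch_site"

    @property
    def proportions(self) -> np.ndarray:
        rest = 1.0 - self.p0 - self.p1
        return np.array([self.p0, self.p1,
                         rest * self.p0 / (self.p0 + self.p1),
                         rest * self.p1 / (self.p0 + self.p1)])


@dataclass(frozen=True)
class Event:
    branch: int
    site: int
    time: float            # along the branch, tipward from the parent node
    from_state: int        # sense-codon indices
    to_state: int


@dataclass
class SimulationTruth:
    seed: int
    regime: object
    code_id: int
    site_class: np.ndarray               # 0..3 (all 0 under M0)
    node_states: np.ndarray              # (n_nodes, n_sites) codon indices
    events: list[Event] = field(default_factory=list)

    def events_on(self, branch: int, site: int | None = None) -> list[Event]:
        return [e for e in self.events
                if e.branch == branch and (site is None or e.site == site)]

    def substitution_counts(self, code: GeneticCode | None = None):
        """(n_synonymous, n_nonsynonymous) over the whole history."""
        code = code or genetic_code(self.code_id)
        aa = code.aa_of_codon
        syn = nonsyn = 0
        for e in self.events:
            if aa[e.from_state] == aa[e.to_state]:
                syn += 1
            else:
                nonsyn += 1
        return syn, nonsyn

    def replay_leaf_states(self, tree: PhyloTree) -> np.ndarray:
        """Recompute all node states from the root states + event log."""
        n_sites = self.node_states.shape[1]
        states = np.full_like(self.node_states, -1)
        states[tree.root] = self.node_states[tree.root]
        by_branch: dict[int, list[Event]] = {}
        for e in self.events:
            by_branch.setdefault(e.branch, []).append(e)
        for node in tree.postorder[::-1]:
            node = int(node)
            if node == tree.root:
                continue
            row = states[int(tree.parent[node])].copy()
            for e in sorted(by_branch.get(node, []), key=lambda e: e.time):
                if row[e.site] != e.from_state:
                    raise SimulationError(
                        f"inconsistent history at branch {node} site {e.site}")
                row[e.site] = e.to_state
            states[node] = row
        return states


# -- codon simulation ------------------------------------------------------

def _branch_site_matrices(regime: BranchSiteRegime, pi, code):
    """Per class-and-role generators under the shared background scale."""
    Q0, mu0 = codon_generator(regime.kappa, regime.omega0, pi, code, False)
    Q1, mu1 = codon_generator(regime.kappa, 1.0, pi, code, False)
    Q2, _ = codon_generator(regime.kappa, regime.omega2, pi, code, False)
    props = regime.proportions
    mu = (props[0] + props[2]) * mu0 + (props[1] + props[3]) * mu1
    bg = [Q0 / mu, Q1 / mu, Q0 / mu, Q1 / mu]
    fg = [Q0 / mu, Q1 / mu, Q2 / mu, Q2 / mu]
    return bg, fg


def _gillespie_site(rng, Q: np.ndarray, state: int, t_total: float,
                    jump_cache: dict) -> tuple[int, list[tuple[float, int, int]]]:
    """Simulate one site along one branch; returns final state and jumps."""
    events = []
    t = 0.0
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            return state, events
        t += rng.exponential(1.0 / rate)
        if t >= t_total:
            return state, events
        probs = jump_cache.get(state)
        if probs is None:
            row = Q[state].copy()
            row[state] = 0.0
            probs = row / row.sum()
            jump_cache[state] = probs
        new = int(rng.choice(len(probs), p=probs))
        events.append((t, state, new))
        state = new


def simulate_codon_alignment(tree: PhyloTree, regime, n_codons: int,
                             seed: int, pi: np.ndarray | None = None,
                             code_id: int = VERTEBRATE_MT,
                             gene: str = "gene") -> tuple[Alignment,
                                                          SimulationTruth]:
    """Evolve an in-frame codon alignment on a tree, event by event.

    ``regime`` is an :class:`M0Regime` or :class:`BranchSiteRegime`; for the
    latter, foreground branches are the tree's tagged ones.  Codon
    frequencies default to uniform over sense codons.
    """
    if n_codons <= 0:
        raise SimulationError("n_codons must be positive")
    code = genetic_code(code_id)
    n = code.n_codons
    pi = np.full(n, 1.0 / n) if pi is None else np.asarray(pi, float)
    pi = pi / pi.sum()

    if isinstance(regime, M0Regime):
        Q = codon_generator(regime.kappa, regime.omega, pi, code, scale=True)
        bg = fg = [Q] * 4
        site_class = np.zeros(n_codons, dtype=np.intp)
    elif isinstance(regime, BranchSiteRegime):
        bg, fg = _branch_site_matrices(regime, pi, code)
        rng_cls = stream(seed, gene, "site_class")
        site_class = rng_cls.choice(4, size=n_codons, p=regime.proportions)
        if not tree.foreground_nodes():
            raise SimulationError("branch-site regime needs foreground-tagged "
                                  "branches on the tree")
    else:
        raise SimulationError(f"unknown regime {regime!r}")

    node_states = np.full((tree.n_nodes, n_codons), -1, dtype=np.intp)
    rng_root = stream(seed, gene, "root")
    node_states[tree.root] = rng_root.choice(n, size=n_codons, p=pi)
    events: list[Event] = []
    fg_set = set(tree.foreground_nodes())

    for node in tree.postorder[::-1]:
        node = int(node)
        if node == tree.root:
            continue
        rng_b = stream(seed, gene, "branch", node)
        t_total = float(tree.branch_length[node])
        matrices = fg if node in fg_set else bg
        caches = [dict() for _ in range(4)]
        parent_states = node_states[int(tree.parent[node])]
        row = np.empty(n_codons, dtype=np.intp)
        for s in range(n_codons):
            cls = int(site_class[s])
            final, jumps = _gillespie_site(rng_b, matrices[cls],
                                           int(parent_states[s]), t_total,
                                           caches[cls])
            row[s] = final
            for (t, a, b) in jumps:
                events.append(Event(node, s, t, a, b))
        node_states[node] = row

    names = tree.leaf_labels
    rows = []
    for node in tree.leaves:
        seq = "".join(code.codons[i] for i in node_states[node])
        rows.append(list(seq))
    aln = Alignment(names, np.array(rows, dtype="U1"), "nt", gene)
    truth = SimulationTruth(seed=seed, regime=regime, code_id=code_id,
                            site_class=site_class, node_states=node_states,
                            events=events)
    return aln, truth


# -- planted parallel changes ----------------------------------------------

def _aa_neighbours(code: GeneticCode) -> list[dict[str, int]]:
    """Per sense codon: {derived amino acid: a 1-nt-neighbour codon index}."""
    ii, jj, _, nonsyn = code.single_change_pairs()
    out: list[dict[str, int]] = [{} for _ in range(code.n_codons)]
    for i, j, ns in zip(ii, jj, nonsyn):
        if ns:
            out[i].setdefault(code.aa_of_codon[j], int(j))
    return out

def plant_parallel_changes(alignment: Alignment, truth: SimulationTruth,
                           tree: PhyloTree, pair: tuple[int, int], k: int,
                           seed: int, site_picker=None):
    """Force k extra parallel amino-acid changes on a branch pair.

    Eligible sites are those whose two parent nodes share the same amino
    acid, where that amino acid is conserved (fraction >= 0.7) among leaves
    outside the two focal subtrees (so ancestors are confidently inferable),
    and which offer a common derived amino acid one nucleotide away from both
    parent codons, not already present outside the focal subtrees (a
    realistic, recognisable parallel replacement).  At each chosen site
    both subtrees below the pair are overwritten with the derived codons
    (histories below are cleared so the event log replays exactly); planted
    events are recorded at the end of each branch.
    """
    if k < 0:
        raise SimulationError("k must be >= 0")
    if k == 0:
        return alignment, truth
    code = genetic_code(truth.code_id)
    aa = code.aa_of_codon
    neighbours = _aa_neighbours(code)
    b1, b2 = pair
    p1, p2 = int(tree.parent[b1]), int(tree.parent[b2])
    n_sites = truth.node_states.shape[1]
    in_focal = {v for b in (b1, b2)
                for v in [b, *[u for u in range(tree.n_nodes)
                               if tree.is_ancestor(b, u)]]}
    outside = [v for v in tree.leaves if v not in in_focal]
    eligible = []
    for s in range(n_sites):
        c1, c2 = truth.node_states[p1, s], truth.node_states[p2, s]
        if aa[c1] != aa[c2]:
            continue
        anc = aa[c1]
        out_aa = [aa[truth.node_states[v, s]] for v in outside]
        if np.mean([x == anc for x in out_aa]) < 0.7:
            continue
        shared = sorted((set(neighbours[c1]) & set(neighbours[c2]))
                        - set(out_aa))
        if shared:
            eligible.append((s, shared))
    if len(eligible) < k:
        raise SimulationError(
            f"only {len(eligible)} eligible sites for {k} planted changes "
            f"(deficit {k - len(eligible)})")
    rng = stream(seed, "plant", b1, b2)
    if site_picker is None:
        idx = rng.choice(len(eligible), size=k, replace=False)
        chosen = [eligible[i] for i in idx]
    else:
        chosen = site_picker(eligible, k)

    new_states = truth.node_states.copy()
    new_events = list(truth.events)
    data = alignment.data.copy()
    name_row = {n: i for i, n in enumerate(alignment.names)}
    for s, shared in chosen:
        derived = shared[int(rng.integers(len(shared)))]
        below_all = set()
        for b, parent in ((b1, p1), (b2, p2)):
            parent_codon = int(truth.node_states[parent, s])
            codon_idx = neighbours[parent_codon][derived]
            below = {b} | {v for v in range(tree.n_nodes)
                           if tree.is_ancestor(b, v)}
            below_all |= below
            new_events = [e for e in new_events
                          if not (e.site == s and e.branch in below)]
            new_events.append(Event(b, s, float(tree.branch_length[b]),
                                    parent_codon, codon_idx))
            for v in below:
                new_states[v, s] = codon_idx
                if tree.is_leaf(v):
                    r = name_row[tree.labels[v]]
                    data[r, 3 * s: 3 * s + 3] = list(code.codons[codon_idx])
    new_aln = Alignment(list(alignment.names), data, alignment.alphabet,
                        alignment.gene)
    new_truth = SimulationTruth(seed=truth.seed, regime=truth.regime,
                                code_id=truth.code_id,
                                site_class=truth.site_class.copy(),
                                node_states=new_states, events=new_events)
    return new_aln, new_truth


# -- amino-acid simulation (endpoint sampling) ------------------------------

def simulate_aa_alignment(tree: PhyloTree, model: SubstitutionModel,
                          n_sites: int, seed: int):
    """Amino-acid alignment + true node states under a +G mixture model."""
    if n_sites <= 0:
        raise SimulationError("n_sites must be positive")
    rates, weights = model.heterogeneity.rates_and_weights()
    rng = stream(seed, "aa", "root")
    cats = rng.choice(len(rates), size=n_sites, p=weights)
    S = model.n_states
    states = np.full((tree.n_nodes, n_sites), -1, dtype=np.intp)
    states[tree.root] = rng.choice(S, size=n_sites, p=model.pi)
    for node in tree.postorder[::-1]:
        node = int(node)
        if node == tree.root:
            continue
        rng_b = stream(seed, "aa", "branch", node)
        t = float(tree.branch_length[node])
        parent = states[int(tree.parent[node])]
        row = parent.copy()
        for ci, rate in enumerate(rates):
            mask = cats == ci
            if not mask.any():
                continue
            P = model.transition_matrix(t, rate)
            cum = P.cumsum(axis=1)
            u = rng_b.random(mask.sum())
            rows = cum[parent[mask]]
            row[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = row
    names = tree.leaf_labels
    data = []
    for node in tree.leaves:
        data.append([model.states[i] for i in states[node]])
    aln = Alignment(names, np.array(data, dtype="U1"), "aa")
    return aln, states, cats


# -- fixture bundles -------------------------------------------------------

@dataclass
class FixtureGene:
    regime: object
    n_codons: int = 300


@dataclass
class FixtureConfig:
    n_taxa: int = 12
    n_deep: int = 2
    genes: dict[str, FixtureGene] = field(default_factory=dict)
    branch_length_mean: float = 0.15
    #: deep-sea lineages are modelled as long isolated terminal branches
    deep_branch_length: float | None = 0.4
    planted_parallel: dict[str, int] = field(default_factory=dict)
    # gene -> k planted parallel changes on the pair of deep terminal branches

    def __post_init__(self):
        if self.n_taxa < 4:
            raise SimulationError("need at least 4 taxa")
        if not 2 <= self.n_deep < self.n_taxa:
            raise SimulationError("n_deep must be in [2, n_taxa)")
        if not self.genes:
            raise SimulationError("fixture config names no genes")


def _separated_leaves(tree: PhyloTree, k: int) -> list[int]:
    """k leaves chosen greedily to maximise pairwise path length."""
    def depth_chain(v):
        out = {}
        d = 0.0
        while v >= 0:
            out[v] = d
            d += float(tree.branch_length[v])
            v = int(tree.parent[v])
        return out

    chains = {v: depth_chain(v) for v in tree.leaves}

    def dist(a, b):
        # path length = distance from each leaf to their lowest common node
        ca, cb = chains[a], chains[b]
        common = [n for n in ca if n in cb]
        lca = min(common, key=lambda n: ca[n])
        return ca[lca] + cb[lca]

    leaves = tree.leaves
    first = max(leaves, key=lambda v: sum(dist(v, w) for w in leaves))
    chosen = [first]
    while len(chosen) < k:
        nxt = max((v for v in leaves if v not in chosen),
                  key=lambda v: min(dist(v, c) for c in chosen))
        chosen.append(nxt)
    return sorted(chosen)


def random_tree(n_taxa: int, seed: int, branch_length_mean: float = 0.15,
                labels: list[str] | None = None) -> PhyloTree:
    """Random binary topology by sequential attachment; Exp branch lengths."""
    rng = stream(seed, "tree")
    labels = labels or [f"t{i + 1}" for i in range(n_taxa)]
    # grow a list of current subtrees, join random pairs
    parts = list(labels)
    while len(parts) > 2:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        la, lb = rng.exponential(branch_length_mean, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        parts = [p for idx, p in enumerate(parts) if idx not in (i, j)]
        parts.append(merged)
    la, lb = rng.exponential(branch_length_mean, size=2)
    newick = f"({parts[0]}:{la:.6f},{parts[1]}:{lb:.6f});"
    return PhyloTree.from_newick(newick)


def make_fixture(config: FixtureConfig, seed: int, outdir) -> dict:
    """Write a self-consistent analysis bundle; returns the manifest dict.

    Layout: genes/<gene>.fasta, tree.nwk (deep-sea terminal branches tagged
    #1), depth.tsv, topology.tsv, truth/<gene>.json, manifest.json.
    """
    outdir = Path(outdir)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    tree = random_tree(config.n_taxa, seed, config.branch_length_mean)
    # deep-sea taxa sit on well-separated lineages (independent invasions of
    # the deep sea, as in real datasets): greedily maximise path separation
    deep_nodes = _separated_leaves(tree, config.n_deep)
    for node in deep_nodes:
        tree.foreground[node] = True
        if config.deep_branch_length is not None:
            tree.branch_length[node] = config.deep_branch_length
        # deep lineages branch off densely sampled shallow clades: keep the
        # edge above the attachment node short so ancestors are inferable
        parent = int(tree.parent[node])
        if tree.parent[parent] >= 0:
            tree.branch_length[parent] = min(
                0.05, float(tree.branch_length[parent]))
    deep_labels = {tree.labels[n] for n in deep_nodes}
    tree.write(outdir / "tree.nwk")

    # depth table: deep taxa at/beyond 1,000 m, shallow well above it
    rng_d = stream(seed, "depths")
    with open(outdir / "depth.tsv", "w") as fh:
        fh.write("taxon_id\tdepth_min\tdepth_max\tgroup\n")
        for name in tree.leaf_labels:
            if name in deep_labels:
                dmax = rng_d.uniform(1000.0, 4000.0)
                dmin = rng_d.uniform(200.0, 0.9 * dmax)
            else:
                dmax = rng_d.uniform(50.0, 800.0)
                dmin = rng_d.uniform(0.0, 0.9 * dmax)
            fh.write(f"{name}\t{dmin:.0f}\t{dmax:.0f}\tfixture\n")

    pair = tuple(deep_nodes[:2])
    manifest = {"schema_version": 1, "seed": int(seed),
                "n_taxa": config.n_taxa, "deep_taxa": sorted(deep_labels),
                "genes": {}}
    topo: dict[str, list[tuple[int, int, str]]] = {}
    for gene_name, gene_cfg in config.genes.items():
        aln, truth = simulate_codon_alignment(
            tree, gene_cfg.regime, gene_cfg.n_codons, seed, gene=gene_name)
        k = config.planted_parallel.get(gene_name, 0)
        if k:
            aln, truth = plant_parallel_changes(aln, truth, tree, pair, k,
                                                seed)
        aln.write(outdir / "genes" / f"{gene_name}.fasta")
        _write_truth(truth, outdir / "truth" / f"{gene_name}.json")
        manifest["genes"][gene_name] = {
            "n_codons": gene_cfg.n_codons,
            "regime": _regime_dict(gene_cfg.regime),
            "planted_parallel": k,
        }
        topo[gene_name] = _random_topology(gene_cfg.n_codons,
                                           stream(seed, gene_name, "topo"))

    with open(outdir / "topology.tsv", "w") as fh:
        fh.write("# protein\tlabel\tstart\tend\n")
        for gene_name, ivs in topo.items():
            for (start, end, label) in ivs:
                fh.write(f"{gene_name}\t{label}\t{start}\t{end}\n")
    manifest["planted_pair"] = [int(pair[0]), int(pair[1])]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _random_topology(n_res: int, rng) -> list[tuple[int, int, str]]:
    """Alternating inside/TM/outside intervals covering 1..n_res."""
    labels = ["inside", "TMhelix", "outside", "TMhelix"]
    cuts = sorted(rng.choice(np.arange(2, n_res), size=min(3, n_res - 2),
                             replace=False))
    edges = [1, *[int(c) for c in cuts], n_res + 1]
    return [(edges[i], edges[i + 1] - 1, labels[i % 4])
            for i in range(len(edges) - 1)]


def _regime_dict(regime) -> dict:
    d = asdict(regime)
    d["type"] = type(regime).__name__
    return d


def _write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "schema_version": 1,
        "seed": truth.seed,
        "code_id": truth.code_id,
        "regime": _regime_dict(truth.regime),
        "site_class": truth.site_class.tolist(),
        "node_states": truth.node_states.tolist(),
        "events": [[e.branch, e.site, e.time, e.from_state, e.to_state]
                   for e in truth.events],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        payload = json.load(fh)
    regime_info = dict(payload["regime"])
    regime_type = regime_info.pop("type")
    cls = {"M0Regime": M0Regime, "BranchSiteRegime": BranchSiteRegime}[regime_type]
    regime = cls(**regime_info)
    return SimulationTruth(
        seed=payload["seed"], regime=regime, code_id=payload["code_id"],
        site_class=np.asarray(payload["site_class"], dtype=np.intp),
        node_states=np.asarray(payload["node_states"], dtype=np.intp),
        events=[Event(b, s, t, f, to)
                for (b, s, t, f, to) in payload["events"]])
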