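"""End-to-end orchestration: selection scan, reconstruction, convergence scan.

Mirrors the study design: per gene, a one-ratio fit gives the gene-wide
dN/dS; each focal (deep-sea) branch is then tested as the foreground of
branch-site Model A against its fixed-omega2 null; ancestral amino acids are
reconstructed under an empirical mitochondrial model; and all focal branch
pairs are scanned for convergent/parallel changes with expected-count
p-values.  Per-gene failures are logged and skipped, not fatal.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as anno
from .alignment import Alignment
from .ancestral import branch_substitutions, marginal_reconstruction
from .codon_selection import (branch_site_test, fit_one_ratio,
                              positively_selected_sites)
from .convergence import (scan_branch_pairs, significance_stars,
                          branch_pair_test)
from .dataset_io import translate_mt
from .likelihood import optimize_branch_lengths
from .models import RateHeterogeneity, aa_model
from .trees import PhyloTree

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    genes_dir: Path
    tree: Path
    output_dir: Path
    genes: list[str]
    depth_table: Path | None = None
    topology: Path | None = None
    seed: int = 0
    freq_mode: str = "F3x4"
    alpha: float = 0.05
    posterior_threshold: float = 0.95
    p_min: float = 0.7
    aa_model_name: str = "mtmam"
    gamma_k: int = 4
    share_lengths: bool = True
    foreground_labels: list[str] | None = None   # default: tree's #k tags

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        paths = raw.get("paths", {})
        settings = raw.get("settings", {})
        cfg = cls(
            genes_dir=Path(paths["genes_dir"]),
            tree=Path(paths["tree"]),
            output_dir=Path(raw.get("output_dir", "mitosel_out")),
            genes=list(raw["genes"]),
            depth_table=Path(paths["depth_table"]) if "depth_table" in paths
            else None,
            topology=Path(paths["topology"]) if "topology" in paths else None,
            seed=int(raw.get("seed", 0)),
            foreground_labels=raw.get("foreground"),
            **{k: settings[k] for k in settings},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.genes_dir, self.tree, self.depth_table, self.topology):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")
        for gene in self.genes:
            p = self.gene_path(gene)
            if not p.exists():
                raise ConfigError(f"missing alignment for gene {gene}: {p}")
        tree = self.load_tree()
        if not self.resolve_foreground(tree):
            raise ConfigError("no foreground branches: tag the tree with #1 "
                              "or list `foreground` labels in the config")

    def gene_path(self, gene: str) -> Path:
        return Path(self.genes_dir) / f"{gene}.fasta"

    def load_tree(self) -> PhyloTree:
        return PhyloTree.read(self.tree)

    def resolve_foreground(self, tree: PhyloTree) -> list[int]:
        if self.foreground_labels:
            return [tree.node_of_label(lab) for lab in self.foreground_labels]
        return tree.foreground_nodes()


def branch_name(tree: PhyloTree, node: int) -> str:
    return tree.labels[node] if tree.is_leaf(node) else f"node{node}"


# -- selection scan --------------------------------------------------------

def run_selection_scan(config: RunConfig) -> dict:
    """Per (gene, foreground branch): one-ratio omega + branch-site LRT."""
    tree = config.load_tree()
    focal = config.resolve_foreground(tree)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    positive_sites: dict[str, dict[str, list[int]]] = {}
    for gene in config.genes:
        try:
            aln = Alignment.read(config.gene_path(gene), alphabet="nt")
            m0 = fit_one_ratio(tree, aln, config.freq_mode)
            if m0.degenerate:
                log.warning("%s: no variation, skipped", gene)
                continue
            for node in focal:
                null, alt, lrt = branch_site_test(
                    tree, aln, foreground=[node],
                    share_lengths=config.share_lengths,
                    freq_mode=config.freq_mode, init=m0)
                sig = lrt.p_value < config.alpha
                pos = positively_selected_sites(
                    alt, config.posterior_threshold) if sig else np.array([])
                positive_sites.setdefault(gene, {})[
                    branch_name(tree, node)] = [int(s) + 1 for s in pos]
                rows.append({
                    "gene": gene, "branch": branch_name(tree, node),
                    "omega_one_ratio": round(m0.omega, 5),
                    "kappa": round(m0.kappa, 5),
                    "lnL_null": round(null.lnl, 6),
                    "lnL_alt": round(alt.lnl, 6),
                    "stat_2dl": round(lrt.statistic, 6),
                    "p_value": float(f"{lrt.p_value:.6g}"),
                    "omega2": round(alt.omega2, 5),
                    "significant": bool(sig),
                })
                log.info("%s / %s: 2dl=%.3f p=%.4g", gene,
                         branch_name(tree, node), lrt.statistic, lrt.p_value)
        except Exception:
            log.exception("gene %s failed; continuing", gene)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "selection.tsv", sep="\t", index=False)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
              "alpha": config.alpha, "results": rows,
              "positive_sites": positive_sites}
    with open(outdir / "selection.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# -- convergence scan ------------------------------------------------------

def run_convergence_scan(config: RunConfig,
                         selection_report: dict | None = None) -> dict:
    """Per gene: reconstruct ancestors, scan focal branch pairs, test counts."""
    tree = config.load_tree()
    focal = config.resolve_foreground(tree)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    het = RateHeterogeneity(0.0, 0.5, config.gamma_k)
    rows = []
    events_json = []
    for gene in config.genes:
        try:
            aln = Alignment.read(config.gene_path(gene), alphabet="nt")
            aa_aln = translate_mt(aln)
            model = aa_model(config.aa_model_name, het)
            fitted_tree, _, fitted_model = optimize_branch_lengths(
                tree, aa_aln, model, optimize_alpha=True)
            recon = marginal_reconstruction(fitted_tree, aa_aln, fitted_model)
            scan = branch_substitutions(recon, fitted_tree, aa_aln,
                                        p_min=config.p_min)
            pair_events = scan_branch_pairs(recon, fitted_tree, focal,
                                            scan.substitutions, gene=gene)
            for pair, events in sorted(pair_events.items()):
                if not events:
                    continue
                result = branch_pair_test(recon, fitted_tree, pair, events)
                b1, b2 = (branch_name(tree, pair[0]),
                          branch_name(tree, pair[1]))
                for ev in events:
                    p = (result.p_parallel if ev.type == "parallel"
                         else result.p_convergent)
                    rows.append({
                        "gene": gene, "change": ev.notation,
                        "branches": f"{b1}, {b2}", "type": ev.type,
                        "p_value": float(f"{p:.6g}"),
                        "stars": significance_stars(p),
                    })
                    events_json.append({
                        "gene": gene, "site": ev.site, "change": ev.notation,
                        "branches": [b1, b2], "type": ev.type,
                        "p_value": float(f"{p:.6g}"),
                        "expected": float(f"{result.expected_parallel:.6g}")
                        if ev.type == "parallel"
                        else float(f"{result.expected_convergent:.6g}"),
                    })
        except Exception:
            log.exception("gene %s failed; continuing", gene)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "convergence.tsv", sep="\t", index=False)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
              "events": events_json}
    if selection_report is not None:
        report["joint_sites"] = joint_signal_sites(selection_report,
                                                   events_json)
    with open(outdir / "convergence.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def joint_signal_sites(selection_report: dict, events: list[dict]
                       ) -> list[dict]:
    """Sites showing both positive selection and convergence/parallelism."""
    pos = selection_report.get("positive_sites", {})
    out = []
    for ev in events:
        gene_pos = pos.get(ev["gene"], {})
        branches_hit = [b for b, sites in gene_pos.items()
                        if ev["site"] in sites]
        if branches_hit:
            out.append({**ev, "selected_on": sorted(branches_hit)})
    return out


def annotate_events(events: list[dict], topology_path) -> list[dict]:
    """Attach TM/inside/outside domain and polarity-change calls to events."""
    topo = anno.read_topology(topology_path)
    out = []
    for ev in events:
        entry = dict(ev)
        gene_topo = topo.get(ev["gene"])
        if gene_topo is not None and 1 <= ev["site"] <= gene_topo.length:
            entry["domain"] = gene_topo.assign_domain(ev["site"])
        change = ev["change"]
        derived = change[-1]
        anc = change.split(str(ev["site"]))[0].split("/")
        calls = []
        for a in anc:
            pc = anno.polarity_change(a, derived)
            calls.append("none" if pc is None else f"{pc[0]}->{pc[1]}")
        entry["polarity_change"] = ";".join(calls)
        out.append(entry)
    return out


def run_all(config: RunConfig) -> dict:
    sel = run_selection_scan(config)
    conv = run_convergence_scan(config, selection_report=sel)
    events = conv["events"]
    if config.topology is not None:
        events = annotate_events(events, config.topology)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
              "selection": sel["results"], "events": events,
              "joint_sites": conv.get("joint_sites", [])}
    validate_report(report)
    outdir = Path(config.output_dir)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def validate_report(report: dict) -> None:
    """Structural check of the combined report against the versioned schema."""
    if report.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ConfigError("report schema version mismatch")
    for key in ("selection", "events"):
        if not isinstance(report.get(key), list):
            raise ConfigError(f"report is missing list field {key!r}")
    for row in report["selection"]:
        for col in ("gene", "branch", "p_value", "significant"):
            if col not in row:
                raise ConfigError(f"selection row missing {col!r}")
    for ev in report["events"]:
        for col in ("gene", "change", "type", "p_value"):
            if col not in ev:
                raise ConfigError(f"event missing {col!r}")
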