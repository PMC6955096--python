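"""Synthetic virus-host co-divergence datasets.

Generates the statistical structure the dating pipeline assumes: a dated
pure-birth host tree; a virus chronogram that mirrors it (every shared
divergence a true co-speciation event) except for a configurable number of
host switches and lineage losses; substitution branch lengths produced by
inverting the power law t = alpha * s**beta (so s(age) = (age/alpha)**(1/beta))
with multiplicative lognormal noise; a subset of tips flagged as slowly
evolving endogenous copies; and a posterior-like ensemble made by jittering
branch lengths.  All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .cospeciation import host_partition
from .trees import (
    Chronogram,
    Phylogeny,
    PosteriorEnsemble,
    TipAssociation,
    write_association,
    write_ensemble,
    write_tree,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_host_chronogram",
    "mirror_virus_tree",
    "time_to_substitutions",
    "endogenize_tips",
    "make_posterior_ensemble",
    "simulate",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate the mammal-scale analysis.

    alpha/beta are the true power-law parameters (dates in myr, change in
    substitutions per site); 13 hosts give 12 internal calibratable nodes
    with a root age around the eutherian radiation; noise/jitter are
    lognormal standard deviations on the log scale.
    """

    alpha: float = 4.0
    beta: float = 0.6
    n_hosts: int = 13
    root_age: float = 100.0
    switch_count: int = 1
    loss_prob: float = 0.0
    erv_fraction: float = 0.3
    erv_rate_scale: float = 0.5
    endogenized_fraction: float = 1.0
    noise_sd: float = 0.05
    ensemble_size: int = 100
    jitter_sd: float = 0.05
    support_low: float = 0.9
    support_high: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if not (0 <= self.erv_fraction < 1 and 0 <= self.loss_prob < 1):
            raise ValueError("erv_fraction and loss_prob must be in [0, 1)")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be >= 0")
        if self.n_hosts < 3:
            raise ValueError("n_hosts must be >= 3")
        if not 0 <= self.support_low <= self.support_high <= 1:
            raise ValueError("support range must satisfy 0 <= low <= high <= 1")


@dataclass
class TrueEvent:
    event_id: str
    virus_tips: frozenset[str]
    host_tips: frozenset[str]
    t: float


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    host: Chronogram
    virus_true: Chronogram
    virus_subs: Phylogeny
    ensemble: PosteriorEnsemble
    association: TipAssociation
    true_events: list[TrueEvent]
    true_node_ages: dict[str, float]  # virus tip-set key "a;b;c" -> age (myr)


# ---------------------------------------------------------------------------
# Host tree
# ---------------------------------------------------------------------------


def simulate_host_chronogram(
    n_hosts: int, root_age: float, seed: int | np.random.Generator
) -> Chronogram:
    """Pure-birth (Yule) chronogram with ``n_hosts`` extant tips, rescaled to
    ``root_age`` myr at the root.

    Lineages split at exponential waiting times; a final holding time is
    appended after the last split so every internal node age is strictly
    positive.  Tips are labelled H1..Hn.
    """
    if n_hosts < 3:
        raise ValueError("n_hosts must be >= 3")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    root.depth = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append(child)
    now = 0.0
    while len(active) < n_hosts:
        now += rng.exponential(1.0 / len(active))
        split = active.pop(int(rng.integers(len(active))))
        split.depth = now
        for _ in range(2):
            active.append(split.new_child())
    now += rng.exponential(1.0 / len(active))
    scale = root_age / now
    for i, leaf in enumerate(active):
        leaf.depth = now
    # convert depths to edge lengths, rescaled so the root sits at root_age
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        node.edge.length = (node.depth - node.parent_node.depth) * scale
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(f"H{i}")
    for node in tree.preorder_internal_node_iter():
        node.support = 1.0
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# Virus chronogram: mirror + switches + losses
# ---------------------------------------------------------------------------


def _virus_label(host_label: str) -> str:
    return f"V_{host_label}"


def _ages(chronogram: Chronogram) -> None:
    """Recompute node ages in place after topology surgery."""
    chronogram._assign_ages(tolerance=None)


def mirror_virus_tree(
    host: Chronogram,
    switch_count: int,
    loss_prob: float,
    seed: int | np.random.Generator,
) -> tuple[Chronogram, TipAssociation, list[TrueEvent]]:
    """Virus chronogram mirroring the host tree, with host switches and losses.

    The virus tree starts as a copy of the host chronogram (tip ``V_H`` on
    host ``H``; every internal node a true co-speciation event).  Each host
    switch prunes a random virus tip and regrafts it onto a contemporaneous
    recipient branch at the midpoint of that branch's age interval — the
    divergence times on the displaced path no longer mirror host divergences
    and the corresponding events leave the truth list.  Each virus tip is
    then lost independently with probability ``loss_prob`` (at least 3 tips
    are always kept).  True events are recomputed from scratch by exact
    split matching, so the truth list is correct for any switch/loss pattern.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taxon_namespace = dendropy.TaxonNamespace()
    virus = dendropy.Tree(host.tree, taxon_namespace=taxon_namespace)
    for leaf in virus.leaf_node_iter():
        leaf.taxon.label = _virus_label(leaf.taxon.label)
    for node in virus.preorder_internal_node_iter():
        node.support = 1.0
    chron = Chronogram(virus)

    for k in range(switch_count):
        tips = list(chron.tree.leaf_node_iter())
        donor = tips[int(rng.integers(len(tips)))]
        parent = donor.parent_node
        sibling_edges = {donor.edge, parent.edge} | {
            c.edge for c in parent.child_nodes()
        }
        candidates = [
            n
            for n in chron.tree.preorder_node_iter()
            if n.parent_node is not None and n.edge not in sibling_edges
        ]
        if not candidates:
            raise ValueError(
                f"switch {k + 1}: no contemporaneous recipient branch available"
            )
        recipient = candidates[int(rng.integers(len(candidates))) ]
        graft_age = (recipient.age + recipient.parent_node.age) / 2.0
        # detach donor, suppress its old parent
        grandparent = parent.parent_node
        parent.remove_child(donor)
        if grandparent is None:
            # parent is the root: the remaining child becomes the new root
            remaining = parent.child_nodes()[0]
            remaining.edge.length = None
            remaining.parent_node = None
            chron.tree.seed_node = remaining
        else:
            remaining = parent.child_nodes()[0]
            grandparent.remove_child(parent)
            grandparent.add_child(remaining)
            remaining.edge.length = grandparent.age - remaining.age
        if recipient.parent_node is None:
            raise ValueError(f"switch {k + 1}: recipient was detached; retry seed")
        # insert a new node on the recipient edge at graft_age
        rec_parent = recipient.parent_node
        rec_parent.remove_child(recipient)
        joint = rec_parent.new_child()
        joint.edge.length = rec_parent.age - graft_age
        joint.support = 1.0
        joint.add_child(recipient)
        recipient.edge.length = graft_age - recipient.age
        joint.add_child(donor)
        donor.edge.length = graft_age  # donor is an extant tip (age 0)
        _ages(chron)

    # losses
    tips = list(chron.tree.leaf_node_iter())
    keep_mask = rng.random(len(tips)) >= loss_prob
    if keep_mask.sum() < 3:
        keep_idx = rng.choice(len(tips), size=3, replace=False)
        keep_mask[:] = False
        keep_mask[keep_idx] = True
    lost = [t.taxon for t, keep in zip(tips, keep_mask) if not keep]
    if lost:
        chron.tree.prune_taxa(lost)
        chron.tree.suppress_unifurcations()
        _ages(chron)

    association = TipAssociation(
        {
            leaf.taxon.label: (leaf.taxon.label.removeprefix("V_"), False)
            for leaf in chron.tree.leaf_node_iter()
        }
    )
    chron = Chronogram(chron.tree)  # revalidate after surgery
    true_events = _true_events(chron, host, association)
    return chron, association, true_events


def _true_events(
    virus: Chronogram, host: Chronogram, association: TipAssociation
) -> list[TrueEvent]:
    """Exact-split truth list: virus nodes whose induced host partition equals
    a host node's child partition AND whose age equals the host node's age."""
    host_index = {
        host_partition(node): node
        for node in host.tree.preorder_internal_node_iter()
    }
    events = []
    counter = 0
    for node in virus.tree.preorder_internal_node_iter():
        parts = frozenset(
            frozenset(
                association.host_of(leaf.taxon.label) for leaf in child.leaf_iter()
            )
            for child in node.child_nodes()
        )
        match = host_index.get(parts)
        if match is None:
            continue
        if abs(node.age - match.age) > 1e-9 * max(match.age, 1.0):
            continue  # topology mirrors but timing displaced by a switch
        counter += 1
        events.append(
            TrueEvent(
                event_id=f"E{counter}",
                virus_tips=virus.leaf_labels_under(node),
                host_tips=host.leaf_labels_under(match),
                t=match.age,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Substitution lengths, ERVs, ensemble
# ---------------------------------------------------------------------------


def expected_distance(age: float, alpha: float, beta: float) -> float:
    """s(age) = (age / alpha) ** (1 / beta): node-to-tip change implied by the
    power law t = alpha * s**beta."""
    return (age / alpha) ** (1.0 / beta)


def time_to_substitutions(
    virus_chronogram: Chronogram,
    alpha: float,
    beta: float,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> Phylogeny:
    """Convert node ages to substitution branch lengths under the power law.

    Each branch gets s(parent age) - s(child age), multiplied by a lognormal
    factor of log-scale sd ``noise_sd``.  At zero noise the node-to-tip path
    from a node of age a to every descendant tip telescopes to exactly
    s(a) = (a/alpha)**(1/beta).
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(virus_chronogram.tree, taxon_namespace=taxon_namespace)
    for src, dst in zip(
        virus_chronogram.tree.preorder_node_iter(), tree.preorder_node_iter()
    ):
        dst.support = src.support
        if dst.parent_node is None:
            continue
        s_span = expected_distance(src.parent_node.age, alpha, beta) - expected_distance(
            src.age, alpha, beta
        )
        factor = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
        dst.edge.length = s_span * factor
    return Phylogeny(tree)


def endogenize_tips(
    phylogeny: Phylogeny,
    association: TipAssociation,
    erv_fraction: float,
    erv_rate_scale: float,
    seed: int | np.random.Generator,
    *,
    endogenized_fraction: float = 1.0,
) -> tuple[Phylogeny, TipAssociation]:
    """Flag a random subset of tips as endogenous and slow their terminal branch.

    The endogenized portion of the terminal branch (fraction
    ``endogenized_fraction`` of its length, default the whole branch) is
    scaled by ``erv_rate_scale``:  L -> L * (1 - f + f * scale).
    """
    if not 0 <= erv_fraction < 1:
        raise ValueError("erv_fraction must be in [0, 1)")
    if not 0 <= endogenized_fraction <= 1:
        raise ValueError("endogenized_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = phylogeny.clone()
    tips = sorted(result.tip_labels)
    n_erv = int(round(erv_fraction * len(tips)))
    chosen = set(
        rng.choice(tips, size=n_erv, replace=False) if n_erv else []
    )
    factor = 1.0 - endogenized_fraction + endogenized_fraction * erv_rate_scale
    for leaf in result.tree.leaf_node_iter():
        if leaf.taxon.label in chosen:
            leaf.edge.length *= factor
    return result, association.with_flags(chosen)


def make_posterior_ensemble(
    phylogeny: Phylogeny,
    ensemble_size: int,
    jitter_sd: float,
    support_range: tuple[float, float],
    seed: int | np.random.Generator,
) -> PosteriorEnsemble:
    """Posterior-like ensemble: branch lengths jittered by iid lognormal
    factors (log-scale sd ``jitter_sd``), supports drawn uniform in
    ``support_range``.  ``jitter_sd`` = 0 gives identical samples.
    Topology is fixed across samples.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    lo, hi = support_range
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples = []
    for _ in range(ensemble_size):
        sample = phylogeny.clone()
        for node in sample.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if jitter_sd > 0:
                node.edge.length *= rng.lognormal(0.0, jitter_sd)
        for node in sample.tree.preorder_internal_node_iter():
            node.support = float(rng.uniform(lo, hi))
        samples.append(sample)
    return PosteriorEnsemble(samples)


# ---------------------------------------------------------------------------
# Top level
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator from a single seed."""
    rng = np.random.default_rng(config.seed)
    host = simulate_host_chronogram(config.n_hosts, config.root_age, rng)
    virus_true, association, true_events = mirror_virus_tree(
        host, config.switch_count, config.loss_prob, rng
    )
    virus_subs = time_to_substitutions(
        virus_true, config.alpha, config.beta, config.noise_sd, rng
    )
    virus_subs, association = endogenize_tips(
        virus_subs,
        association,
        config.erv_fraction,
        config.erv_rate_scale,
        rng,
        endogenized_fraction=config.endogenized_fraction,
    )
    ensemble = make_posterior_ensemble(
        virus_subs,
        config.ensemble_size,
        config.jitter_sd,
        (config.support_low, config.support_high),
        rng,
    )
    true_node_ages = {
        ";".join(sorted(virus_true.leaf_labels_under(node))): node.age
        for node in virus_true.tree.preorder_internal_node_iter()
    }
    return SimulatedDataset(
        config=config,
        host=host,
        virus_true=virus_true,
        virus_subs=virus_subs,
        ensemble=ensemble,
        association=association,
        true_events=true_events,
        true_node_ages=true_node_ages,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write host.nwk, virus_true.nwk, virus_subs.nwk, ensemble.nex,
    association.tsv, truth.json and a manifest echoing the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tree(dataset.host, outdir / "host.nwk")
    write_tree(dataset.virus_true, outdir / "virus_true.nwk")
    write_tree(dataset.virus_subs, outdir / "virus_subs.nwk")
    write_ensemble(dataset.ensemble, outdir / "ensemble.nex")
    write_association(dataset.association, outdir / "association.tsv")
    truth = {
        "alpha": dataset.config.alpha,
        "beta": dataset.config.beta,
        "true_events": [
            {
                "event_id": e.event_id,
                "virus_tips": sorted(e.virus_tips),
                "host_tips": sorted(e.host_tips),
                "t": e.t,
            }
            for e in dataset.true_events
        ],
        "true_node_ages": dataset.true_node_ages,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2), encoding="utf-8")
    manifest = {
        "seed": dataset.config.seed,
        "config": dataclasses.asdict(dataset.config),
        "outputs": [
            "host.nwk",
            "virus_true.nwk",
            "virus_subs.nwk",
            "ensemble.nex",
            "association.tsv",
            "truth.json",
        ],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )
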