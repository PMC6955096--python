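"""Phylogeny, chronogram and posterior-ensemble I/O.

All trees are held as rooted :class:`dendropy.Tree` objects wrapped in thin
validating containers.  Branch lengths on virus trees are in substitutions
per site; chronograms carry node ages in millions of years (myr).  Internal
node labels, when numeric, are interpreted as Bayesian posterior probability
clade supports in [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "TreeValidationError",
    "TreeParseError",
    "Phylogeny",
    "Chronogram",
    "TipAssociation",
    "PosteriorEnsemble",
    "read_tree",
    "read_chronogram",
    "read_ensemble",
    "read_association",
    "write_tree",
    "write_ensemble",
    "write_association",
    "reroot_on_outgroup",
    "retained_sample_count",
]


class TreeValidationError(ValueError):
    """A tree violates a structural invariant (duplicate tips, negative lengths...)."""


class TreeParseError(ValueError):
    """A tree file could not be parsed."""


def _parse_support(label: str | None) -> float | None:
    if label is None:
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if 0.0 <= value <= 1.0:
        return value
    return None


class Phylogeny:
    """A rooted phylogeny with non-negative branch lengths and unique tip labels.

    Internal-node supports (posterior probabilities) are stored on
    ``node.support``; a missing support is ``None``, never 0, and downstream
    support thresholding treats missing as failing.
    """

    def __init__(self, tree: dendropy.Tree, *, validate: bool = True):
        self.tree = tree
        tree.is_rooted = True  # trees are used exactly as read, rooted
        for node in tree.preorder_node_iter():
            if not hasattr(node, "support"):
                node.support = _parse_support(node.label) if not node.is_leaf() else None
        if validate:
            self.validate()

    # ---------------------------------------------------------------- basics
    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def validate(self) -> None:
        labels = self.tip_labels
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise TreeValidationError(f"duplicate tip label: {lab!r}")
            seen.add(lab)
        for node in self.tree.preorder_node_iter():
            if node is self.root:
                continue
            if node.edge.length is None:
                raise TreeValidationError(
                    f"missing branch length above node {_describe(node)}"
                )
            if node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.edge.length} above {_describe(node)}"
                )
            if not node.is_leaf() and len(node.child_nodes()) < 2:
                raise TreeValidationError(
                    f"internal node {_describe(node)} has a single child"
                )

    # ------------------------------------------------------------- traversal
    def find_tip(self, label: str) -> dendropy.Node:
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == label:
                return leaf
        raise KeyError(f"tip {label!r} not in tree")

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a set of tip labels."""
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        if len(labels) == 1:
            return self.find_tip(next(iter(labels)))
        node = self.tree.mrca(taxon_labels=labels)
        if node is None:  # pragma: no cover - dendropy returns root instead
            raise KeyError(f"no MRCA for {sorted(labels)}")
        return node

    def leaf_labels_under(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(leaf.taxon.label for leaf in node.leaf_iter())

    def is_monophyletic(self, labels: Iterable[str]) -> bool:
        labels = frozenset(labels)
        return self.leaf_labels_under(self.mrca(labels)) == labels

    def clone(self) -> "Phylogeny":
        copy = dendropy.Tree(self.tree)
        for src, dst in zip(
            self.tree.preorder_node_iter(), copy.preorder_node_iter()
        ):
            dst.support = src.support
        return type(self)(copy, validate=False)

    # ------------------------------------------------------------------- I/O
    def as_newick(self) -> str:
        tree = self.tree
        for node in tree.preorder_internal_node_iter():
            node.label = (
                _format_float(node.support) if node.support is not None else None
            )
        s = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"


class Chronogram(Phylogeny):
    """An ultrametric, dated phylogeny; ``node.age`` is in myr (0 at extant tips).

    Ages are derived from branch lengths: age = (max root-to-tip distance)
    minus (root-to-node distance).  Ultrametricity is enforced within
    ``tolerance`` (default 1e-6 x root age).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        validate: bool = True,
        tolerance: float | None = None,
    ):
        super().__init__(tree, validate=validate)
        self._assign_ages(tolerance=tolerance)

    def _assign_ages(self, tolerance: float | None) -> None:
        depths: dict[dendropy.Node, float] = {self.root: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is self.root:
                continue
            depths[node] = depths[node.parent_node] + node.edge.length
        tip_depths = {n: d for n, d in depths.items() if n.is_leaf()}
        root_age = max(tip_depths.values())
        if tolerance is None:
            tolerance = 1e-6 * root_age if root_age > 0 else 1e-12
        shallow = min(tip_depths, key=tip_depths.get)
        deep = max(tip_depths, key=tip_depths.get)
        if depths[deep] - depths[shallow] > tolerance:
            raise TreeValidationError(
                "tree is not ultrametric: tips "
                f"{shallow.taxon.label!r} (depth {depths[shallow]:.6g}) and "
                f"{deep.taxon.label!r} (depth {depths[deep]:.6g}) differ by more "
                f"than tolerance {tolerance:.3g}"
            )
        for node, depth in depths.items():
            node.age = max(root_age - depth, 0.0)
        for leaf in tip_depths:
            leaf.age = 0.0
        self.root_age = root_age

    def age_of(self, node: dendropy.Node) -> float:
        return node.age

    def validate(self) -> None:
        super().validate()
        # parent age strictly greater than child age is implied by positive
        # branch lengths; zero-length chronogram branches are rejected here.
        for node in self.tree.preorder_node_iter():
            if node is not self.root and node.edge.length == 0:
                raise TreeValidationError(
                    f"zero-length chronogram branch above {_describe(node)}"
                )


@dataclass(frozen=True)
class HostLink:
    host: str
    is_endogenous: bool


class TipAssociation:
    """Mapping from virus tip label to (host taxon, endogenous flag)."""

    def __init__(self, links: Mapping[str, tuple[str, bool]]):
        self._links = {v: HostLink(h, bool(e)) for v, (h, e) in links.items()}

    def __contains__(self, virus_tip: str) -> bool:
        return virus_tip in self._links

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self) -> Iterator[str]:
        return iter(self._links)

    def host_of(self, virus_tip: str) -> str:
        try:
            return self._links[virus_tip].host
        except KeyError:
            raise KeyError(f"virus tip {virus_tip!r} has no host association") from None

    def is_endogenous(self, virus_tip: str) -> bool:
        try:
            return self._links[virus_tip].is_endogenous
        except KeyError:
            raise KeyError(f"virus tip {virus_tip!r} has no host association") from None

    @property
    def virus_tips(self) -> frozenset[str]:
        return frozenset(self._links)

    @property
    def erv_tips(self) -> frozenset[str]:
        return frozenset(v for v, l in self._links.items() if l.is_endogenous)

    @property
    def hosts(self) -> frozenset[str]:
        return frozenset(l.host for l in self._links.values())

    def hosts_of(self, virus_tips: Iterable[str]) -> frozenset[str]:
        return frozenset(self.host_of(v) for v in virus_tips)

    def check_covers(self, tree: Phylogeny) -> None:
        """Every tree tip must appear in the association exactly once."""
        missing = set(tree.tip_labels) - set(self._links)
        if missing:
            raise TreeValidationError(
                f"virus tips without host association: {sorted(missing)}"
            )

    def check_hosts_in(self, chronogram: Phylogeny) -> list[str]:
        """Return host taxa absent from the chronogram (callers decide severity)."""
        return sorted(self.hosts - set(chronogram.tip_labels))

    def with_flags(self, endogenous: Iterable[str]) -> "TipAssociation":
        endo = set(endogenous)
        return TipAssociation(
            {v: (l.host, v in endo) for v, l in self._links.items()}
        )

    def items(self):
        return ((v, (l.host, l.is_endogenous)) for v, l in self._links.items())


class PosteriorEnsemble:
    """An ordered collection of posterior tree samples sharing one tip set."""

    def __init__(self, samples: Sequence[Phylogeny]):
        if not samples:
            raise TreeValidationError("ensemble must contain at least one sample")
        tip_set = frozenset(samples[0].tip_labels)
        for i, sample in enumerate(samples[1:], start=2):
            if frozenset(sample.tip_labels) != tip_set:
                raise TreeValidationError(
                    f"sample {i} has a different tip set from sample 1"
                )
        self.samples = list(samples)
        self.tip_set = tip_set

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Phylogeny]:
        return iter(self.samples)

    def __getitem__(self, i) -> Phylogeny:
        return self.samples[i]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SCHEMAS = {"newick": "newick", "nexus": "nexus"}


def _load_dendropy_tree(path: str | Path, schema: str) -> dendropy.Tree:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Multiple occurrences of the same taxa" in str(exc):
            raise TreeValidationError(f"duplicate tip label in {path}: {exc}") from exc
        raise TreeParseError(f"cannot parse {path} as {schema}: {exc}") from exc


def read_tree(path: str | Path, format: str = "newick") -> Phylogeny:
    """Read a single rooted phylogeny from a Newick or NEXUS file."""
    schema = _SCHEMAS.get(format.lower())
    if schema is None:
        raise ValueError(f"unsupported tree format {format!r}")
    return Phylogeny(_load_dendropy_tree(path, schema))


def read_chronogram(
    path: str | Path, format: str = "newick", tolerance: float | None = None
) -> Chronogram:
    """Read a dated ultrametric host tree; node ages are derived from branch lengths."""
    schema = _SCHEMAS.get(format.lower())
    if schema is None:
        raise ValueError(f"unsupported tree format {format!r}")
    return Chronogram(_load_dendropy_tree(path, schema), tolerance=tolerance)


def read_ensemble(path: str | Path, format: str = "nexus") -> PosteriorEnsemble:
    """Read an ordered posterior tree ensemble (NEXUS TREES block or multi-Newick)."""
    schema = _SCHEMAS.get(format.lower())
    if schema is None:
        raise ValueError(f"unsupported tree format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"cannot parse {path} as {schema}: {exc}") from exc
    return PosteriorEnsemble([Phylogeny(t) for t in trees])


def write_tree(phylogeny: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(phylogeny.as_newick(), encoding="utf-8")


def write_ensemble(ensemble: PosteriorEnsemble, path: str | Path) -> None:
    """Write an ensemble as a NEXUS TREES block, preserving sample order."""
    lines = ["#NEXUS", "", "BEGIN TREES;"]
    for i, sample in enumerate(ensemble, start=1):
        lines.append(f"    TREE sample_{i} = [&R] {sample.as_newick().strip()}")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_ASSOCIATION_COLUMNS = ("virus_tip", "host_taxon", "endogenous")


def read_association(path: str | Path) -> TipAssociation:
    """Read a TSV with header columns virus_tip, host_taxon, endogenous (0/1)."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _ASSOCIATION_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing association column(s) {missing}")
        links: dict[str, tuple[str, bool]] = {}
        for row in reader:
            tip = row["virus_tip"]
            if tip in links:
                raise ValueError(f"{path}: duplicate virus_tip row {tip!r}")
            flag = row["endogenous"].strip()
            if flag not in {"0", "1"}:
                raise ValueError(
                    f"{path}: endogenous must be 0 or 1, got {flag!r} for {tip!r}"
                )
            links[tip] = (row["host_taxon"], flag == "1")
    return TipAssociation(links)


def write_association(association: TipAssociation, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ASSOCIATION_COLUMNS)
        for virus_tip, (host, endo) in sorted(association.items()):
            writer.writerow([virus_tip, host, int(endo)])


def reroot_on_outgroup(phylogeny: Phylogeny, outgroup_tips: Iterable[str]) -> Phylogeny:
    """Re-root a tree on the edge above the MRCA of the given outgroup tips.

    Never invoked implicitly: trees are otherwise used exactly as read.
    """
    copy = phylogeny.clone()
    node = copy.mrca(outgroup_tips)
    if node is copy.root:
        raise TreeValidationError("outgroup spans the whole tree; cannot re-root")
    copy.tree.reroot_at_edge(node.edge, update_bipartitions=False)
    copy.tree.suppress_unifurcations()
    return Phylogeny(copy.tree, validate=False)


def retained_sample_count(
    steps: int, sample_interval: int, burnin_fraction: float = 0.25
) -> int:
    """Number of posterior samples retained after burn-in.

    A chain of ``steps`` MCMC steps sampled every ``sample_interval``-th step
    yields ``steps // sample_interval`` samples; the first
    ``burnin_fraction`` of them is discarded (floor).  E.g. 10,000,000 steps
    sampled every 1,000th with 25% burn-in retains 7,500 samples.
    """
    if steps <= 0 or sample_interval <= 0:
        raise ValueError("steps and sample_interval must be positive")
    if not 0.0 <= burnin_fraction < 1.0:
        raise ValueError("burnin_fraction must be in [0, 1)")
    n = steps // sample_interval
    return n - int(n * burnin_fraction)


# ---------------------------------------------------------------------------


def _describe(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return f"<internal:{sorted(l.taxon.label for l in node.leaf_iter())[:3]}...>"


def _format_float(x: float) -> str:
    return format(x, ".17g")
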