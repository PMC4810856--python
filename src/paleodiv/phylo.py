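"""Supertree handling, stratigraphic time-scaling, and phylogenetic
diversity with ghost lineages (PDE).

A supertree topology carries no time information of its own; node ages are
assigned a posteriori from the tips' stratigraphic first appearances
(FADs, in Ma): each internal node is as old as the oldest FAD among its
descendants.  This "basic" dating creates zero-length branches wherever a
node and its oldest descendant share an age.  Three strategies deal with
the unresolved and zero-length parts of the tree:

``equal``
    polytomies are left in place and each run of zero-length branches
    shares out, in equal parts, the duration of the first directly
    ancestral branch of positive length (with a root-stem extension
    providing slack above the root);
``random``
    each polytomy is resolved to a random binary subtree before dating;
``ordered``
    each polytomy is resolved so that lineages branch in order of first
    stratigraphic appearance (ties broken at random).

The phylogenetic diversity estimate (PDE) for a time bin counts every
lineage — tree branch, with terminal branches extended to the tip's last
appearance — whose time span intersects the bin.  Branches implied by
topology but unsampled in the fossil record ("ghost lineages") are thereby
counted, so PDE is never below the raw in-bin taxon count.  The reported
PDE is the mean over the three dating strategies, with the stochastic two
averaged over many seeded resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import dendropy
import numpy as np

from .bins import BinScheme
from .series import DiversitySeries

logger = logging.getLogger(__name__)

__all__ = [
    "DatedTree",
    "read_newick",
    "write_newick",
    "polytomies",
    "resolve_polytomies",
    "time_scale",
    "drop_tips",
    "collapse_to_genera",
    "pde",
    "pde_estimate",
]

PolytomyMethod = Literal["equal", "random", "ordered"]
_TOL = 1e-9


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, preserving underscores in labels."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed newick in {path}: {exc}") from exc


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def polytomies(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal nodes with more than two children."""
    return [n for n in tree.preorder_node_iter() if len(n.child_nodes()) > 2]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(tree)


def resolve_polytomies(
    tree: dendropy.Tree,
    method: PolytomyMethod,
    fads: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """Return a copy with polytomies resolved per the chosen strategy.

    ``equal`` leaves the topology untouched (zero-length branches are
    handled at dating time).  ``random`` joins random child pairs until
    each node is binary.  ``ordered`` arranges each polytomy as a
    caterpillar in which lineages with older first appearances branch
    first; equal first appearances are ordered at random.  An
    already-binary tree is returned unchanged (as a copy) by all methods.
    """
    tree = _clone(tree)
    if method == "equal":
        return tree
    if rng is None:
        rng = np.random.default_rng()
    for node in list(tree.preorder_node_iter()):
        children = node.child_nodes()
        if len(children) <= 2:
            continue
        if method == "random":
            pool = list(children)
            for c in pool:
                node.remove_child(c)
            while len(pool) > 2:
                i, j = sorted(rng.choice(len(pool), size=2, replace=False))
                new = dendropy.Node()
                new.add_child(pool[i])
                new.add_child(pool[j])
                pool = [p for k, p in enumerate(pool) if k not in (i, j)]
                pool.append(new)
            for p in pool:
                node.add_child(p)
        elif method == "ordered":
            if fads is None:
                raise ValueError("ordered resolution requires tip first appearances")
            aged = []
            for c in children:
                try:
                    aged.append((_oldest_fad(c, fads), c))
                except KeyError as exc:
                    raise ValueError(
                        f"ordered resolution: no first appearance for tip {exc}"
                    ) from exc
            # random shuffle then stable sort: ties between identical first
            # appearances come out in random order
            order = rng.permutation(len(aged))
            aged = [aged[k] for k in order]
            aged.sort(key=lambda t: -t[0])
            for c in children:
                node.remove_child(c)
            # caterpillar: oldest lineage branches first, youngest pair deepest
            lineage = aged[-1][1]
            for _, c in reversed(aged[:-1]):
                new = dendropy.Node()
                new.add_child(c)
                new.add_child(lineage)
                lineage = new
            # the top join is `node` itself
            for c in list(lineage.child_nodes()):
                lineage.remove_child(c)
                node.add_child(c)
        else:
            raise ValueError(f"unknown polytomy method {method!r}")
    return tree


def _oldest_fad(node: dendropy.Node, fads: Mapping[str, float]) -> float:
    ages = []
    for leaf in node.leaf_iter():
        label = leaf.taxon.label
        if label not in fads:
            raise KeyError(label)
        ages.append(fads[label])
    return max(ages)


@dataclass
class DatedTree:
    """A tree with node ages in Ma and per-tip appearance dates.

    Node ages are stored in ``ages`` keyed by node; tips additionally
    carry first (fad) and last (lad) appearance dates.  Every branch has
    non-negative duration (child age <= parent age) and each tip sits at
    its fad.
    """

    tree: dendropy.Tree
    ages: dict[dendropy.Node, float]
    fads: dict[str, float]
    lads: dict[str, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                if self.ages[node] > self.ages[node.parent_node] + _TOL:
                    raise ValueError(
                        "child node older than its parent in dated tree"
                    )

    @property
    def root_age(self) -> float:
        return self.ages[self.tree.seed_node]

    def branch_lengths(self) -> list[float]:
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append(self.ages[node.parent_node] - self.ages[node])
        return out

    def lineage_spans(self) -> list[tuple[float, float]]:
        """(origin age, end age) of every lineage.

        A lineage runs from its parent node's age down to its child node's
        age; terminal lineages extend to the tip's last appearance.
        """
        spans = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            start = self.ages[node.parent_node]
            if node.is_leaf():
                end = self.lads.get(node.taxon.label, self.ages[node])
            else:
                end = self.ages[node]
            spans.append((start, end))
        return spans

    def tip_labels(self) -> list[str]:
        return tip_labels(self.tree)


def time_scale(
    tree: dendropy.Tree,
    fads: Mapping[str, float],
    lads: Mapping[str, float] | None = None,
    method: PolytomyMethod = "equal",
    root_extension: float = 5.0,
    rng: np.random.Generator | None = None,
) -> DatedTree:
    """Date a tree from tip first appearances.

    Basic dating places each internal node at the oldest first appearance
    among its descendant tips, which yields zero-length branches along
    every path to an oldest tip.  For the ``random`` and ``ordered``
    methods the polytomies are resolved first and the zero-length
    branches are left as dated (minimum-implied-gap ages); for ``equal``
    the tree keeps its topology and every run of zero-length branches
    then shares, in equal parts, the time of the first directly ancestral
    positive-length branch.  A root stem of ``root_extension`` Myr
    provides slack above the root, so the root node may move back in time
    under ``equal``.

    Tips lacking a last appearance are treated as point occurrences
    (lad = fad).
    """
    missing = [l for l in tip_labels(tree) if l not in fads]
    if missing:
        raise ValueError(f"no first appearance date for tip(s): {missing[:5]}")
    if root_extension < 0:
        raise ValueError("root_extension must be >= 0")
    work = resolve_polytomies(tree, method, fads=fads, rng=rng)
    ages: dict[dendropy.Node, float] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            ages[node] = float(fads[node.taxon.label])
        else:
            ages[node] = max(ages[c] for c in node.child_nodes())
    if method == "equal":
        _equalize_zero_branches(work, ages, root_extension)
    lads = dict(lads or {})
    full_lads = {
        l: float(lads.get(l, fads[l])) for l in tip_labels(work)
    }
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    return DatedTree(
        tree=work,
        ages=ages,
        fads={l: float(fads[l]) for l in tip_labels(work)},
        lads=full_lads,
        meta={"method": method, "root_extension": root_extension},
    )


def _equalize_zero_branches(
    tree: dendropy.Tree,
    ages: dict[dendropy.Node, float],
    root_extension: float,
) -> None:
    """Share each run of zero-length branches equally into the first
    ancestral positive-length branch (mutates ``ages`` in place)."""
    root = tree.seed_node
    stem_top = ages[root] + root_extension

    def edge_len(node: dendropy.Node) -> float:
        if node.parent_node is None:
            return stem_top - ages[node]
        return ages[node.parent_node] - ages[node]

    # Deepest-first, canonically keyed order: a maximal run of zero-length
    # branches is then handled in one pass from its deepest member, and the
    # result does not depend on tip input order.
    def sort_key(node: dendropy.Node):
        depth = 0
        cur = node
        while cur.parent_node is not None:
            depth += 1
            cur = cur.parent_node
        label = min(l.taxon.label for l in node.leaf_iter())
        return (-depth, label)

    for node in sorted(tree.preorder_node_iter(), key=sort_key):
        if edge_len(node) > _TOL:
            continue
        # walk up through consecutive zero-length branches to the first
        # positive-length ancestral branch
        path = [node]
        cur = node.parent_node
        while cur is not None and edge_len(cur) <= _TOL:
            path.append(cur)
            cur = cur.parent_node
        if cur is None:
            # no positive branch anywhere above (root_extension == 0)
            logger.warning(
                "no ancestral slack for a zero-length branch; leaving as is"
            )
            continue
        top_age = stem_top if cur.parent_node is None else ages[cur.parent_node]
        bottom_age = ages[node]
        chain = [cur] + list(reversed(path))  # top node ... bottom node
        k = len(chain) - 1 + 1  # edges: cur's own edge plus the zero run
        total = top_age - bottom_age
        for i, nd in enumerate(chain[:-1], start=1):
            ages[nd] = top_age - total * i / k
        # bottom node keeps its age (it is pinned by its fad)


def drop_tips(dtree: DatedTree, keep: set[str] | list[str]) -> DatedTree:
    """Subtree restricted to ``keep``; retained node ages are unchanged.

    Degree-two internal nodes left by the pruning are excised.
    """
    keep = set(keep)
    present = set(dtree.tip_labels())
    unknown = keep - present
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)[:5]}")
    if not keep:
        raise ValueError("cannot drop all tips")
    tree = _clone(dtree.tree)
    # the clone shares topology: annotate clone nodes with their ages via a
    # parallel preorder walk, so pruning preserves them on surviving nodes
    for orig, copy in zip(
        dtree.tree.preorder_node_iter(), tree.preorder_node_iter()
    ):
        copy.age_ma = dtree.ages[orig]
    tree.retain_taxa_with_labels(sorted(keep))
    tree.suppress_unifurcations()
    ages = {node: node.age_ma for node in tree.preorder_node_iter()}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    return DatedTree(
        tree=tree,
        ages=ages,
        fads={l: dtree.fads[l] for l in keep},
        lads={l: dtree.lads[l] for l in keep},
        meta=dict(dtree.meta),
    )


def collapse_to_genera(
    dtree: DatedTree,
    genus_of: Mapping[str, str] | None = None,
    mode: Literal["pooled", "earliest"] = "pooled",
) -> DatedTree:
    """Collapse species tips to one lineage per genus.

    ``pooled`` (default) keeps, per genus, the tip with the oldest first
    appearance and assigns it the genus's pooled fad-lad range;
    ``earliest`` keeps that tip with its own dates.  ``genus_of`` maps tip
    label to genus; by default the first whitespace-separated word of the
    label is used.
    """
    labels = dtree.tip_labels()
    if genus_of is None:
        genus_of = {l: l.split()[0].split("_")[0] for l in labels}
    by_genus: dict[str, list[str]] = {}
    for l in labels:
        by_genus.setdefault(genus_of[l], []).append(l)
    keep = []
    pooled: dict[str, tuple[float, float]] = {}
    for genus, members in by_genus.items():
        rep = max(members, key=lambda l: (dtree.fads[l], l))
        keep.append(rep)
        pooled[rep] = (
            max(dtree.fads[m] for m in members),
            min(dtree.lads[m] for m in members),
        )
    out = drop_tips(dtree, set(keep))
    if mode == "pooled":
        for rep, (fad, lad) in pooled.items():
            out.fads[rep] = fad
            out.lads[rep] = lad
    # relabel tips to genus names
    for leaf in out.tree.leaf_node_iter():
        old = leaf.taxon.label
        new = genus_of[old]
        leaf.taxon.label = new
        for d in (out.fads, out.lads):
            d[new] = d.pop(old)
    return out


def pde(dtree: DatedTree, scheme: BinScheme) -> DiversitySeries:
    """Ghost-lineage phylogenetic diversity per time bin.

    Counts lineages (branches, with terminal branches extended to the
    tip's last appearance) whose time span intersects each half-open bin
    ``[older, younger)``.  A lineage originating and ending inside one
    bin counts once in that bin.
    """
    spans = dtree.lineage_spans()
    values = np.zeros(len(scheme))
    for i, b in enumerate(scheme):
        n = 0
        for start, end in spans:
            if start > b.younger and end <= b.older:
                n += 1
        values[i] = n
    return DiversitySeries(
        scheme, values, label="pde", meta=dict(dtree.meta)
    )


def pde_estimate(
    tree: dendropy.Tree,
    fads: Mapping[str, float],
    lads: Mapping[str, float] | None,
    scheme: BinScheme,
    n_resolutions: int = 100,
    root_extension: float = 5.0,
    seed: int = 0,
) -> dict[str, DiversitySeries]:
    """PDE under all three dating strategies plus their mean.

    ``equal`` is deterministic and run once; ``random`` and ``ordered``
    are averaged over ``n_resolutions`` seeded polytomy resolutions each.
    Returns a dict with keys ``equal``, ``random``, ``ordered`` and
    ``mean`` (the reported series).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, DiversitySeries] = {}
    eq = pde(time_scale(tree, fads, lads, "equal", root_extension), scheme)
    eq.label = "pde_equal"
    out["equal"] = eq
    for method in ("random", "ordered"):
        acc = np.zeros((n_resolutions, len(scheme)))
        for r in range(n_resolutions):
            dt = time_scale(tree, fads, lads, method, root_extension, rng=rng)
            acc[r] = pde(dt, scheme).values
        out[method] = DiversitySeries(
            scheme,
            acc.mean(axis=0),
            dispersion=acc.std(axis=0, ddof=1) if n_resolutions > 1 else None,
            label=f"pde_{method}",
            meta={"n_resolutions": n_resolutions, "seed": seed},
        )
    stacked = np.vstack([out[m].values for m in ("equal", "random", "ordered")])
    out["mean"] = DiversitySeries(
        scheme,
        stacked.mean(axis=0),
        label="pde_mean",
        meta={"n_resolutions": n_resolutions, "seed": seed,
              "root_extension": root_extension},
    )
    return out
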