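"""Element tree inference: neighbor-joining, bootstrap, rough dating.

The element phylogeny is inferred by Saitou–Nei neighbor-joining on the
p-distance matrix, with nodal support from site-resampling bootstrap.
Dating is a deliberately simple calibrated-rate scaling: the midpoint-
rooted tree is ultrametricized (node height = mean root-to-tip path
below the node), a global substitution rate is taken as the mean of
height/age over the calibration nodes, and every node height is divided
by that rate.  It supports the ordering of transfer events in reports;
it is not a relaxed-clock analysis.

Determinism: ties in the NJ Q-criterion are broken by joining the
lowest-index pair; negative branch lengths are clamped to zero with a
warning.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .distances import DistanceMatrix, build_matrix


class ElementTree:
    """Element phylogeny with branch lengths in substitutions/site.

    Wraps a rooted dendropy tree.  ``support`` maps bipartitions (the
    frozenset of labels on the smaller, or lexicographically first, side)
    to bootstrap percentages; ``node_ages`` (Myr) appear after
    :func:`calibrate_ages`.
    """

    def __init__(self, tree: dendropy.Tree, labels: list[str]) -> None:
        tree.is_rooted = True
        self.tree = tree
        self.labels = list(labels)
        self.support: dict[frozenset, float] = {}
        self.node_ages: dict[frozenset, float] = {}
        self.rate: float | None = None

    # -- queries ---------------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return sorted(
            lf.taxon.label for lf in self.tree.leaf_node_iter()
        )

    def clades(self) -> set[frozenset]:
        """Leaf sets of internal nodes (rooted clades, non-trivial)."""
        out = set()
        n_all = len(self.leaf_labels())
        for node in self.tree.preorder_internal_node_iter():
            leaves = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            if 1 < len(leaves) < n_all:
                out.add(leaves)
        return out

    def bipartitions(self) -> set[frozenset]:
        """Unrooted splits, canonicalized to the side not containing the
        alphabetically first label."""
        first = min(self.leaf_labels())
        out = set()
        for side in self.clades():
            if first in side:
                side = frozenset(set(self.leaf_labels()) - side)
            if 1 < len(side):
                out.add(side)
        return out

    def is_monophyletic(self, labels: set[str]) -> bool:
        labels = set(labels)
        if len(labels) == 1:
            return True
        taxa = [
            self.tree.taxon_namespace.get_taxon(lab) for lab in labels
        ]
        if any(t is None for t in taxa):
            raise KeyError(f"labels not in tree: {labels}")
        mrca = self.tree.mrca(taxa=taxa)
        return {lf.taxon.label for lf in mrca.leaf_iter()} == labels

    def mrca_leafset(self, labels: set[str]) -> set[str]:
        taxa = [self.tree.taxon_namespace.get_taxon(lab) for lab in labels]
        missing = [lab for lab, t in zip(labels, taxa) if t is None]
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        mrca = self.tree.mrca(taxa=taxa)
        return {lf.taxon.label for lf in mrca.leaf_iter()}

    def mrca_age(self, labels: set[str]) -> float | None:
        """Calibrated age of the MRCA of ``labels`` (None if undated)."""
        key = frozenset(self.mrca_leafset(set(labels)))
        return self.node_ages.get(key)

    def to_newick(self) -> str:
        t = self.tree.clone(depth=1)
        for node in t.preorder_internal_node_iter():
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            sup = self.support.get(_canon(leaves, self.leaf_labels()))
            if sup is not None:
                node.label = f"{sup:g}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()


def _canon(side: frozenset, all_labels: list[str]) -> frozenset:
    """Canonical unrooted-split key: the side without the first label."""
    first = min(all_labels)
    if first in side:
        return frozenset(set(all_labels) - side)
    return side


def neighbor_joining(matrix: DistanceMatrix) -> ElementTree:
    """Saitou–Nei neighbor-joining.

    Requires all pairs computed; raises ``ValueError`` naming the
    offending pairs otherwise (exclude them and rebuild the matrix).
    """
    if matrix.not_computed:
        pairs = sorted(tuple(sorted(p)) for p in matrix.not_computed)
        raise ValueError(
            "distance matrix has not-computed pairs; exclude these "
            f"records first: {pairs}"
        )
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    taxa = dendropy.TaxonNamespace(labels)
    nodes = {}
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[lab] = nd
    D = matrix.d.astype(float).copy()
    active = list(range(n))
    node_of = {i: nodes[labels[i]] for i in active}
    next_id = n
    Dfull = {}
    for i in range(n):
        for j in range(n):
            Dfull[(i, j)] = D[i, j]

    def dist(i, j):
        return Dfull[(i, j)]

    while len(active) > 2:
        m = len(active)
        # Q-matrix; lowest-index tie break on (i, j) with i < j
        best = None
        row_sums = {i: sum(dist(i, k) for k in active if k != i)
                    for i in active}
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist(i, j) - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        # branch lengths to the new node
        if m > 2:
            li = 0.5 * dist(i, j) + (row_sums[i] - row_sums[j]) / (
                2 * (m - 2))
        else:
            li = 0.5 * dist(i, j)
        lj = dist(i, j) - li
        li, lj = _clamp(li), _clamp(lj)
        parent = dendropy.Node()
        ni, nj = node_of[i], node_of[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            Dfull[(u, k)] = Dfull[(k, u)] = _clamp(
                0.5 * (dist(i, k) + dist(j, k) - dist(i, j))
            )
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = parent

    i, j = active
    root = dendropy.Node()
    ni, nj = node_of[i], node_of[j]
    root.add_child(ni)
    root.add_child(nj)
    d_ij = _clamp(dist(i, j))
    ni.edge.length = d_ij / 2
    nj.edge.length = d_ij / 2
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return ElementTree(tree, labels)


def _clamp(x: float) -> float:
    if x < 0:
        if x < -1e-9:
            warnings.warn(
                f"negative branch length {x:.3g} clamped to 0",
                stacklevel=2,
            )
        return 0.0
    return float(x)


def midpoint_root(etree: ElementTree) -> ElementTree:
    t = etree.tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True,
                         suppress_unifurcations=True)
    out = ElementTree(t, etree.labels)
    out.support = dict(etree.support)
    return out


def outgroup_root(etree: ElementTree,
                  outgroup: str | set[str]) -> ElementTree:
    """Root on the edge separating the outgroup from everything else.

    ``outgroup`` may be a single label or a label set that forms one
    side of an unrooted split of the tree.
    """
    t = etree.tree.clone(depth=1)
    labels = set(lf.taxon.label for lf in t.leaf_node_iter())
    og = {outgroup} if isinstance(outgroup, str) else set(outgroup)
    if not og <= labels:
        raise KeyError(f"outgroup not in tree: {sorted(og - labels)}")
    if len(og) == 1:
        edge = t.find_node_with_taxon_label(next(iter(og))).edge
    else:
        edge = None
        for node in t.preorder_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if leaves == og or leaves == labels - og:
                edge = node.edge
                break
        if edge is None or edge.tail_node is None:
            raise ValueError(
                f"outgroup {sorted(og)} is not a split of the tree"
            )
    t.reroot_at_edge(edge, update_bipartitions=True,
                     suppress_unifurcations=True)
    out = ElementTree(t, etree.labels)
    out.support = dict(etree.support)
    return out


def bootstrap_supports(
    records: dict[str, str],
    n_reps: int = 100,
    seed: int = 0,
    mode: str = "nt",
    coverage: dict[str, tuple[int, int]] | None = None,
    tree: ElementTree | None = None,
) -> ElementTree:
    """Site-resampling bootstrap supports for the NJ tree.

    Columns are resampled with replacement, the matrix and NJ tree
    rebuilt per replicate, and each internal edge of the point-estimate
    tree is annotated with the percentage of replicates containing its
    bipartition.  Reproducible for a fixed ``seed``.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be >= 1")
    lengths = {len(s) for s in records.values()}
    if len(lengths) != 1:
        raise ValueError("records are not aligned")
    ncol = lengths.pop()
    if tree is None:
        tree = neighbor_joining(
            build_matrix(records, mode=mode, coverage=coverage)
        )
    labels = list(records)
    rows = {
        lab: np.frombuffer(s.upper().encode(), dtype="S1")
        for lab, s in records.items()
    }
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {
        bp: 0 for bp in tree.bipartitions()
    }
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = {
            lab: rows[lab][idx].tobytes().decode() for lab in labels
        }
        # coverage intervals do not survive column resampling; fragments
        # contribute their missingness via the resampled '-' columns
        rep_tree = neighbor_joining(build_matrix(rep, mode=mode))
        rep_bps = rep_tree.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    tree.support = {
        bp: 100.0 * c / n_reps for bp, c in counts.items()
    }
    return tree


def calibrate_ages(
    etree: ElementTree,
    calibrations: list[tuple[str, str, float]],
) -> ElementTree:
    """Scale the (rooted) element tree to absolute time.

    Each calibration is ``(label_a, label_b, age_myr)`` anchoring the
    MRCA of the two leaves.  Node height is the mean root-to-tip path
    below the node; the global rate is the mean over calibrations of
    height/age (substitutions/site/Myr); estimated node age is
    height/rate.  Stored in ``node_ages`` keyed by clade leaf set,
    and the rate in ``etree.rate``.
    """
    if not calibrations:
        raise ValueError("at least one calibration required")
    heights = {}
    for node in etree.tree.preorder_internal_node_iter():
        paths = []
        for lf in node.leaf_iter():
            d = 0.0
            nd = lf
            while nd is not node:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            paths.append(d)
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        heights[leaves] = float(np.mean(paths))
    rates = []
    for a, b, age in calibrations:
        key = frozenset(etree.mrca_leafset({a, b}))
        if key not in heights:
            raise KeyError(f"calibration pair ({a}, {b}) has no node")
        if age <= 0:
            raise ValueError("calibration age must be positive")
        rates.append(heights[key] / age)
    rate = float(np.mean(rates))
    if rate <= 0:
        raise ValueError("calibration implies non-positive rate")
    etree.rate = rate
    etree.node_ages = {k: h / rate for k, h in heights.items()}
    return etree
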