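"""Dated host phylogeny: split-age and monophyly queries.

The host tree is an ultrametric chronogram with branch lengths in Myr;
internal-node ages are recovered as tree height minus root-to-node path
length.  The bundled five-taxon *Bacillus* chronogram places the basal
split (the *B. rossius* lineage versus the rest) at 22.8 Myr, the
*B. grandii*/*B. atticus* radiation at 17 Myr, the *B. g. grandii* /
*B. atticus* split at 15.4 Myr and the *B. g. benazzii* /
*B. g. maretimi* split at 2 Myr.
"""

from __future__ import annotations

import importlib.resources

import dendropy


class NonUltrametricError(ValueError):
    """Leaf depths disagree beyond tolerance; offending leaves listed."""


class UnknownTaxonError(KeyError):
    pass


class DatedHostTree:
    """Rooted ultrametric host phylogeny with node ages in Myr.

    ``surveyed`` is the set of taxa whose genomes were actually screened
    for elements; absence statements (patchy distribution) are only
    meaningful over surveyed taxa.  Defaults to all leaves.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        surveyed: set[str] | None = None,
        tol: float = 1e-6,
    ) -> None:
        self.tree = tree
        self.tree.is_rooted = True
        self.tree.update_bipartitions(suppress_unifurcations=False)
        self.tree.calc_node_ages(ultrametricity_precision=False)
        depths = {}
        for leaf in tree.leaf_node_iter():
            depths[leaf.taxon.label] = leaf.distance_from_root()
        vals = sorted(depths.values())
        ref = vals[len(vals) // 2]  # median depth: robust reference
        height = max(vals)
        bad = sorted(
            lab for lab, dep in depths.items()
            if abs(dep - ref) > tol * max(ref, 1.0)
        )
        if bad:
            raise NonUltrametricError(
                f"tree is not ultrametric; offending leaves: {bad}"
            )
        self.taxa = sorted(depths)
        self.surveyed = set(surveyed) if surveyed is not None \
            else set(self.taxa)
        unknown = self.surveyed - set(self.taxa)
        if unknown:
            raise UnknownTaxonError(
                f"surveyed taxa not in tree: {sorted(unknown)}"
            )
        self._height = height
        # age per node = height - depth
        self._ages = {}
        for node in tree.preorder_node_iter():
            self._ages[node] = height - node.distance_from_root()

    @property
    def root_age(self) -> float:
        return self._height

    def node_ages(self) -> list[float]:
        """Ages of internal nodes, descending."""
        return sorted(
            (self._ages[n] for n in self.tree.preorder_internal_node_iter()
             if len(n.child_nodes()) > 1 or n is self.tree.seed_node),
            reverse=True,
        )

    def _leaf(self, taxon: str) -> dendropy.Node:
        nd = self.tree.find_node_with_taxon_label(taxon)
        if nd is None:
            raise UnknownTaxonError(taxon)
        return nd

    def split_age(self, taxon_a: str, taxon_b: str) -> float:
        """Age (Myr) of the most recent common ancestor of two leaves."""
        if taxon_a == taxon_b:
            self._leaf(taxon_a)
            return 0.0
        a, b = self._leaf(taxon_a), self._leaf(taxon_b)
        mrca = self.tree.mrca(taxa=[a.taxon, b.taxon])
        return float(self._ages[mrca])

    def is_clade(self, taxa: set[str]) -> bool:
        """True iff ``taxa`` equals the full leaf set of some node."""
        taxa = set(taxa)
        if not taxa:
            raise ValueError("empty taxon set")
        for t in taxa:
            self._leaf(t)
        if len(taxa) == 1:
            return True
        mrca = self.tree.mrca(
            taxa=[self._leaf(t).taxon for t in taxa]
        )
        leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        return leaves == taxa

    def is_clade_among_surveyed(self, taxa: set[str]) -> bool:
        """Monophyly on the host tree restricted to surveyed taxa."""
        taxa = set(taxa)
        if not taxa <= self.surveyed:
            raise UnknownTaxonError(
                f"taxa outside surveyed set: {sorted(taxa - self.surveyed)}"
            )
        if len(taxa) == 1:
            return True
        mrca = self.tree.mrca(taxa=[self._leaf(t).taxon for t in taxa])
        leaves = {
            lf.taxon.label for lf in mrca.leaf_iter()
        } & self.surveyed
        return leaves == taxa

    def bipartitions(self) -> list[tuple[set[str], set[str]]]:
        """Non-trivial (clade, complement) splits of the host tree."""
        all_taxa = set(self.taxa)
        out = []
        for node in self.tree.preorder_internal_node_iter():
            leaves = {lf.taxon.label for lf in node.leaf_iter()}
            if 1 < len(leaves) < len(all_taxa):
                out.append((leaves, all_taxa - leaves))
        return out

    def ages_table(self):
        """Pairwise split ages as a tidy DataFrame."""
        import pandas as pd

        rows = []
        for i, a in enumerate(self.taxa):
            for b in self.taxa[i + 1:]:
                rows.append({"taxon_a": a, "taxon_b": b,
                             "split_age_myr": self.split_age(a, b)})
        return pd.DataFrame(rows)


def parse_dated_newick(
    text: str,
    surveyed: set[str] | None = None,
    tol: float = 1e-6,
) -> DatedHostTree:
    """Parse a Newick chronogram (branch lengths in Myr)."""
    tree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return DatedHostTree(tree, surveyed=surveyed, tol=tol)


def load_fixture_host_tree(surveyed: set[str] | None = None) -> \
        DatedHostTree:
    """The bundled five-taxon *Bacillus* chronogram."""
    text = (
        importlib.resources.files("r2ht.data") / "host_tree.nwk"
    ).read_text()
    return parse_dated_newick(text, surveyed=surveyed)
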