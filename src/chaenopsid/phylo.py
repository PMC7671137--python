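"""Rooted-tree model, Newick I/O, and composite-phylogeny assembly.

Species-level relationships are known for only some chaenopsid genera, so
the family tree used for character mapping is a composite: a genus-level
backbone with within-genus polytomies (and one named species group inside
*Emblemaria*).  Trees are rooted; polytomies are permitted and meaningful
(hard or soft semantics are chosen at mapping time, not here).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import yaml

from .characters import fixture_path

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    """Raised for malformed trees or irreconcilable backbone specs."""


class Phylogeny:
    """A rooted tree with uniquely labelled tips; thin dendropy wrapper."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.normalize()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls(tree)

    @classmethod
    def star(cls, tips: Iterable[str]) -> "Phylogeny":
        """A single root polytomy over ``tips``."""
        labels = list(tips)
        newick = "(" + ",".join(labels) + ");"
        return cls.from_newick(newick)

    def normalize(self) -> None:
        """Suppress unary internal nodes and validate tip-label uniqueness."""
        self._tree.suppress_unifurcations()
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if not labels:
            raise TreeError("tree has no labelled tips")

    # -- views ---------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def tip_labels(self) -> list[str]:
        out = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is not None and leaf.taxon.label:
                out.append(leaf.taxon.label)
            elif leaf.label:
                out.append(leaf.label)
            else:
                raise TreeError("unlabelled tip")
        return out

    def n_tips(self) -> int:
        return len(self.tip_labels())

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def max_out_degree(self) -> int:
        return max(
            (len(n.child_nodes()) for n in self.postorder()), default=0
        )

    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) in (0, 2) for n in self.postorder()
        )

    def tip_bipartition(self, clade_tips: set[str]) -> bool:
        """True if some edge splits exactly ``clade_tips`` from the rest."""
        for node in self.postorder():
            below = {
                leaf.taxon.label for leaf in node.leaf_iter()
            }
            if below == clade_tips:
                return True
        return False

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
        return s

    def clone(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())


def node_label(node: dendropy.Node) -> str:
    """Stable human-readable label for any node (tips by taxon label)."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    leaves = sorted(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    )
    return f"mrca({leaves[0]}..{leaves[-1]},n={len(leaves)})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree; branch lengths are ignored downstream."""
    return Phylogeny.from_newick(Path(path).read_text())


def write_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Composite assembly
# ---------------------------------------------------------------------------

def load_backbone(path: str | Path | None = None) -> dict:
    """Load a backbone spec (YAML). Defaults to the packaged family backbone."""
    if path is None:
        path = fixture_path("backbone.yaml")
    spec = yaml.safe_load(Path(path).read_text())
    if not isinstance(spec, dict) or "backbone" not in spec:
        raise TreeError("backbone spec needs a top-level 'backbone' mapping")
    return spec


def genus_of(species: str) -> str:
    """Genus is the first whitespace-separated token of the species name."""
    return species.split()[0]


def species_by_genus(species: Iterable[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for sp in species:
        out.setdefault(genus_of(sp), []).append(sp)
    for members in out.values():
        members.sort()
    return out


def _genus_newick(
    genus: str,
    members: list[str],
    subgroups: Mapping[str, list[dict]] | None,
) -> str:
    """Newick fragment for one genus: polytomy, with named subgroup clades."""
    quoted = {sp: "'" + sp.replace("'", "''") + "'" for sp in members}
    groups = (subgroups or {}).get(genus, [])
    grouped: set[str] = set()
    parts: list[str] = []
    for grp in groups:
        gmembers = [sp for sp in grp["members"] if sp in members]
        absent = [sp for sp in grp["members"] if sp not in members]
        if absent:
            logger.warning(
                "subgroup %s: members not in sample, dropped: %s",
                grp.get("name", "?"), absent,
            )
        if len(gmembers) >= 2:
            parts.append("(" + ",".join(quoted[sp] for sp in gmembers) + ")")
            grouped.update(gmembers)
        elif gmembers:
            grouped.update(gmembers)  # singleton group degenerates to a tip
            parts.append(quoted[gmembers[0]])
    parts.extend(quoted[sp] for sp in members if sp not in grouped)
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(parts) + ")"


def _clade_newick(
    node: dict,
    membership: Mapping[str, list[str]],
    subgroups: Mapping[str, list[dict]] | None,
    used_genera: set[str],
    allow_partial: bool,
) -> str | None:
    if "genus" in node:
        genus = node["genus"]
        members = membership.get(genus, [])
        if not members:
            msg = f"backbone genus {genus!r} has no sampled species"
            if allow_partial:
                logger.warning("%s; dropped from tree", msg)
                return None
            raise TreeError(msg)
        used_genera.add(genus)
        return _genus_newick(genus, members, subgroups)
    if "children" not in node:
        raise TreeError(f"backbone node without 'genus' or 'children': {node}")
    parts = [
        frag
        for child in node["children"]
        if (
            frag := _clade_newick(
                child, membership, subgroups, used_genera, allow_partial
            )
        )
        is not None
    ]
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    return "(" + ",".join(parts) + ")"


def assemble_composite(
    spec: dict | None = None,
    species: Iterable[str] | None = None,
    allow_partial: bool = False,
) -> Phylogeny:
    """Build the composite phylogeny from a backbone spec and a species list.

    ``species`` defaults to the species of the packaged count table.  Every
    sampled species must be placed exactly once and every backbone genus must
    have sampled members, otherwise a reconciliation error is raised (relaxed
    to warnings by ``allow_partial``).  Assembly is deterministic: species
    are sorted within genera, so identical inputs give an identical Newick
    string.
    """
    if spec is None:
        spec = load_backbone()
    if species is None:
        from .characters import read_count_table

        species = list(read_count_table()["species"])
    species = list(species)
    membership = species_by_genus(species)
    subgroups = spec.get("subgroups")
    used: set[str] = set()
    newick = _clade_newick(
        spec["backbone"], membership, subgroups, used, allow_partial
    )
    if newick is None:
        raise TreeError("backbone resolved to an empty tree")
    stray = sorted(set(membership) - used)
    if stray:
        msg = f"sampled genera missing from backbone: {stray}"
        if not allow_partial:
            raise TreeError(msg)
        logger.warning("%s; their species are not in the tree", msg)
    tree = Phylogeny.from_newick(newick + ";")
    placed = set(tree.tip_labels())
    expected = {sp for g in used for sp in membership[g]}
    if placed != expected:  # pragma: no cover - guarded by construction
        raise TreeError(
            f"reconciliation failure: tree tips != sampled species "
            f"(missing {sorted(expected - placed)}, "
            f"extra {sorted(placed - expected)})"
        )
    return tree


def composite_tree() -> Phylogeny:
    """The packaged default composite tree (66 tips)."""
    return read_newick(fixture_path("composite_tree.nwk"))
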