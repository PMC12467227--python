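"""Taxonomy trees and irreversible-loss (Dollo) ancestral reconstruction.

A trait (a TOR-complex component, or a complex defined by its diagnostic
scaffold) is assumed to have been gained once, at or above the root, and to be
lost irreversibly along lineages.  Under that model the minimum-loss ancestral
labelling is unique: an internal node is trait-present exactly when some
non-missing descendant tip is present, and each maximal subtree containing
absent tips but no present tips hangs from one "loss edge".  The number of loss
edges is the number of independent loss events, and presence on two or more
lineages stemming from the root implies presence in the root ancestor (for the
eukaryote tree, LECA).

Taxonomy trees (e.g. NCBI Common Tree exports) are rooted and frequently
multifurcating; polytomies are evaluated child-by-child, so a polytomy with k
all-absent children under a present parent counts k losses — the conservative
(maximal) count for that unresolved topology.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"

#: tiers that count as a detection when converting a tier matrix to tip states
PRESENT_TIERS = frozenset({"H", "M", "L", "P"})

#: complex -> diagnostic scaffold component
COMPLEX_SCAFFOLD = {"TORC1": "RAPTOR", "TORC2": "RICTOR"}


class TaxonTree:
    """Rooted, possibly multifurcating tree with uniquely labelled nodes.

    Tips carry species ids; internal nodes keep their Newick labels when
    present and otherwise receive stable auto-labels ``N<k>`` in preorder.
    Edges are identified by their child node label.
    """

    def __init__(self) -> None:
        self.root: str = ""
        self._children: dict[str, tuple[str, ...]] = {}
        self._parent: dict[str, str | None] = {}
        self._auto: set[str] = set()
        self.clade_map: dict[str, str] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "TaxonTree":
        """Parse a Newick string; branch lengths are ignored, polytomies kept."""
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "TaxonTree":
        tree = cls()
        labels: dict[int, str] = {}
        seen: set[str] = set()
        counter = 0
        for node in dtree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if not label:
                    raise ValueError("tip without a label")
            else:
                label = node.label
                if not label:
                    counter += 1
                    label = f"N{counter}"
                    while label in seen:
                        counter += 1
                        label = f"N{counter}"
                    tree._auto.add(label)
            if label in seen:
                kind = "tip" if node.is_leaf() else "node"
                raise ValueError(f"duplicate {kind} label: {label!r}")
            seen.add(label)
            labels[id(node)] = label
        for node in dtree.preorder_node_iter():
            label = labels[id(node)]
            tree._children[label] = tuple(labels[id(c)] for c in node.child_nodes())
            parent = node.parent_node
            tree._parent[label] = labels[id(parent)] if parent is not None else None
            if tree._parent[label] is None:
                tree.root = label
        return tree

    @classmethod
    def build(
        cls,
        children: Mapping[str, Iterable[str]],
        root: str,
        clade_map: Mapping[str, str] | None = None,
    ) -> "TaxonTree":
        """Build from an explicit child mapping (used by the simulator)."""
        tree = cls()
        tree.root = root
        tree._children = {k: tuple(v) for k, v in children.items()}
        tree._parent = {root: None}
        stack = [root]
        while stack:
            node = stack.pop()
            tree._children.setdefault(node, ())
            for child in tree._children[node]:
                tree._parent[child] = node
                stack.append(child)
        if clade_map:
            tree.clade_map = dict(clade_map)
        return tree

    # -- queries ------------------------------------------------------------

    def children(self, label: str) -> tuple[str, ...]:
        return self._children[label]

    def parent(self, label: str) -> str | None:
        return self._parent[label]

    def is_tip(self, label: str) -> bool:
        return not self._children[label]

    @property
    def tip_labels(self) -> list[str]:
        return [n for n in self.preorder() if self.is_tip(n)]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._children.values() if not n)

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self._children[node]))
        return out

    def postorder(self) -> list[str]:
        return list(reversed(self._topdown()))

    def _topdown(self) -> list[str]:
        # preorder-like ordering in which every parent precedes its children
        return self.preorder()

    def subtree_tips(self, label: str) -> list[str]:
        out: list[str] = []
        stack = [label]
        while stack:
            node = stack.pop()
            if self.is_tip(node):
                out.append(node)
            else:
                stack.extend(reversed(self._children[node]))
        return out

    def neighbors(self, label: str) -> list[str]:
        """Adjacent nodes in the undirected tree graph."""
        out = list(self._children[label])
        parent = self._parent[label]
        if parent is not None:
            out.append(parent)
        return out

    def tips_within(self, tip: str, radius: int) -> list[str]:
        """Other tips reachable within ``radius`` edges of ``tip``."""
        seen = {tip}
        frontier = [tip]
        found: list[str] = []
        for _ in range(radius):
            nxt: list[str] = []
            for node in frontier:
                for nb in self.neighbors(node):
                    if nb not in seen:
                        seen.add(nb)
                        nxt.append(nb)
                        if self.is_tip(nb):
                            found.append(nb)
            frontier = nxt
        return found

    def has_polytomy(self) -> bool:
        return any(len(c) > 2 for c in self._children.values())

    # -- serialisation ------------------------------------------------------

    def to_newick(self, node_comments: Mapping[str, str] | None = None) -> str:
        """Write Newick preserving child order; auto internal labels omitted.

        ``node_comments`` attaches a ``[&state=...]`` comment per node label,
        used for the annotated reconstruction output.
        """

        def render(label: str) -> str:
            kids = self._children[label]
            if kids:
                body = "(" + ",".join(render(k) for k in kids) + ")"
                name = "" if label in self._auto else label
            else:
                body = ""
                name = label
            comment = ""
            if node_comments and label in node_comments:
                comment = f"[&state={node_comments[label]}]"
            return body + name + comment

        return render(self.root) + ";"


def read_tree(source: str) -> TaxonTree:
    """Read a Newick tree from a string or a file path."""
    text = source
    if "(" not in source:  # no Newick structure -> treat as path
        with io.open(source, "r") as fh:
            text = fh.read()
    return TaxonTree.from_newick(text)


@dataclass(frozen=True)
class LossReconstruction:
    """Minimum-loss ancestral labelling for one trait on one tree."""

    trait: str
    node_states: Mapping[str, str]
    loss_edges: frozenset
    root_state: str
    tips_unknown: frozenset = field(default_factory=frozenset)

    @property
    def n_independent_losses(self) -> int:
        return len(self.loss_edges)


def dollo_reconstruct(
    tree: TaxonTree, tip_states: Mapping[str, str], trait: str = ""
) -> LossReconstruction:
    """Minimum-loss reconstruction of ancestral states under irreversibility.

    ``tip_states`` maps every tip to ``present``/``absent``/``unknown``.  An
    internal node is present iff any non-unknown descendant tip is present; a
    loss edge is recorded at every edge whose parent is present and whose child
    subtree contains no present tip and at least one absent tip.  Subtrees
    consisting solely of unknown tips inherit the parent state and contribute
    no loss edges.
    """
    tips = set(tree.tip_labels)
    missing = tips.difference(tip_states)
    if missing:
        raise ValueError(f"tips without a state: {sorted(missing)[:5]}")

    has_p: dict[str, bool] = {}
    has_a: dict[str, bool] = {}
    for node in tree.postorder():
        if tree.is_tip(node):
            state = tip_states[node]
            if state not in (PRESENT, ABSENT, UNKNOWN):
                raise ValueError(f"bad state {state!r} for tip {node!r}")
            has_p[node] = state == PRESENT
            has_a[node] = state == ABSENT
        else:
            kids = tree.children(node)
            has_p[node] = any(has_p[k] for k in kids)
            has_a[node] = any(has_a[k] for k in kids)

    states: dict[str, str] = {}
    losses: set[str] = set()
    root = tree.root
    states[root] = PRESENT if has_p[root] else ABSENT
    for node in tree.preorder():
        if node == root:
            continue
        parent_state = states[tree.parent(node)]
        if parent_state == ABSENT:
            states[node] = ABSENT
        elif has_p[node]:
            states[node] = PRESENT
        elif has_a[node]:
            states[node] = ABSENT
            losses.add(node)
        else:  # unknown-only subtree: inherit, no loss evidence
            states[node] = PRESENT

    unknown_tips = frozenset(t for t in tips if tip_states[t] == UNKNOWN)
    return LossReconstruction(
        trait=trait,
        node_states=states,
        loss_edges=frozenset(losses),
        root_state=states[root],
        tips_unknown=unknown_tips,
    )


def infer_root_state(tree: TaxonTree, tip_states: Mapping[str, str]) -> str:
    """Classify the root (LECA) state of a trait under irreversibility.

    Returns ``present_at_root`` when present tips occur under at least two
    distinct children of the root (the single gain must then sit at or above
    the root), ``origin_within_tree`` when presence is confined to one root
    child's subtree, and ``absent`` when no tip is present.
    """
    present_tips = {t for t, s in tip_states.items() if s == PRESENT}
    if not present_tips:
        return "absent"
    n_root_lineages = 0
    for child in tree.children(tree.root):
        if present_tips.intersection(tree.subtree_tips(child)):
            n_root_lineages += 1
    return "present_at_root" if n_root_lineages >= 2 else "origin_within_tree"


def tier_matrix_to_tip_states(
    tiers: pd.DataFrame,
    trait: str,
    completeness: Mapping[str, float] | None = None,
    unknown_policy: str = "absent",
    busco_low_threshold: float = 0.70,
) -> dict[str, str]:
    """Convert a species x component tier matrix to tip states for one trait.

    ``trait`` is a component name or a complex name (TORC1/TORC2, read from the
    diagnostic scaffold).  With ``unknown_policy='missing'``, an ABS call from a
    species with completeness below ``busco_low_threshold`` is treated as
    missing data rather than genuine absence.
    """
    component = COMPLEX_SCAFFOLD.get(trait, trait)
    if component not in tiers.columns:
        raise KeyError(f"component {component!r} not in tier matrix")
    if unknown_policy not in ("absent", "missing"):
        raise ValueError(f"unknown policy {unknown_policy!r}")
    states: dict[str, str] = {}
    for species, tier in tiers[component].items():
        if tier in PRESENT_TIERS:
            states[species] = PRESENT
        elif (
            unknown_policy == "missing"
            and completeness is not None
            and completeness.get(species, 1.0) < busco_low_threshold
        ):
            states[species] = UNKNOWN
        else:
            states[species] = ABSENT
    return states


def count_losses_per_trait(
    tiers: pd.DataFrame,
    tree: TaxonTree,
    completeness: Mapping[str, float] | None = None,
    unknown_policy: str = "absent",
    busco_low_threshold: float = 0.70,
) -> dict[str, LossReconstruction]:
    """Dollo reconstructions for every component and both complexes.

    Species present in the matrix must be tips of the tree; extra tips are
    allowed and treated as unknown.
    """
    extra = set(tiers.index).difference(tree.tip_labels)
    if extra:
        raise ValueError(f"matrix species not in tree: {sorted(extra)[:5]}")
    traits = list(tiers.columns) + list(COMPLEX_SCAFFOLD)
    out: dict[str, LossReconstruction] = {}
    all_tips = tree.tip_labels
    for trait in traits:
        states = tier_matrix_to_tip_states(
            tiers, trait, completeness, unknown_policy, busco_low_threshold
        )
        for tip in all_tips:
            states.setdefault(tip, UNKNOWN)
        out[trait] = dollo_reconstruct(tree, states, trait=trait)
    return out


def loss_table(reconstructions: Mapping[str, LossReconstruction]) -> pd.DataFrame:
    """Summary table: one row per trait with loss count, edges and root state."""
    rows = []
    for trait, rec in reconstructions.items():
        rows.append(
            {
                "trait": trait,
                "n_losses": rec.n_independent_losses,
                "loss_edges": ";".join(sorted(rec.loss_edges)),
                "root_state": rec.root_state,
                "n_unknown_tips": len(rec.tips_unknown),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# Worked examples: presence/absence patterns reported for three alveolate and
# stramenopile lineages, on NCBI-taxonomy topologies.  These are the published
# qualitative patterns (per-clade component presence), encoded as inputs.
# ---------------------------------------------------------------------------

ALVEOLATA_NEWICK = (
    "(((((Polarella_glacialis,Symbiodinium_endosymbionts)Suessiales,"
    "Amoebophrya)Dinophyceae,Perkinsozoa),"
    "((Chromera_velia,Vitrella_brassicaformis)Chromerida,Apicomplexa))Myzozoa,"
    "Ciliophora)Alveolata;"
)

# Reported complex presence per taxon: dinoflagellate endosymbionts and the
# parasitic Amoebophrya lack both complexes, apicomplexans lack both, Chromera
# retains TORC1 only, ciliates retain TORC2 only.
ALVEOLATA_PRESENCE = {
    "TORC1": {
        "Polarella_glacialis": PRESENT,
        "Symbiodinium_endosymbionts": ABSENT,
        "Amoebophrya": ABSENT,
        "Perkinsozoa": PRESENT,
        "Chromera_velia": PRESENT,
        "Vitrella_brassicaformis": PRESENT,
        "Apicomplexa": ABSENT,
        "Ciliophora": ABSENT,
    },
    "TORC2": {
        "Polarella_glacialis": PRESENT,
        "Symbiodinium_endosymbionts": ABSENT,
        "Amoebophrya": ABSENT,
        "Perkinsozoa": PRESENT,
        "Chromera_velia": ABSENT,
        "Vitrella_brassicaformis": PRESENT,
        "Apicomplexa": ABSENT,
        "Ciliophora": PRESENT,
    },
}

DINOPHYCEAE_NEWICK = (
    "((Polarella_glacialis,Symbiodinium_endosymbionts)Suessiales,"
    "Amoebophrya)Dinophyceae;"
)

OCHROPHYTA_NEWICK = (
    "(((Bacillariophyta,Parmales),Pelagophyceae),Phaeophyceae)Ochrophyta;"
)

# TORC2 is uniformly absent from diatoms and pelagophytes but retained in the
# sister Parmales and in brown algae.
OCHROPHYTA_TORC2 = {
    "Bacillariophyta": ABSENT,
    "Parmales": PRESENT,
    "Pelagophyceae": ABSENT,
    "Phaeophyceae": PRESENT,
}


def alveolata_example() -> tuple[TaxonTree, dict[str, dict[str, str]]]:
    """Alveolata supergroup case: returns (tree, {complex: tip states})."""
    return TaxonTree.from_newick(ALVEOLATA_NEWICK), {
        k: dict(v) for k, v in ALVEOLATA_PRESENCE.items()
    }


def dinophyceae_example() -> tuple[TaxonTree, dict[str, dict[str, str]]]:
    """Dinoflagellate subtree of the Alveolata case."""
    tree = TaxonTree.from_newick(DINOPHYCEAE_NEWICK)
    tips = set(tree.tip_labels)
    states = {
        cplx: {t: s for t, s in full.items() if t in tips}
        for cplx, full in ALVEOLATA_PRESENCE.items()
    }
    return tree, states


def ochrophyta_example() -> tuple[TaxonTree, dict[str, str]]:
    """Ochrophyta TORC2 case: returns (tree, tip states for TORC2)."""
    return TaxonTree.from_newick(OCHROPHYTA_NEWICK), dict(OCHROPHYTA_TORC2)
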