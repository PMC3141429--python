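"""Dollo-parsimony gain/loss inference for gene families on a rooted species tree.

The model: each gene family arises exactly once (a single *gain* on one branch)
and may subsequently be lost any number of times, with losses irreversible.
Under this model the minimum-loss explanation of a presence/absence row is
unique: the gain sits on the branch entering the most recent common ancestor
(MRCA) of all species carrying the family, and one loss sits on the stem
branch of every maximal subtree within that clade whose surveyed species all
lack the family.  This is exactly the outgroup polarization argument used to
resolve a human/mouse difference into a primate-lineage gain versus a
rodent-lineage loss: if relatives of the gene survive in an outgroup clade,
the family must predate the split and its absence is secondary.

Unknown states (unsurveyed species or unassembled regions) never force a
loss and are excluded from the MRCA computation.

Branches are addressed as ``"parent_label>child_label"`` strings, with
deterministic internal-node labels built from the smallest leaf labels of each
child subtree, so event reports are stable and diffable.  The branch entering
the root is ``"root>..."``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy

from .matrix import ABSENT, PRESENT, UNKNOWN, PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "SpeciesTree",
    "EventMap",
    "FamilyEvents",
    "parse_tree",
    "infer_events",
    "replay_events",
    "lineage_summary",
    "brute_force_oracle",
]


@dataclass
class Node:
    label: str
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # keep debugger output short
        return f"Node({self.label!r})"


class SpeciesTree:
    """A rooted species tree with addressable, deterministically named branches."""

    def __init__(self, root: Node):
        self.root = root
        self._by_label: dict[str, Node] = {}
        for node in self.preorder():
            if node.label in self._by_label:
                raise ValueError(f"duplicate node label {node.label!r}")
            self._by_label[node.label] = node
        self._leaves_under: dict[str, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                self._leaves_under[node.label] = frozenset([node.label])
            else:
                self._leaves_under[node.label] = frozenset().union(
                    *(self._leaves_under[c.label] for c in node.children)
                )

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        if "[&U]" in newick.upper().replace(" ", ""):
            raise ValueError("tree is flagged unrooted; a rooted tree is required")
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        leaf_names = [lf.taxon.label for lf in dtree.leaf_node_iter() if lf.taxon]
        if len(set(leaf_names)) != len(leaf_names):
            raise ValueError("duplicate leaf labels in tree")

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                if dnode.taxon is None:
                    raise ValueError("leaf without a label")
                return Node(label=dnode.taxon.label)
            node = Node(label="")
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        root = convert(dtree.seed_node)
        _assign_internal_labels(root)
        return cls(root)

    def newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                return node.label
            return "(" + ",".join(render(c) for c in node.children) + ")"

        return render(self.root) + ";"

    # -- traversal and lookup -----------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def node(self, label: str) -> Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.preorder() if n.is_leaf]

    def leaves_under(self, node: Node | str) -> frozenset[str]:
        label = node if isinstance(node, str) else node.label
        return self._leaves_under[label]

    def mrca(self, labels) -> Node:
        labels = set(labels)
        missing = labels - set(self.leaf_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        node = self.node(next(iter(labels)))
        while not labels <= self._leaves_under[node.label]:
            node = node.parent
        return node

    # -- branch addressing --------------------------------------------

    def branch_name(self, node: Node) -> str:
        parent = node.parent.label if node.parent is not None else "root"
        return f"{parent}>{node.label}"

    def branch_names(self) -> list[str]:
        return [self.branch_name(n) for n in self.preorder()]

    def branch_child(self, branch: str) -> Node:
        _, _, child = branch.partition(">")
        return self.node(child)

    def path_branches(self, ancestor: Node | str, leaf: str) -> list[str]:
        """Branches from ``ancestor`` down to ``leaf`` (ancestor's own stem excluded)."""
        top = self.node(ancestor) if isinstance(ancestor, str) else ancestor
        node = self.node(leaf)
        path = []
        while node is not top:
            path.append(self.branch_name(node))
            node = node.parent
            if node is None:
                raise ValueError(f"{top.label!r} is not an ancestor of {leaf!r}")
        return list(reversed(path))


def _assign_internal_labels(root: Node) -> None:
    """Name internal nodes from the two smallest child-subtree minimum leaves.

    Each internal node's label is ``a+b`` where a, b are the two
    lexicographically smallest values among the minimum leaf labels of its
    child subtrees.  The pair's MRCA is the node itself, so labels are unique.
    """

    def min_leaf(node: Node) -> str:
        if node.is_leaf:
            return node.label
        return min(min_leaf(c) for c in node.children)

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        mins = sorted(min_leaf(c) for c in node.children)
        node.label = f"{mins[0]}+{mins[1]}"
        for c in node.children:
            walk(c)

    walk(root)


def parse_tree(newick: str) -> SpeciesTree:
    """Parse a rooted Newick string into a :class:`SpeciesTree`."""
    return SpeciesTree.from_newick(newick)


@dataclass(frozen=True)
class FamilyEvents:
    """One gain branch (or None for an all-absent family) plus loss branches."""

    gain: str | None
    losses: frozenset[str]
    annotation: str = ""  # free text, e.g. loss-by-deletion vs excessive divergence


@dataclass
class EventMap:
    events: dict[str, FamilyEvents]

    def __getitem__(self, family: str) -> FamilyEvents:
        return self.events[family]

    def __iter__(self):
        return iter(self.events)

    def items(self):
        return self.events.items()


def infer_events(matrix: PresenceMatrix, tree: SpeciesTree) -> EventMap:
    """Minimum-loss Dollo reconstruction for every family in the matrix.

    The gain goes on the branch entering the MRCA of the family's present
    leaves; losses go on the stem branches of the maximal subtrees inside the
    gain clade whose surveyed (non-unknown) leaves are all absent.  A family
    present nowhere gets ``gain=None`` and no losses, with a warning.

    Raises
    ------
    KeyError
        If a matrix species is not a leaf of the tree.
    """
    tree_leaves = set(tree.leaf_labels)
    missing = set(matrix.species) - tree_leaves
    if missing:
        raise KeyError(f"matrix species not in tree: {sorted(missing)}")
    events: dict[str, FamilyEvents] = {}
    for family in matrix.families:
        row = matrix.row(family)
        present = [sp for sp, st in row.items() if st == PRESENT]
        if not present:
            logger.warning("family %r present in no species; no gain inferred", family)
            events[family] = FamilyEvents(gain=None, losses=frozenset())
            continue
        gain_node = tree.mrca(present)
        losses = _minimal_losses(tree, gain_node, row)
        events[family] = FamilyEvents(
            gain=tree.branch_name(gain_node), losses=frozenset(losses)
        )
    return EventMap(events)


def _minimal_losses(tree: SpeciesTree, gain_node: Node, row: dict[str, str]) -> set[str]:
    """Stem branches of maximal all-absent subtrees within the gain clade."""
    def surveyed_absent(node: Node) -> tuple[bool, bool]:
        """(all surveyed leaves absent, has >=1 surveyed leaf) below node."""
        leaves = tree.leaves_under(node)
        known = [lf for lf in leaves if row.get(lf, UNKNOWN) != UNKNOWN]
        if not known:
            return False, False
        return all(row[lf] == ABSENT for lf in known), True

    losses = set()

    def walk(node: Node) -> None:
        for child in node.children:
            all_absent, has_known = surveyed_absent(child)
            if all_absent and has_known:
                losses.add(tree.branch_name(child))
            else:
                walk(child)

    walk(gain_node)
    return losses


def replay_events(events: EventMap, tree: SpeciesTree) -> dict[str, dict[str, str]]:
    """Play each family's gain-then-losses down the tree; return leaf states.

    Every leaf gets ``present`` or ``absent`` (replay has no uncertainty).
    """
    out: dict[str, dict[str, str]] = {}
    for family, fe in events.items():
        if fe.gain is None:
            out[family] = {lf: ABSENT for lf in tree.leaf_labels}
            continue
        clade = tree.leaves_under(tree.branch_child(fe.gain))
        lost: set[str] = set()
        for branch in fe.losses:
            lost |= tree.leaves_under(tree.branch_child(branch))
        out[family] = {
            lf: (PRESENT if lf in clade and lf not in lost else ABSENT)
            for lf in tree.leaf_labels
        }
    return out


def lineage_summary(
    events: EventMap, tree: SpeciesTree, focal_leaves: tuple[str, str]
) -> dict[str, dict[str, list[str]]]:
    """Tally gains and losses along each focal leaf's lineage.

    The lineage of a focal leaf is the branch path from the MRCA of the focal
    pair down to that leaf.  A family counts as gained (lost) on the lineage
    when its gain branch (one of its loss branches) lies on that path.
    Family lists come back alphabetically sorted.
    """
    for leaf in focal_leaves:
        if leaf not in set(tree.leaf_labels):
            raise KeyError(f"focal leaf {leaf!r} not in tree")
    anc = tree.mrca(set(focal_leaves))
    out: dict[str, dict[str, list[str]]] = {}
    for leaf in focal_leaves:
        path = set(tree.path_branches(anc, leaf))
        gains = sorted(f for f, fe in events.items() if fe.gain in path)
        losses = sorted(f for f, fe in events.items() if fe.losses & path)
        out[leaf] = {"gains": gains, "losses": losses}
    return out


def brute_force_oracle(
    row: dict[str, str], tree: SpeciesTree
) -> tuple[int, tuple[str | None, frozenset[str]]]:
    """Exhaustive minimum-loss search over every possible gain placement.

    For each candidate gain node the forced minimal loss set is computed by an
    independent recursive routine, and the global minimum over placements is
    returned as ``(loss_count, (gain_branch, loss_branches))``.  Intended as a
    testing oracle; guarded to trees of <= 12 leaves.
    """
    if len(tree.leaf_labels) > 12:
        raise ValueError("oracle is restricted to trees with <= 12 leaves")
    present = {sp for sp, st in row.items() if st == PRESENT}
    if not present:
        return 0, (None, frozenset())

    best: tuple[int, int, str, frozenset[str]] | None = None
    for gain_node in tree.preorder():
        clade = tree.leaves_under(gain_node)
        if not present <= clade:
            continue

        def losses_below(node: Node) -> tuple[set[str], bool]:
            """(loss branches under node, subtree entirely loseable)."""
            leaves = tree.leaves_under(node)
            known = [lf for lf in leaves if row.get(lf, UNKNOWN) != UNKNOWN]
            if known and all(row[lf] == ABSENT for lf in known):
                return {tree.branch_name(node)}, True
            acc: set[str] = set()
            for child in node.children:
                sub, _ = losses_below(child)
                acc |= sub
            return acc, False

        acc: set[str] = set()
        for child in gain_node.children:
            sub, _ = losses_below(child)
            acc |= sub
        key = (len(acc), len(clade), gain_node.label, frozenset(acc))
        if best is None or key[:3] < best[:3]:
            best = key
    assert best is not None  # gain at root is always feasible
    count, _, gain_label, losses = best
    return count, (tree.branch_name(tree.node(gain_label)), losses)
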