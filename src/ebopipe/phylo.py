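"""Gene presence/absence matrices and gain/loss mapping on a fixed tree.

The default reconstruction criterion is Dollo parsimony: a character may be
gained once (on the branch above the most recent common ancestor of all
leaves carrying it) and lost any number of times.  The loss set is the set
of maximal subtrees inside the gain clade whose scored leaves are all
absent, which is provably the minimum number of losses compatible with a
single gain.  Fitch (reversible, minimum total changes; Hartigan's
generalization on polytomies) is provided as a sensitivity check.

Unknown states (draft genomes, suspected assembly gaps) are excluded from
the MRCA computation and impose no constraint on losses, so missing data
never invents events.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

PRESENT, ABSENT, UNKNOWN = 1, 0, None


@dataclass
class TreeNode:
    id: str
    name: str | None = None
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted tree with stable node ids; branch id = child-node id."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        for node in self.postorder():
            if node.id in self.nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "RootedTree":
        """Parse a rooted Newick string (basal bi- or trifurcation accepted).

        Leaf ids are leaf names; internal nodes get postorder ids n1, n2...
        Branch lengths are preserved but ignored by the parsimony criteria.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"invalid Newick: {exc}") from exc
        names = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dup}")
        if len(names) < 2:
            raise ValueError("a rooted tree needs at least 2 leaves")

        counter = 0

        def build(dnode) -> TreeNode:
            nonlocal counter
            children = [build(c) for c in dnode.child_nodes()]
            if children:
                counter += 1
                node = TreeNode(id=f"n{counter}", length=dnode.edge.length)
            else:
                node = TreeNode(
                    id=dnode.taxon.label, name=dnode.taxon.label, length=dnode.edge.length
                )
            for c in children:
                c.parent = node
            node.children = children
            return node

        return cls(build(dtree.seed_node))

    def to_newick(self, annotations: Mapping[str, str] | None = None) -> str:
        """Newick with optional per-branch ``[&...]`` comment annotations."""

        def render(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.name or node.id
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.length is not None:
                core += f":{node.length:g}"
            if annotations and node.id in annotations:
                core += f"[&{annotations[node.id]}]"
            return core

        return render(self.root) + ";"

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterable[TreeNode]:
        def walk(node):
            for c in node.children:
                yield from walk(c)
            yield node

        yield from walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def mrca(self, names: Sequence[str]) -> TreeNode:
        if not names:
            raise ValueError("mrca of empty leaf set")
        paths = []
        for name in names:
            if name not in self.nodes:
                raise KeyError(f"leaf {name!r} not in tree")
            node, path = self.nodes[name], []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])  # root..leaf
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def subtree_leaves(self, node: TreeNode) -> list[TreeNode]:
        return [n for n in self._walk(node) if n.is_leaf]

    def _walk(self, node: TreeNode) -> Iterable[TreeNode]:
        yield node
        for c in node.children:
            yield from self._walk(c)


def read_newick(source: str | Path) -> RootedTree:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    return RootedTree.from_newick(text)


# ---------------------------------------------------------------------------
# Dollo parsimony


@dataclass
class DolloEntry:
    """Single-gain/multiple-loss reconstruction for one character."""

    character: str
    gain_branch: str | None  # node id of the gain clade; None = never gained
    ancestral_at_root: bool
    loss_branches: list[str]


def dollo_events(
    tree: RootedTree, states: Mapping[str, int | None], character: str = ""
) -> DolloEntry:
    """Map one presence/absence column under Dollo parsimony.

    The gain sits on the branch above the MRCA of all present leaves
    (``ancestral_at_root`` when that MRCA is the root); losses are the
    maximal all-absent subtrees inside the gain clade.  Unknown leaves are
    excluded from the MRCA and never create or block a loss on their own.
    """
    scored = {k: v for k, v in states.items() if v is not None}
    if not scored:
        if not states:
            raise ValueError(f"character {character!r}: empty column")
        raise ValueError(f"character {character!r}: all states unknown")
    present = [k for k, v in scored.items() if v == PRESENT]
    if not present:
        return DolloEntry(character, None, False, [])
    gain = tree.mrca(present)

    absentish: dict[str, bool] = {}
    has_scored: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state = states.get(node.name, UNKNOWN)
            has_scored[node.id] = state is not None
            absentish[node.id] = state == ABSENT
        else:
            kids = node.children
            has_scored[node.id] = any(has_scored[c.id] for c in kids)
            absentish[node.id] = has_scored[node.id] and all(
                absentish[c.id] or not has_scored[c.id] for c in kids
            )

    losses: list[str] = []

    def collect(node: TreeNode, parent_absent: bool) -> None:
        a = absentish[node.id]
        if a and not parent_absent:
            losses.append(node.id)
        for c in node.children:
            collect(c, a)

    collect(gain, parent_absent=False)
    return DolloEntry(character, gain.id, gain is tree.root, sorted(losses))


def dollo_replay(tree: RootedTree, entry: DolloEntry) -> dict[str, int]:
    """Simulate leaf states implied by a (gain, losses) reconstruction."""
    states: dict[str, int] = {name: ABSENT for name in tree.leaf_names()}
    if entry.gain_branch is None:
        return states
    gain = tree.nodes[entry.gain_branch]
    lost = set(entry.loss_branches)

    def walk(node: TreeNode, alive: bool) -> None:
        if node.id in lost:
            alive = False
        if node.is_leaf:
            states[node.name] = PRESENT if alive else ABSENT
        for c in node.children:
            walk(c, alive)

    walk(gain, alive=True)
    return states


# ---------------------------------------------------------------------------
# Fitch / Hartigan parsimony


def fitch_events(
    tree: RootedTree, states: Mapping[str, int | None], character: str = ""
) -> tuple[int, dict[str, int]]:
    """Minimum reversible state changes plus one optimal internal labelling.

    Hartigan's algorithm, valid on polytomies; unknown leaves carry the
    full state set {present, absent} and never force a change.
    """
    scored = {k: v for k, v in states.items() if v is not None}
    if not scored:
        raise ValueError(f"character {character!r}: all states unknown")

    upper: dict[str, frozenset[int]] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            s = states.get(node.name, UNKNOWN)
            upper[node.id] = frozenset({0, 1}) if s is None else frozenset({s})
        else:
            count = {0: 0, 1: 0}
            for c in node.children:
                for s in upper[c.id]:
                    count[s] += 1
            kmax = max(count.values())
            upper[node.id] = frozenset(s for s in (0, 1) if count[s] == kmax)
            changes += len(node.children) - kmax

    labelling: dict[str, int] = {}

    def down(node: TreeNode, parent_state: int | None) -> None:
        cand = upper[node.id]
        if parent_state is not None and parent_state in cand:
            state = parent_state
        else:
            state = max(cand)  # deterministic: prefer presence
        labelling[node.id] = state
        for c in node.children:
            down(c, state)

    down(tree.root, None)
    return changes, labelling


# ---------------------------------------------------------------------------
# Presence matrices


@dataclass
class PresenceMatrix:
    """Taxa x characters matrix over {present, absent, unknown}."""

    data: pd.DataFrame  # values 1 / 0 / pd.NA
    pseudo: set[tuple[str, str]] = field(default_factory=set)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def column(self, character: str) -> dict[str, int | None]:
        col = self.data[character]
        return {t: (None if pd.isna(v) else int(v)) for t, v in col.items()}

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.map(lambda v: "?" if pd.isna(v) else str(int(v)))
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        data = df.map(lambda v: pd.NA if str(v).strip() == "?" else int(v))
        return cls(data=data)


def matrix_from_calls(calls, panel) -> PresenceMatrix:
    """Presence matrix from per-genome architecture calls (marker panel).

    A family is unknown (not absent) when it is missing from a genome whose
    architecture call carries a suspected assembly gap.
    """
    from .markers import MarkerFamily

    codes = [f.code if isinstance(f, MarkerFamily) else str(f) for f in panel]
    taxa = [c.taxon for c in calls]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon ids: {dup}")
    rows = {}
    for call in calls:
        present = {m.family for cl in call.clusters for m in cl.members}
        present |= {fam for fam, _ in call.detached_paralogs}
        row = {}
        for code in codes:
            if code in present:
                row[code] = 1
            elif call.assembly_gap_suspected:
                row[code] = pd.NA
            else:
                row[code] = 0
        rows[call.taxon] = row
    return PresenceMatrix(pd.DataFrame.from_dict(rows, orient="index", dtype="object")[codes])


def matrix_from_genomes(genomes, genes: Sequence[str] | None = None) -> PresenceMatrix:
    """Presence matrix from annotated genomes, keyed on gene labels.

    Pseudogenes score absent but are recorded in a footnote set, mirroring
    the convention of listing pseudogenes separately from losses.
    """
    taxa = [g.taxon or g.genome_id for g in genomes]
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon ids: {dup}")
    label_sets, pseudo_sets = {}, {}
    for g, taxon in zip(genomes, taxa):
        label_sets[taxon] = {f.label for f in g.features if f.label and not f.pseudo}
        pseudo_sets[taxon] = {f.label for f in g.features if f.label and f.pseudo}
    if genes is None:
        genes = sorted(set().union(*label_sets.values(), *pseudo_sets.values()))
    data = pd.DataFrame(
        {
            gene: {t: (1 if gene in label_sets[t] else 0) for t in taxa}
            for gene in genes
        },
        dtype="object",
    )[list(genes)]
    pseudo = {(t, gene) for t in taxa for gene in pseudo_sets[t] if gene in genes}
    return PresenceMatrix(data=data.loc[taxa], pseudo=pseudo)


# ---------------------------------------------------------------------------
# Whole-matrix mapping


def map_all(
    tree: RootedTree,
    matrix: PresenceMatrix,
    criterion: str = "dollo",
) -> tuple[dict[str, DolloEntry], pd.DataFrame]:
    """Map every character; returns the event map and a per-branch summary.

    Matrix taxa must be a subset of tree leaves (leaves without data score
    unknown); unknown-only characters are rejected per character.
    """
    leaves = set(tree.leaf_names())
    extra = sorted(set(matrix.taxa) - leaves)
    if extra:
        raise ValueError(f"taxa absent from tree: {extra}")
    events: dict[str, DolloEntry] = {}
    branch_rows: dict[str, dict[str, int]] = {
        n.id: {"gains": 0, "losses": 0} for n in tree.postorder()
    }
    for character in matrix.characters:
        entry = dollo_events(tree, matrix.column(character), character)
        events[character] = entry
        if entry.gain_branch is not None:
            branch_rows[entry.gain_branch]["gains"] += 1
            for b in entry.loss_branches:
                branch_rows[b]["losses"] += 1
    summary = pd.DataFrame(
        [
            {"branch": b, "gains": r["gains"], "losses": r["losses"]}
            for b, r in branch_rows.items()
        ]
    )
    return events, summary


def events_table(events: Mapping[str, DolloEntry]) -> pd.DataFrame:
    rows = []
    for character in events:
        e = events[character]
        gain = (
            "never_gained" if e.gain_branch is None
            else "root" if e.ancestral_at_root
            else e.gain_branch
        )
        rows.append(
            {
                "character": character,
                "gain_branch": gain,
                "loss_branches": ";".join(e.loss_branches) or "-",
                "n_losses": len(e.loss_branches),
            }
        )
    return pd.DataFrame(rows, columns=["character", "gain_branch", "loss_branches", "n_losses"])


def write_events_tsv(events: Mapping[str, DolloEntry], path: str | Path) -> None:
    events_table(events).to_csv(path, sep="\t", index=False)


def annotated_newick(tree: RootedTree, events: Mapping[str, DolloEntry]) -> str:
    """Newick with gains/losses per branch as comment tags."""
    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    for char, e in events.items():
        if e.gain_branch is not None:
            gains.setdefault(e.gain_branch, []).append(char)
            for b in e.loss_branches:
                losses.setdefault(b, []).append(char)
    ann = {}
    for node_id in set(gains) | set(losses):
        parts = []
        if node_id in gains:
            parts.append("gain=" + "|".join(sorted(gains[node_id])))
        if node_id in losses:
            parts.append("loss=" + "|".join(sorted(losses[node_id])))
        ann[node_id] = ",".join(parts)
    return tree.to_newick(annotations=ann)


def render_events_text(tree: RootedTree, events: Mapping[str, DolloEntry]) -> str:
    """Plain-text tree with +gene / -gene glyphs on branches."""
    gains: dict[str, list[str]] = {}
    losses: dict[str, list[str]] = {}
    for char, e in events.items():
        if e.gain_branch is not None:
            gains.setdefault(e.gain_branch, []).append(char)
            for b in e.loss_branches:
                losses.setdefault(b, []).append(char)

    out = io.StringIO()

    def glyphs(node: TreeNode) -> str:
        marks = [f"+{c}" for c in sorted(gains.get(node.id, []))]
        marks += [f"-{c}" for c in sorted(losses.get(node.id, []))]
        return f" [{' '.join(marks)}]" if marks else ""

    def walk(node: TreeNode, prefix: str, is_last: bool) -> None:
        connector = "`-- " if is_last else "|-- "
        label = node.name if node.is_leaf else node.id
        out.write(f"{prefix}{connector}{label}{glyphs(node)}\n")
        child_prefix = prefix + ("    " if is_last else "|   ")
        for i, c in enumerate(node.children):
            walk(c, child_prefix, i == len(node.children) - 1)

    out.write(f"{tree.root.id}{glyphs(tree.root)}\n")
    for i, c in enumerate(tree.root.children):
        walk(c, "", i == len(tree.root.children) - 1)
    return out.getvalue()
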