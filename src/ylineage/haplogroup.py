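"""Haplogroup tree handling, hierarchical classification and carrier frequencies.

A haplogroup tree is a rooted hierarchy of clades, each defined by one or
more phyloequivalent SNP markers. Samples are classified to the deepest
clade on a root-descending path at which they carry the derived allele;
descent stops at the first explicitly ancestral clade, with missing calls
handled by a strict (stop) or permissive (look deeper) policy. A packaged
encoding of the Q-M3 subtree used throughout this package ships as data,
so updated trees are drop-in files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .genotypes import ANCESTRAL, DERIVED, MISSING, SNPGenotypeTable


class TreeStructureError(ValueError):
    """Raised for cycles, multiple roots, duplicate markers or orphan nodes."""


@dataclass(frozen=True)
class TreeNode:
    name: str
    markers: tuple[str, ...]
    parent: str | None


@dataclass
class HaplogroupTree:
    """Rooted hierarchy of haplogroup-defining SNP markers."""

    nodes: dict[str, TreeNode]
    root: str

    def __post_init__(self) -> None:
        self._validate()
        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                self._children[node.parent].append(node.name)
        for kids in self._children.values():
            kids.sort()

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeStructureError(
                f"expected exactly one root, found {[r.name for r in roots]}"
            )
        if roots[0].name != self.root:
            raise TreeStructureError(f"declared root {self.root!r} is not the parentless node")
        seen_markers: dict[str, str] = {}
        for node in self.nodes.values():
            if not node.markers:
                raise TreeStructureError(f"node {node.name!r} defines no markers")
            if node.parent is not None and node.parent not in self.nodes:
                raise TreeStructureError(f"node {node.name!r} has unknown parent {node.parent!r}")
            for m in node.markers:
                if m in seen_markers:
                    raise TreeStructureError(
                        f"marker {m!r} duplicated on nodes {seen_markers[m]!r} and {node.name!r}"
                    )
                seen_markers[m] = node.name
        # reachability doubles as the cycle check: a cycle is unreachable from the root
        reached, stack = set(), [self.root]
        while stack:
            name = stack.pop()
            reached.add(name)
            stack.extend(
                n.name for n in self.nodes.values() if n.parent == name and n.name not in reached
            )
        unreached = set(self.nodes) - reached
        if unreached:
            raise TreeStructureError(f"nodes unreachable from root (cycle?): {sorted(unreached)}")

    def children(self, name: str) -> list[str]:
        return self._children[name]

    def path_to_root(self, name: str) -> list[str]:
        path = [name]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def path_from_root(self, name: str) -> list[str]:
        return list(reversed(self.path_to_root(name)))

    def depth(self, name: str) -> int:
        return len(self.path_to_root(name)) - 1

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(m for node in self.nodes.values() for m in node.markers)

    def node_of_marker(self, marker: str) -> str:
        for node in self.nodes.values():
            if marker in node.markers:
                return node.name
        raise KeyError(marker)

    @classmethod
    def from_dict(cls, payload: dict) -> "HaplogroupTree":
        nodes = {}
        for rec in payload["nodes"]:
            markers = rec.get("markers") or []
            node = TreeNode(
                name=str(rec["name"]),
                markers=tuple(str(m) for m in markers),
                parent=rec.get("parent"),
            )
            if node.name in nodes:
                raise TreeStructureError(f"duplicate node name {node.name!r}")
            nodes[node.name] = node
        return cls(nodes=nodes, root=str(payload["root"]))


def load_tree(path) -> HaplogroupTree:
    """Load a haplogroup tree from a YAML or JSON file (JSON is a YAML subset)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return HaplogroupTree.from_dict(payload)


def default_tree() -> HaplogroupTree:
    """The packaged Q-M3 subtree (root Q-M242 down to the CO sublineages)."""
    ref = resources.files("ylineage").joinpath("data/qm3_tree.yaml")
    payload = yaml.safe_load(ref.read_text())
    return HaplogroupTree.from_dict(payload)


@dataclass
class ClassificationResult:
    sample_id: str
    haplogroup: str
    path: list[str] = field(default_factory=list)
    conflicts: list[tuple[str, str]] = field(default_factory=list)
    missing_on_path: list[str] = field(default_factory=list)


def _node_state(table: SNPGenotypeTable, sample: str, node: TreeNode, typed: set[str]) -> str:
    """Aggregate a node's phyloequivalent markers into one state.

    ANY typed derived marker and NO ancestral one -> derived; any ancestral
    -> ancestral; all missing/untyped -> missing. Derived+ancestral
    disagreement is an internal conflict: reported, state treated as
    ancestral (the sample is not promoted on contradictory evidence).
    """
    states = [table.state(sample, m) for m in node.markers if m in typed]
    if not states or all(s == MISSING for s in states):
        return MISSING
    if ANCESTRAL in states:
        return "conflict" if DERIVED in states else ANCESTRAL
    return DERIVED


def classify_haplogroup(
    genotypes: SNPGenotypeTable,
    tree: HaplogroupTree,
    policy: str = "strict",
) -> list[ClassificationResult]:
    """Classify every sample to its deepest consistent haplogroup.

    policy="strict" stops descent at the first missing node; "permissive"
    passes through missing nodes whenever a deeper derived node exists.
    Samples ancestral at the root classify as "not <root>"; samples with
    no informative call classify as "unknown". Conflicts list every
    (ancestral ancestor, derived descendant) node pair observed.
    """
    if policy not in {"strict", "permissive"}:
        raise ValueError(f"unknown policy {policy!r}")
    typed = set(genotypes.markers) & set(tree.markers)
    unknown = set(genotypes.markers) - set(tree.markers)
    if unknown:
        warnings.warn(f"markers not in tree ignored: {sorted(unknown)}", stacklevel=2)

    results = []
    for sample in genotypes.samples:
        state = {
            name: _node_state(genotypes, sample, node, typed)
            for name, node in tree.nodes.items()
        }

        def deepest(name: str) -> str | None:
            """Deepest derived node reachable from `name` (inclusive), or None."""
            best = name if state[name] == DERIVED else None
            for child in tree.children(name):
                if state[child] == DERIVED:
                    sub = deepest(child)
                elif state[child] == MISSING and policy == "permissive":
                    sub = deepest(child)
                    if sub is not None and state[sub] != DERIVED:
                        sub = None
                else:
                    sub = None
                if sub is not None and (best is None or tree.depth(sub) > tree.depth(best)):
                    best = sub
            return best

        conflicts = []
        for name, node in tree.nodes.items():
            if state[name] != DERIVED:
                continue
            for anc in tree.path_to_root(name)[1:]:
                if state[anc] in (ANCESTRAL, "conflict"):
                    conflicts.append((anc, name))
        for name, node in tree.nodes.items():
            if state[name] == "conflict":
                conflicts.append((name, name))  # internal phyloequivalence disagreement

        if all(s == MISSING for s in state.values()):
            results.append(
                ClassificationResult(sample, "unknown", [], conflicts, [])
            )
            continue
        if state[tree.root] != DERIVED and not (
            policy == "permissive" and state[tree.root] == MISSING and deepest(tree.root)
        ):
            label = "unknown" if state[tree.root] == MISSING else f"not {tree.root}"
            results.append(ClassificationResult(sample, label, [], conflicts, []))
            continue

        terminal = deepest(tree.root) or tree.root
        path = tree.path_from_root(terminal)
        missing_on_path = [
            m
            for name in path
            for m in tree.nodes[name].markers
            if m not in typed or genotypes.state(sample, m) == MISSING
        ]
        results.append(
            ClassificationResult(sample, terminal, path, sorted(set(conflicts)), missing_on_path)
        )
    return results


def _percent(derived: int, genotyped: int) -> float | None:
    """100*derived/genotyped, rounded half-up to one decimal; None when 0 typed."""
    if genotyped == 0:
        return None
    q = (Decimal(100 * derived) / Decimal(genotyped)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def carrier_frequency_table(
    genotypes: SNPGenotypeTable, grouping: str | None = None
) -> pd.DataFrame:
    """Per-marker derived counts, genotyped totals and percentages (1 decimal).

    With `grouping` ("population" or "group"), rows are emitted per marker
    and label plus a "total" row per marker; otherwise one row per marker.
    """
    rows = []
    labels = genotypes.label(grouping) if grouping else None
    for marker in genotypes.markers:
        col = genotypes.states[marker]
        if labels is not None:
            for value in sorted(labels.dropna().unique()):
                sub = col[labels == value]
                d, g = int((sub == DERIVED).sum()), int((sub != MISSING).sum())
                rows.append((marker, value, d, g, _percent(d, g)))
        d, g = int((col == DERIVED).sum()), int((col != MISSING).sum())
        rows.append((marker, "total", d, g, _percent(d, g)))
    return pd.DataFrame(rows, columns=["marker", "group", "derived", "genotyped", "percent"])
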