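"""Rooted phylogenetic trees: Newick I/O, megatree grafting, bladj age
calibration, random polytomy resolution, and cophenetic distances.

The tree container is deliberately minimal and mutable: the grafting and
calibration steps splice nodes in and out of an existing backbone, which is
awkward with immutable tree libraries.  Trees are rooted; branch lengths are
optional until calibration assigns node ages (Myr), after which
``length = parent.age - child.age`` and the tree is ultrametric (tips at 0).
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "NewickParseError",
    "CalibrationConflictError",
    "AgeTable",
    "TaxonPath",
    "GraftResult",
    "CopheneticMatrix",
    "parse_newick",
    "write_newick",
    "suppress_unary",
    "graft_taxa",
    "calibrate_bladj",
    "resolve_polytomies",
    "cophenetic",
]


class TreeError(ValueError):
    pass


class NewickParseError(TreeError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class CalibrationConflictError(TreeError):
    pass


def normalize_name(name: str) -> str:
    """Case-insensitive, whitespace/underscore-insensitive matching key."""
    return re.sub(r"\s+", "_", name.strip()).lower()


class Node:
    __slots__ = ("name", "length", "parent", "children", "age", "fixed")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.age: Optional[float] = None  # Myr before present
        self.fixed: bool = False  # age anchored by an age table (dated node)

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> None:
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"{len(self.children)}ch"
        return f"<Node {self.name or '?'} {kind}>"


class Tree:
    """A rooted tree.  Tip names must be unique; interior names unique where present."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name or "" for n in self.tips()]

    def interior(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    def find(self, name: str) -> Optional[Node]:
        key = normalize_name(name)
        for n in self.preorder():
            if n.name is not None and normalize_name(n.name) == key:
                return n
        return None

    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    # -- structure ---------------------------------------------------------

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.age = node.age
            new.fixed = node.fixed
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root))

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.interior())

    def is_calibrated(self) -> bool:
        return all(n.age is not None for n in self.preorder())

    def validate(self) -> None:
        seen_tips: set[str] = set()
        seen_int: set[str] = set()
        for n in self.preorder():
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on {n.name!r}")
            if n.is_tip:
                if not n.name:
                    raise TreeError("unnamed tip")
                if n.name in seen_tips:
                    raise TreeError(f"duplicate tip name {n.name!r}")
                seen_tips.add(n.name)
            elif n.name:
                if n.name in seen_int:
                    raise TreeError(f"duplicate interior name {n.name!r}")
                seen_int.add(n.name)

    def validate_calibration(self) -> None:
        for n in self.preorder():
            if n.age is None:
                raise CalibrationConflictError(f"node {n.name!r} has no age")
            if n.is_tip and n.age != 0:
                raise CalibrationConflictError(f"tip {n.name!r} has age {n.age} != 0")
            for c in n.children:
                if c.age is None or c.age >= n.age:
                    raise CalibrationConflictError(
                        f"child {c.name!r} (age {c.age}) not younger than "
                        f"parent {n.name!r} (age {n.age})"
                    )

    def set_lengths_from_ages(self) -> None:
        for n in self.preorder():
            n.length = None if n.parent is None else n.parent.age - n.age


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_LABEL_END = set("(),:;")


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Supports unquoted and single-quoted labels and real-valued branch
    lengths.  Raises :class:`NewickParseError` with the character offset of
    the first problem, and :class:`TreeError` on duplicate tip names.
    """
    s = text
    pos = 0
    n = len(s)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and s[pos].isspace():
            pos += 1

    def read_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == "'":
            start = pos
            pos += 1
            out = []
            while pos < n:
                if s[pos] == "'":
                    if pos + 1 < n and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise NewickParseError("unterminated quoted label", start)
        start = pos
        while pos < n and not s[pos].isspace() and s[pos] not in _LABEL_END:
            pos += 1
        return s[start:pos] if pos > start else None

    def read_length() -> Optional[float]:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (s[pos] in "+-.eE" or s[pos].isdigit()):
                pos += 1
            try:
                val = float(s[start:pos])
            except ValueError:
                raise NewickParseError("expected branch length after ':'", start)
            if val < 0:
                raise NewickParseError("negative branch length", start)
            return val
        return None

    def read_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < n and s[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.add_child(read_clade())
                skip_ws()
                if pos >= n:
                    raise NewickParseError("unbalanced parenthesis", open_at)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError("expected ',' or ')'", pos)
        at = pos
        node.name = read_label()
        node.length = read_length()
        if not node.children and node.name is None:
            raise NewickParseError("expected a taxon label", at)
        return node

    skip_ws()
    if pos >= n:
        raise NewickParseError("empty Newick string", 0)
    root = read_clade()
    skip_ws()
    if pos >= n or s[pos] != ";":
        raise NewickParseError("expected terminating ';'", pos)
    pos += 1
    skip_ws()
    if pos < n:
        raise NewickParseError("trailing characters after ';'", pos)
    tree = Tree(root)
    tree.validate()
    return tree


_UNQUOTED_OK = re.compile(r"^[^\s(),:;'\[\]]+$")


def _fmt_label(name: str) -> str:
    if _UNQUOTED_OK.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick; inverse of :func:`parse_newick`."""

    def rec(node: Node) -> str:
        parts = ""
        if node.children:
            parts = "(" + ",".join(rec(c) for c in node.children) + ")"
        label = _fmt_label(node.name) if node.name else ""
        length = "" if node.length is None else f":{node.length:.12g}"
        return parts + label + length

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Ages and taxon paths
# ---------------------------------------------------------------------------


class AgeTable:
    """Node-name -> age (Myr, > 0) table (Phylocom ages-file compatible)."""

    def __init__(self, entries: dict[str, float]):
        norm: dict[str, float] = {}
        self.display: dict[str, float] = {}
        for name, age in entries.items():
            key = normalize_name(name)
            if key in norm:
                raise TreeError(f"duplicate age entry for {name!r}")
            if not np.isfinite(age) or age <= 0:
                raise TreeError(f"age for {name!r} must be positive, got {age}")
            norm[key] = float(age)
            self.display[name] = float(age)
        self._entries = norm

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._entries

    def get(self, name: str) -> Optional[float]:
        return self._entries.get(normalize_name(name))

    def items(self):
        return self.display.items()

    @classmethod
    def from_file(cls, path) -> "AgeTable":
        entries: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise TreeError(f"{path}:{lineno}: expected 'name age'")
                entries[parts[0]] = float(parts[1])
        return cls(entries)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, age in self.display.items():
                fh.write(f"{name}\t{age:.12g}\n")


@dataclass(frozen=True)
class TaxonPath:
    """family / genus / terminal triple used to graft a taxon onto a backbone."""

    family: str
    genus: str
    terminal: str

    def __post_init__(self):
        for part, label in ((self.family, "family"), (self.genus, "genus"),
                            (self.terminal, "terminal")):
            if not part or not part.strip():
                raise TreeError(f"TaxonPath {label} must be non-empty")


@dataclass
class GraftResult:
    tree: Tree
    skipped: list[TaxonPath] = field(default_factory=list)


def graft_taxa(backbone: Tree, taxa: Sequence[TaxonPath]) -> GraftResult:
    """Graft a family/genus/terminal taxon list onto a backbone megatree.

    Matching is case-insensitive with whitespace/underscores normalized.  A
    taxon whose genus matches a backbone node is attached below that node; if
    only the family matches, a new genus node is created under the family
    node first.  Congeners therefore form a polytomy at the genus node.
    Backbone nodes with no grafted descendants are pruned; taxa whose family
    is absent are returned in ``skipped``.
    """
    if not taxa:
        raise TreeError("empty taxon list")
    tree = backbone.copy()
    index: dict[str, Node] = {}
    for node in tree.preorder():
        if node.name:
            index.setdefault(normalize_name(node.name), node)

    seen_paths: set[TaxonPath] = set()
    tip_names: set[str] = set()
    grafted: list[Node] = []
    skipped: list[TaxonPath] = []
    for taxon in taxa:
        if taxon in seen_paths:
            continue
        seen_paths.add(taxon)
        tip_name = re.sub(r"\s+", "_", taxon.terminal.strip())
        if normalize_name(tip_name) in tip_names:
            raise TreeError(f"duplicate terminal label {taxon.terminal!r}")
        anchor = index.get(normalize_name(taxon.genus))
        if anchor is None:
            fam = index.get(normalize_name(taxon.family))
            if fam is None:
                skipped.append(taxon)
                continue
            anchor = fam.add_child(Node(taxon.genus))
            index[normalize_name(taxon.genus)] = anchor
        tip = anchor.add_child(Node(tip_name))
        tip_names.add(normalize_name(tip_name))
        grafted.append(tip)

    if not grafted:
        raise TreeError("no taxon could be grafted onto the backbone")

    keep: set[int] = set()
    for tip in grafted:
        node: Optional[Node] = tip
        while node is not None and id(node) not in keep:
            keep.add(id(node))
            node = node.parent

    def prune(node: Node) -> None:
        for child in list(node.children):
            if id(child) in keep:
                prune(child)
            else:
                child.detach()

    prune(tree.root)
    suppress_unary(tree, keep=lambda n: bool(n.name))
    tree.validate()
    return GraftResult(tree=tree, skipped=skipped)


def suppress_unary(tree: Tree, keep: Optional[Callable[[Node], bool]] = None) -> Tree:
    """Splice out interior nodes with a single child (in place).

    Nodes for which ``keep`` returns True (e.g. named or dated nodes) are
    left untouched.  Branch lengths, where present, are summed across the
    spliced edge.  Returns the tree for chaining.
    """
    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.is_tip or len(node.children) != 1:
                continue
            if keep is not None and keep(node):
                continue
            child = node.children[0]
            if node.parent is None:
                child.parent = None
                child.length = None
                tree.root = child
            else:
                child.parent = node.parent
                idx = node.parent.children.index(node)
                node.parent.children[idx] = child
                if node.length is not None and child.length is not None:
                    child.length += node.length
                elif child.length is None:
                    child.length = node.length
            changed = True
    return tree


# ---------------------------------------------------------------------------
# bladj calibration
# ---------------------------------------------------------------------------


def _bladj_assign(tree: Tree) -> None:
    """Interpolate ages for unfixed nodes given fixed anchors (in ``node.age``).

    Every maximal chain of unfixed nodes between a fixed ancestor (age a) and
    a fixed descendant (age b, including tips at 0) is spaced evenly:
    the i-th of k chain nodes gets ``a - i * (a - b) / (k + 1)``.  Fixed
    nodes are processed oldest-first and, from each, the path toward the
    oldest reachable fixed terminal is assigned first; assignments then act
    as new anchors.  Inconsistent anchor ages raise
    :class:`CalibrationConflictError`.
    """
    counter = 0
    heap: list[tuple[float, int, Node]] = []
    for node in tree.preorder():
        if node.fixed:
            if node.age is None:
                raise CalibrationConflictError(f"fixed node {node.name!r} lacks an age")
            heapq.heappush(heap, (-node.age, counter, node))
            counter += 1

    def paths_from(anchor: Node) -> list[tuple[Node, list[Node]]]:
        """All maximal unfixed chains anchor -> ... -> fixed terminal."""
        found: list[tuple[Node, list[Node]]] = []

        def rec(node: Node, path: list[Node]) -> None:
            for child in node.children:
                if child.fixed or child.age is not None:
                    if path:
                        found.append((child, list(path)))
                else:
                    path.append(child)
                    rec(child, path)
                    path.pop()

        rec(anchor, [])
        return found

    while heap:
        _, _, anchor = heapq.heappop(heap)
        while True:
            candidates = paths_from(anchor)
            if not candidates:
                break
            # oldest terminal first; ties broken by shorter chain
            terminal, chain = max(
                candidates, key=lambda tc: (tc[0].age, -len(tc[1]))
            )
            a, b = anchor.age, terminal.age
            if b >= a:
                raise CalibrationConflictError(
                    f"dated descendant {terminal.name!r} (age {b}) is not younger "
                    f"than its nearest dated ancestor {anchor.name!r} (age {a})"
                )
            k = len(chain)
            for i, node in enumerate(chain, start=1):
                node.age = a - i * (a - b) / (k + 1)
                heapq.heappush(heap, (-node.age, counter, node))
                counter += 1
        # direct fixed children consistency is checked in final validation

    tree.validate_calibration()
    tree.set_lengths_from_ages()


def calibrate_bladj(tree: Tree, ages: AgeTable,
                    root_age: Optional[float] = None) -> Tree:
    """Calibrate a tree: dated (named) nodes take their table age exactly,
    tips get age 0, and undated interior nodes are spaced evenly along each
    path between fixed-age nodes (the bladj rule).

    The root must be named in ``ages`` or ``root_age`` given.  Conflicting
    dates (a descendant at least as old as its nearest dated ancestor) raise
    :class:`CalibrationConflictError` — no silent clamping.
    """
    out = tree.copy()
    matched: set[str] = set()
    for node in out.preorder():
        node.age = None
        node.fixed = False
        if node.is_tip:
            node.age = 0.0
            if node.name and node.name in ages:
                raise CalibrationConflictError(
                    f"tip {node.name!r} appears in the age table; tips have age 0"
                )
            continue
        if node.name:
            age = ages.get(node.name)
            if age is not None:
                node.age = age
                node.fixed = True
                matched.add(normalize_name(node.name))
    missing = [n for n, _ in ages.items() if normalize_name(n) not in matched]
    if missing:
        raise TreeError(f"age-table names not found in tree: {missing}")
    if not out.root.fixed:
        if root_age is None:
            raise TreeError("root is undated and no root_age supplied")
        out.root.age = float(root_age)
        out.root.fixed = True
    _bladj_assign(out)
    return out


def resolve_polytomies(tree: Tree, seed: int) -> Tree:
    """Randomly resolve every polytomy into dichotomies, then re-interpolate.

    Each polytomy is resolved by sequential random pairing: two children are
    drawn uniformly and joined under a new (undated) node until two remain —
    for a trichotomy each of the three rooted resolutions has probability
    1/3.  Dated nodes keep their ages; all undated and newly created nodes
    are re-aged by the bladj rule.  Deterministic for a fixed seed.
    """
    if not tree.is_calibrated():
        raise TreeError("resolve_polytomies requires a calibrated tree")
    rng = np.random.default_rng(seed)
    out = tree.copy()
    # unary nodes (left by pruning a backbone) are spliced out first so the
    # result is strictly bifurcating; their dated ages drop out as anchors
    suppress_unary(out, keep=lambda n: n.parent is None)
    for node in list(out.preorder()):
        while len(node.children) > 2:
            m = len(node.children)
            i, j = sorted(rng.choice(m, size=2, replace=False))
            a, b = node.children[i], node.children[j]
            merged = Node()
            merged.parent = node
            merged.children = [a, b]
            a.parent = b.parent = merged
            node.children[i] = merged
            del node.children[j]
    # keep only dated anchors; everything else is re-interpolated
    for node in out.preorder():
        if node.is_tip:
            node.age = 0.0
            node.fixed = False
        elif not node.fixed:
            node.age = None
    if not out.root.fixed and out.root.age is None:
        raise TreeError("root age lost during resolution")
    if not out.root.fixed:
        out.root.fixed = True  # pragma: no cover - defensive
    _bladj_assign(out)
    return out


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------


class CopheneticMatrix:
    """Symmetric tip-to-tip path-distance matrix (Myr) with labeled axes."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise TreeError("labels and matrix shape disagree")
        if not np.allclose(values, values.T) or np.any(np.diag(values) != 0):
            raise TreeError("cophenetic matrix must be symmetric with zero diagonal")
        if np.any(values < 0):
            raise TreeError("negative cophenetic distance")
        self.labels = list(labels)
        self.values = values
        self._pos = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, taxa: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._pos[t] for t in taxa], dtype=int)
        except KeyError as exc:
            raise TreeError(f"taxon {exc.args[0]!r} not in cophenetic matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._pos[a], self._pos[b]])


def cophenetic(tree: Tree) -> CopheneticMatrix:
    """Tip-to-tip path distances of a calibrated tree (= 2 x MRCA age)."""
    if not tree.is_calibrated():
        raise TreeError("cophenetic requires a calibrated tree")
    tips = tree.tips()
    labels = [t.name for t in tips]
    pos = {id(t): i for i, t in enumerate(tips)}
    ntips = len(tips)
    D = np.zeros((ntips, ntips))
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipsets[id(node)] = np.array([pos[id(node)]], dtype=int)
            continue
        sets = [tipsets.pop(id(c)) for c in node.children]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                D[np.ix_(sets[i], sets[j])] = 2.0 * node.age
                D[np.ix_(sets[j], sets[i])] = 2.0 * node.age
        tipsets[id(node)] = np.concatenate(sets)
    return CopheneticMatrix(labels, D)
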