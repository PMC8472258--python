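"""Trees and tabular inputs for the karyotype-evolution pipeline.

This module owns the in-memory :class:`Phylogram` used by both ancestral
reconstruction engines, plus readers/writers for the plain-text formats the
pipeline consumes: Newick trees, two-column chromosome-count tables (either
TSV or the ``>taxon``/count dialect used by chromosome-number evolution
software), and per-taxon continuous-trait tables.

Newick parsing is delegated to :mod:`dendropy`; the parsed tree is converted
to a flat array representation (parent pointers, branch lengths, children
lists) that the pruning and GLS machinery can traverse without recursion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("karyoevol")

#: Default seed used by the CLI when the user does not pass ``--seed``.
DEFAULT_SEED = 1436

MISSING_MARKERS = {"x", "X", "-", "", "na", "NA", "?"}


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips, ...)."""


class TableError(ValueError):
    """Malformed counts/trait table input."""


def normalize_label(label: str) -> str:
    """Trim whitespace and replace internal runs of spaces with underscores.

    Newick convention: quoted labels may contain spaces, but downstream
    matching between trees and tables is done on the underscored form.
    """
    return "_".join(str(label).strip().split())


class Phylogram:
    """Rooted phylogenetic tree with branch lengths.

    Nodes are stored in preorder (root first, input order preserved).  Each
    node has a parent index (``-1`` for the root), a branch length (length of
    the edge above the node; 0.0 for the root), and an optional label.  Tip
    labels must be unique and non-empty; internal nodes without a label get a
    deterministic id ``N1, N2, ...`` in preorder.

    Branch lengths of exactly 0 are legal: a CTMC transition across a
    0-length branch is the identity.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[Optional[str]],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.length = np.asarray(lengths, dtype=float)
        self.label: list[Optional[str]] = list(labels)
        n = self.parent.size
        if not (self.length.size == n and len(self.label) == n):
            raise NewickError("parent/length/label arrays differ in size")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise NewickError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if i == self.root:
                continue
            if p == i or p < 0 or p >= n:
                raise NewickError(f"invalid parent pointer at node {i}")
            self.children[int(p)].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children], dtype=bool)
        neg = np.flatnonzero((self.length < 0) & (np.arange(n) != self.root))
        if neg.size:
            i = int(neg[0])
            raise NewickError(
                f"negative branch length {self.length[i]} above node "
                f"{self.label[i] or i!r}"
            )
        if not math.isfinite(self.length[self.root]):
            self.length[self.root] = 0.0
        # deterministic node ids: tips keep their label, internals get N<k>
        self.node_id: list[str] = []
        k = 0
        for i in range(n):
            if self.is_tip[i]:
                lab = self.label[i]
                if not lab:
                    raise NewickError(f"tip node {i} has no label")
                self.node_id.append(lab)
            else:
                k += 1
                self.node_id.append(self.label[i] or f"N{k}")
        tips = [self.node_id[i] for i in np.flatnonzero(self.is_tip)]
        if len(set(tips)) != len(tips):
            seen, dups = set(), set()
            for t in tips:
                (dups if t in seen else seen).add(t)
            raise NewickError(f"duplicate tip labels: {sorted(dups)}")
        self._index = {nid: i for i, nid in enumerate(self.node_id)}
        if len(self._index) != n:
            raise NewickError("node ids are not unique")
        self._postorder = self._compute_postorder()
        self._check_connected()

    # ------------------------------------------------------------------ core
    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.asarray(order[::-1], dtype=int)

    def _check_connected(self) -> None:
        if self._postorder.size != self.parent.size:
            raise NewickError("tree is not connected (unreachable nodes)")

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.node_id[i] for i in self.tip_indices]

    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self._postorder[::-1]

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def depths(self) -> np.ndarray:
        """Distance from the root to each node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.length[v]
        return d

    def height(self) -> float:
        return float(self.depths().max())

    def total_length(self) -> float:
        mask = np.arange(self.n_nodes) != self.root
        return float(self.length[mask].sum())

    # ------------------------------------------------------------------ i/o
    def to_newick(
        self,
        annotations: Optional[Mapping[str, object]] = None,
        precision: int = 10,
    ) -> str:
        """Render as Newick, optionally with ``[&...]`` node comments."""
        ann = dict(annotations or {})
        for nid in ann:
            if nid not in self._index:
                raise KeyError(f"annotation for unknown node id {nid!r}")
        frag: dict[int, str] = {}
        for v in self.postorder():
            if self.is_tip[v]:
                s = self.node_id[v]
            else:
                inner = ",".join(frag[c] for c in self.children[v])
                lab = self.label[v] or ""
                s = f"({inner}){lab}"
            nid = self.node_id[v]
            if nid in ann:
                val = ann[nid]
                if isinstance(val, Mapping):
                    body = ",".join(f"{k}={_fmt(x)}" for k, x in val.items())
                else:
                    body = _fmt(val)
                s += f"[&{body}]"
            if v != self.root:
                s += f":{self.length[v]:.{precision}g}"
            frag[v] = s
        return frag[self.root] + ";"

    # ------------------------------------------------------------ restructure
    def prune_to_taxa(self, keep: Iterable[str]) -> "Phylogram":
        """Subtree spanned by ``keep`` tips, with unifurcations suppressed.

        Branch lengths along suppressed paths are summed; if the old root is
        left with a single child the root stem is dropped (the child becomes
        the new root), matching the usual drop-tip convention.
        """
        keep = {normalize_label(t) for t in keep}
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")
        retain = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_indices:
            if self.node_id[i] in keep:
                v = i
                while v >= 0 and not retain[v]:
                    retain[v] = True
                    v = self.parent[v] if v != self.root else -1
        # rebuild with path compression
        new_parent: list[int] = []
        new_len: list[float] = []
        new_lab: list[Optional[str]] = []
        remap: dict[int, int] = {}

        def n_kept_children(v: int) -> list[int]:
            out = []
            for c in self.children[v]:
                if retain[c]:
                    out.append(c)
            return out

        def effective(v: int) -> tuple[int, float]:
            # follow chains of single-child internal nodes
            extra = 0.0
            while not self.is_tip[v]:
                kids = n_kept_children(v)
                if len(kids) != 1:
                    break
                v = kids[0]
                extra += self.length[v]
            return v, extra

        start, _ = effective(self.root)
        stack: list[tuple[int, int, float]] = [(start, -1, 0.0)]
        while stack:
            v, par_new, blen = stack.pop()
            idx = len(new_parent)
            remap[v] = idx
            new_parent.append(par_new)
            new_len.append(blen if par_new >= 0 else 0.0)
            new_lab.append(self.label[v])
            for c in n_kept_children(v):
                cv, extra = effective(c)
                stack.append((cv, idx, float(self.length[c] + extra)))
        return Phylogram(new_parent, new_len, new_lab)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Phylogram {self.n_tips} tips, {self.n_nodes} nodes>"


def _fmt(x: object) -> str:
    if isinstance(x, float):
        return f"{x:.6f}"
    return str(x)


# --------------------------------------------------------------------- Newick
def read_newick(text: str) -> Phylogram:
    """Parse a Newick string into a :class:`Phylogram`.

    Polytomies are allowed; branch lengths are required on every non-root
    edge.  Duplicate tip labels and negative lengths raise
    :class:`NewickError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"cannot parse Newick: {exc}") from exc
    parent: list[int] = []
    lengths: list[float] = []
    labels: list[Optional[str]] = []
    index: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        idx = len(parent)
        index[id(node)] = idx
        if node.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(node.parent_node)])
            if node.edge.length is None:
                who = node.taxon.label if node.taxon else f"internal node {idx}"
                raise NewickError(f"missing branch length above {who}")
            lengths.append(float(node.edge.length))
        if node.taxon is not None:
            labels.append(normalize_label(node.taxon.label))
        elif node.label:
            labels.append(normalize_label(node.label))
        else:
            labels.append(None)
    if not parent:
        raise NewickError("empty tree")
    return Phylogram(parent, lengths, labels)


def write_newick(tree: Phylogram) -> str:
    return tree.to_newick()


@dataclass
class AnnotatedTree:
    """Newick-with-comments text plus the companion per-node table."""

    newick: str
    table: pd.DataFrame

    def table_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.6f")


def write_annotated_tree(
    tree: Phylogram, annotations: Mapping[str, object]
) -> AnnotatedTree:
    """Attach per-node annotations as ``[&...]`` comments and a TSV table.

    ``annotations`` maps node ids to either a scalar or a ``{key: value}``
    mapping.  Unknown node ids raise ``KeyError``.  Values survive the TSV
    round trip to 6 decimals.
    """
    newick = tree.to_newick(annotations=annotations)
    rows = []
    for nid in tree.node_id:
        row: dict[str, object] = {"node": nid}
        if nid in annotations:
            val = annotations[nid]
            if isinstance(val, Mapping):
                row.update(val)
            else:
                row["value"] = val
        rows.append(row)
    return AnnotatedTree(newick=newick, table=pd.DataFrame(rows))


# --------------------------------------------------------------------- tables
@dataclass
class CountsTable:
    """Per-taxon haploid/base chromosome counts (``None`` marks missing)."""

    data: dict[str, Optional[int]] = field(default_factory=dict)

    def __getitem__(self, taxon: str) -> Optional[int]:
        return self.data[taxon]

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        return iter(self.data)

    @property
    def taxa(self) -> list[str]:
        return list(self.data)

    def non_missing(self) -> dict[str, int]:
        return {t: c for t, c in self.data.items() if c is not None}

    def max_count(self) -> int:
        vals = [c for c in self.data.values() if c is not None]
        if not vals:
            raise TableError("counts table has no non-missing entries")
        return max(vals)


@dataclass
class TraitTable:
    """Per-taxon continuous trait values (``None`` marks missing)."""

    data: dict[str, Optional[float]] = field(default_factory=dict)
    name: str = "trait"

    def __getitem__(self, taxon: str) -> Optional[float]:
        return self.data[taxon]

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        return iter(self.data)

    @property
    def taxa(self) -> list[str]:
        return list(self.data)

    def non_missing(self) -> dict[str, float]:
        return {t: v for t, v in self.data.items() if v is not None}


def _parse_count(token: str, lineno: int) -> Optional[int]:
    token = token.strip()
    if token in MISSING_MARKERS:
        return None
    try:
        as_float = float(token)
    except ValueError:
        raise TableError(f"line {lineno}: non-numeric count {token!r}") from None
    if not as_float.is_integer():
        raise TableError(f"line {lineno}: non-integer count {token!r}")
    count = int(as_float)
    if count < 1:
        raise TableError(f"line {lineno}: count must be >= 1, got {count}")
    return count


def read_counts(text: str) -> CountsTable:
    """Parse a chromosome-count table.

    Two dialects are auto-detected: plain two-column TSV (taxon, count) and
    the alternating ``>taxon`` / count format used by chromosome-number
    evolution software.  Missing markers (``x``, ``-``, empty) are preserved
    as missing.
    """
    lines = text.splitlines()
    data: dict[str, Optional[int]] = {}
    if any(ln.lstrip().startswith(">") for ln in lines):
        taxon: Optional[str] = None
        taxon_line = 0
        for lineno, ln in enumerate(lines, 1):
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith(">"):
                if taxon is not None:
                    raise TableError(
                        f"line {taxon_line}: taxon {taxon!r} has no count line"
                    )
                taxon = normalize_label(ln[1:])
                taxon_line = lineno
            else:
                if taxon is None:
                    raise TableError(f"line {lineno}: count without a taxon header")
                data[taxon] = _parse_count(ln, lineno)
                taxon = None
        if taxon is not None:
            raise TableError(f"line {taxon_line}: taxon {taxon!r} has no count line")
    else:
        for lineno, ln in enumerate(lines, 1):
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                parts = ln.split()
            if len(parts) < 2:
                raise TableError(f"line {lineno}: expected 'taxon<TAB>count'")
            data[normalize_label(parts[0])] = _parse_count(parts[1], lineno)
    return CountsTable(data)


def read_traits(text: str, name: str = "trait") -> TraitTable:
    """Parse a two-column TSV of taxon and continuous trait value."""
    data: dict[str, Optional[float]] = {}
    for lineno, ln in enumerate(text.splitlines(), 1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            parts = ln.split()
        if len(parts) < 2:
            raise TableError(f"line {lineno}: expected 'taxon<TAB>value'")
        token = parts[1].strip()
        if token in MISSING_MARKERS:
            data[normalize_label(parts[0])] = None
            continue
        try:
            val = float(token)
        except ValueError:
            raise TableError(f"line {lineno}: non-numeric value {token!r}") from None
        if not math.isfinite(val):
            raise TableError(f"line {lineno}: non-finite value {token!r}")
        data[normalize_label(parts[0])] = val
    return TraitTable(data, name=name)


def check_tree_table(tree: Phylogram, table: CountsTable | TraitTable) -> None:
    """Reject any non-missing table taxon absent from the tree.

    The error message reports the symmetric difference of the two label sets
    so the user can see both unmatched tips and unmatched table rows.
    """
    table_taxa = set(
        t for t, v in table.data.items() if v is not None
    )
    tips = set(tree.tip_labels)
    if not table_taxa <= tips:
        only_table = sorted(table_taxa - tips)
        only_tree = sorted(tips - table_taxa)
        raise TableError(
            "taxon mismatch between tree and table; "
            f"in table only: {only_table}; in tree only: {only_tree}"
        )
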