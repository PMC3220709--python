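"""Distance matrices, neighbor-joining, bootstrap supports, subclades.

The built-in tree path is neighbor joining on p or Poisson-corrected
distances with nonparametric column-resampling bootstrap; externally
built trees can be imported from Newick (supports read from internal
node labels, as percentages) and used for subclade extraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .msa import GAP, MSA, InputError

#: Cap applied to Poisson distances when sequences share no identical columns.
MAX_DISTANCE = 10.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if np.any(np.abs(self.matrix - self.matrix.T) > 1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    children: list["TreeNode"] = field(default_factory=list)
    label: str | None = None  # leaf name
    length: float = 0.0
    support: float | None = None  # percentage in [0, 100]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_set(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.leaves())


@dataclass
class SupportTree:
    """An (operationally unrooted) tree with optional percentage supports."""

    root: TreeNode

    def __post_init__(self) -> None:
        labels = [leaf.label for leaf in self.root.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for node in self._walk(self.root):
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError("supports must lie in [0, 100]")

    @staticmethod
    def _walk(node: TreeNode):
        yield node
        for c in node.children:
            yield from SupportTree._walk(c)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_set()

    def bipartitions(self) -> dict[frozenset[str], float | None]:
        """Non-trivial splits, canonical side, with the edge's support.

        The canonical side of a split is the side not containing the
        lexicographically smallest leaf label.
        """
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        out: dict[frozenset[str], float | None] = {}
        for node in self._walk(self.root):
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_set()
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            canonical = all_leaves - side if ref in side else side
            out[canonical] = node.support
        return out

    def newick(self) -> str:
        return _to_newick(self.root) + ";"


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def _to_newick(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.label}:{_fmt_len(node.length)}"
    inner = ",".join(_to_newick(c) for c in node.children)
    sup = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){sup}:{_fmt_len(node.length)}"


def write_newick(tree: SupportTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        return TreeNode(label=label, length=dnode.edge.length or 0.0)
    support = None
    if dnode.label is not None:
        try:
            support = float(dnode.label)
        except ValueError:
            support = None
    return TreeNode(
        children=[_from_dendropy(c) for c in dnode.child_nodes()],
        length=dnode.edge.length or 0.0,
        support=support,
    )


def read_newick(source: str | Path, *, is_path: bool = True) -> SupportTree:
    """Parse a Newick tree; internal node labels are read as supports."""
    kwargs = dict(schema="newick", preserve_underscores=True)
    if is_path:
        dtree = dendropy.Tree.get(path=str(source), **kwargs)
    else:
        dtree = dendropy.Tree.get(data=str(source), **kwargs)
    root = _from_dendropy(dtree.seed_node)
    root.support = None  # a root label is not an edge support
    return SupportTree(root=root)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def distance_matrix(msa: MSA, model: str = "p") -> DistanceMatrix:
    """Pairwise p or Poisson-corrected distances over mutually ungapped columns."""
    if model not in {"p", "poisson"}:
        raise InputError(f"unknown distance model {model!r}")
    n = msa.n_rows
    if n < 3:
        raise InputError("need at least 3 sequences for a distance matrix")
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in msa.rows]
    gap = GAP.encode()
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (rows[i] != gap) & (rows[j] != gap)
            overlap = int(ok.sum())
            if overlap == 0:
                raise InputError(
                    f"sequences {msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped columns"
                )
            p = float((rows[i][ok] != rows[j][ok]).sum()) / overlap
            if model == "p":
                dist = p
            elif p >= 1.0:
                warnings.warn(
                    f"saturated pair ({msa.ids[i]!r}, {msa.ids[j]!r}): "
                    f"capping Poisson distance at {MAX_DISTANCE}"
                )
                dist = MAX_DISTANCE
            else:
                dist = -math.log1p(-p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=list(msa.ids), matrix=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _clamp(x: float) -> float:
    if x < 0:
        if x < -1e-9:
            warnings.warn(f"negative branch length {x:.3g} clamped to 0")
        return 0.0
    return x


def nj_tree(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining; deterministic with ties broken by the
    smallest (lexicographic) pair of cluster representative labels."""
    n = len(dm.labels)
    if n < 3:
        raise InputError("neighbor joining needs at least 3 labels")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lbl) for lbl in dm.labels]
    reps: list[str] = list(dm.labels)  # smallest leaf label per cluster
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best_q = math.inf
        best_pair: tuple[int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((reps[i], reps[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12
                    and best_pair is not None
                    and key < tuple(sorted((reps[best_pair[0]], reps[best_pair[1]])))
                ):
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        # reuse slot i for the merged cluster
        for k in active:
            if k != i and k != j:
                d[i, k] = d[k, i] = max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2)
        nodes[i] = new
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = _clamp(ln)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportTree(root=root)


def tree_path_distances(tree: SupportTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (additivity oracle helper)."""
    labels = sorted(tree.leaf_labels)
    index = {lbl: k for k, lbl in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def below(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: node.length}
        merged: dict[str, float] = {}
        sub = [below(c) for c in node.children]
        for x in range(len(sub)):
            for y in range(x + 1, len(sub)):
                for lx, dx in sub[x].items():
                    for ly, dy in sub[y].items():
                        d[index[lx], index[ly]] = d[index[ly], index[lx]] = dx + dy
        for s in sub:
            for lbl, dist in s.items():
                merged[lbl] = dist + node.length
        return merged

    sub = [below(c) for c in tree.root.children]
    for x in range(len(sub)):
        for y in range(x + 1, len(sub)):
            for lx, dx in sub[x].items():
                for ly, dy in sub[y].items():
                    d[index[lx], index[ly]] = d[index[ly], index[lx]] = dx + dy
    return DistanceMatrix(labels=labels, matrix=d)


def rf_distance(t1: SupportTree, t2: SupportTree) -> int:
    """Robinson-Foulds distance (symmetric difference of non-trivial splits)."""
    if t1.leaf_labels != t2.leaf_labels:
        raise InputError("trees must share the same leaf set")
    b1 = set(t1.bipartitions())
    b2 = set(t2.bipartitions())
    return len(b1 ^ b2)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _resample_columns(msa: MSA, rng: np.random.Generator) -> MSA:
    cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
    rows = ["".join(row[j] for j in cols) for row in msa.rows]
    return MSA(ids=list(msa.ids), rows=rows)


def bootstrap_supports(
    msa: MSA, B: int = 100, seed: int = 0, model: str = "p"
) -> SupportTree:
    """NJ tree from ``msa`` with bootstrap percentages on internal nodes.

    ``B = 0`` returns the tree without supports.  Deterministic for a
    fixed seed.
    """
    if B < 0:
        raise InputError("bootstrap replicate count must be >= 0")
    tree = nj_tree(distance_matrix(msa, model))
    if B == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(B):
        rep = nj_tree(distance_matrix(_resample_columns(msa, rng), model))
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    all_leaves = tree.leaf_labels
    ref = min(all_leaves)
    for node in tree._walk(tree.root):
        if node is tree.root or node.is_leaf:
            continue
        side = node.leaf_set()
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        canonical = all_leaves - side if ref in side else side
        node.support = 100.0 * counts.get(canonical, 0) / B
    return tree


# ---------------------------------------------------------------------------
# subclade extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Subclade:
    family: str
    leaves: frozenset[str]
    support: float | None
    low_support: bool
    note: str = ""


def extract_subclade(
    tree: SupportTree,
    seeds: set[str] | frozenset[str],
    min_support: float = 70.0,
    family: str = "subclade",
) -> Subclade:
    """Smallest bipartition side containing every seed leaf.

    When the seeds span the root of every rooting, the full leaf set is
    returned with a note.  ``low_support`` is set when the defining
    split's support is absent or below ``min_support``.
    """
    if not seeds:
        raise InputError("seed set must be non-empty")
    seeds = frozenset(seeds)
    all_leaves = tree.leaf_labels
    unknown = seeds - all_leaves
    if unknown:
        raise InputError(f"seed ids not in tree: {sorted(unknown)}")

    candidates: list[tuple[frozenset[str], float | None]] = []
    for node in tree._walk(tree.root):
        if node is tree.root:
            continue
        side = node.leaf_set()
        complement = all_leaves - side
        candidates.append((side, node.support))
        if complement:
            candidates.append((complement, node.support))
    best: tuple[frozenset[str], float | None] | None = None
    for side, support in candidates:
        if seeds <= side:
            if best is None or (len(side), tuple(sorted(side))) < (
                len(best[0]),
                tuple(sorted(best[0])),
            ):
                best = (side, support)
    if best is None or len(best[0]) == len(all_leaves):
        return Subclade(
            family=family,
            leaves=all_leaves,
            support=None,
            low_support=True,
            note="seeds span the root; returning full leaf set",
        )
    side, support = best
    trivial = len(side) < 2 or len(all_leaves - side) < 2
    support = None if trivial else support
    return Subclade(
        family=family,
        leaves=side,
        support=support,
        low_support=support is None or support < min_support,
    )


def write_subclades_tsv(subclades: list[Subclade], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tn_leaves\tsupport\tlow_support\tleaves\tnote\n")
        for sc in subclades:
            sup = "" if sc.support is None else f"{sc.support:g}"
            fh.write(
                f"{sc.family}\t{len(sc.leaves)}\t{sup}\t{int(sc.low_support)}\t"
                f"{','.join(sorted(sc.leaves))}\t{sc.note}\n"
            )
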