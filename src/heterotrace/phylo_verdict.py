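"""Distance phylogeny with bootstrap, monophyly testing, and the W-origin
verdict.

Trees are built by neighbor joining on Jukes-Cantor-corrected distances with
column-resampling bootstrap — a deliberate, documented substitution for
likelihood tree inference: at these divergences the acceptance surface is
the topology (which haplotype the W groups with), not branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import InputError
from .trace_origin import TraceResult


class SaturationError(ValueError):
    """Pairwise mismatch fraction at or beyond the Jukes-Cantor ceiling."""


@dataclass
class AlignedHaplotypeMatrix:
    """Equal-length aligned sequences, one per taxon."""

    names: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.seqs):
            raise InputError("names/seqs length mismatch")
        if len(self.names) < 2:
            raise InputError("need >= 2 taxa")
        if len({len(s) for s in self.seqs}) != 1:
            raise InputError("aligned rows must have equal length")
        if len(set(self.names)) != len(self.names):
            raise InputError("duplicate taxon names")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def _encoded(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            len(self.names), -1
        )
        valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        return arr, valid

    def resample_columns(self, rng: np.random.Generator) -> "AlignedHaplotypeMatrix":
        idx = rng.integers(0, self.n_columns, self.n_columns)
        return AlignedHaplotypeMatrix(
            list(self.names), ["".join(s[i] for i in idx) for s in self.seqs]
        )


def _jc_from_encoded(arr: np.ndarray, valid: np.ndarray, names: list[str]) -> pd.DataFrame:
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nb = int(both.sum())
            if nb == 0:
                raise SaturationError(f"no comparable columns for {names[i]}/{names[j]}")
            p = float((arr[i, both] != arr[j, both]).sum()) / nb
            if p >= 0.75:
                raise SaturationError(
                    f"pair {names[i]}/{names[j]} saturated (p={p:.3f} >= 0.75)"
                )
            d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return pd.DataFrame(d, index=names, columns=names)


def jc_distance(matrix: AlignedHaplotypeMatrix) -> pd.DataFrame:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - 4p/3), computed over
    columns where both rows hold A/C/G/T."""
    arr, valid = matrix._encoded()
    return _jc_from_encoded(arr, valid, matrix.names)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None, children=None):
        self.name = name
        self.children: list[tuple["Node", float]] = children or []

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out: frozenset = frozenset()
        for child, _ in self.children:
            out |= child.leaves()
        return out


@dataclass
class SupportTree:
    """Unrooted topology (trifurcating root node) with branch lengths and
    per-internal-bipartition bootstrap supports (percent)."""

    root: Node
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> frozenset:
        return self.root.leaves()

    def _normalize(self, side: frozenset) -> frozenset:
        ref = min(self.taxa)
        return side if ref not in side else self.taxa - side

    def bipartitions(self) -> dict[frozenset, float]:
        """Internal bipartitions (normalized to the side without the
        lexicographically first taxon) mapped to branch lengths."""
        n = len(self.taxa)
        out: dict[frozenset, float] = {}

        def walk(node: Node):
            for child, length in node.children:
                side = child.leaves()
                if 1 < len(side) < n - 1:
                    out[self._normalize(side)] = length
                walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: Node, length: float | None) -> str:
            if not node.children:
                s = node.name or ""
            else:
                inner = ",".join(fmt(c, l) for c, l in node.children)
                label = ""
                side = node.leaves()
                n = len(self.taxa)
                if 1 < len(side) < n - 1:
                    sup = self.supports.get(self._normalize(side))
                    if sup is not None:
                        label = str(int(round(sup)))
                s = f"({inner}){label}"
            if length is not None:
                s += f":{length:.6g}"
            return s

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "SupportTree":
        tree = cls(_parse_newick(text.strip()))
        # internal node labels, when numeric, are bootstrap supports
        def walk(node: Node):
            for child, _ in node.children:
                if child.children and child.name:
                    try:
                        sup = float(child.name)
                    except ValueError:
                        sup = None
                    if sup is not None:
                        side = child.leaves()
                        if 1 < len(side) < len(tree.taxa) - 1:
                            tree.supports[tree._normalize(side)] = sup
                walk(child)

        walk(tree.root)
        return tree

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""

        def find(node: Node, name: str, acc: float, path):
            if not node.children:
                if node.name == name:
                    path.append(acc)
                return
            for child, length in node.children:
                find(child, name, acc + length, path)

        def trace(node: Node, name: str) -> list[tuple[Node, float]] | None:
            if not node.children:
                return [(node, 0.0)] if node.name == name else None
            for child, length in node.children:
                sub = trace(child, name)
                if sub is not None:
                    return [(node, 0.0)] + [
                        (n_, l_ + (length if i == 0 else 0.0))
                        for i, (n_, l_) in enumerate(sub)
                    ]
            return None

        pa = trace(self.root, a)
        pb = trace(self.root, b)
        if pa is None or pb is None:
            raise InputError(f"taxon {a!r} or {b!r} not in tree")
        nodes_a = [n_ for n_, _ in pa]
        k = 0
        for na, nb in zip(pa, pb):
            if na[0] is nb[0]:
                k += 1
            else:
                break
        return sum(l for _, l in pa[k:]) + sum(l for _, l in pb[k:])


def _parse_newick(text: str) -> Node:
    if not text.endswith(";"):
        raise InputError("newick must end with ';'")
    pos = 0
    s = text[:-1]

    def parse() -> tuple[Node, float | None]:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                child, length = parse()
                children.append((child, 0.0 if length is None else length))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
            label, length = read_label_length()
            return Node(label or None, children), length
        label, length = read_label_length()
        return Node(label), length

    def read_label_length() -> tuple[str, float | None]:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        length = None
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            length = float(s[start:pos])
        return label, length

    node, _ = parse()
    return node


def nj_tree(distances: pd.DataFrame) -> SupportTree:
    """Neighbor joining; on additive distances the returned tree reproduces
    the inputs exactly. Ties are broken by taxon-name order."""
    d = distances
    if list(d.index) != list(d.columns):
        raise InputError("distance table index/columns differ")
    if not np.allclose(d.values, d.values.T, atol=1e-9):
        raise InputError("distance table is not symmetric")
    labels = list(d.index)
    if len(labels) < 2:
        raise InputError("need >= 2 taxa")
    nodes: dict[str, Node] = {l: Node(l) for l in labels}
    D = {
        (a, b): float(d.loc[a, b]) for a in labels for b in labels if a != b
    }
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * D[(a, b)] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        la = 0.5 * D[(a, b)] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = D[(a, b)] - la
        new = Node(None, [(nodes[a], la), (nodes[b], lb)])
        key = f"_internal{counter}"
        counter += 1
        nodes[key] = new
        for c in active:
            if c in (a, b):
                continue
            D[(key, c)] = D[(c, key)] = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
        active = sorted([c for c in active if c not in (a, b)] + [key])
    if len(active) == 2:
        a, b = active
        root = Node(None, [(nodes[a], 0.0), (nodes[b], D[(a, b)])])
    else:
        a, b, c = active
        la = 0.5 * (D[(a, b)] + D[(a, c)] - D[(b, c)])
        lb = 0.5 * (D[(a, b)] + D[(b, c)] - D[(a, c)])
        lc = 0.5 * (D[(a, c)] + D[(b, c)] - D[(a, b)])
        root = Node(None, [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return SupportTree(root)


def bootstrap_support(
    matrix: AlignedHaplotypeMatrix, B: int = 100, seed: int = 0
) -> SupportTree:
    """NJ tree with column-resampling bootstrap supports; ``B=0`` returns the
    tree with supports unset."""
    arr, valid = matrix._encoded()
    tree = nj_tree(_jc_from_encoded(arr, valid, matrix.names))
    if B <= 0:
        return tree
    rng = np.random.default_rng(seed)
    originals = set(tree.bipartitions())
    counts = {bp: 0 for bp in originals}
    n_ok = 0
    L = matrix.n_columns
    for _ in range(B):
        idx = rng.integers(0, L, L)
        try:
            dist = _jc_from_encoded(arr[:, idx], valid[:, idx], matrix.names)
            rep = nj_tree(dist)
        except SaturationError:
            continue
        n_ok += 1
        found = set(rep.bipartitions())
        for bp in originals & found:
            counts[bp] += 1
    tree.supports = {
        bp: 100.0 * c / n_ok if n_ok else 0.0 for bp, c in counts.items()
    }
    return tree


# ---------------------------------------------------------------------------
# monophyly and the verdict
# ---------------------------------------------------------------------------


def test_monophyly(
    tree: SupportTree, ingroup: set, outgroup: str
) -> tuple[bool, float | None]:
    """Is ``ingroup`` a clade when the tree is rooted on ``outgroup``?

    Returns (flag, support of the corresponding bipartition). When the
    ingroup is everything except the outgroup the split is a pendant edge:
    trivially monophyletic, support 100.
    """
    taxa = tree.taxa
    missing = (set(ingroup) | {outgroup}) - set(taxa)
    if missing:
        raise InputError(f"taxa missing from tree: {sorted(missing)}")
    ingroup = frozenset(ingroup)
    if ingroup == taxa - {outgroup}:
        return True, 100.0
    bps = tree.bipartitions()
    key = tree._normalize(ingroup)
    if key in bps:
        return True, tree.supports.get(key)
    return False, None


def supported_grouping(
    tree: SupportTree,
    include: set,
    exclude: set,
    min_support: float = 70.0,
) -> tuple[bool, float | None]:
    """Does some internal bipartition side contain all of ``include`` and
    none of ``exclude`` with bootstrap support >= ``min_support``?

    With no bootstrap supports recorded, topology alone decides.
    """
    include = frozenset(include)
    exclude = frozenset(exclude)
    taxa = tree.taxa
    best: float | None = None
    found = False
    for key in tree.bipartitions():
        for side in (key, taxa - key):
            if include <= side and not (exclude & side):
                sup = tree.supports.get(key)
                found = True
                if sup is not None and (best is None or sup > best):
                    best = sup
    if not found:
        return False, None
    if not tree.supports:  # no bootstrap run
        return True, None
    return (best is not None and best >= min_support), best


def w_origin_verdict(
    trace_w: TraceResult,
    tree: SupportTree,
    alpha: float = 0.05,
    min_support: float = 70.0,
    taxa: tuple[str, str, str, str] = ("X", "Y", "Z", "W"),
    outgroup: str | None = None,
) -> dict:
    """Combine allele-match counts on the W with the tree topology.

    W_from_Y requires the two-sided exact binomial test on (n_Y, n_X) to
    reject 0.5 toward Y at ``alpha`` AND a supported clade grouping W with Y
    to the exclusion of X (and of the outgroup, auto-detected as the single
    extra taxon when not named); mirrored for W_from_X. Loci scored
    "neither" or unplaced are excluded from the binomial count.
    """
    x, y, _z, w = taxa
    if outgroup is None:
        extra = tree.taxa - set(taxa)
        outgroup = next(iter(extra)) if len(extra) == 1 else None
    out_set = {outgroup} if outgroup else set()
    n_y, n_x = trace_w.n_y_match, trace_w.n_x_match
    n = n_y + n_x
    report: dict = {
        "n_y_match": n_y,
        "n_x_match": n_x,
        "n_neither": trace_w.n_neither,
        "n_unplaced": trace_w.n_unplaced,
        "alpha": alpha,
        "min_support": min_support,
    }
    if n == 0:
        report.update(verdict="undetermined", reason="zero placed informative loci")
        return report
    p = float(stats.binomtest(n_y, n, 0.5).pvalue)
    report["binomial_p"] = p
    group_y, sup_y = supported_grouping(tree, {y, w}, {x} | out_set, min_support)
    group_x, sup_x = supported_grouping(tree, {x, w}, {y} | out_set, min_support)
    report["tree_groups_w_with_y"] = group_y
    report["tree_groups_w_with_x"] = group_x
    report["support_w_with_y"] = sup_y
    report["support_w_with_x"] = sup_x
    if n_y > n_x and p <= alpha and group_y:
        report["verdict"] = "W_from_Y"
    elif n_x > n_y and p <= alpha and group_x:
        report["verdict"] = "W_from_X"
    else:
        report["verdict"] = "undetermined"
        if n_y == n_x:
            report["reason"] = "symmetric allele evidence"
    return report
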