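"""ERV group definition from pol amino-acid sequences.

Groups are preliminary retroviral lineages: clades of a neighbor-joining
tree (uncorrected p-distances, pairwise deletion) with bootstrap support
above 0.70 whose members are more similar to one another than to any other
clade.  Each accepted group is summarised by mean within-group amino-acid
similarity, species distribution, and a representative consensus with an
intact reconstructable RT.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

GAPLIKE = set("-X*.")


# --------------------------------------------------------------------------
# distances

def pairwise_pdistance(a: str, b: str) -> float:
    """Proportion of differing sites under pairwise deletion of gap or
    ambiguous columns; sequences must come from a common alignment."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned (equal length)")
    diffs = comp = 0
    for x, y in zip(a, b):
        if x in GAPLIKE or y in GAPLIKE:
            continue
        comp += 1
        diffs += x != y
    if comp == 0:
        raise ValueError("no comparable sites")
    return diffs / comp


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")

    @classmethod
    def from_alignment(cls, ids: list[str], rows: list[str]) -> "DistanceMatrix":
        n = len(ids)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = pairwise_pdistance(rows[i], rows[j])
        return cls(list(ids), m)


# --------------------------------------------------------------------------
# trees

@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.leaves())

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:.2f}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def bipartitions(self, all_names: frozenset[str] | None = None) -> set[frozenset[str]]:
        """Leaf sets of internal edges, each reported as the smaller side
        (ties by sorted tuple) so rooting is irrelevant."""
        names = all_names or self.leaf_names()
        out: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or not node.children:
                continue
            side = node.leaf_names()
            other = names - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return out


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining, deterministic.

    Q-criterion ties break on the lexicographically smallest pair of
    cluster labels (each cluster keyed by its smallest leaf label), so the
    result does not depend on input row order; negative branch lengths are
    clamped to zero with the deficit moved to the sister branch."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    keys: list[str] = [str(l) for l in dm.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = None
        for i_loc, j_loc in ties:
            if i_loc > j_loc:
                continue
            key = tuple(sorted((keys[active[i_loc]], keys[active[j_loc]])))
            if best is None or key < best[0]:
                best = (key, int(i_loc), int(j_loc))
        _, i_loc, j_loc = best
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (totals[i_loc] - totals[j_loc]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node
        dnew = 0.5 * (d[i, active] + d[j, active] - dij)
        d[i, active] = dnew
        d[active, i] = dnew
        d[i, i] = 0.0
        nodes[i] = parent
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    # final three-way join (unrooted star), closed form
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def bootstrap_supports(ids: list[str], rows: list[str], n_reps: int = 1000,
                       seed: int = 0) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap support per bipartition of the original
    NJ tree (replicate r is seeded with seed+r, so results are independent
    of execution order)."""
    ncol = len(rows[0])
    if ncol < 10:
        raise ValueError("alignment has fewer than 10 columns")
    arr = np.array([list(r) for r in rows])
    base = nj_tree(DistanceMatrix.from_alignment(ids, rows))
    names = frozenset(ids)
    target = base.bipartitions(names)
    counts = {bp: 0 for bp in target}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        try:
            rep = nj_tree(DistanceMatrix.from_alignment(ids, rep_rows))
        except ValueError:
            continue
        found = rep.bipartitions(names)
        for bp in target:
            if bp in found:
                counts[bp] += 1
    return {bp: c / n_reps for bp, c in counts.items()}


def annotate_supports(tree: TreeNode, supports: dict[frozenset[str], float]) -> None:
    names = tree.leaf_names()
    for node in tree.walk():
        if node is tree or not node.children:
            continue
        side = node.leaf_names()
        key = min(side, names - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.support = supports[key]


# --------------------------------------------------------------------------
# groups

@dataclass
class ERVGroup:
    group_id: str
    members: list[str]
    representative: str | None = None
    class_label: str | None = None
    mean_similarity: float = 1.0
    species: set[str] = field(default_factory=set)
    age: object | None = None
    unrepresented: bool = False


def define_groups(tree: TreeNode, supports: dict[frozenset[str], float],
                  dm: DistanceMatrix, threshold: float = 0.70,
                  separation: float = 2.0) -> list[list[str]]:
    """Partition leaves into groups: maximal supported clades whose members
    resemble one another more than other lineages.

    Support must exceed ``threshold`` strictly; both sides of each
    supported edge are clade candidates (the tree is unrooted).  The
    candidate hierarchy is resolved top-down and sub-lineages are merged
    back together unless the distance between them exceeds ``separation``
    times their internal diversity; singletons are allowed.
    """
    names = tree.leaf_names()
    idx = {l: i for i, l in enumerate(dm.labels)}
    cands: set[frozenset[str]] = set()
    for key, sup in supports.items():
        if sup > threshold:
            cands.add(frozenset(key))
            cands.add(names - key)
    cands = {c for c in cands if 1 < len(c) < len(names)}

    def mean_dist(a, b) -> float:
        pairs = [(x, y) for x in a for y in b if x != y]
        if not pairs:
            return 0.0
        return float(np.mean([dm.matrix[idx[x], idx[y]] for x, y in pairs]))

    def maximal_disjoint(universe: frozenset[str]) -> list[frozenset[str]]:
        inside = sorted((c for c in cands if c < universe),
                        key=lambda c: (-len(c), tuple(sorted(c))))
        out: list[frozenset[str]] = []
        for c in inside:
            if all(not (c & o) for o in out):
                out.append(c)
        return out

    def resolve(universe: frozenset[str], is_top: bool = False) -> list[frozenset[str]]:
        """Finest partition induced by the supported clade hierarchy.

        A supported clade without supported substructure stays whole; the
        full leaf set is not itself a supported clade, so with no
        candidates at all every leaf is a singleton."""
        if len(universe) == 1:
            return [universe]
        subs = maximal_disjoint(universe)
        if not subs:
            if is_top:
                return [frozenset([l]) for l in sorted(universe)]
            return [universe]
        groups: list[frozenset[str]] = []
        for s in subs:
            groups.extend(resolve(s))
        for leftover in universe - frozenset().union(*subs):
            groups.append(frozenset([leftover]))
        return groups

    groups = resolve(names, is_top=True)
    # agglomerative merge-back: fragments of one lineage sit within the
    # lineage's own diversity of each other; distinct lineages are at least
    # ``separation`` times farther apart
    while len(groups) > 1:
        scale_floor = max((mean_dist(g, g) for g in groups if len(g) > 1),
                          default=0.0)
        best = None
        for a, b in itertools.combinations(groups, 2):
            d = mean_dist(a, b)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        w = max(mean_dist(a, a) if len(a) > 1 else 0.0,
                mean_dist(b, b) if len(b) > 1 else 0.0) or scale_floor
        if w == 0.0 or d > separation * w:
            break
        groups.remove(a)
        groups.remove(b)
        groups.append(a | b)

    groups.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return [sorted(c) for c in groups]


def summarize_group(group_id: str, members: list[str], dm: DistanceMatrix,
                    species_of, consensus_rt_intact: dict[str, bool] | None = None,
                    consensus_distance=None) -> ERVGroup:
    """Mean within-group similarity, species presence and representative.

    ``species_of`` maps a member id to its species.  ``consensus_rt_intact``
    maps candidate consensus ids to whether their RT was reconstructed;
    ``consensus_distance(consensus_id, member_ids)`` ranks candidates by
    closeness.  Groups with no intact-RT consensus are flagged
    unrepresented, mirroring the requirement that every group be backed by
    a consensus whose RT reconstructs cleanly."""
    if not members:
        raise ValueError("empty group")
    idx = {l: i for i, l in enumerate(dm.labels)}
    sims = [1.0 - dm.matrix[idx[a], idx[b]]
            for a, b in itertools.combinations(members, 2)]
    group = ERVGroup(
        group_id=group_id, members=list(members),
        mean_similarity=float(np.mean(sims)) if sims else 1.0,
        species={species_of(m) for m in members})
    if consensus_rt_intact is not None:
        intact = [c for c, ok in consensus_rt_intact.items() if ok]
        if not intact:
            group.unrepresented = True
        else:
            if consensus_distance is None:
                group.representative = sorted(intact)[0]
            else:
                group.representative = min(
                    intact, key=lambda c: (consensus_distance(c, members), c))
    return group
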