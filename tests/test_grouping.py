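"""Group definition: p-distances, neighbor joining (vs independent
oracles), bootstrap supports, clade-based grouping and summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleoerv.grouping import (DistanceMatrix, ERVGroup, bootstrap_supports,
                               define_groups, nj_tree, pairwise_pdistance,
                               summarize_group)


class TestPDistance:
    def test_identity(self):
        assert pairwise_pdistance("MKV", "MKV") == 0

    def test_direct_count(self):
        assert pairwise_pdistance("MKV", "MRV") == pytest.approx(1 / 3)

    def test_pairwise_deletion_of_gapped_columns(self):
        assert pairwise_pdistance("MK-V", "MRQV") == pytest.approx(1 / 3)

    def test_ambiguous_residues_excluded(self):
        assert pairwise_pdistance("MXV", "MKV") == 0

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError):
            pairwise_pdistance("--", "AB")


def random_additive_tree(n, rng):
    """Random binary topology with positive branch lengths; returns leaf
    path-distance matrix and the set of non-trivial splits."""
    nodes = [frozenset([i]) for i in range(n)]
    dist = np.zeros((n, n))
    heights = {frozenset([i]): 0.0 for i in range(n)}
    # random agglomeration with random edge lengths builds an additive tree
    active = list(range(n))
    d = np.zeros((n, n))
    members = {i: [i] for i in range(n)}
    extra = {i: {i: 0.0} for i in range(n)}  # leaf -> dist to cluster root
    splits = []
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[int(i)], active[int(j)]
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for x in members[a]:
            for y in members[b]:
                d[x, y] = d[y, x] = extra[a][x] + la + extra[b][y] + lb
        new = max(active) + 1
        members[new] = members[a] + members[b]
        extra[new] = {x: extra[a][x] + la for x in members[a]}
        extra[new].update({y: extra[b][y] + lb for y in members[b]})
        if 2 <= len(members[a]) <= n - 2:
            splits.append(frozenset(members[a]))
        if 2 <= len(members[b]) <= n - 2:
            splits.append(frozenset(members[b]))
        active.remove(a)
        active.remove(b)
        active.append(new)
    return d, splits


def quartet_splits_from_matrix(d):
    """Four-point-condition oracle: for each quartet, the pairing with the
    smallest sum is the induced split."""
    n = d.shape[0]
    out = set()
    for q in itertools.combinations(range(n), 4):
        i, j, k, l = q
        sums = {(frozenset([i, j]), frozenset([k, l])): d[i, j] + d[k, l],
                (frozenset([i, k]), frozenset([j, l])): d[i, k] + d[j, l],
                (frozenset([i, l]), frozenset([j, k])): d[i, l] + d[j, k]}
        pairing = min(sums, key=sums.get)
        out.add(frozenset(pairing))
    return out


def quartets_from_tree(tree, labels):
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = set()
    bps = tree.bipartitions()
    full = frozenset(labels)
    for bp in bps:
        side = {idx[x] for x in bp}
        other = {idx[x] for x in full - bp}
        for a, b in itertools.combinations(side, 2):
            for c, d_ in itertools.combinations(other, 2):
                out.add(frozenset([frozenset([a, b]), frozenset([c, d_])]))
    return out


class TestNJ:
    def test_spec_quartet_example(self):
        labels = list("ABCD")
        m = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        t = nj_tree(DistanceMatrix(labels, m))
        assert t.bipartitions() == {frozenset("AB")}
        # internal branch length 1; leaves A:1 B:2 C:3 D:4
        lengths = {}
        for node in t.walk():
            if node.name:
                lengths[node.name] = node.length
            elif node is not t:
                internal = node.length
        assert lengths == {"A": 1, "B": 2, "C": 3, "D": 4}
        assert internal == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        m = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        t = nj_tree(DistanceMatrix(list("XYZ"), m))
        lengths = {n.name: n.length for n in t.walk() if n.name}
        assert lengths["X"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["Y"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["Z"] == pytest.approx((6 + 8 - 4) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            DistanceMatrix(list("abc"), m)

    @pytest.mark.parametrize("trial", range(25))
    def test_additive_recovery_against_quartet_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        d, _ = random_additive_tree(n, rng)
        labels = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(labels, d))
        got = quartets_from_tree(tree, labels)
        want = quartet_splits_from_matrix(d)
        # every induced quartet must agree with the four-point oracle
        assert got <= want

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 7
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            labels = [f"t{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(labels, m)).bipartitions()
            sk = skbio.tree.nj(SkDM(m, labels))
            allnames = frozenset(labels)
            theirs = set()
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    theirs.add(min(side, allnames - side,
                                   key=lambda s: (len(s), tuple(sorted(s)))))
            assert mine == theirs


def two_cluster_alignment(rng, n_per=4, length=120):
    base1 = "".join(rng.choice(list("ACDEFGHIKL"), length))
    base2 = "".join(rng.choice(list("MNPQRSTVWY"), length))

    def mutate(s, k):
        s = list(s)
        for i in rng.choice(length, k, replace=False):
            s[i] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
        return "".join(s)

    ids = [f"s{i}" for i in range(2 * n_per)]
    rows = [mutate(base1, 6) for _ in range(n_per)] + \
           [mutate(base2, 6) for _ in range(n_per)]
    return ids, rows


class TestBootstrap:
    def test_two_clusters_strong_central_support(self, rng):
        ids, rows = two_cluster_alignment(rng)
        sup = bootstrap_supports(ids, rows, n_reps=200, seed=11)
        central = frozenset(ids[:4])
        assert sup[central] >= 0.95

    def test_single_replicate_supports_binary(self, rng):
        ids, rows = two_cluster_alignment(rng)
        sup = bootstrap_supports(ids, rows, n_reps=1, seed=5)
        assert set(sup.values()) <= {0.0, 1.0}

    def test_star_radiation_low_supports(self, rng):
        # independent mutants of one ancestor (a star phylogeny): no clade
        # is real, so no bipartition should look strongly supported
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        anc = "".join(rng.choice(alphabet, 150))
        rows = []
        for _ in range(6):
            row = list(anc)
            for i in rng.choice(150, 15, replace=False):
                row[i] = rng.choice(alphabet)
            rows.append("".join(row))
        ids = [f"s{i}" for i in range(6)]
        sup = bootstrap_supports(ids, rows, n_reps=200, seed=2)
        assert max(sup.values()) <= 0.90

    def test_taxon_order_invariance(self, rng):
        ids, rows = two_cluster_alignment(rng)
        sup1 = bootstrap_supports(ids, rows, n_reps=50, seed=7)
        order = list(np.random.default_rng(0).permutation(len(ids)))
        sup2 = bootstrap_supports([ids[i] for i in order],
                                  [rows[i] for i in order], n_reps=50, seed=7)
        assert sup1 == sup2

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_supports(["a", "b", "c"], ["AAA", "AAA", "AAA"], 10, 0)


class TestDefineGroups:
    def _four_families(self, rng, n_per=5, length=150, intra=4):
        fams = []
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        ancestors = ["".join(rng.choice(alphabet, length)) for _ in range(4)]

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(length, k, replace=False):
                s[i] = rng.choice(alphabet)
            return "".join(s)

        ids, rows, fam_of = [], [], {}
        for f, anc in enumerate(ancestors):
            for m in range(n_per):
                ids.append(f"f{f}m{m}")
                rows.append(mutate(anc, intra))
                fam_of[ids[-1]] = f
        return ids, rows, fam_of

    def test_four_planted_families_recovered_exactly(self, rng):
        ids, rows, fam_of = self._four_families(rng)
        sup = bootstrap_supports(ids, rows, n_reps=150, seed=3)
        dm = DistanceMatrix.from_alignment(ids, rows)
        groups = define_groups(nj_tree(dm), sup, dm)
        assert len(groups) == 4
        for g in groups:
            assert len({fam_of[m] for m in g}) == 1 and len(g) == 5

    def test_support_exactly_070_is_not_enough(self, rng):
        ids, rows, _ = self._four_families(rng)
        dm = DistanceMatrix.from_alignment(ids, rows)
        tree = nj_tree(dm)
        forced = {bp: 0.70 for bp in tree.bipartitions()}
        groups = define_groups(tree, forced, dm)
        assert all(len(g) == 1 for g in groups)  # strict >

    def test_groups_partition_members(self, rng):
        ids, rows, _ = self._four_families(rng)
        sup = bootstrap_supports(ids, rows, n_reps=100, seed=9)
        dm = DistanceMatrix.from_alignment(ids, rows)
        groups = define_groups(nj_tree(dm), sup, dm)
        flat = [m for g in groups for m in g]
        assert sorted(flat) == sorted(ids)


class TestSummarize:
    def test_identical_members_similarity_one(self):
        dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        g = summarize_group("G1", list("abc"), dm, species_of=lambda m: "sp")
        assert g.mean_similarity == 1.0 and g.species == {"sp"}

    def test_two_species_presence(self):
        dm = DistanceMatrix(["A_1", "B_1"], np.array([[0, .1], [.1, 0]]))
        g = summarize_group("G1", ["A_1", "B_1"], dm,
                            species_of=lambda m: m.split("_")[0])
        assert g.species == {"A", "B"}

    def test_group_without_intact_rt_consensus_flagged(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, .1], [.1, 0]]))
        g = summarize_group("G1", ["a", "b"], dm, species_of=lambda m: "sp",
                            consensus_rt_intact={"cons1": False})
        assert g.unrepresented and g.representative is None

    def test_empty_group_rejected(self):
        dm = DistanceMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            summarize_group("G1", [], dm, species_of=lambda m: "sp")
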