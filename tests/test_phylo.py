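import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from rhizoscreen.errors import ConfigurationError, DataError
from rhizoscreen.phylo import (align_family, concatenate, distance_matrix,
                               neighbor_joining, p_distance, read_newick,
                               robinson_foulds, round_half_away,
                               similarity_ranges, write_newick)
from rhizoscreen.proteome import AMINO_ACIDS, GroupAssignment


class TestAlignFamily:
    def test_equal_length_inputs_pass_through(self):
        members = {"a": "ACDEF", "b": "ACDEG", "c": "ACDEH"}
        assert align_family(members) == members

    def test_single_gap_inserted_into_shorter_sequence(self):
        aln = align_family({"long": "ACDEF", "short": "ACEF"})
        assert aln["long"] == "ACDEF"
        assert aln["short"].replace("-", "") == "ACEF"
        assert aln["short"].count("-") == 1
        assert len(aln["short"]) == 5

    def test_center_star_rows_all_equal_length(self):
        rng = np.random.default_rng(4)
        base = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 50))
        members = {
            "full": base,
            "del1": base[:20] + base[23:],
            "del2": base[:37] + base[39:],
        }
        aln = align_family(members)
        assert len({len(r) for r in aln.values()}) == 1
        for key, row in aln.items():
            assert row.replace("-", "") == members[key]

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ConfigurationError):
            align_family({"only": "ACDEF"})


class TestConcatenate:
    def test_lengths_add_up(self):
        fam1 = {"t1": "A" * 100, "t2": "C" * 100}
        fam2 = {"t1": "D" * 50, "t2": "E" * 50}
        sm = concatenate([fam1, fam2], ["t1", "t2"])
        assert all(len(v) == 150 for v in sm.values())

    def test_single_family_is_identity(self):
        fam = {"t1": "ACD", "t2": "ACE"}
        assert concatenate([fam], ["t1", "t2"]) == fam

    def test_missing_taxon_rejected(self):
        with pytest.raises(DataError, match="single-copy"):
            concatenate([{"t1": "ACD"}], ["t1", "t2"])

    def test_family_order_does_not_change_distances(self):
        rng = np.random.default_rng(5)
        fams = []
        for _ in range(4):
            base = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))
            fams.append({
                "t1": base,
                "t2": "".join(
                    c if rng.random() > 0.2 else AMINO_ACIDS[rng.integers(0, 20)]
                    for c in base
                ),
            })
        taxa = ["t1", "t2"]
        d_fwd = p_distance(*concatenate(fams, taxa).values())
        d_rev = p_distance(*concatenate(fams[::-1], taxa).values())
        assert d_fwd == pytest.approx(d_rev)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AAAA", "AAAT", 0.25),
            ("AA-A", "AAAA", 0.0),
            ("ACDEF", "ACDEF", 0.0),
            ("AC-E", "A-CE", 0.0),  # only 2 comparable sites, both equal
        ],
    )
    def test_pairwise_deletion_rule(self, a, b, expected):
        assert p_distance(a, b) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            p_distance("AAA", "AAAA")

    def test_all_gap_overlap_rejected(self):
        with pytest.raises(DataError, match="comparable"):
            p_distance("A--", "-AA")

    def test_triangle_inequality_on_gapless_rows(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 4, 25))
                    for _ in range(3)]
            d01 = p_distance(rows[0], rows[1])
            d12 = p_distance(rows[1], rows[2])
            d02 = p_distance(rows[0], rows[2])
            assert d02 <= d01 + d12 + 1e-12


def _random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths; returns (tree, dm)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    for node in nodes:
        node.length = float(rng.uniform(0.5, 3.0))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        parent.length = float(rng.uniform(0.5, 3.0))
        nodes.append(parent)
    root = TreeNode(children=nodes)
    tips = list(root.tips())
    D = np.zeros((n_taxa, n_taxa))
    by_name = {t.name: t for t in tips}
    for a, b in itertools.combinations(taxa, 2):
        d = by_name[a].distance(by_name[b])
        D[taxa.index(a), taxa.index(b)] = D[taxa.index(b), taxa.index(a)] = d
    return root, DistanceMatrix(D, ids=taxa)


class TestNeighborJoining:
    def test_worked_four_taxon_additive_matrix(self):
        dm = DistanceMatrix(
            np.array([
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ], dtype=float),
            ids=list("ABCD"),
        )
        tree = neighbor_joining(dm)
        # the AB|CD split with leaf edges 1,2,3,4 and internal edge 1
        for a, b in itertools.combinations("ABCD", 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(dm[a, b])
        expected = read_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert robinson_foulds(tree, expected) == 0

    def test_reconstructs_any_additive_matrix_exactly(self):
        rng = np.random.default_rng(9)
        for n_taxa in (4, 5, 6, 7, 8):
            truth, dm = _random_additive_tree(rng, n_taxa)
            tree = neighbor_joining(dm)
            assert robinson_foulds(tree, truth) == 0
            for a, b in itertools.combinations(dm.ids, 2):
                assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                    dm[a, b], abs=1e-9
                )

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ConfigurationError):
            neighbor_joining(dm)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(10)
        noisy = rng.uniform(0.0, 0.05, (5, 5))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        tree = neighbor_joining(DistanceMatrix(noisy, ids=list("abcde")))
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestSimilarityRanges:
    @staticmethod
    def _groups():
        return GroupAssignment({
            "focal": "FOCAL",
            "a1": "ACiM", "a2": "ACiM",
            "m1": "nonACiM", "m2": "nonACiM",
            "r1": "nonACiR", "r2": "nonACiR",
        })

    def test_identical_sequences_give_full_similarity(self):
        rows = {t: "ACDEF" for t in ("focal", "a1", "a2", "m1", "m2", "r1", "r2")}
        dm = distance_matrix(rows)
        assert similarity_ranges(dm, self._groups(), ("FOCAL", "ACiM")) == (100.0, 100.0)

    def test_single_pair_at_quarter_distance(self):
        groups = GroupAssignment({
            "focal": "FOCAL", "a1": "ACiM", "a2": "ACiM",
            "m1": "nonACiM", "m2": "nonACiM", "r1": "nonACiR", "r2": "nonACiR",
        })
        dm = DistanceMatrix(np.full((2, 2), 0.25) - 0.25 * np.eye(2),
                            ids=["focal", "a1"])
        assert similarity_ranges(dm, groups, ("FOCAL", "ACiM")) == (75.0, 75.0)

    def test_island_similarity_exceeds_between_genus_core_similarity(self, tiny_dataset):
        ds = tiny_dataset
        fam_members = {
            fid: dict(zip(grp["strain"], grp["gene_id"]))
            for fid, grp in ds.truth_families.groupby("family_id")
        }
        island_taxa = [ds.focal] + ds.groups.strains("ACiM")
        island_alns = [
            {t: ds.proteomes[t][fam_members[fid][t]].seq for t in island_taxa}
            for fid in ds.island_families
        ]
        dm_island = distance_matrix(concatenate(island_alns, island_taxa))
        lo_island, _ = similarity_ranges(dm_island, ds.groups, ("FOCAL", "ACiM"))

        core = [fid for fid, m in fam_members.items()
                if set(m) == set(ds.proteomes)]
        taxa = sorted(ds.proteomes)
        core_alns = [{t: ds.proteomes[t][fam_members[fid][t]].seq for t in taxa}
                     for fid in core]
        dm_core = distance_matrix(concatenate(core_alns, taxa))
        _, hi_acim = similarity_ranges(dm_core, ds.groups, ("FOCAL", "ACiM"))
        assert lo_island > hi_acim

    def test_empty_group_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 0.1], [0.1, 0.0]]), ids=["focal", "a1"])
        with pytest.raises(ConfigurationError):
            similarity_ranges(dm, self._groups(), ("FOCAL", "nonACiR"))

    def test_half_away_rounding(self):
        assert round_half_away(65.25, 1) == 65.3
        assert round_half_away(65.24, 1) == 65.2


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert robinson_foulds(t, read_newick("((A:1,B:1):1,(C:1,D:1):1);")) == 0

    def test_alternative_quartets_distance_two(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(t1, t2) == 2
        assert robinson_foulds(t2, t1) == 2

    def test_leaf_mismatch_rejected(self):
        t1 = read_newick("((A:1,B:1):1,C:1);")
        t2 = read_newick("((A:1,B:1):1,D:1);")
        with pytest.raises(DataError):
            robinson_foulds(t1, t2)


class TestNewickRoundTrip:
    def test_topology_and_lengths_preserved(self, tmp_path):
        rng = np.random.default_rng(11)
        truth, dm = _random_additive_tree(rng, 6)
        tree = neighbor_joining(dm)
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert robinson_foulds(tree, back) == 0
        for a, b in itertools.combinations(dm.ids, 2):
            assert back.find(a).distance(back.find(b)) == pytest.approx(
                tree.find(a).distance(tree.find(b)), abs=1e-9
            )
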