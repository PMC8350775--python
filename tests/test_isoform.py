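import numpy as np
import pytest

from mitoring.genome_io import CircularGenome, reverse_complement_seq
from mitoring.isoform import (BlockArrangement, are_isoforms, decompose,
                              decompose_blocks, recombination_moves,
                              structural_diff, UnrelatedGenomes)
from mitoring.synthetic_data import (GenomeSpec, RepeatSpec,
                                     generate_mitogenome, random_dna,
                                     shuffle_isoform)

from conftest import make_block_genome
from oracles import oracle_isoforms, seq_canon, seq_neighbors, _canon_state


@pytest.fixture
def two_family_genome():
    spec = GenomeSpec(length=20_000, seed=21,
                      repeat_specs=[RepeatSpec(700, "inverted", name="RA"),
                                    RepeatSpec(600, "direct", name="RB")])
    return generate_mitogenome(spec)


class TestDecompose:
    def test_identical_repeat_free_single_block(self, repeat_free_genome):
        g = repeat_free_genome
        blocks, arr_a, arr_b = decompose_blocks(g, g, min_repeat=500)
        assert len(blocks) == 1
        assert arr_a.circles == arr_b.circles

    def test_one_inversion_two_blocks(self, rng):
        g, reps = make_block_genome(
            rng, [("R", 600)], [4_000, 3_000],
            ["b0", "R", "b1", "-R"])
        iso = CircularGenome("iso", _invert_between(g.seq, reps["R"]))
        blocks, arr_a, arr_b = decompose_blocks(g, iso, min_repeat=500)
        assert len(blocks) == 2
        # arrangements differ by exactly one sign/order change
        assert arr_a.canonical() != arr_b.canonical()
        signs_a = sorted(s for _, s in arr_a.circles[0])
        signs_b = sorted(s for _, s in arr_b.circles[0])
        assert signs_a != signs_b

    def test_six_block_instance_recovered(self, rng):
        # three repeat families delimit six blocks on the circle
        g, _ = make_block_genome(
            rng, [("R1", 600), ("R2", 550), ("R3", 520)],
            [2_000, 1_800, 1_500, 1_200, 1_000, 900],
            ["b0", "R1", "b1", "R2", "b2", "R3", "b3", "R1", "b4", "R2", "b5", "R3"])
        blocks, arr_a, _ = decompose_blocks(g, g, min_repeat=500)
        assert len(blocks) == 6
        syms = [s for s, _ in arr_a.circles[0]]
        assert len(syms) == 12  # 6 blocks + 6 repeat copies

    def test_unrelated_genomes_error(self):
        a, _ = generate_mitogenome(GenomeSpec(length=5_000, seed=1))
        b, _ = generate_mitogenome(GenomeSpec(length=5_000, seed=2))
        with pytest.raises(UnrelatedGenomes):
            decompose_blocks(a, b, min_repeat=500)


def _invert_between(seq, repeat):
    """Invert the segment between the two copies of an inverted repeat."""
    p1 = seq.find(repeat)
    p2 = seq.find(reverse_complement_seq(repeat))
    assert p1 != -1 and p2 != -1
    a, b = sorted((p1, p2))
    e1 = a + len(repeat)
    return seq[:e1] + reverse_complement_seq(seq[e1:b]) + seq[b:]


class TestMoves:
    def test_single_inverted_pair_one_neighbor(self):
        arr = BlockArrangement(((("A", 1), ("R", 1), ("B", 1), ("R", -1)),),
                               frozenset({"R"}))
        nbrs = recombination_moves(arr)
        assert len(nbrs) == 1
        assert all(len(n.circles) == 1 for n in nbrs)

    def test_single_direct_pair_one_fission(self):
        arr = BlockArrangement(((("A", 1), ("R", 1), ("B", 1), ("R", 1)),),
                               frozenset({"R"}))
        nbrs = recombination_moves(arr)
        assert len(nbrs) == 1
        assert all(len(n.circles) == 2 for n in nbrs)

    def test_no_multicopy_family_no_moves(self):
        arr = BlockArrangement(((("A", 1), ("R", 1), ("B", 1)),),
                               frozenset({"R"}))
        assert recombination_moves(arr) == set()

    def test_moves_conserve_symbol_multiset(self):
        arr = BlockArrangement(
            ((("A", 1), ("R", 1), ("B", 1), ("R", -1), ("C", 1), ("S", 1),
              ("D", 1), ("S", 1)),),
            frozenset({"R", "S"}))
        base = arr.symbol_counts()
        for n in recombination_moves(arr):
            assert n.symbol_counts() == base


class TestAreIsoforms:
    def test_reflexive(self, two_family_genome):
        g, _ = two_family_genome
        v = are_isoforms(g, g, min_repeat=500)
        assert v.equivalent and v.moves == []

    def test_rotation_and_rc_zero_moves(self, two_family_genome):
        g, _ = two_family_genome
        assert are_isoforms(g, g.rotate(5_000), min_repeat=500).moves == []
        assert are_isoforms(g, g.reverse_complement(), min_repeat=500).moves == []

    def test_one_inversion_one_move(self, two_family_genome):
        g, truth = two_family_genome
        iso, log = shuffle_isoform(g, truth, n_moves=1, seed=3)
        v = are_isoforms(g, iso, min_repeat=500)
        assert v.equivalent and len(v.moves) == 1
        assert v.moves[0][1] == "inversion"

    def test_symmetry(self, two_family_genome):
        g, truth = two_family_genome
        iso, _ = shuffle_isoform(g, truth, n_moves=1, seed=5)
        va = are_isoforms(g, iso, min_repeat=500)
        vb = are_isoforms(iso, g, min_repeat=500)
        assert va.equivalent == vb.equivalent
        assert len(va.moves) == len(vb.moves)

    def test_shuffle_recognized_within_n_moves(self, two_family_genome):
        g, truth = two_family_genome
        for n in (1, 2, 3):
            iso, _ = shuffle_isoform(g, truth, n_moves=n, seed=n * 7)
            v = are_isoforms(g, iso, min_repeat=500)
            assert v.equivalent and len(v.moves) <= n

    def test_deleted_block_not_equivalent(self, two_family_genome):
        g, _ = two_family_genome
        gdel = CircularGenome("del", g.seq[:3_000] + g.seq[4_000:])
        v = are_isoforms(g, gdel, min_repeat=500)
        assert v.equivalent is False
        assert any(d["type"] == "private_segment" for d in v.differences)

    def test_exchange_needs_two_moves(self, rng):
        # interleaved direct families R..S..R..S: swapping the segments
        # between them is a fission + fusion
        R, S = random_dna(rng, 600), random_dna(rng, 600)
        w, x, y, z = (random_dna(rng, n) for n in (3_000, 2_500, 2_800, 2_600))
        a = CircularGenome("a", R + w + S + x + R + y + S + z)
        b = CircularGenome("b", R + y + S + x + R + w + S + z)
        v = are_isoforms(a, b, min_repeat=500)
        assert v.equivalent and len(v.moves) == 2
        assert {m[1] for m in v.moves} == {"fission", "fusion"}

    def test_repeat_free_insertion_not_equivalent(self, rng):
        # a fragment of block B inserted into block C with no flanking repeat
        g, reps = make_block_genome(
            rng, [("R", 600)], [4_000, 3_500, 3_000],
            ["b0", "R", "b1", "-R", "b2"])
        seq = g.seq
        bstart = seq.find(reps["R"]) + 600
        fragment = seq[bstart + 500: bstart + 1_500]  # 1 kb of block b1
        insert_at = len(seq) - 1_000  # inside b2
        b = CircularGenome("b", seq[:insert_at] + fragment + seq[insert_at:])
        v = are_isoforms(g, b, min_repeat=500)
        assert v.equivalent is False
        assert v.differences

    def test_replay_path_reaches_goal(self, two_family_genome):
        g, truth = two_family_genome
        iso, _ = shuffle_isoform(g, truth, n_moves=2, seed=13)
        v = are_isoforms(g, iso, min_repeat=500)
        assert v.equivalent
        if v.moves:
            dec = decompose(g, iso, min_repeat=500)
            syms = dec.arrangement_a.repeat_symbols
            # each consecutive state pair on the path is one legal move apart
            for s0, s1 in zip(v.path, v.path[1:]):
                nbrs = {n.circles for n in
                        recombination_moves(BlockArrangement(s0, syms))}
                assert s1 in nbrs


def _random_instance(seed):
    """Small sequence-level instance: circle with 2-3 repeat families."""
    rng = np.random.default_rng(seed)
    n_fam = int(rng.integers(1, 3))
    reps = [random_dna(rng, int(rng.integers(60, 100))) for _ in range(n_fam)]
    layout = []
    for i, R in enumerate(reps):
        layout.append(R)
        layout.append(random_dna(rng, int(rng.integers(150, 350))))
        layout.append(R if rng.random() < 0.5 else
                      reverse_complement_seq(R))
        layout.append(random_dna(rng, int(rng.integers(150, 350))))
    return "".join(layout), reps


class TestOracleEquivalence:
    """BFS over symbol arrangements must agree with exhaustive enumeration
    over raw sequences on small instances."""

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_instances(self, seed):
        start, reps = _random_instance(seed)
        reach = {}
        from oracles import seq_reachable
        reach = seq_reachable(start, reps, max_depth=3)
        # pick the deepest single-circle state as the comparison target
        singles = [(d, s) for s, d in reach.items() if len(s) == 1]
        depth, target = max(singles)
        a = CircularGenome("a", start)
        b = CircularGenome("b", target[0])
        v = are_isoforms(a, b, min_repeat=50, max_moves=4)
        assert v.equivalent is True
        assert len(v.moves) <= depth

    @pytest.mark.parametrize("seed", range(5))
    def test_negative_instances(self, seed):
        start, reps = _random_instance(seed + 100)
        rng = np.random.default_rng(seed + 200)
        # delete 300 bp of non-repeat sequence -> content differs
        d0 = start.find(reps[0]) + len(reps[0]) + 10
        mutated = start[:d0] + start[d0 + 300:]
        ok, _ = oracle_isoforms(start, mutated, reps, max_depth=3)
        assert not ok
        v = are_isoforms(CircularGenome("a", start), CircularGenome("b", mutated),
                         min_repeat=50, max_moves=4)
        assert v.equivalent is False

    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_verdict_matches_oracle_on_move_sequences(self, seed):
        start, reps = _random_instance(seed)
        from oracles import seq_reachable
        reach = seq_reachable(start, reps, max_depth=3)
        singles = sorted((d, s) for s, d in reach.items() if len(s) == 1)
        for depth, state in singles[:6]:
            v = are_isoforms(CircularGenome("a", start),
                             CircularGenome("b", state[0]),
                             min_repeat=50, max_moves=4)
            assert v.equivalent is True, (depth, state)
            assert len(v.moves) <= depth


class TestStructuralDiff:
    def test_identical_empty_diff(self, repeat_free_genome):
        d = structural_diff(repeat_free_genome, repeat_free_genome, min_repeat=500)
        assert d["identical"]
        assert d["private_a"] == d["private_b"] == []

    def test_rsal_style_copy_number_difference(self, rng):
        # 122 bp repeat: two copies in genome a, single copy in genome b
        rep = random_dna(rng, 122)
        w, x, y = (random_dna(rng, n) for n in (3_000, 2_500, 2_000))
        a = CircularGenome("a", w + rep + x + rep + y)
        b = CircularGenome("b", w + rep + x + y)
        d = structural_diff(a, b, min_repeat=100)
        assert any(r["copies_a"] != r["copies_b"] for r in d["repeats"])
        assert d["mediating_families"]
        # sequence-level count finds the single-copy homolog in b
        row = next(r for r in d["repeats"] if r["copies_a"] != r["copies_b"])
        assert row.get("copies_b_sequence_level") == 1

    def test_expanded_repeat_length_difference(self, rng):
        core = random_dna(rng, 3_553 // 4)  # scaled-down R03 expansion
        ext = random_dna(rng, 1_800)
        w, x = random_dna(rng, 4_000), random_dna(rng, 3_500)
        a = CircularGenome("a", w + core + x + core)
        b = CircularGenome("b", w + core + ext + x + core + ext)
        d = structural_diff(a, b, min_repeat=500)
        assert any(r.get("length_difference") for r in d["repeats"])

    def test_inversion_names_mediating_family(self, rng):
        g, reps = make_block_genome(
            rng, [("R", 600)], [4_000, 3_000], ["b0", "R", "b1", "-R"])
        iso = CircularGenome("iso", _invert_between(g.seq, reps["R"]))
        d = structural_diff(g, iso, min_repeat=500)
        assert d["mediating_families"]
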