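"""Anchoring, chaining, duplication masking and rearrangement calls."""

import numpy as np
import pytest

from chondriome.genome import CircularGenome, revcomp, rotate
from chondriome import simulate as sim
from chondriome import synteny as syn


def _random_genome(seed, n, topology="circular"):
    rng = np.random.default_rng(seed)
    return CircularGenome(f"g{seed}", "".join(rng.choice(list("ACGT"), size=n)),
                          topology)


def brute_force_mems(q: str, s: str, min_len: int):
    """Quadratic scan for maximal exact matches between two linear strings."""
    out = set()
    for i in range(len(q)):
        for j in range(len(s)):
            if q[i] != s[j]:
                continue
            if i > 0 and j > 0 and q[i - 1] == s[j - 1]:
                continue  # not left-maximal
            k = 0
            while i + k < len(q) and j + k < len(s) and q[i + k] == s[j + k]:
                k += 1
            if k >= min_len:
                out.add((i, j, k))
    return out


class TestFindAnchors:
    def test_matches_quadratic_oracle_on_linear_pairs(self):
        for seed in range(6):
            q = _random_genome(seed, 300, "linear")
            s = _random_genome(seed + 50, 300, "linear")
            # plant some shared material so matches exist
            s = CircularGenome(s.id, s.seq[:120] + q.seq[40:140] + s.seq[220:],
                              "linear")
            got = {
                (a.q_start, a.s_start, a.length)
                for a in syn.find_anchors(q, s, min_len=12)
                if a.strand == "+"
            }
            assert got == brute_force_mems(q.seq, s.seq, 12)

    def test_identity_gives_full_length_anchor(self):
        g = _random_genome(1, 500)
        anchors = syn.find_anchors(g, g, min_len=50)
        assert any(a.length == len(g) and a.strand == "+" for a in anchors)

    def test_revcomp_gives_minus_strand_anchor(self):
        g = _random_genome(2, 400)
        rc = CircularGenome("rc", revcomp(g.seq))
        anchors = syn.find_anchors(g, rc, min_len=50)
        assert any(a.length == len(g) and a.strand == "-" for a in anchors)

    def test_anchor_set_is_rotation_invariant(self):
        q = _random_genome(3, 400)
        s = CircularGenome("s", q.seq[:200] + revcomp(q.seq[250:350]) + q.seq[200:250])
        base = {
            (a.length, a.strand) for a in syn.find_anchors(q, s, min_len=30)
        }
        rotated = {
            (a.length, a.strand)
            for a in syn.find_anchors(rotate(q, 137), s, min_len=30)
        }
        assert base == rotated


class TestChainBlocks:
    def test_identical_genomes_single_perfect_block(self):
        g = _random_genome(4, 2_000)
        blocks = syn.chain_blocks(syn.find_anchors(g, g), g, g)
        assert len(blocks) == 1
        assert blocks[0].identity == 1.0
        assert blocks[0].n_snp == 0 and blocks[0].n_indel == 0

    def test_five_snps_counted_in_one_block(self, midsize_reference):
        g, _, repeats = midsize_reference
        events = sim.random_events(np.random.default_rng(11), g, repeats, n_snp=5)
        derived, _ = sim.apply_events(g, events)
        blocks = syn.chain_blocks(syn.find_anchors(derived, g), derived, g)
        assert len(blocks) == 1
        assert blocks[0].n_snp == 5

    def test_translocated_segment_splits_blocks(self):
        g = _random_genome(5, 40_000)
        # move a 20 kb segment elsewhere
        moved = g.seq[:5_000] + g.seq[25_000:] + g.seq[5_000:25_000]
        q = CircularGenome("t", moved)
        blocks = syn.chain_blocks(syn.find_anchors(q, g), q, g)
        assert len(blocks) >= 2


class TestDuplications:
    def test_random_genome_clean(self):
        g = _random_genome(6, 30_000)
        assert syn.detect_duplications(g) == []

    def test_planted_pairs_found_and_masked(self):
        cfg = sim.SimConfig(seed=2, genome_length=150_000, n_repeat_pairs=3,
                            repeat_length=12_000, n_genes=6)
        g, _, _ = sim.simulate_reference(cfg)
        calls = syn.detect_duplications(g)
        assert len(calls) == 3
        assert all(abs(c.size - 12_000) <= 50 for c in calls)
        masked, ivs = syn.mask_large_duplications(g)
        assert len(ivs) == 3
        assert len(g) - len(masked) == sum(b - a for a, b in ivs)

    def test_threshold_monotonicity(self):
        cfg = sim.SimConfig(seed=3, genome_length=100_000, n_repeat_pairs=2,
                            repeat_length=11_000, n_genes=4)
        g, _, _ = sim.simulate_reference(cfg)
        assert len(syn.detect_duplications(g, dup_min=10_000)) == 2
        assert syn.detect_duplications(g, dup_min=20_000) == []

    def test_masking_idempotent(self):
        cfg = sim.SimConfig(seed=4, genome_length=100_000, n_repeat_pairs=2,
                            repeat_length=12_000, n_genes=4)
        g, _, _ = sim.simulate_reference(cfg)
        once, ivs1 = syn.mask_large_duplications(g)
        twice, ivs2 = syn.mask_large_duplications(once)
        assert twice.seq == once.seq and ivs2 == []


class TestRecombination:
    def test_self_comparison_no_junctions(self):
        g = _random_genome(7, 20_000)
        res = syn.compare_genomes(g, g)
        assert res["n_junctions"] == 0

    def test_single_exchange_two_junctions(self):
        cfg = sim.SimConfig(seed=11, genome_length=120_000, n_repeat_pairs=1,
                            repeat_length=400, repeat_orientation="inverted",
                            repeat_copy_gap=(6_000, 15_000), n_genes=10)
        g, _, repeats = sim.simulate_reference(cfg)
        events = sim.random_events(np.random.default_rng(101), g, repeats, n_recomb=1)
        derived, _ = sim.apply_events(g, events)
        res = syn.compare_genomes(derived, g)
        assert res["n_junctions"] == 2

    def test_junction_count_rotation_invariant(self):
        cfg = sim.SimConfig(seed=12, genome_length=120_000, n_repeat_pairs=2,
                            repeat_length=400, repeat_orientation="inverted",
                            repeat_copy_gap=(6_000, 15_000), n_genes=10)
        g, _, repeats = sim.simulate_reference(cfg)
        events = sim.random_events(np.random.default_rng(102), g, repeats, n_recomb=2)
        derived, _ = sim.apply_events(g, events)
        counts = {
            syn.compare_genomes(rotate(derived, k), g)["n_junctions"]
            for k in (0, 31_007, 99_999)
        }
        assert counts == {4}

    def test_empty_block_list_rejected(self):
        g = _random_genome(8, 1_000)
        with pytest.raises(ValueError):
            syn.detect_recombination([], g, g)


class TestLargeIndels:
    def test_identical_genomes_no_calls(self):
        g = _random_genome(9, 20_000)
        res = syn.compare_genomes(g, g)
        assert res["large_indels"] == []

    def test_planted_6881_insertion_recovered(self, midsize_reference):
        g, _, repeats = midsize_reference
        events = sim.random_events(np.random.default_rng(21), g, repeats,
                                   n_ins=1, ins_length=6_881)
        derived, _ = sim.apply_events(g, events)
        res = syn.compare_genomes(derived, g)
        ins = [c for c in res["large_indels"] if c.kind == "insertion"]
        assert len(ins) == 1
        assert abs(ins[0].size - 6_881) <= 50  # anchor-length boundary slack
        planted_at = events[0].positions[0][0]
        got = ins[0].q_interval[0] % len(derived)  # coordinates may be unrolled
        assert min(abs(got - planted_at), len(derived) - abs(got - planted_at)) <= 50

    def test_small_insertion_below_threshold_ignored(self, midsize_reference):
        g, _, repeats = midsize_reference
        events = sim.random_events(np.random.default_rng(22), g, repeats,
                                   n_ins=1, ins_length=900)
        derived, _ = sim.apply_events(g, events)
        res = syn.compare_genomes(derived, g, indel_min=1_000)
        assert res["large_indels"] == []


class TestVariantTally:
    def test_identical_genomes_zero(self):
        g = _random_genome(10, 10_000)
        assert syn.compare_genomes(g, g)["n_syntenic_variants"] == 0

    def test_planted_snps_and_indels_counted_once_each(self, midsize_reference):
        g, _, repeats = midsize_reference
        events = sim.random_events(np.random.default_rng(23), g, repeats,
                                   n_snp=5, n_small_indel=2, small_indel_len=3)
        derived, _ = sim.apply_events(g, events)
        res = syn.compare_genomes(derived, g)
        assert res["n_syntenic_variants"] == 7

    def test_tally_rotation_invariant(self, midsize_reference):
        g, _, repeats = midsize_reference
        events = sim.random_events(np.random.default_rng(24), g, repeats,
                                   n_snp=4, n_small_indel=1)
        derived, _ = sim.apply_events(g, events)
        tallies = {
            syn.compare_genomes(rotate(derived, k), g)["n_syntenic_variants"]
            for k in (0, 17, 55_555)
        }
        assert tallies == {5}


class TestDotplot:
    def test_identity_single_diagonal_row(self, tmp_path):
        g = _random_genome(12, 3_000)
        blocks = syn.chain_blocks(syn.find_anchors(g, g), g, g)
        out = tmp_path / "dp.tsv"
        syn.export_dotplot(blocks, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + len(blocks) == 2
        assert lines[1].split("\t")[4] == "+"

    def test_inversion_gives_minus_strand_row(self, tmp_path):
        g = _random_genome(13, 6_000)
        q = CircularGenome("inv", g.seq[:2_000] + revcomp(g.seq[2_000:4_500]) + g.seq[4_500:])
        blocks = syn.chain_blocks(syn.find_anchors(q, g), q, g)
        out = tmp_path / "dp.tsv"
        syn.export_dotplot(blocks, out)
        strands = {line.split("\t")[4] for line in out.read_text().splitlines()[1:]}
        assert "-" in strands
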