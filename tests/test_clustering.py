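import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nuiforge.align import PairwiseScheme
from nuiforge.clustering import (
    Msa,
    PaddedSeq,
    align_component,
    build_components,
    cluster_component,
    drop_singletons,
    global_score,
    pad_component,
    pairwise_identity,
    pick_representatives,
    select_representatives,
    soft_mask,
)
from nuiforge.formats import GenomeSequence

from conftest import make_call


# ---------------------------------------------------------------------------
# oracles


def union_find_components(intervals):
    """Brute-force transitive closure under pairwise >=1 bp overlap."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (c1, s1, e1), (c2, s2, e2) = intervals[i], intervals[j]
            if c1 == c2 and s1 < e2 and s2 < e1:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def dp_max_matches(a, b, scheme=None):
    """Plain-python affine DP: max matched columns among optimal-score
    global alignments (independent of the package's aligner)."""
    scheme = scheme or PairwiseScheme()
    op, ex = scheme.gap_open, scheme.gap_extend
    NEG = (-1e15, 0)
    n, m = len(a), len(b)

    def sub(x, y):
        x, y = x.upper(), y.upper()
        if x == "N" or y == "N":
            return scheme.n_score, 0
        if x == y:
            return scheme.match, 1
        return scheme.mismatch, 0

    def add(v, s, mt=0):
        return (v[0] + s, v[1] + mt)

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, n + 1):
        Ix[i][0] = (op + ex * (i - 1), 0)
    for j in range(1, m + 1):
        Iy[0][j] = (op + ex * (j - 1), 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s, mt = sub(a[i - 1], b[j - 1])
            h = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = add(h, s, mt)
            Ix[i][j] = max(
                add(max(M[i - 1][j], Ix[i - 1][j], Iy[i - 1][j]), op),
                add(Ix[i - 1][j], ex),
            )
            Iy[i][j] = max(
                add(max(M[i][j - 1], Ix[i][j - 1], Iy[i][j - 1]), op),
                add(Iy[i][j - 1], ex),
            )
    return max(M[n][m], Ix[n][m], Iy[n][m])[1]


def column_walk_score(msa: Msa, row: int) -> float:
    """Independent consensus-walk scorer (re-derives everything per column)."""
    score = 0.0
    for col in sorted(msa.insert_cols[row]):
        column = [r[col] for r in msa.rows]
        ch = msa.rows[row][col]
        if ch == "-":
            continue
        if ch.upper() == "N":
            score -= 0.5
            continue
        tally = {}
        for c in column:
            if c != "-" and c.upper() != "N":
                tally[c.upper()] = tally.get(c.upper(), 0) + 1
        winners = sorted(
            s for s, k in tally.items() if k == max(tally.values())
        )
        consensus = winners[0]
        if ch.upper() == consensus:
            score += 0.2 if ch.islower() else 2.0
        else:
            score -= 1.0
    return score


# ---------------------------------------------------------------------------
# components


class TestBuildComponents:
    def test_one_shared_base_groups(self):
        calls = [
            make_call("S1", ref_start=100, ref_end=120),
            make_call("S2", ref_start=119, ref_end=140),
        ]
        comps = build_components(calls)
        assert len(comps) == 1
        assert (comps[0].start, comps[0].end) == (100, 140)

    def test_half_open_adjacency_does_not_group(self):
        calls = [
            make_call("S1", ref_start=100, ref_end=101),
            make_call("S2", ref_start=101, ref_end=102),
        ]
        assert len(build_components(calls)) == 2

    def test_zero_length_footprints_at_same_point_group(self):
        calls = [
            make_call("S1", ref_start=100, ref_end=100),
            make_call("S2", ref_start=100, ref_end=100),
        ]
        assert len(build_components(calls)) == 1

    def test_500_random_intervals_match_union_find_oracle(self):
        rng = random.Random(3)
        calls = []
        for i in range(500):
            start = rng.randrange(5000)
            end = start + rng.choice([0, 0, rng.randint(1, 40)])
            calls.append(
                make_call(f"S{i}", chrom=rng.choice(["chr1", "chr2"]),
                          ref_start=start, ref_end=end)
            )
        comps = build_components(calls)
        idx = {id(c): i for i, c in enumerate(calls)}
        got = {frozenset(idx[id(m)] for m in comp.members) for comp in comps}
        expected = union_find_components(
            [(c.chrom,) + c.footprint for c in calls]
        )
        assert got == expected

    def test_partition_of_input(self):
        rng = random.Random(4)
        calls = [
            make_call(f"S{i}", ref_start=rng.randrange(1000),
                      ref_end=rng.randrange(1000, 1010))
            for i in range(50)
        ]
        calls = [c for c in calls if c.ref_end >= c.ref_start]
        comps = build_components(calls)
        assert sum(len(c.members) for c in comps) == len(calls)


class TestDropSingletons:
    def test_two_haplotypes_one_sample_dropped(self):
        calls = [
            make_call("S1", hap="1", ref_start=100, ref_end=100),
            make_call("S1", hap="2", ref_start=100, ref_end=100),
        ]
        assert drop_singletons(build_components(calls)) == []

    def test_two_samples_kept(self):
        calls = [
            make_call("S1", ref_start=100, ref_end=100),
            make_call("S2", ref_start=100, ref_end=100),
        ]
        assert len(drop_singletons(build_components(calls))) == 1

    def test_empty_input(self):
        assert drop_singletons([]) == []


class TestPadComponent:
    def ref(self, n=1000, seed=0):
        rng = random.Random(seed)
        return GenomeSequence("chr1", "".join(rng.choice("ACGT") for _ in range(n)))

    def test_short_members_stay_unpadded(self):
        calls = [
            make_call("S1", ref_start=300, ref_end=300, sequence="ACGTACGTACGT"),
            make_call("S2", ref_start=300, ref_end=300, sequence="ACGTACGTACGT"),
        ]
        (comp,) = build_components(calls)
        padded = pad_component(comp, self.ref())
        assert all(p.text == p.member.sequence for p in padded)

    def test_padded_text_matches_string_reconstruction(self):
        ref = self.ref()
        seq = "G" * 80
        calls = [
            make_call("S1", ref_start=300, ref_end=310, sequence=seq),
            make_call("S2", ref_start=295, ref_end=305, sequence=seq),
        ]
        (comp,) = build_components(calls)
        padded = pad_component(comp, ref)
        for p in padded:
            m = p.member
            lo = min(comp.start, m.ref_start) - 50
            hi = max(comp.end, m.ref_end) + 50
            expected = ref.bases[lo : m.ref_start] + seq + ref.bases[m.ref_end : hi]
            assert p.text == expected
            assert p.insert_segment == seq

    def test_left_pad_clipped_at_chromosome_start(self):
        ref = self.ref()
        calls = [
            make_call("S1", ref_start=10, ref_end=10, sequence="T" * 70),
            make_call("S2", ref_start=10, ref_end=10, sequence="T" * 70),
        ]
        (comp,) = build_components(calls)
        padded = pad_component(comp, ref)
        assert padded[0].text.startswith(ref.bases[0:10])
        assert padded[0].insert_start == 10


class TestSoftMask:
    def test_dinucleotide_array_fully_masked(self):
        text = "AC" * 10
        assert soft_mask(text, "tandem") == text.lower()
        # brute-force period scan confirms a period-2 array
        assert all(text[i] == text[i + 2] for i in range(len(text) - 2))

    def test_random_kb_mostly_unmasked(self):
        rng = random.Random(7)
        text = "".join(rng.choice("ACGT") for _ in range(1000))
        masked = soft_mask(text)
        assert sum(1 for c in masked if c.islower()) < 100

    def test_all_n_unchanged(self):
        assert soft_mask("N" * 50) == "N" * 50

    def test_letters_never_altered(self):
        rng = random.Random(8)
        text = "".join(rng.choice("ACGT") for _ in range(300)) + "AT" * 30
        assert soft_mask(text).upper() == text.upper()

    def test_external_intervals_override(self):
        out = soft_mask("ACGTACGT", external_intervals=[(2, 5)])
        assert out == "ACgtaCGT"


class TestAlignComponent:
    def pads(self, seqs):
        return [
            PaddedSeq(make_call(f"S{i}", sequence=s), s, 0, len(s))
            for i, s in enumerate(seqs)
        ]

    def test_identical_sequences_gapless(self):
        msa = align_component(self.pads(["ACGTACGT"] * 3))
        assert all("-" not in r for r in msa.rows)

    def test_internal_insertion_gives_exact_gap_columns(self):
        a = "ACGTACGTACGTACGTAAAA"
        b = a[:10] + "GGGGG" + a[10:]
        msa = align_component(self.pads([a, b]))
        assert msa.rows[0].count("-") == 5
        assert msa.rows[1].count("-") == 0

    def test_single_sequence_trivial(self):
        msa = align_component(self.pads(["ACGT"]))
        assert msa.rows == ["ACGT"]
        assert msa.insert_cols == [{0, 1, 2, 3}]

    def test_degapping_recovers_inputs(self):
        rng = random.Random(9)
        seqs = []
        base = "".join(rng.choice("ACGT") for _ in range(60))
        for _ in range(4):
            s = list(base)
            for _ in range(rng.randint(0, 4)):
                pos = rng.randrange(len(s))
                s.insert(pos, rng.choice("ACGT"))
            seqs.append("".join(s))
        msa = align_component(self.pads(seqs))
        assert [r.replace("-", "") for r in msa.rows] == seqs
        assert len({len(r) for r in msa.rows}) == 1


class TestGlobalScore:
    def msa_of(self, seqs):
        pads = [
            PaddedSeq(make_call(f"S{i}", sequence=s), s, 0, len(s))
            for i, s in enumerate(seqs)
        ]
        return align_component(pads)

    def test_identical_unmasked_segments_score_2_per_base(self):
        msa = self.msa_of(["ACGTACGTAC", "ACGTACGTAC"])
        assert global_score(msa, 0) == pytest.approx(20.0)
        assert global_score(msa, 1) == pytest.approx(20.0)

    def test_fully_masked_match_scores_point2_per_base(self):
        msa = self.msa_of(["acgta", "acgta"])
        assert global_score(msa, 0) == pytest.approx(1.0)

    def test_all_n_segment_scores_minus_half_per_base(self):
        msa = self.msa_of(["NNNN", "ACGT"])
        assert global_score(msa, 0) == pytest.approx(-2.0)

    def test_random_components_match_column_walk_oracle(self):
        rng = random.Random(10)
        for _ in range(60):
            base = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 30)))
            seqs = []
            for _ in range(3):
                s = list(base)
                for _ in range(rng.randint(0, 3)):
                    pos = rng.randrange(len(s))
                    op = rng.random()
                    if op < 0.4:
                        s[pos] = rng.choice("ACGTN")
                    elif op < 0.7:
                        s[pos] = s[pos].lower()
                    else:
                        s.insert(pos, rng.choice("ACGT"))
                seqs.append("".join(s))
            msa = self.msa_of(seqs)
            for row in range(3):
                assert global_score(msa, row) == pytest.approx(
                    column_walk_score(msa, row)
                )


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 1.0

    def test_eight_of_ten(self):
        a = "ACGTACGTAC"
        b = "ACGTACGTGG"
        assert pairwise_identity(a, b) == pytest.approx(
            dp_max_matches(a, b) / 10
        )
        assert pairwise_identity(a, b) == pytest.approx(0.8)

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAAA", "CCCCC") == 0.0

    def test_substring_identity_is_one(self):
        assert pairwise_identity("ACGTACGTACGT", "GTACGT") == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(11)
        for _ in range(60):
            a = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 25)))
            b = "".join(rng.choice("ACGTN") for _ in range(rng.randint(1, 25)))
            expected = dp_max_matches(a, b) / min(len(a), len(b))
            assert pairwise_identity(a, b) == pytest.approx(expected), (a, b)


class TestClusterComponent:
    def pads(self, seqs, samples=None):
        samples = samples or [f"S{i}" for i in range(len(seqs))]
        return [
            PaddedSeq(make_call(s_id, sequence=s), s, 0, len(s))
            for s_id, s in zip(samples, seqs)
        ]

    def test_identical_members_one_cluster(self):
        pads = self.pads(["ACGTACGTAC"] * 4)
        clusters = cluster_component(pads, [20.0] * 4)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 4

    def test_two_divergent_groups_two_clusters(self):
        rng = random.Random(12)
        g1 = "".join(rng.choice("ACGT") for _ in range(30))
        g2 = "".join(rng.choice("ACGT") for _ in range(30))
        assert pairwise_identity(g1, g2) < 0.8
        pads = self.pads([g1, g1, g2, g2])
        clusters = cluster_component(pads, [60.0, 60.0, 50.0, 50.0])
        assert len(clusters) == 2
        assert clusters[0].top.sequence == g1
        assert clusters[1].top.sequence == g2

    def test_identity_exactly_080_joins(self):
        a = "ACGTACGTAC"
        b = "ACGTACGTGG"  # identity exactly 0.8
        assert pairwise_identity(a, b) == pytest.approx(0.8)
        clusters = cluster_component(self.pads([a, b]), [20.0, 16.0])
        assert len(clusters) == 1

    def test_order_invariance(self):
        rng = random.Random(13)
        seqs = []
        base = "".join(rng.choice("ACGT") for _ in range(40))
        for i in range(5):
            s = list(base)
            s[i * 3] = "T" if s[i * 3] != "T" else "A"
            seqs.append("".join(s))
        samples = [f"S{i}" for i in range(5)]
        scores = [float(50 - i) for i in range(5)]
        ref = cluster_component(self.pads(seqs, samples), scores)
        perm = [3, 1, 4, 0, 2]
        shuffled = cluster_component(
            self.pads([seqs[i] for i in perm], [samples[i] for i in perm]),
            [scores[i] for i in perm],
        )
        def key(cs):
            return [
                (c.top.sample_id, sorted(m.sample_id for m in c.members))
                for c in cs
            ]
        assert key(ref) == key(shuffled)


class TestPickRepresentatives:
    def test_single_cluster_top_chosen(self):
        calls = [
            make_call("S1", ref_start=100, ref_end=100),
            make_call("S2", ref_start=100, ref_end=100),
        ]
        (comp,) = build_components(calls)
        pads = [PaddedSeq(c, c.sequence, 0, len(c.sequence)) for c in comp.members]
        clusters = cluster_component(pads, [24.0, 24.0], comp.id)
        reps = pick_representatives(clusters, comp)
        assert len(reps) == 1
        assert reps[0].support_samples == 2

    def test_disjoint_cluster_footprints_two_representatives(self):
        rng = random.Random(14)
        s1 = "".join(rng.choice("ACGT") for _ in range(40))
        s2 = "".join(rng.choice("ACGT") for _ in range(40))
        # a single-sample wide-footprint call bridges two distinct loci
        # into one component but cannot itself become a representative
        calls = [
            make_call("S1", ref_start=100, ref_end=100, sequence=s1),
            make_call("S2", ref_start=100, ref_end=100, sequence=s1),
            make_call("S1", ref_start=160, ref_end=160, sequence=s2),
            make_call("S2", ref_start=160, ref_end=160, sequence=s2),
            make_call(
                "S3",
                ref_start=90,
                ref_end=170,
                sequence="".join(rng.choice("ACGT") for _ in range(160)),
            ),
        ]
        rng_ref = GenomeSequence(
            "chr1", "".join(rng.choice("ACGT") for _ in range(1000))
        )
        reps = select_representatives(calls, rng_ref)
        assert {(r.ref_start, r.ref_end) for r in reps} == {(100, 100), (160, 160)}
        assert {r.sequence for r in reps} == {s1, s2}

    def test_alphabetical_tie_break(self):
        calls = [
            make_call("NA12878", ref_start=100, ref_end=100),
            make_call("HG002", ref_start=100, ref_end=100),
        ]
        ref = GenomeSequence("chr1", "A" * 500)
        reps = select_representatives(calls, ref)
        assert len(reps) == 1
        assert reps[0].sample_id == "HG002"
        # oracle: the tie-break is exactly a sort on (sample, haplotype)
        assert reps[0].sample_id == min(c.sample_id for c in calls)


class TestSelectionInvariants:
    def test_representative_outscores_members(self, small_bundle, small_reps):
        by_key = {(r.chrom, r.ref_start): r for r in small_reps}
        for ev in small_bundle.truth.recurrent_events():
            rep = by_key[(ev.chrom, ev.position)]
            assert rep.global_score >= 0

    def test_resolved_copy_beats_n_gapped_copy(self):
        rng = random.Random(15)
        seq = "".join(rng.choice("ACGT") for _ in range(120))
        corrupted = seq[:50] + "N" * 10 + seq[60:]
        calls = [
            make_call("S_resolved", ref_start=100, ref_end=100, sequence=seq),
            make_call("S_gapped", ref_start=100, ref_end=100, sequence=corrupted),
        ]
        ref = GenomeSequence("chr1", "".join(rng.choice("ACGT") for _ in range(2000)))
        (rep,) = select_representatives(calls, ref)
        assert rep.sample_id == "S_resolved"
        assert rep.sequence == seq

    def test_input_order_invariance(self, small_bundle):
        rng = random.Random(16)
        shuffled = list(small_bundle.calls)
        rng.shuffle(shuffled)
        reps1 = select_representatives(small_bundle.calls, small_bundle.ref)
        reps2 = select_representatives(shuffled, small_bundle.ref)
        assert reps1 == reps2
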