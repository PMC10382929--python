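import numpy as np
import pytest

from minikaryo.assembler import (
    AssemblyError,
    _identity,
    bait_assemble,
    canonical_rotation,
    derive_ncr_consensus,
    filter_reads,
    iterative_extend,
    read_fastq_pairs,
    rotation_equal,
)
from minikaryo.stretch import percent_difference
from minikaryo.synth import ReadPair, generate_ancestral_genome, simulate_reads

from conftest import TOY, TOY_ASM, TOY_READS


def make_pair(seq1="ACGT" * 25, qual1=None, seq2=None, qual2=None):
    seq2 = seq2 or seq1
    qual1 = qual1 or "F" * len(seq1)
    qual2 = qual2 or "F" * len(seq2)
    return ReadPair(
        name="r", mate1=seq1, qual1=qual1, mate2=seq2, qual2=qual2,
        origin_label="x", origin_start=0,
    )


@pytest.fixture(scope="module")
def toy():
    genome = generate_ancestral_genome(seed=3, **TOY)
    pairs = simulate_reads(genome, seed=4, **TOY_READS)
    return genome, pairs


def gene_seq(genome, name):
    for m in genome.karyotype:
        for f in m.genes:
            if f.name == name:
                return f.sequence, m
    raise KeyError(name)


class TestFilterReads:
    def test_clean_reads_all_retained(self, toy):
        _, pairs = toy
        assert filter_reads(pairs) == pairs

    def test_n_fraction_rule(self):
        good = make_pair()
        bad = make_pair(seq1="N" * 11 + "A" * 89)  # 11% N
        assert filter_reads([good, bad]) == [good]

    def test_exactly_ten_percent_kept(self):
        borderline = make_pair(seq1="N" * 10 + "A" * 90)
        assert filter_reads([borderline]) == [borderline]

    def test_low_quality_rule(self):
        bad_q = "#" * 51 + "F" * 49  # 51% of bases at Q2 <= Q20
        ok_q = "#" * 50 + "F" * 50
        assert filter_reads([make_pair(seq1="A" * 100, qual1=bad_q)]) == []
        ok = make_pair(seq1="A" * 100, qual1=ok_q)
        assert filter_reads([ok]) == [ok]

    def test_either_mate_fails_drops_pair(self):
        bad = make_pair(seq2="N" * 20 + "A" * 80)
        assert filter_reads([bad]) == []

    def test_idempotent(self, toy):
        _, pairs = toy
        once = filter_reads(pairs)
        assert filter_reads(once) == once

    def test_matches_bruteforce_on_random_qualities(self):
        rng = np.random.default_rng(31)
        pairs = []
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=50, p=[0.22] * 4 + [0.12]))
            qual = "".join(chr(33 + int(q)) for q in rng.integers(2, 41, size=50))
            seq2 = "".join(rng.choice(list("ACGTN"), size=50, p=[0.22] * 4 + [0.12]))
            qual2 = "".join(chr(33 + int(q)) for q in rng.integers(2, 41, size=50))
            pairs.append(make_pair(seq1=seq, qual1=qual, seq2=seq2, qual2=qual2))

        def ok(seq, qual):
            n_ok = seq.count("N") / len(seq) <= 0.10
            q_ok = sum(ord(c) - 33 <= 20 for c in qual) / len(qual) <= 0.50
            return n_ok and q_ok

        expected = [p for p in pairs if ok(p.mate1, p.qual1) and ok(p.mate2, p.qual2)]
        assert filter_reads(pairs) == expected

    def test_malformed_record_reports_index(self):
        bad = ReadPair("r", "ACGT", "FF", "ACGT", "FFFF", "x", 0)
        with pytest.raises(AssemblyError, match="record 0"):
            filter_reads([bad])


class TestIterativeExtend:
    def test_noiseless_circle_reconstruction(self, toy):
        genome, pairs = toy
        seed, truth = gene_seq(genome, "cox1")
        contig = iterative_extend(pairs, seed, **TOY_ASM)
        assert contig.circular
        assert rotation_equal(contig.sequence, truth.sequence())

    def test_seed_not_covered(self, toy):
        genome, _ = toy
        other = generate_ancestral_genome(seed=99, **TOY)
        single = [p for p in simulate_reads(other, seed=1, **TOY_READS)
                  if p.origin_label == "mc01"]
        seed, _ = gene_seq(genome, "cox1")
        with pytest.raises(AssemblyError, match="seed not covered"):
            iterative_extend(single, seed, **TOY_ASM)

    def test_seed_shorter_than_overlap_rejected(self, toy):
        _, pairs = toy
        with pytest.raises(AssemblyError, match="min_overlap"):
            iterative_extend(pairs, "ACGT", **TOY_ASM)

    def test_noisy_reads_consensus_accuracy(self):
        genome = generate_ancestral_genome(seed=8, **TOY)
        pairs = simulate_reads(
            genome, coverage=50, read_len=100, insert_len=180,
            error_rate=0.01, seed=9,
        )
        seed, truth = gene_seq(genome, "cox1")
        contig = iterative_extend(pairs, seed, min_overlap=50, min_identity=0.95)
        assert contig.circular
        # binomial consensus error at 50x with 1% errors is far below 0.5%
        diff = percent_difference(
            canonical_rotation(contig.sequence), canonical_rotation(truth.sequence())
        )
        assert diff < 0.5

    def test_raising_identity_never_accepts_more(self, toy):
        genome, _ = toy
        pairs = simulate_reads(genome, error_rate=0.02, seed=10, **TOY_READS)
        seed, _ = gene_seq(genome, "cox1")
        contig = iterative_extend(pairs, seed, min_overlap=50, min_identity=0.90)
        window = contig.sequence[:150]
        for lo, hi in [(0.90, 0.95), (0.95, 0.99), (0.99, 1.0)]:
            accept_lo = {
                p.mate1 for p in pairs
                if len(p.mate1) >= 50 and _identity(p.mate1[:50], window[:50]) >= lo
            }
            accept_hi = {
                p.mate1 for p in pairs
                if len(p.mate1) >= 50 and _identity(p.mate1[:50], window[:50]) >= hi
            }
            assert accept_hi <= accept_lo


class TestNcrConsensus:
    def test_planted_shared_ncr(self, toy):
        genome, pairs = toy
        _, m1 = gene_seq(genome, "cox1")
        _, m2 = gene_seq(genome, "rrnS")
        c1 = iterative_extend(pairs, gene_seq(genome, "cox1")[0], **TOY_ASM)
        c2 = iterative_extend(pairs, gene_seq(genome, "rrnS")[0], **TOY_ASM)
        ncr = derive_ncr_consensus(c1, c2, min_overlap=40, min_identity=0.99)
        assert genome.at_motif in ncr  # the genuinely conserved upstream block

    def test_identical_contigs_full_circle(self, toy):
        genome, pairs = toy
        c = iterative_extend(pairs, gene_seq(genome, "cox1")[0], **TOY_ASM)
        consensus = derive_ncr_consensus(c, c, min_overlap=40)
        assert len(consensus) == len(c.sequence)

    def test_two_substitutions_tolerated(self):
        from minikaryo.assembler import Contig

        genome = generate_ancestral_genome(seed=51, **TOY)
        truth_ncr = genome.karyotype.chromosome("mc01").ncr_sequence
        cl1 = genome.karyotype.chromosome("mc01").cluster_sequence
        cl2 = genome.karyotype.chromosome("mc02").cluster_sequence

        def mutate(s, pos):
            repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            return s[:pos] + repl + s[pos + 1 :]

        # two circles sharing the whole NCR, one substitution in each copy
        a = Contig(sequence=cl1 + mutate(truth_ncr, 60), circular=True)
        b = Contig(sequence=cl2 + mutate(truth_ncr, 170), circular=True)
        consensus = derive_ncr_consensus(a, b, min_overlap=40, min_identity=0.98)
        assert len(consensus) >= len(truth_ncr) - 4
        # consensus covers (nearly) the whole NCR with at most 2 mismatches vs truth
        hit = (a.sequence + a.sequence).find(consensus)
        assert abs(hit - len(cl1)) <= 6
        offset = hit - len(cl1)
        skip, pos = max(0, -offset), max(0, offset)
        diffs = sum(1 for x, y in zip(consensus[skip:], truth_ncr[pos:]) if x != y)
        assert diffs <= 2

    def test_linear_contigs_rejected(self, toy):
        from minikaryo.assembler import Contig

        with pytest.raises(AssemblyError):
            derive_ncr_consensus(
                Contig("ACGT" * 100, circular=False), Contig("ACGT" * 100, circular=True)
            )


class TestBaitAssemble:
    def test_full_genome_recovered(self, toy):
        genome, pairs = toy
        c1 = iterative_extend(pairs, gene_seq(genome, "cox1")[0], **TOY_ASM)
        c2 = iterative_extend(pairs, gene_seq(genome, "rrnS")[0], **TOY_ASM)
        ncr = derive_ncr_consensus(c1, c2, min_overlap=40)
        contigs = bait_assemble(pairs, ncr, **TOY_ASM)
        assert len(contigs) == 10
        truths = {canonical_rotation(m.sequence()) for m in genome.karyotype}
        got = {canonical_rotation(c.sequence) for c in contigs}
        assert got == truths
        assert all(c.circular and c.provenance == "baited" for c in contigs)

    def test_reads_from_single_minichromosome(self, toy):
        genome, pairs = toy
        sub = [p for p in pairs if p.origin_label == "mc03"]
        c1 = iterative_extend(sub, gene_seq(genome, "cox1")[0], **TOY_ASM)
        ncr = derive_ncr_consensus(c1, c1, min_overlap=40)
        # bait with the mc03 circle itself: exactly one circle comes back
        m3 = genome.karyotype.chromosome("mc03")
        contigs = bait_assemble(sub, m3.ncr_sequence, **TOY_ASM)
        assert len(contigs) == 1
        assert rotation_equal(contigs[0].sequence, m3.sequence())

    @pytest.mark.parametrize("n_chrom", [9, 10, 11])
    def test_minichromosome_count_estimate(self, n_chrom):
        # build partitions of 9/10/11 parts by merging/splitting the default
        from minikaryo.synth import DEFAULT_PARTITION

        parts = [list(p) for p in DEFAULT_PARTITION]
        if n_chrom == 9:
            parts[2] = parts[2] + parts.pop(6)
        elif n_chrom == 11:
            parts.append([parts[0].pop(), parts[0].pop()])
        genome = generate_ancestral_genome(
            n_minichromosomes=n_chrom, partition=parts, seed=60 + n_chrom, **TOY
        )
        pairs = simulate_reads(genome, seed=61, **TOY_READS)
        c1 = iterative_extend(pairs, gene_seq(genome, "cox1")[0], **TOY_ASM)
        c2 = iterative_extend(pairs, gene_seq(genome, "rrnS")[0], **TOY_ASM)
        ncr = derive_ncr_consensus(c1, c2, min_overlap=40)
        contigs = bait_assemble(pairs, ncr, **TOY_ASM)
        assert len(contigs) == n_chrom

    def test_empty_consensus_rejected(self, toy):
        _, pairs = toy
        with pytest.raises(AssemblyError):
            bait_assemble(pairs, "")


class TestRotation:
    def test_canonical_rotation_minimal(self):
        assert canonical_rotation("BCA") == "ABC"
        assert canonical_rotation("AAB") == "AAB"
        assert canonical_rotation("BAA") == "AAB"

    def test_rotation_equal(self):
        assert rotation_equal("ACGTT", "TTACG")
        assert not rotation_equal("ACGTT", "ACGTA")
        assert not rotation_equal("ACGT", "ACG")
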