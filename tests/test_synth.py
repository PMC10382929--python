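import numpy as np
import pytest

from minikaryo.model import KaryotypeError, Status, revcomp, serialize_karyotype
from minikaryo.recomb import EventRecord, infer_events
from minikaryo.stretch import find_conserved_motifs
from minikaryo.synth import (
    DEFAULT_PARTITION,
    MotifSpec,
    apply_events,
    generate_ancestral_genome,
    simulate_reads,
    write_fastq_pairs,
)

from conftest import TOY, TOY_READS


@pytest.fixture(scope="module")
def genome():
    return generate_ancestral_genome(seed=42)


@pytest.fixture(scope="module")
def toy_genome():
    return generate_ancestral_genome(seed=42, **TOY)


class TestGenerateGenome:
    def test_ten_circles_with_motifs(self, genome):
        assert len(genome.karyotype) == 10
        for m in genome.karyotype:
            assert genome.at_motif in m.ncr_sequence
            assert genome.gc_motif in m.ncr_sequence

    def test_motif_positions(self, genome):
        for m in genome.karyotype:
            # GC-rich downstream of the cluster (NCR start), AT-rich upstream
            assert m.ncr_sequence.find(genome.gc_motif) < len(m.ncr_sequence) // 2
            assert m.ncr_sequence.find(genome.at_motif) > len(m.ncr_sequence) // 2

    def test_deterministic_under_seed(self):
        g1 = generate_ancestral_genome(seed=5)
        g2 = generate_ancestral_genome(seed=5)
        assert [m.sequence() for m in g1.karyotype] == [m.sequence() for m in g2.karyotype]
        g3 = generate_ancestral_genome(seed=6)
        assert [m.sequence() for m in g3.karyotype] != [m.sequence() for m in g1.karyotype]

    def test_size_additivity_invariant(self, genome):
        for m in genome.karyotype:
            assert m.total_len_bp == m.cluster_len_bp + m.ncr_len_bp
            m.check_size_additivity()

    def test_gene_counts_within_range(self, genome):
        for m in genome.karyotype:
            assert 2 <= m.n_full_genes() <= 8

    def test_ncr_lengths_in_range(self, genome):
        for m in genome.karyotype:
            assert 686 <= m.ncr_len_bp <= 1296

    def test_one_reverse_run(self, genome):
        rev = [
            f.name for m in genome.karyotype for f in m.genes
            if f.orientation.value == "reverse"
        ]
        assert sorted(rev) == ["Q", "T", "nad1"]

    def test_partition_must_cover_vocabulary(self):
        bad = [list(p) for p in DEFAULT_PARTITION]
        bad[0] = bad[0][:-1]  # drop atp8
        with pytest.raises(KaryotypeError, match="cover"):
            generate_ancestral_genome(partition=bad)

    def test_motif_recovery_closed_loop(self, genome):
        hits = find_conserved_motifs(genome.ncrs(), min_len=20)
        consensuses = [h.consensus for h in hits]
        assert any(genome.at_motif in c for c in consensuses)
        assert any(genome.gc_motif in c for c in consensuses)
        at_hit = next(h for h in hits if genome.at_motif in h.consensus)
        gc_hit = next(h for h in hits if genome.gc_motif in h.consensus)
        assert at_hit.position_class == "upstream_of_cluster"
        assert at_hit.at_fraction >= 45 / at_hit.length_bp  # planted part is 100% AT
        assert gc_hit.position_class == "downstream_of_cluster"

    def test_custom_motif_spec(self):
        g = generate_ancestral_genome(
            motif_spec=MotifSpec(at_len=60, at_fraction=0.75, gc_len=38, gc_fraction=0.763),
            seed=1,
        )
        assert len(g.at_motif) == 60
        assert len(g.gc_motif) == 38


class TestApplyEvents:
    def test_empty_event_list_is_identity(self, genome):
        derived, log = apply_events(genome, events=[])
        assert log.events == []
        assert [m.sequence() for m in derived.karyotype] == [
            m.sequence() for m in genome.karyotype
        ]

    def test_duplication_copies_sequence_verbatim(self, genome):
        # L1 lives on the nad2 chromosome (mc08) in the default partition
        e = EventRecord(
            type="duplication_insert", genes=("L1",), donor="mc08",
            recipient="mc10", details={"insert_pos": 1},
        )
        derived, _ = apply_events(genome, events=[e])
        occs = derived.karyotype.full_occurrences("L1")
        assert len(occs) == 2
        seqs = {
            derived.karyotype.chromosome(label).genes[pos].sequence
            for label, pos in occs
        }
        assert len(seqs) == 1  # identical in sequence and length

    def test_anchor_based_insert(self, genome):
        e = EventRecord(
            type="duplication_insert", genes=("L1",), donor="mc08",
            recipient="mc10", anchor="rrnL",
        )
        derived, log = apply_events(genome, events=[e])
        mc10 = derived.karyotype.chromosome("mc10")
        names = [f.name for f in mc10.genes]
        assert names.index("L1") == names.index("rrnL") - 1
        assert "insert_pos" in log.events[0].details

    def test_truth_log_replays_byte_identically(self, genome):
        derived, log = apply_events(genome, n_events=3, seed=11)
        replayed, _ = apply_events(genome, events=log.events)
        assert serialize_karyotype(replayed.karyotype) == serialize_karyotype(derived.karyotype)
        assert [m.sequence() for m in replayed.karyotype] == [
            m.sequence() for m in derived.karyotype
        ]

    def test_inapplicable_event_names_it(self, genome):
        e = EventRecord(
            type="translocation", genes=("cox1",), donor="mc01",
            recipient="mc02", details={"insert_pos": 0},
        )
        with pytest.raises(KaryotypeError, match="cox1"):
            apply_events(genome, events=[e])

    def test_single_translocation_recovered(self, genome):
        e = EventRecord(
            type="translocation", genes=("W",), donor="mc05",
            recipient="mc03", details={"insert_pos": 0},
        )
        derived, _ = apply_events(genome, events=[e])
        events = infer_events(genome.karyotype, derived.karyotype)
        assert [ev.key for ev in events] == [("translocation", ("W",), "mc05")]

    def test_partial_duplication_window_size(self, genome):
        derived, log = apply_events(
            genome, n_events=3, event_types=("partial_duplication",), seed=13
        )
        pseudos = [
            f for m in derived.karyotype for f in m.genes if f.status is Status.pseudo
        ]
        assert len(pseudos) == 3
        for f in pseudos:
            assert f.length_bp <= 450
            full = next(
                g.sequence
                for m in genome.karyotype
                for g in m.genes
                if g.name == f.name and g.is_full
            )
            assert f.sequence in full  # copied window of the full gene

    def test_derived_passes_additivity(self, genome):
        derived, _ = apply_events(genome, n_events=3, seed=21)
        for m in derived.karyotype:
            m.check_size_additivity()

    def test_three_event_closed_loop(self, genome):
        derived, log = apply_events(genome, n_events=3, seed=29)
        inferred = infer_events(genome.karyotype, derived.karyotype)
        assert sorted(e.key for e in inferred) == sorted(e.key for e in log.events)


class TestSimulateReads:
    def test_depth_near_target(self, toy_genome):
        pairs = simulate_reads(toy_genome, seed=1, **TOY_READS)
        depth = {m.label: 0 for m in toy_genome.karyotype}
        for p in pairs:
            depth[p.origin_label] += len(p.mate1) + len(p.mate2)
        for m in toy_genome.karyotype:
            assert depth[m.label] / m.total_len_bp == pytest.approx(30, rel=0.15)

    def test_error_free_reads_are_substrings_of_circle(self, toy_genome):
        pairs = simulate_reads(toy_genome, seed=2, **TOY_READS)
        doubled = {m.label: m.sequence() * 2 for m in toy_genome.karyotype}
        for p in pairs[:200]:
            assert p.mate1 in doubled[p.origin_label]
            assert revcomp(p.mate2) in doubled[p.origin_label]

    def test_read_count_closed_form(self, toy_genome):
        cov, rl = 30, 100
        pairs = simulate_reads(toy_genome, coverage=cov, read_len=rl, insert_len=180, seed=3)
        for m in toy_genome.karyotype:
            n = sum(1 for p in pairs if p.origin_label == m.label)
            expected = cov * m.total_len_bp / (2 * rl)
            assert abs(n - expected) <= 1

    def test_error_rate_applied(self, toy_genome):
        noisy = simulate_reads(toy_genome, error_rate=0.02, seed=4, **TOY_READS)
        doubled = {m.label: m.sequence() * 2 for m in toy_genome.karyotype}
        n_diff = total = 0
        for p in noisy:
            truth = doubled[p.origin_label][p.origin_start : p.origin_start + len(p.mate1)]
            n_diff += sum(1 for x, y in zip(p.mate1, truth) if x != y)
            total += len(p.mate1)
        assert n_diff / total == pytest.approx(0.02, rel=0.2)

    def test_insert_must_fit(self, toy_genome):
        with pytest.raises(ValueError):
            simulate_reads(toy_genome, coverage=1, read_len=100, insert_len=10_000)

    def test_fastq_round_trip(self, toy_genome, tmp_path):
        from minikaryo.assembler import read_fastq_pairs

        pairs = simulate_reads(toy_genome, seed=5, **TOY_READS)[:50]
        write_fastq_pairs(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        loaded = read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert [(p.mate1, p.mate2) for p in loaded] == [(p.mate1, p.mate2) for p in pairs]
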