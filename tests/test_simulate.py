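import numpy as np
import pytest

from gallsift import simulate
from gallsift.kmers import canonical_set, revcomp
from gallsift.seqio import write_fastq
from gallsift.simulate import (SimulationConfig, generate_foreign_pool,
                               generate_host_genome, plant_insertions,
                               read_truth, simulate_reads, write_truth)


def small_config(**kw):
    base = dict(seed=1, n_chrom=2, chrom_len=20_000, n_insertions=2,
                insertion_len_range=(500, 800), min_flank=300,
                n_endophytes=1, endophyte_len=3_000, n_core_microbes=1,
                error_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestHostGenome:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        a = generate_host_genome(cfg)
        b = generate_host_genome(cfg)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]

    def test_gc_content_near_target(self):
        # binomial bound: 1 Mb at p=0.5 stays within +-0.01 (p < 1e-6)
        cfg = small_config(n_chrom=1, chrom_len=1_000_000)
        seq = generate_host_genome(cfg)[0].seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_gc_zero_gives_at_only(self):
        cfg = small_config(gc=0.0, chrom_len=5_000, min_flank=300)
        seq = generate_host_genome(cfg)[0].seq
        assert set(seq) <= {"A", "T"}

    def test_chrom_len_must_allow_flanks(self):
        with pytest.raises(ValueError, match="min_flank"):
            cfg = small_config(chrom_len=500)
            generate_host_genome(cfg)


class TestForeignPool:
    def test_roles_and_counts(self):
        cfg = small_config(n_endophytes=3, n_insertions=2)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        assert len(simulate.pool_by_role(pool, simulate.ROLE_ENDOPHYTE)) == 3
        assert len(simulate.pool_by_role(pool, simulate.ROLE_SHARED)) == 1
        assert len(simulate.pool_by_role(pool, simulate.ROLE_DONOR)) == 2

    def test_no_31mer_shared_with_host(self):
        cfg = small_config()
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        host_kmers = canonical_set([r.seq for r in host], 31)
        pool_kmers = canonical_set([r.seq for r in pool], 31)
        assert np.intersect1d(host_kmers, pool_kmers).size == 0

    def test_deterministic(self):
        cfg = small_config()
        host = generate_host_genome(cfg)
        a = generate_foreign_pool(cfg, host)
        b = generate_foreign_pool(cfg, host)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]


class TestPlantInsertions:
    def test_zero_insertions_is_identity(self):
        cfg = small_config(n_insertions=0)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        gall, truth = plant_insertions(host, pool, cfg)
        assert [(r.id, r.seq) for r in gall] == [(r.id, r.seq) for r in host]
        assert truth.events == []

    @pytest.mark.parametrize("micro", [0, 6])
    def test_length_conservation(self, micro):
        cfg = small_config(microhomology_len=micro)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        gall, truth = plant_insertions(host, pool, cfg)
        expected = sum(len(r) for r in host) + sum(
            e.insert_len + len(e.microhomology) for e in truth.events)
        assert sum(len(r) for r in gall) == expected
        assert all(len(e.microhomology) == micro for e in truth.events)

    def test_splice_substring_oracle(self):
        cfg = small_config(n_insertions=1)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        gall, truth = plant_insertions(host, pool, cfg)
        ev = truth.events[0]
        h = next(r.seq for r in host if r.id == ev.chrom)
        g = next(r.seq for r in gall if r.id == ev.chrom)
        donor = next(r.seq for r in pool if r.id == ev.foreign_id)
        p = ev.position
        assert g[p - 50:p] == h[p - 50:p]
        assert g[p:p + ev.insert_len] == donor[ev.foreign_start:ev.foreign_end]
        assert g[p + ev.insert_len:p + ev.insert_len + 50] == h[p:p + 50]

    def test_flank_and_spacing_invariants(self):
        cfg = small_config(n_insertions=5, chrom_len=50_000)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        _, truth = plant_insertions(host, pool, cfg)
        by_chrom = {}
        for ev in truth.events:
            assert cfg.min_flank <= ev.position <= cfg.chrom_len - cfg.min_flank
            by_chrom.setdefault(ev.chrom, []).append(ev.position)
        for positions in by_chrom.values():
            positions.sort()
            assert all(b - a >= 2 * cfg.read_len
                       for a, b in zip(positions, positions[1:]))

    def test_site_exhaustion(self):
        cfg = small_config(n_chrom=1, chrom_len=700, n_insertions=3,
                           endophyte_len=1000)
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        with pytest.raises(RuntimeError, match="site exhaustion"):
            plant_insertions(host, pool, cfg)


class TestSimulateReads:
    def test_read_count_formula(self):
        # round(16 * 100_000 / 150) = 10_667
        cfg = small_config(n_chrom=1, chrom_len=100_000, n_insertions=0)
        host = generate_host_genome(cfg)
        reads = simulate_reads([(host[0], 1.0)], cfg, "healthy")
        assert len(reads) == 10_667
        assert all(len(r) == 150 for r in reads[:100])

    def test_error_free_reads_are_substrings(self):
        cfg = small_config(n_chrom=1, chrom_len=5_000, n_insertions=0)
        host = generate_host_genome(cfg)
        reads = simulate_reads([(host[0], 1.0)], cfg, "healthy")
        genome = host[0].seq
        for r in reads[:200]:
            assert r.seq in genome or revcomp(r.seq) in genome

    def test_deterministic_fastq_bytes(self):
        cfg = small_config(n_chrom=1, chrom_len=5_000, n_insertions=0,
                           error_rate=0.01)
        host = generate_host_genome(cfg)
        a = write_fastq(simulate_reads([(host[0], 1.0)], cfg, "gall"))
        b = write_fastq(simulate_reads([(host[0], 1.0)], cfg, "gall"))
        assert a == b

    def test_error_rate_perturbs_reads(self):
        cfg = small_config(n_chrom=1, chrom_len=5_000, n_insertions=0,
                           error_rate=0.05)
        host = generate_host_genome(cfg)
        reads = simulate_reads([(host[0], 1.0)], cfg, "gall")
        genome = host[0].seq
        mutated = sum(1 for r in reads
                      if r.seq not in genome and revcomp(r.seq) not in genome)
        assert mutated > len(reads) / 2  # P(error-free read) ~ 0.9995^150... at 5%: tiny

    def test_paired_mode_emits_proper_mates(self):
        cfg = small_config(n_chrom=1, chrom_len=10_000, n_insertions=0,
                           paired=True, read_len=250)
        host = generate_host_genome(cfg)
        reads = simulate_reads([(host[0], 1.0)], cfg, "healthy")
        genome = host[0].seq
        assert len(reads) % 2 == 0
        for r1, r2 in zip(reads[:40:2], reads[1:40:2]):
            assert r1.id.endswith("/1") and r2.id.endswith("/2")
            assert r1.id[:-2] == r2.id[:-2]
            assert len(r1) == len(r2) == 250
            # mates face each other across a 200-bp inner gap; locate the
            # fragment via whichever mate lies on the genome forward strand
            i = genome.find(r1.seq)
            if i >= 0:
                assert genome.find(revcomp(r2.seq), i) == i + 250 + 200
            else:
                j = genome.find(r2.seq)
                assert j >= 0
                assert genome.find(revcomp(r1.seq), j) == j + 250 + 200

    def test_read_len_longer_than_genome_errors(self):
        cfg = small_config(n_chrom=1, chrom_len=5_000, n_insertions=0)
        host = generate_host_genome(cfg)
        from gallsift.seqio import SequenceRecord
        tiny = SequenceRecord("tiny", "ACGT" * 10)
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads([(host[0], 1.0), (tiny, 1.0)], cfg, "gall")


class TestTruthFile:
    def test_round_trip_and_1based_convention(self, tmp_path):
        cfg = small_config()
        host = generate_host_genome(cfg)
        pool = generate_foreign_pool(cfg, host)
        _, truth = plant_insertions(host, pool, cfg)
        path = tmp_path / "truth.tsv"
        write_truth(truth, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == simulate.TRUTH_HEADER
        first = lines[1].split("\t")
        assert int(first[1]) == truth.events[0].position + 1
        assert read_truth(str(path)).events == truth.events

    def test_empty_truth_writes_header_only(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(simulate.SimulationTruth(), str(path))
        assert path.read_text() == "\t".join(simulate.TRUTH_HEADER) + "\n"
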