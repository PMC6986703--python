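import numpy as np
import pytest

from plastomarker.divgap import (
    Pileup,
    diversity_gap,
    interspecific_diversity,
    intraspecific_diversity,
    pileup_from_reads,
    pileup_from_sam,
    rank_windows,
    site_heterozygosity,
)
from plastomarker.seqio import GenomeRecord, MultipleAlignment, ReadSet
from plastomarker.synthetic_data import (
    ReadSimConfig,
    default_trio_config,
    simulate_genome_trio,
    simulate_heteroplasmic_reads,
)

from oracles import mean_pairwise_read_diversity


def random_seq(n, seed):
    return "".join(np.array(list("ACGT"))[np.random.default_rng(seed).integers(0, 4, n)])


class TestSiteHeterozygosity:
    def test_single_base_zero(self):
        assert site_heterozygosity([10, 0, 0, 0]) == 0.0

    def test_nine_one(self):
        # {A:9, G:1}: 9 discordant pairs of 45
        assert site_heterozygosity([9, 0, 1, 0]) == pytest.approx(9 / 45)

    def test_five_five(self):
        assert site_heterozygosity([5, 0, 5, 0]) == pytest.approx(25 / 45)


class TestInterspecificDiversity:
    def test_identical_rows_zero(self):
        msa = MultipleAlignment(row_ids=["a", "b"], rows=["ACGT" * 25] * 2)
        pi, usable = interspecific_diversity(msa, (0, 100))
        assert pi == 0.0 and usable == 100

    def test_one_mismatch_in_100(self):
        r1 = "ACGT" * 25
        r2 = r1[:50] + ("A" if r1[50] != "A" else "C") + r1[51:]
        msa = MultipleAlignment(row_ids=["a", "b"], rows=[r1, r2])
        pi, _ = interspecific_diversity(msa, (0, 100))
        assert pi == pytest.approx(0.01)

    def test_three_rows_pairwise_average(self):
        base = random_seq(100, 1)
        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)
        # pairwise mismatch counts: (a,b)=1, (a,c)=2, (b,c)=3
        a = base
        b = mutate(base, [10])
        c = mutate(base, [20, 30])
        msa = MultipleAlignment(row_ids=list("abc"), rows=[a, b, c])
        pi, _ = interspecific_diversity(msa, (0, 100))
        assert pi == pytest.approx((1 + 2 + 3) / 3 / 100)

    def test_gap_and_n_columns_excluded(self):
        msa = MultipleAlignment(row_ids=["a", "b"], rows=["A-N" + "ACGT" * 25, "AANACGT" + "ACGT" * 24])
        _, usable = interspecific_diversity(msa, (0, 3), min_sites=1)
        assert usable == 1

    def test_too_few_sites_undefined(self):
        msa = MultipleAlignment(row_ids=["a", "b"], rows=["ACGT", "ACGT"])
        pi, _ = interspecific_diversity(msa, (0, 4), min_sites=20)
        assert pi is None


class TestIntraspecificDiversity:
    def test_single_base_columns_zero(self):
        p = Pileup(50)
        p.counts[:, 0] = 20  # all A
        pi, _ = intraspecific_diversity(p, (0, 50))
        assert pi == 0.0

    def test_equals_read_pair_oracle(self):
        """pi_intra matches direct averaging of pairwise read mismatches."""
        rng = np.random.default_rng(9)
        n_cols, n_reads = 30, 15
        columns = [
            [str(b) for b in rng.choice(list("AG"), n_reads, p=[0.8, 0.2])]
            for _ in range(n_cols)
        ]
        p = Pileup(n_cols)
        for i, bases in enumerate(columns):
            for b in bases:
                p.add_base(i, b)
        pi, _ = intraspecific_diversity(p, (0, n_cols), min_cov=2, min_sites=1)
        assert pi == pytest.approx(mean_pairwise_read_diversity(columns))

    def test_low_coverage_sites_skipped(self):
        p = Pileup(40)
        p.counts[:20, 0] = 20
        p.counts[20:, 0] = 3  # below min_cov=10
        pi, n_qual = intraspecific_diversity(p, (0, 40), min_sites=5)
        assert n_qual == 20

    def test_high_deletion_sites_skipped(self):
        p = Pileup(40)
        p.counts[:, 0] = 10
        p.counts[:10, 4] = 60  # deletion fraction > 0.5
        _, n_qual = intraspecific_diversity(p, (0, 40), min_sites=5)
        assert n_qual == 30


class TestDiversityGap:
    def test_arithmetic(self):
        assert diversity_gap(0.05, {"a": 0.01, "b": 0.002, "c": 0.0}) == pytest.approx(0.04)

    def test_equal_gives_zero(self):
        assert diversity_gap(0.01, {"a": 0.01}) == pytest.approx(0.0)

    def test_all_zero(self):
        assert diversity_gap(0.0, {"a": 0.0}) == 0.0

    def test_undefined_input_propagates(self):
        assert diversity_gap(None, {"a": 0.0}) is None
        assert diversity_gap(0.05, {"a": None}) is None

    def test_mean_aggregation(self):
        assert diversity_gap(0.05, {"a": 0.02, "b": 0.0}, aggregate="mean") == pytest.approx(0.04)


class TestPileupFromReads:
    def test_error_free_tiling_reads(self):
        ref = GenomeRecord(id="r", sequence=random_seq(1000, 2))
        reads = ReadSet(
            species_label="r",
            reads=[(f"t{i}", ref.sequence[i * 100 : i * 100 + 100], None) for i in range(10)],
        )
        p = pileup_from_reads(reads, ref)
        assert p.mapped_reads == 10
        covered = p.counts[:, :4].sum(axis=1)
        assert (covered == 1).all()
        # every covered column carries exactly the reference base
        for i in range(1000):
            base_idx = "ACGT".index(ref.sequence[i])
            assert p.counts[i, base_idx] == 1

    def test_unrelated_read_discarded(self):
        ref = GenomeRecord(id="r", sequence=random_seq(1000, 3))
        junk = random_seq(250, 12345)
        p = pileup_from_reads(ReadSet(species_label="r", reads=[("j", junk, None)]), ref)
        assert p.mapped_reads == 0 and p.discarded_reads == 1

    def test_reverse_strand_reads_counted_forward(self):
        from plastomarker.seqio import reverse_complement

        ref = GenomeRecord(id="r", sequence=random_seq(500, 4))
        rc = reverse_complement(ref.sequence[100:200])
        p = pileup_from_reads(ReadSet(species_label="r", reads=[("rc", rc, None)]), ref)
        assert p.counts[100:200, :4].sum() == 100

    def test_sam_pileup_matches_internal(self, tmp_path):
        """Pre-mapped SAM input and internal mapping give identical pileups
        on an error-free fixture."""
        ref = GenomeRecord(id="ref", sequence=random_seq(600, 5))
        starts = [0, 50, 120, 300, 349]
        reads = [(f"q{k}", ref.sequence[s : s + 150]) for k, s in enumerate(starts)]
        internal = pileup_from_reads(
            ReadSet(species_label="ref", reads=[(n, s, None) for n, s in reads]), ref
        )
        sam = tmp_path / "reads.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:ref\tLN:600\n")
            for (name, seq), s in zip(reads, starts):
                fh.write(f"{name}\t0\tref\t{s + 1}\t60\t150M\t*\t0\t0\t{seq}\t*\n")
        external = pileup_from_sam(sam, ref)
        assert (internal.counts == external.counts).all()

    def test_empty_readset_warns(self):
        ref = GenomeRecord(id="r", sequence="ACGT" * 100)
        p = pileup_from_reads(ReadSet(species_label="r", reads=[]), ref)
        assert p.mapped_reads == 0


class TestRankWindows:
    def _trio_with_reads(self, seed, error_rate=0.01, genome_length=6000, depth=30):
        cfg = default_trio_config(seed=seed, genome_length=genome_length)
        genomes, log = simulate_genome_trio(cfg)
        pileups = {}
        for i, g in enumerate(genomes):
            rs, _ = simulate_heteroplasmic_reads(
                g, ReadSimConfig(depth=depth, error_rate=error_rate, seed=seed * 100 + i)
            )
            pileups[g.id] = pileup_from_reads(rs, g)
        return log, pileups

    def test_implanted_window_ranks_first(self):
        log, pileups = self._trio_with_reads(seed=1)
        cands = rank_windows(log.alignment, pileups)
        assert cands, "no candidates found"
        s, e = log.implants[0]["interval"]
        top = cands[0]
        assert top.window[0] < e and top.window[1] > s  # overlaps the implant

    def test_no_divergence_gives_empty_list(self):
        seq = random_seq(2000, 6)
        msa = MultipleAlignment(row_ids=list("abc"), rows=[seq] * 3)
        g = GenomeRecord(id="a", sequence=seq, circular=True)
        rs, _ = simulate_heteroplasmic_reads(
            g, ReadSimConfig(depth=20, error_rate=0.0, read_length=100, seed=0)
        )
        pileups = {lab: pileup_from_reads(rs, GenomeRecord(id=lab, sequence=seq, circular=True))
                   for lab in "abc"}
        assert rank_windows(msa, pileups) == []

    def test_homopolymer_window_excluded(self):
        """A divergent window containing an 8-base run never becomes a
        candidate even though its gap score is high."""
        cfg = default_trio_config(seed=2, genome_length=6000)
        genomes, log = simulate_genome_trio(cfg)
        s, _ = log.implants[0]["interval"]
        # inject a homopolymer into every row inside the implanted window
        rows = [r[: s + 20] + "A" * 8 + r[s + 28 :] for r in log.alignment.rows]
        msa = MultipleAlignment(row_ids=log.alignment.row_ids, rows=rows)
        genomes2 = [
            GenomeRecord(id=lab, sequence=msa.ungapped(i), circular=True)
            for i, lab in enumerate(msa.row_ids)
        ]
        pileups = {}
        for i, g in enumerate(genomes2):
            rs, _ = simulate_heteroplasmic_reads(
                g, ReadSimConfig(depth=30, error_rate=0.0, seed=200 + i)
            )
            pileups[g.id] = pileup_from_reads(rs, g)
        cands = rank_windows(msa, pileups)
        run_start, run_end = s + 20, s + 28
        for c in cands:
            flank_span = (c.left_flank[0], c.right_flank[1])
            assert not (flank_span[0] <= run_start and run_end <= flank_span[1])

    def test_pi_values_bounded_and_label_invariant(self):
        log, pileups = self._trio_with_reads(seed=3, genome_length=4000, depth=20)
        from plastomarker.divgap import scan_windows

        windows = scan_windows(log.alignment, pileups)
        for w in windows:
            if w.pi_inter is not None:
                assert 0.0 <= w.pi_inter <= 1.0
            for v in w.pi_intra.values():
                if v is not None:
                    assert 0.0 <= v <= 1.0


def test_pi_inter_monotone_under_added_substitutions():
    """Adding substitutions to one row inside a window never decreases
    that window's interspecific diversity."""
    base = random_seq(200, 8)
    rows = [base, base, base]
    msa0 = MultipleAlignment(row_ids=list("abc"), rows=rows)
    pi_prev, _ = interspecific_diversity(msa0, (0, 200))
    rng = np.random.default_rng(8)
    mutated = list(base)
    for _ in range(10):
        p = int(rng.integers(0, 200))
        mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        msa = MultipleAlignment(row_ids=list("abc"), rows=["".join(mutated), base, base])
        pi, _ = interspecific_diversity(msa, (0, 200))
        assert pi >= pi_prev - 1e-12
        pi_prev = pi
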