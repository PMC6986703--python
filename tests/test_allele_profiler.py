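import numpy as np
import pytest

from plastomarker.allele_profiler import (
    dominant_share,
    extract_target_fragment,
    recruit_reads,
    tabulate_alleles,
)
from plastomarker.seqio import GenomeRecord, ReadSet, reverse_complement

from oracles import smith_waterman


def random_seq(n, seed):
    return "".join(np.array(list("ACGT"))[np.random.default_rng(seed).integers(0, 4, n)])


class TestExtractTargetFragment:
    def test_centering_arithmetic(self):
        g = GenomeRecord(id="g", sequence=random_seq(10_000, 1), circular=False)
        frag = extract_target_fragment(g, (5000, 5038), 600)
        assert frag.fragment_interval == (4719, 5319)
        assert frag.target_columns == (281, 319)
        assert len(frag.fragment_seq) == 600

    def test_zero_length_target_symmetric(self):
        g = GenomeRecord(id="g", sequence=random_seq(10_000, 2), circular=False)
        frag = extract_target_fragment(g, (700, 700), 600)
        assert frag.fragment_interval == (400, 1000)

    def test_wrap_on_circular_genome(self):
        g = GenomeRecord(id="g", sequence=random_seq(10_000, 3), circular=True)
        frag = extract_target_fragment(g, (10, 48), 600)
        assert len(frag.fragment_seq) == 600
        # fragment content wraps through the origin
        assert frag.fragment_seq == g.sequence[-271:] + g.sequence[:329]

    def test_clip_at_linear_end(self):
        g = GenomeRecord(id="g", sequence=random_seq(1000, 4), circular=False)
        frag = extract_target_fragment(g, (10, 48), 600)
        assert frag.fragment_interval[0] == 0  # clipped, not negative

    def test_target_longer_than_fragment_rejected(self):
        g = GenomeRecord(id="g", sequence=random_seq(1000, 5), circular=False)
        with pytest.raises(ValueError):
            extract_target_fragment(g, (0, 700), 600)


class TestRecruitReads:
    def _fragment(self, seed=6, n=600):
        g = GenomeRecord(id="g", sequence=random_seq(5000, seed), circular=False)
        return extract_target_fragment(g, (2481, 2519), n)

    def test_exact_substring_recruited(self):
        frag = self._fragment()
        read = frag.fragment_seq[100:350]
        out = recruit_reads(frag, ReadSet(species_label="s", reads=[("r", read, None)]))
        assert len(out) == 1

    def test_reverse_strand_recruited_and_normalized(self):
        frag = self._fragment()
        read = reverse_complement(frag.fragment_seq[100:350])
        out = recruit_reads(frag, ReadSet(species_label="s", reads=[("r", read, None)]))
        assert len(out) == 1
        assert out.reads[0][1] == frag.fragment_seq[100:350]

    def test_random_read_rejected(self):
        frag = self._fragment()
        junk = random_seq(250, 99999)
        out = recruit_reads(frag, ReadSet(species_label="s", reads=[("r", junk, None)]))
        assert len(out) == 0

    def test_threshold_behavior_matches_sw_oracle(self):
        """Accept/reject decisions agree with a brute-force local-alignment
        oracle on a mixed 20-read fixture."""
        rng = np.random.default_rng(7)
        frag = self._fragment(seed=7, n=200)
        reads = []
        for i in range(10):  # clear hits: 60-mers with ~5% substitutions
            s = int(rng.integers(0, 140))
            chars = list(frag.fragment_seq[s : s + 60])
            for p in rng.choice(60, 3, replace=False):
                chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
            reads.append((f"hit{i}", "".join(chars), None))
        for i in range(10):  # clear rejects: unrelated random reads
            reads.append((f"junk{i}", random_seq(60, 1000 + i), None))
        out = recruit_reads(
            frag,
            ReadSet(species_label="s", reads=reads),
            min_score_identity=0.8,
            min_hit_len=30,
        )
        got = {rid for rid, _, _ in out.reads}
        expected = set()
        for rid, seq, _ in reads:
            best = (0, 0.0)
            for candidate in (seq, reverse_complement(seq)):
                best = max(best, smith_waterman(candidate, frag.fragment_seq))
            if best[0] >= 30 and best[1] >= 0.8:
                expected.add(rid)
        assert got == expected
        assert expected == {f"hit{i}" for i in range(10)}


class TestTabulateAlleles:
    def _setup(self):
        g = GenomeRecord(id="g", sequence=random_seq(3000, 8), circular=False)
        frag = extract_target_fragment(g, (1490, 1520), 400)
        t0, t1 = frag.target_interval
        alleles = {
            "X": g.sequence[1400:1600],
            "Y": g.sequence[1400:1490] + _mutate(g.sequence[1490:1520], [5]) + g.sequence[1520:1600],
            "Z": g.sequence[1400:1490] + _mutate(g.sequence[1490:1520], [5, 12]) + g.sequence[1520:1600],
        }
        return frag, alleles

    def test_counts_and_shares(self):
        frag, alleles = self._setup()
        reads = []
        for allele, mult in (("X", 5), ("Y", 3), ("Z", 2)):
            for i in range(mult):
                reads.append((f"{allele}{i}", alleles[allele], None))
        rs = ReadSet(species_label="s", reads=reads)
        table = tabulate_alleles(recruit_reads(frag, rs), frag)
        assert table.total_mapped == 10
        assert [r.count for r in table.records] == [5, 3, 2]
        assert [r.share for r in table.records] == pytest.approx([0.5, 0.3, 0.2])

    def test_min_count_preserves_total(self):
        frag, alleles = self._setup()
        reads = [("x0", alleles["X"], None), ("x1", alleles["X"], None), ("y0", alleles["Y"], None)]
        rs = ReadSet(species_label="s", reads=reads)
        table = tabulate_alleles(recruit_reads(frag, rs), frag, min_count=2)
        assert table.total_mapped == 3
        assert len(table.records) == 1 and table.records[0].count == 2
        assert table.records[0].share == pytest.approx(2 / 3)

    def test_order_invariance(self):
        frag, alleles = self._setup()
        reads = [(f"r{i}", alleles[a], None) for i, a in enumerate("XXYXZYZXY")]
        t1 = tabulate_alleles(recruit_reads(frag, ReadSet(species_label="s", reads=reads)), frag)
        t2 = tabulate_alleles(
            recruit_reads(frag, ReadSet(species_label="s", reads=list(reversed(reads)))), frag
        )
        assert [(r.allele, r.count) for r in t1.records] == [
            (r.allele, r.count) for r in t2.records
        ]

    def test_non_spanning_reads_not_counted(self):
        frag, alleles = self._setup()
        t0, _ = frag.target_columns
        partial = frag.fragment_seq[: t0 + 10]  # ends inside the target
        rs = ReadSet(species_label="s", reads=[("p", partial, None), ("x", alleles["X"], None)])
        table = tabulate_alleles(recruit_reads(frag, rs), frag)
        assert table.total_mapped == 1


def _mutate(s, positions):
    out = list(s)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestDominantShare:
    def test_published_table_shares(self, cz11_tables):
        """Dominant-allele shares reproduce the published per-species values:
        80% (356/445), 94.84% (588/620), 55.12%/40.55% (420 and 309 of 762)."""
        lan = cz11_tables["A_lancea"]
        mac = cz11_tables["A_macrocephala"]
        chi = cz11_tables["A_chinensis"]
        assert lan.total_mapped == 445 and lan.records[0].count == 356
        assert dominant_share(lan)[0] == pytest.approx(0.800, abs=1e-4)
        assert mac.total_mapped == 620 and mac.records[0].count == 588
        assert dominant_share(mac)[0] == pytest.approx(0.9484, abs=1e-4)
        assert chi.total_mapped == 762
        assert [r.count for r in chi.records[:2]] == [420, 309]
        s1, s2 = dominant_share(chi, 2)
        assert s1 == pytest.approx(0.5512, abs=1e-4)
        assert s2 == pytest.approx(0.4055, abs=1e-4)

    def test_single_record_share_one(self):
        from plastomarker.allele_profiler import AlleleRecord, AlleleTable

        t = AlleleTable(species_label="s", total_mapped=7,
                        records=[AlleleRecord(allele="ACGT", count=7, share=1.0)])
        assert dominant_share(t) == [1.0]

    def test_empty_table_rejected(self):
        from plastomarker.allele_profiler import AlleleTable

        with pytest.raises(ValueError):
            dominant_share(AlleleTable(species_label="s", total_mapped=0))
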