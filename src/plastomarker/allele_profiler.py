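"""Target-centered allele profiling from sequencing reads.

Given a genome and a short target region (e.g. a diagnostic marker locus),
extract a fragment with the target centered, recruit the reads that align to
the fragment, and tabulate the distinct allele strings observed over the
target window: per-species tables of gapped allele sequences with read
counts and frequency shares, whose top rows are the species' dominant
allele(s).  Within one read pool the spread of allele types measures
heteroplasmy plus residual sequencing error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from ._align import best_local_hit, infix_affine_alignment, place_read
from .seqio import GenomeRecord, ReadSet, slice_region

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetFragment:
    genome_id: str
    fragment_interval: tuple[int, int]  # may exceed genome length if wrapped
    target_interval: tuple[int, int]  # genome coordinates of the target
    fragment_seq: str

    @property
    def target_columns(self) -> tuple[int, int]:
        """Target interval in fragment-local coordinates."""
        off = self.target_interval[0] - self.fragment_interval[0]
        if off < 0:  # wrapped through the origin
            off += self.fragment_interval[1] - self.fragment_interval[0]
        return (off, off + (self.target_interval[1] - self.target_interval[0]))


@dataclass(frozen=True)
class AlleleRecord:
    allele: str  # gapped string over the target window columns
    count: int
    share: float  # of total mapped (spanning) reads


@dataclass
class AlleleTable:
    species_label: str
    total_mapped: int
    records: list[AlleleRecord] = field(default_factory=list)


def extract_target_fragment(
    genome: GenomeRecord, target: tuple[int, int], fragment_len: int = 600
) -> TargetFragment:
    """Fragment of ``fragment_len`` bp with the target region in the middle.

    Left pad = floor((fragment_len - |target|) / 2).  Wraps on circular
    genomes; clips (with a warning) at the ends of linear ones.
    """
    t_start, t_end = target
    t_len = t_end - t_start
    if t_len >= fragment_len:
        raise ValueError(f"target ({t_len} bp) not shorter than fragment ({fragment_len} bp)")
    if t_start < 0 or t_end > len(genome):
        raise ValueError("target outside genome")
    left_pad = (fragment_len - t_len) // 2
    f_start = t_start - left_pad
    f_end = f_start + fragment_len
    n = len(genome)
    if genome.circular:
        seq = slice_region(genome, (f_start, f_end), allow_wrap=True)
        if f_start < 0:
            f_start += n
            f_end += n
    else:
        clipped_start = max(0, f_start)
        clipped_end = min(n, f_end)
        if clipped_start != f_start or clipped_end != f_end:
            logger.warning(
                "fragment [%d,%d) clipped to [%d,%d) at linear genome ends",
                f_start, f_end, clipped_start, clipped_end,
            )
        f_start, f_end = clipped_start, clipped_end
        seq = genome.sequence[f_start:f_end]
    return TargetFragment(
        genome_id=genome.id,
        fragment_interval=(f_start, f_end),
        target_interval=(t_start, t_end),
        fragment_seq=seq,
    )


def recruit_reads(
    fragment: TargetFragment,
    reads: ReadSet,
    min_score_identity: float = 0.8,
    min_hit_len: int = 50,
) -> ReadSet:
    """Reads whose best local alignment to the fragment (either strand) has
    aligned length >= min_hit_len and identity >= min_score_identity,
    orientation-normalized to the fragment strand.

    Reads sharing no 11-mer seed with the fragment (either strand) are
    rejected outright; a fast edit-distance screen accepts obviously matching
    reads; the remainder get a full Smith-Waterman-style local alignment.
    """
    from .seqio import reverse_complement

    target = fragment.fragment_seq
    k = 11
    seeds = {target[i : i + k] for i in range(len(target) - k + 1)}
    seeds |= {reverse_complement(s) for s in seeds}
    recruited: list[tuple[str, str, Optional[str]]] = []
    for rid, seq, qual in reads.reads:
        if not any(seq[i : i + k] in seeds for i in range(len(seq) - k + 1)):
            continue
        plc = place_read(seq, target)
        if (
            plc is not None
            and plc.aligned_length >= min_hit_len
            and plc.identity >= min_score_identity
        ):
            recruited.append((rid, plc.query, qual))
            continue
        length, identity, strand = best_local_hit(seq, target)
        if length >= min_hit_len and identity >= min_score_identity:
            oriented = seq if strand == "+" else reverse_complement(seq)
            recruited.append((rid, oriented, qual))
    if not recruited:
        logger.warning(
            "no reads recruited to fragment %s:%s", fragment.genome_id, fragment.fragment_interval
        )
    return ReadSet(species_label=reads.species_label, reads=recruited)


def _allele_string(
    frag_row: str, read_row: str, target_cols: tuple[int, int]
) -> Optional[str]:
    """The read's aligned characters over the target columns; None unless the
    read fully spans them.  Deletions appear as '-'; bases the read carries
    beyond the fragment (insertions) are appended at the preceding column."""
    t_start, t_end = target_cols
    # aligned span of the read in fragment coordinates
    idx = [i for i, c in enumerate(read_row) if c != "-"]
    if not idx:
        return None
    first, last = idx[0], idx[-1]
    span_start = sum(1 for c in frag_row[:first] if c != "-")
    span_end = sum(1 for c in frag_row[: last + 1] if c != "-")
    if span_start > t_start or span_end < t_end:
        return None
    out: dict[int, str] = {}
    fpos = 0
    for fc, rc in zip(frag_row, read_row):
        if fc != "-":
            if t_start <= fpos < t_end:
                out[fpos] = out.get(fpos, "") + rc
            fpos += 1
        elif rc != "-" and t_start < fpos <= t_end:
            # read insertion between fragment positions fpos-1 and fpos
            out[fpos - 1] = out.get(fpos - 1, "") + rc
    return "".join(out.get(p, "-") for p in range(t_start, t_end))


def tabulate_alleles(
    recruited: ReadSet,
    fragment: TargetFragment,
    min_count: int = 1,
) -> AlleleTable:
    """Align recruited reads to the fragment and tabulate target alleles.

    Only reads fully spanning the target window contribute; ``total_mapped``
    is fixed before the ``min_count`` filter drops rare records, so shares of
    surviving records always refer to all spanning reads.  Records are sorted
    by count descending, ties lexicographically by allele string.
    """
    target_cols = fragment.target_columns
    counts: dict[str, int] = {}
    cache: dict[str, Optional[str]] = {}
    skipped = 0
    for _, seq, _ in recruited.reads:
        if seq in cache:
            allele = cache[seq]
        else:
            frag_row, read_row = infix_affine_alignment(seq, fragment.fragment_seq)
            allele = _allele_string(frag_row, read_row, target_cols)
            cache[seq] = allele
        if allele is None:
            skipped += 1
            continue
        counts[allele] = counts.get(allele, 0) + 1
    if skipped:
        logger.info("%d reads did not span the target window", skipped)
    total = sum(counts.values())
    records = [
        AlleleRecord(allele=a, count=c, share=c / total if total else 0.0)
        for a, c in counts.items()
        if c >= min_count
    ]
    records.sort(key=lambda r: (-r.count, r.allele))
    return AlleleTable(
        species_label=recruited.species_label, total_mapped=total, records=records
    )


def dominant_share(table: AlleleTable, k: int = 1) -> list[float]:
    """Shares of the top-k allele records (count / total_mapped)."""
    if table.total_mapped == 0 or not table.records:
        raise ValueError("empty allele table")
    return [r.count / table.total_mapped for r in table.records[:k]]
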