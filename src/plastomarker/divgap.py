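"""Diversity-gap scoring of genomic windows.

The marker-discovery statistic ranks candidate barcode regions by the
"diversity gap"

    G = pi_inter - max_s pi_intra[s]

where pi_inter is the interspecific nucleotide diversity of a window computed
from an aligned set of genomes (average pairwise mismatch fraction per site,
Nei-Li style) and pi_intra[s] is the intraspecific diversity of species *s*
estimated from its own sequencing reads: per pileup column the probability
that two reads drawn without replacement disagree, averaged over qualifying
sites.  A good marker region shows a large gap — divergent between species,
homogeneous within each — and clean (homopolymer-free, conserved) flanks so
it can be amplified and Sanger-sequenced reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pysam

from ._align import place_read
from .seqio import GenomeRecord, MultipleAlignment, ReadSet

logger = logging.getLogger(__name__)

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_DEL_IDX = 4


@dataclass(frozen=True)
class PileupColumn:
    """Per-site base counts from reads mapped to one reference position."""

    ref_position: int
    base_counts: dict[str, int]
    deletion_count: int

    @property
    def coverage(self) -> int:
        return sum(self.base_counts.values()) + self.deletion_count


class Pileup:
    """Dense per-position counts (A, C, G, T, deletion) over a reference.

    Backed by an ``(L, 5)`` integer array; insertions relative to the
    reference are tallied separately (they do not enter pi) in
    ``insertion_counts``.
    """

    def __init__(self, reference_length: int):
        self.counts = np.zeros((reference_length, 5), dtype=np.int64)
        self.insertion_counts: dict[int, int] = {}
        self.discarded_reads = 0
        self.mapped_reads = 0

    def __len__(self) -> int:
        return self.counts.shape[0]

    def column(self, pos: int) -> PileupColumn:
        row = self.counts[pos]
        return PileupColumn(
            ref_position=pos,
            base_counts={b: int(row[i]) for b, i in _BASE_IDX.items()},
            deletion_count=int(row[_DEL_IDX]),
        )

    def add_base(self, pos: int, base: str) -> None:
        idx = _BASE_IDX.get(base)
        if idx is not None:
            self.counts[pos, idx] += 1

    def add_deletion(self, pos: int) -> None:
        self.counts[pos, _DEL_IDX] += 1

    def add_insertion(self, pos: int) -> None:
        self.insertion_counts[pos] = self.insertion_counts.get(pos, 0) + 1


def pileup_from_reads(
    reads: ReadSet,
    reference: GenomeRecord,
    min_identity: float = 0.9,
) -> Pileup:
    """Map each read (best gapped placement, either strand) and accumulate
    base/deletion counts.  Reads below ``min_identity`` over their aligned
    span are discarded.  For circular references the reference is extended
    by one read length so origin-spanning reads place correctly.
    """
    ref_seq = reference.sequence
    n = len(ref_seq)
    pileup = Pileup(n)
    if not reads.reads:
        logger.warning("empty read set %s: empty pileup", reads.species_label)
        return pileup
    max_read = max(len(seq) for _, seq, _ in reads.reads)
    target = ref_seq + (ref_seq[: max_read] if reference.circular else "")
    for _, seq, _ in reads.reads:
        plc = place_read(seq, target)
        if plc is None or plc.identity < min_identity:
            pileup.discarded_reads += 1
            continue
        pileup.mapped_reads += 1
        _accumulate(pileup, plc.query, plc.ref_start, plc.cigar, n)
    return pileup


def _accumulate(pileup: Pileup, query: str, ref_start: int, cigar, n: int) -> None:
    qpos = 0
    rpos = ref_start
    for length, op in cigar:
        if op in "=XM":
            for k in range(length):
                pileup.add_base((rpos + k) % n, query[qpos + k])
            qpos += length
            rpos += length
        elif op == "I":
            pileup.add_insertion(rpos % n)
            qpos += length
        elif op == "D":
            for k in range(length):
                pileup.add_deletion((rpos + k) % n)
            rpos += length


def pileup_from_sam(path: str, reference: GenomeRecord) -> Pileup:
    """Build a pileup from a pre-mapped SAM text file.

    Only QNAME/FLAG/RNAME/POS/CIGAR/SEQ are consumed; CIGAR ops M/=/X/I/D/S
    are honored.  Soft-clipped bases are skipped, unmapped records ignored.
    """
    n = len(reference)
    pileup = Pileup(n)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigartuples is None or rec.query_sequence is None:
                continue
            pileup.mapped_reads += 1
            qpos = 0
            rpos = rec.reference_start
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    for k in range(length):
                        pileup.add_base((rpos + k) % n, rec.query_sequence[qpos + k])
                    qpos += length
                    rpos += length
                elif op == 1:  # I
                    pileup.add_insertion(rpos % n)
                    qpos += length
                elif op == 2:  # D
                    for k in range(length):
                        pileup.add_deletion((rpos + k) % n)
                    rpos += length
                elif op == 4:  # S
                    qpos += length
    return pileup


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

#: Below this many usable/qualifying sites a window's pi is undefined.
DEFAULT_MIN_SITES = 20


def interspecific_diversity(
    msa: MultipleAlignment,
    window: tuple[int, int],
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[Optional[float], int]:
    """Average pairwise mismatch fraction over gap-free, N-free columns.

    Returns ``(pi_inter, usable_sites)``; pi is None when fewer than
    ``min_sites`` columns are usable.
    """
    start, end = window
    if start < 0 or end > msa.column_count:
        raise ValueError(f"window [{start},{end}) outside alignment")
    rows = msa.rows
    pairs = list(combinations(range(len(rows)), 2))
    usable = 0
    mismatch_sum = 0
    for col in range(start, end):
        column = [r[col] for r in rows]
        if "-" in column or "N" in column:
            continue
        usable += 1
        for a, b in pairs:
            if column[a] != column[b]:
                mismatch_sum += 1
    if usable < min_sites:
        return None, usable
    return mismatch_sum / (len(pairs) * usable), usable


def site_heterozygosity(base_counts: Sequence[int]) -> float:
    """Probability two reads drawn without replacement carry different bases.

    h = sum_{b<b'} c_b c_b' / (n(n-1)/2) with n = total base-carrying reads.
    """
    n = int(sum(base_counts))
    if n < 2:
        return 0.0
    same = sum(c * (c - 1) for c in base_counts) / 2
    total = n * (n - 1) / 2
    return float((total - same) / total)


def intraspecific_diversity(
    pileup: Pileup,
    window: tuple[int, int],
    min_cov: int = 10,
    min_sites: int = DEFAULT_MIN_SITES,
    max_del_fraction: float = 0.5,
) -> tuple[Optional[float], int]:
    """Mean site heterozygosity over qualifying sites in the window.

    A site qualifies when coverage >= min_cov and its deletion fraction is
    <= max_del_fraction.  Returns (pi_intra, qualifying_sites); None when
    fewer than min_sites qualify.
    """
    start, end = window
    counts = pileup.counts[start:end]
    cov = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        del_frac = np.where(cov > 0, counts[:, _DEL_IDX] / np.maximum(cov, 1), 0.0)
    qual = (cov >= min_cov) & (del_frac <= max_del_fraction)
    n_qual = int(qual.sum())
    if n_qual < min_sites:
        return None, n_qual
    hs = [site_heterozygosity(counts[i, :4]) for i in np.nonzero(qual)[0]]
    return float(np.mean(hs)), n_qual


def diversity_gap(
    pi_inter: Optional[float],
    pi_intra_by_species: dict[str, Optional[float]],
    aggregate: str = "max",
) -> Optional[float]:
    """G = pi_inter - max_s pi_intra[s] (or mean, if configured).

    Returns None (window excluded) when any input is undefined.
    """
    if pi_inter is None or any(v is None for v in pi_intra_by_species.values()):
        return None
    values = list(pi_intra_by_species.values())
    agg = max(values) if aggregate == "max" else float(np.mean(values))
    return pi_inter - agg


# ---------------------------------------------------------------------------
# window scan and ranking
# ---------------------------------------------------------------------------

@dataclass
class WindowDiversity:
    window: tuple[int, int]  # alignment-column interval
    pi_inter: Optional[float]
    pi_intra: dict[str, Optional[float]]
    gap_score: Optional[float]
    usable_sites: int
    homopolymer_flag: bool
    flank_ok: bool
    ref_windows: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class MarkerCandidate:
    rank: int
    window: tuple[int, int]
    gap_score: float
    diversity: WindowDiversity
    left_flank: tuple[int, int]
    right_flank: tuple[int, int]


def _has_homopolymer(rows: Sequence[str], start: int, end: int, max_run: int) -> bool:
    for row in rows:
        segment = row[max(0, start) : end].replace("-", "")
        run = 0
        prev = ""
        for ch in segment:
            run = run + 1 if ch == prev else 1
            prev = ch
            if run >= max_run:
                return True
    return False


def _flank_clean(
    msa: MultipleAlignment, start: int, end: int, flank_max_pi: float
) -> bool:
    if start < 0 or end > msa.column_count:
        return False
    for col in range(start, end):
        column = [r[col] for r in msa.rows]
        if "-" in column:
            return False
    pi, usable = interspecific_diversity(msa, (start, end), min_sites=1)
    return pi is not None and pi <= flank_max_pi


def scan_windows(
    msa: MultipleAlignment,
    pileups: dict[str, Pileup],
    window_len: int = 200,
    step: int = 50,
    homopolymer_max: int = 8,
    flank_len: int = 20,
    flank_max_pi: float = 0.0,
    min_cov: int = 10,
    min_sites: int = DEFAULT_MIN_SITES,
    aggregate: str = "max",
) -> list[WindowDiversity]:
    """Slide windows over alignment columns and score each one.

    ``pileups`` maps species label (a row id of the alignment) to the pileup
    of that species' reads on its own genome; alignment columns are projected
    into each species' coordinates through the row's ungapped offsets.
    """
    col_maps = {
        rid: msa.column_to_seq_pos(i) for i, rid in enumerate(msa.row_ids)
    }
    missing = set(pileups) - set(msa.row_ids)
    if missing:
        raise ValueError(f"pileup species not in alignment: {sorted(missing)}")
    results: list[WindowDiversity] = []
    ncols = msa.column_count
    for start in range(0, max(ncols - window_len, 0) + 1, step):
        end = start + window_len
        pi_inter, usable = interspecific_diversity(msa, (start, end), min_sites)
        pi_intra: dict[str, Optional[float]] = {}
        ref_windows: dict[str, tuple[int, int]] = {}
        for label, pileup in pileups.items():
            cmap = col_maps[label]
            rs = cmap[start]
            re_ = cmap[end] if end < ncols else len(pileup)
            ref_windows[label] = (rs, re_)
            pi_s, _ = intraspecific_diversity(
                pileup, (rs, re_), min_cov=min_cov, min_sites=min_sites
            )
            pi_intra[label] = pi_s
        g = diversity_gap(pi_inter, pi_intra, aggregate) if pileups else pi_inter
        homopoly = _has_homopolymer(
            msa.rows, start - flank_len, end + flank_len, homopolymer_max
        )
        flank_ok = _flank_clean(
            msa, start - flank_len, start, flank_max_pi
        ) and _flank_clean(msa, end, end + flank_len, flank_max_pi)
        results.append(
            WindowDiversity(
                window=(start, end),
                pi_inter=pi_inter,
                pi_intra=pi_intra,
                gap_score=g,
                usable_sites=usable,
                homopolymer_flag=homopoly,
                flank_ok=flank_ok,
                ref_windows=ref_windows,
            )
        )
    return results


def rank_windows(
    msa: MultipleAlignment,
    pileups: dict[str, Pileup],
    window_len: int = 200,
    step: int = 50,
    homopolymer_max: int = 8,
    flank_len: int = 20,
    flank_max_pi: float = 0.0,
    min_cov: int = 10,
    min_sites: int = DEFAULT_MIN_SITES,
    aggregate: str = "max",
) -> list[MarkerCandidate]:
    """Rank candidate marker windows by diversity gap, descending.

    Windows flagged for homopolymers, with unusable flanks, with undefined
    statistics, or with G <= 0 are excluded; overlapping survivors are merged
    keeping the higher-G window (ties break to the smaller start).
    """
    scored = scan_windows(
        msa,
        pileups,
        window_len=window_len,
        step=step,
        homopolymer_max=homopolymer_max,
        flank_len=flank_len,
        flank_max_pi=flank_max_pi,
        min_cov=min_cov,
        min_sites=min_sites,
        aggregate=aggregate,
    )
    eligible = [
        w
        for w in scored
        if w.gap_score is not None
        and w.gap_score > 0
        and not w.homopolymer_flag
        and w.flank_ok
    ]
    eligible.sort(key=lambda w: (-w.gap_score, w.window[0]))
    kept: list[WindowDiversity] = []
    for w in eligible:
        if all(
            w.window[1] <= k.window[0] or w.window[0] >= k.window[1] for k in kept
        ):
            kept.append(w)
    if not kept:
        logger.warning("no window passed the candidate filters")
    return [
        MarkerCandidate(
            rank=r + 1,
            window=w.window,
            gap_score=w.gap_score,
            diversity=w,
            left_flank=(w.window[0] - flank_len, w.window[0]),
            right_flank=(w.window[1], w.window[1] + flank_len),
        )
        for r, w in enumerate(kept)
    ]
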