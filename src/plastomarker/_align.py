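"""Shared gapped-alignment helpers.

edlib provides fast edit-distance alignment (global "NW" and infix "HW"
modes); Biopython's PairwiseAligner provides affine-gap local alignment where
Smith–Waterman semantics are needed.  On top of these we add CIGAR parsing,
a gap right-normalization pass (so length variants in repetitive context are
reported at a canonical position, matching how allele tables print trailing
'-' padding) and a small star-MSA used for rule derivation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
from Bio import Align

from .seqio import reverse_complement

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class Placement:
    """A read placed on a reference: location, strand, edit distance."""

    ref_start: int
    ref_end: int
    cigar: list[tuple[int, str]]
    distance: int
    strand: str  # '+' or '-'
    query: str  # orientation-normalized query (reference strand)

    @property
    def aligned_length(self) -> int:
        return sum(n for n, _ in self.cigar)

    @property
    def identity(self) -> float:
        return 1.0 - self.distance / self.aligned_length if self.aligned_length else 0.0


def place_read(read: str, reference: str) -> Placement | None:
    """Best infix (semi-global) placement of a read on either strand."""
    best: Placement | None = None
    for strand, seq in (("+", read), ("-", reverse_complement(read))):
        res = edlib.align(seq, reference, mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        start, end = res["locations"][0]
        plc = Placement(
            ref_start=start,
            ref_end=end + 1,
            cigar=parse_cigar(res["cigar"]),
            distance=res["editDistance"],
            strand=strand,
            query=seq,
        )
        if best is None or plc.distance < best.distance:
            best = plc
    return best


def global_alignment(a: str, b: str) -> tuple[str, str]:
    """Gapped global alignment of two sequences (edit-distance optimal),
    with gap runs shifted as far right as score allows."""
    res = edlib.align(a, b, mode="NW", task="path")
    row_a, row_b = _expand(a, b, parse_cigar(res["cigar"]))
    return normalize_gaps_right(row_a, row_b)


def glocal_alignment(pattern: str, text: str) -> tuple[str, str]:
    """Align ``pattern`` in full against its best-matching infix of ``text``
    (free end gaps on the text only).  Returns right-normalized gapped rows
    (pattern row, text row)."""
    res = edlib.align(pattern, text, mode="HW", task="path")
    start, end = res["locations"][0]
    row_p, row_t = _expand(pattern, text[start : end + 1], parse_cigar(res["cigar"]))
    return normalize_gaps_right(row_p, row_t)


def _expand(a: str, b: str, cigar: list[tuple[int, str]]) -> tuple[str, str]:
    """Expand a query-vs-target CIGAR into two gapped rows (query=a)."""
    ra: list[str] = []
    rb: list[str] = []
    i = j = 0
    for n, op in cigar:
        if op in "=XM":
            ra.append(a[i : i + n])
            rb.append(b[j : j + n])
            i += n
            j += n
        elif op == "I":  # present in a, absent in b
            ra.append(a[i : i + n])
            rb.append("-" * n)
            i += n
        elif op == "D":
            ra.append("-" * n)
            rb.append(b[j : j + n])
            j += n
    return "".join(ra), "".join(rb)


def normalize_gaps_right(row_a: str, row_b: str) -> tuple[str, str]:
    """Slide each gap run right while the alignment score is unchanged.

    Moving a gap run one column right swaps the character just after the run
    into its first column; the score is unchanged iff that character matches
    the other row equally well at both ends of the run.
    """
    a = list(row_a)
    b = list(row_b)

    def shift(g: list[str], o: list[str]) -> bool:
        moved = False
        n = len(g)
        i = 0
        while i < n:
            if g[i] != "-":
                i += 1
                continue
            j = i
            while j < n and g[j] == "-":
                j += 1
            if i == 0:  # end-gap run (unaligned overhang): leave in place
                i = j
                continue
            # interior gap run [i, j); try to slide right
            while j < n and g[j] != "-" and o[j] != "-":
                ch = g[j]
                if (ch == o[i]) != (ch == o[j]):
                    break
                g[i] = ch
                g[j] = "-"
                i += 1
                j += 1
                moved = True
            i = j
        return moved

    while shift(a, b) or shift(b, a):
        pass
    return "".join(a), "".join(b)


def star_msa(sequences: dict[str, str]) -> tuple[list[str], list[str]]:
    """Multiple alignment of short, near-identical sequences by star
    alignment around the longest sequence, merging insertion columns.

    Returns (ids, gapped rows).  Adequate for amplicon-scale inputs where
    indels are short and unambiguous after right-normalization; not a general
    MSA tool.
    """
    ids = sorted(sequences)  # deterministic, input-order independent
    center_id = max(ids, key=lambda k: (len(sequences[k]), k))
    center = sequences[center_id]
    pairwise = {}
    for k in ids:
        if k == center_id:
            continue
        row_q, row_c = affine_global_alignment(sequences[k], center)
        pairwise[k] = (row_q, row_c)

    # merge: build the union gap structure over the center sequence
    # insertions[i] = max inserted length before center position i (i in 0..len)
    insertions = [0] * (len(center) + 1)
    for row_q, row_c in pairwise.values():
        cpos = 0
        run = 0
        for qc, cc in zip(row_q, row_c):
            if cc == "-":
                run += 1
            else:
                if run:
                    insertions[cpos] = max(insertions[cpos], run)
                    run = 0
                cpos += 1
        if run:
            insertions[cpos] = max(insertions[cpos], run)

    def project(row_q: str, row_c: str) -> str:
        out: list[str] = []
        cpos = 0
        pending: list[str] = []
        for qc, cc in zip(row_q, row_c):
            if cc == "-":
                pending.append(qc)
            else:
                out.append(pending_pad(pending, insertions[cpos]))
                pending = []
                out.append(qc)
                cpos += 1
        out.append(pending_pad(pending, insertions[len(center)]))
        return "".join(out)

    def pending_pad(pending: list[str], width: int) -> str:
        s = "".join(pending)
        return s + "-" * (width - len(s))

    rows = {}
    rows[center_id] = project(center, center)
    for k, (row_q, row_c) in pairwise.items():
        rows[k] = project(row_q, row_c)
    return ids, [rows[k] for k in ids]


_infix_aligner: Align.PairwiseAligner | None = None


def infix_affine_alignment(read: str, fragment: str) -> tuple[str, str]:
    """Affine-gap alignment of a read to a fragment with free end gaps on the
    read row (the fragment may overhang on both sides).  Affine costs keep
    multi-base indels contiguous; gap runs are then right-normalized.

    Returns (fragment row, read row), both spanning the whole fragment.
    """
    global _infix_aligner
    if _infix_aligner is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 2
        al.mismatch_score = -3
        al.open_gap_score = -6
        al.extend_gap_score = -1
        al.end_deletion_score = 0  # free end gaps in the read row
        _infix_aligner = al
    aln = _infix_aligner.align(fragment, read)[0]
    frag_row, read_row = str(aln[0]), str(aln[1])
    return normalize_gaps_right(frag_row, read_row)


_global_affine: Align.PairwiseAligner | None = None


def affine_global_alignment(a: str, b: str) -> tuple[str, str]:
    """Global alignment with affine gaps (open -6, extend -1), so multi-base
    indels stay contiguous; gap runs right-normalized."""
    global _global_affine
    if _global_affine is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 2
        al.mismatch_score = -3
        al.open_gap_score = -6
        al.extend_gap_score = -1
        _global_affine = al
    aln = _global_affine.align(a, b)[0]
    return normalize_gaps_right(str(aln[0]), str(aln[1]))


_overlap_affine: Align.PairwiseAligner | None = None


def overlap_affine_alignment(a: str, b: str) -> tuple[str, str]:
    """Affine alignment with free end gaps on both sequences (overlap mode):
    terminal absence in either sequence costs nothing, interior indels are
    affine.  Returns right-normalized rows (a row, b row)."""
    global _overlap_affine
    if _overlap_affine is None:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.match_score = 2
        al.mismatch_score = -3
        al.open_gap_score = -6
        al.extend_gap_score = -1
        al.end_deletion_score = 0
        al.end_insertion_score = 0
        _overlap_affine = al
    aln = _overlap_affine.align(a, b)[0]
    return normalize_gaps_right(str(aln[0]), str(aln[1]))


_local_aligner: Align.PairwiseAligner | None = None


def local_aligner() -> Align.PairwiseAligner:
    """Smith–Waterman-style local aligner (match 2, mismatch -3, gap -5/-2)."""
    global _local_aligner
    if _local_aligner is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = 2
        al.mismatch_score = -3
        al.open_gap_score = -5
        al.extend_gap_score = -2
        _local_aligner = al
    return _local_aligner


def best_local_hit(query: str, target: str) -> tuple[int, float, str]:
    """Best local alignment of query vs target on either strand.

    Returns (aligned_length, identity, strand); (0, 0.0, '+') when no positive-
    scoring alignment exists.
    """
    best = (0, 0.0, "+")
    al = local_aligner()
    for strand, seq in (("+", query), ("-", reverse_complement(query))):
        try:
            alignment = al.align(seq, target)[0]
        except (IndexError, ValueError):
            continue
        qa, ta = alignment[0], alignment[1]
        length = len(qa)
        if length == 0:
            continue
        matches = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
        identity = matches / length
        if (length, identity) > (best[0], best[1]):
            best = (length, identity, strand)
    return best
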