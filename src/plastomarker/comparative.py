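"""Comparative plastome statistics.

Covers the descriptive layer of the analysis: GC content (overall and per
quadripartite partition), microsatellite (SSR) scanning with MISA-style
unit-count thresholds, exact long-repeat detection (forward and palindromic),
SNP/indel cataloguing from a multi-genome alignment, and codon usage with
RSCU (relative synonymous codon usage).

Conventions
-----------
* SSRs are perfect tandem runs only; a single mismatch terminates a run.
  Motifs are reported as their lexicographically least rotation and a run is
  reported at its smallest period only (no "AA" dimers inside a poly-A run).
* Repeats are exact: two copies match verbatim (forward) or as exact reverse
  complements (palindromic).  Approximate (similarity < 100%) repeats are out
  of scope.
* A SNP site is a gap-free, N-free alignment column with >= 2 distinct bases.
  An indel event is a maximal run of gap columns sharing one gap/non-gap row
  pattern; a 5-column gap therefore counts as ONE indel of length 5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .seqio import FeatureAnnotation, MultipleAlignment, reverse_complement

#: MISA-style minimum unit counts per motif length.
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 8, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N's excluded from both counts."""
    counts = Counter(seq.upper())
    acgt = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if acgt == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (counts["G"] + counts["C"]) / acgt


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SsrHit:
    motif: str  # canonical (lexicographically least rotation)
    unit_count: int
    interval: tuple[int, int]
    context: str = "unknown"  # CDS / intron / IGS / unknown

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _smallest_period(motif: str) -> int:
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[:p] * (m // p):
            return p
    return m


def find_ssrs(
    seq: str, thresholds: Optional[dict[int, int]] = None
) -> list[SsrHit]:
    """Maximal perfect tandem runs with motif lengths 1-6 meeting thresholds.

    A run of period m over ``[s, e)`` satisfies seq[i] == seq[i-m] for all
    i in [s+m, e) and is maximal; only complete units are reported, so the
    hit interval is ``[s, s + k*m)`` with k = floor((e-s)/m).
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    n = len(seq)
    hits: list[SsrHit] = []
    for m, min_units in sorted(thresholds.items()):
        i = m
        run_start = 0
        while i <= n:
            if i < n and seq[i] == seq[i - m] and seq[i] != "N":
                i += 1
                continue
            # maximal matching stretch ended at i; run covers [run_start, i)
            span = i - run_start
            k = span // m
            if k >= min_units:
                motif = seq[run_start : run_start + m]
                if _smallest_period(motif) == m and "N" not in motif:
                    hits.append(
                        SsrHit(
                            motif=canonical_rotation(motif),
                            unit_count=k,
                            interval=(run_start, run_start + k * m),
                        )
                    )
            i += 1
            run_start = i - m
    hits.sort(key=lambda h: (h.interval, len(h.motif)))
    return hits


def classify_ssr_context(
    hits: Sequence[SsrHit], features: Sequence[FeatureAnnotation]
) -> list[SsrHit]:
    """Label hits CDS / intron / IGS by the position of their midpoint."""
    out = []
    for h in hits:
        context = "IGS"
        mid = (h.interval[0] + h.interval[1]) // 2
        for f in features:
            s, e = f.span
            if s <= mid < e:
                in_exon = any(a <= mid < b for a, b in f.intervals)
                if in_exon:
                    context = "CDS" if f.kind == "CDS" else "unknown"
                else:
                    context = "intron"
                break
        out.append(SsrHit(h.motif, h.unit_count, h.interval, context))
    return out


# ---------------------------------------------------------------------------
# exact long repeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatHit:
    kind: str  # forward / palindromic
    intervals: tuple[tuple[int, int], tuple[int, int]]
    length: int


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_repeats(seq: str, min_len: int = 30) -> list[RepeatHit]:
    """All maximal exact forward and palindromic repeats of length >= min_len.

    Seed-and-extend on shared min_len-mers.  A forward pair (i, j, L) is
    maximal when it cannot be extended on either side; a palindromic pair
    extends copy A rightwards together with copy B leftwards (and vice
    versa).  Self-overlapping tandem hits of one run are collapsed to the
    smallest-spacing representative.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    n = len(seq)
    k = min_len
    raw: set[tuple[str, int, int, int]] = set()

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)

    for positions in index.values():
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                i, j, length = positions[ai], positions[bi], k
                while i > 0 and j > 0 and seq[i - 1] == seq[j - 1] != "N":
                    i -= 1
                    j -= 1
                    length += 1
                while (
                    i + length < n
                    and j + length < n
                    and seq[i + length] == seq[j + length] != "N"
                ):
                    length += 1
                raw.add(("forward", i, j, length))

    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(reverse_complement(kmer), ()):
            # copy A = [a, a+L), copy B = [b, b+L), B == revcomp(A)
            a, b, length = i, j, k
            while (
                a + length < n
                and b > 0
                and seq[a + length] != "N"
                and seq[b - 1] == _COMP[seq[a + length]]
            ):
                b -= 1
                length += 1
            while (
                a > 0
                and b + length < n
                and seq[a - 1] != "N"
                and seq[b + length] == _COMP[seq[a - 1]]
            ):
                a -= 1
                length += 1
            lo, hi = (a, b) if a <= b else (b, a)
            raw.add(("palindromic", lo, hi, length))

    return collapse_repeat_hits(raw)


def collapse_repeat_hits(
    raw: set[tuple[str, int, int, int]]
) -> list[RepeatHit]:
    """Deduplicate maximal pairs; pairs whose copies overlap (tandem runs)
    are grouped by their footprint and only the smallest spacing is kept."""
    by_key: dict[tuple, tuple[str, int, int, int]] = {}
    for kind, i, j, length in raw:
        if j < i + length:  # overlapping copies -> one tandem family
            key = (kind, "tandem", i, j + length)
        else:
            key = (kind, "pair", i, j, length)
        prev = by_key.get(key)
        if prev is None or (j - i) < (prev[2] - prev[1]):
            by_key[key] = (kind, i, j, length)
    out = [
        RepeatHit(kind=kd, intervals=((i, i + ln), (j, j + ln)), length=ln)
        for kd, i, j, ln in by_key.values()
    ]
    out.sort(key=lambda h: (h.intervals, h.kind))
    return out


# ---------------------------------------------------------------------------
# variant catalogue from an alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSite:
    column: int  # alignment column, 0-based
    bases: tuple[str, ...]  # per row
    feature: Optional[str] = None


@dataclass(frozen=True)
class IndelEvent:
    columns: tuple[int, int]  # half-open alignment column interval
    pattern: tuple[bool, ...]  # per row: True = has bases, False = gap
    length: int
    feature: Optional[str] = None


@dataclass
class VariantCatalog:
    snp_sites: list[SnpSite] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)
    per_feature: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def snp_count(self) -> int:
        return len(self.snp_sites)

    @property
    def indel_count(self) -> int:
        return len(self.indels)


def call_variants(
    msa: MultipleAlignment,
    features: Optional[Sequence[FeatureAnnotation]] = None,
    reference_row: int = 0,
) -> VariantCatalog:
    """Catalogue SNP sites and indel events from an alignment.

    Columns gapped in every row are ignored.  ``features`` (optional) are
    intervals on the ungapped reference row; a site is assigned to the feature
    containing its reference coordinate.
    """
    rows = msa.rows
    ncols = msa.column_count
    cat = VariantCatalog()
    ref_map = msa.column_to_seq_pos(reference_row)

    def feature_at(col: int) -> Optional[str]:
        if not features:
            return None
        pos = ref_map[col]
        for f in features:
            if any(s <= pos < e for s, e in f.intervals):
                return f.name
        return None

    run_start = None
    run_pattern: tuple[bool, ...] | None = None
    for col in range(ncols + 1):
        if col < ncols:
            column = [r[col] for r in rows]
            has_gap = "-" in column
            pattern = tuple(c != "-" for c in column) if has_gap else None
            all_gap = has_gap and not any(pattern)
        else:
            has_gap, pattern, all_gap = False, None, False
        if run_pattern is not None and pattern != run_pattern:
            cat.indels.append(
                IndelEvent(
                    columns=(run_start, col),
                    pattern=run_pattern,
                    length=col - run_start,
                    feature=feature_at(run_start),
                )
            )
            run_pattern, run_start = None, None
        if col == ncols:
            break
        if has_gap and not all_gap:
            if run_pattern is None:
                run_start, run_pattern = col, pattern
            continue
        if not has_gap:
            bases = set(column)
            if "N" not in bases and len(bases) >= 2:
                cat.snp_sites.append(
                    SnpSite(column=col, bases=tuple(column), feature=feature_at(col))
                )

    if features:
        tally: dict[str, dict[str, int]] = {}
        for s in cat.snp_sites:
            if s.feature:
                tally.setdefault(s.feature, {"snps": 0, "indels": 0})["snps"] += 1
        for e in cat.indels:
            if e.feature:
                tally.setdefault(e.feature, {"snps": 0, "indels": 0})["indels"] += 1
        cat.per_feature = tally
    return cat


# ---------------------------------------------------------------------------
# codon usage / RSCU
# ---------------------------------------------------------------------------

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid (one-letter), with '*' for stop codons.
CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    CODON_TO_AA[_stop] = "*"

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass
class CodonUsage:
    codon_counts: dict[str, int]
    aa_totals: dict[str, int]
    rscu: dict[str, Optional[float]]

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())


def codon_usage(cds_seqs: Sequence[str]) -> CodonUsage:
    """Codon counts and RSCU over in-frame coding sequences.

    RSCU(c) = count(c) * k / sum of counts over c's synonymous codons, with
    k the synonymous family size (bacterial/plastid table 11 grouping; stop
    codons form their own group).  Sequences whose length is not a multiple
    of 3 are rejected with a warning, not fatally.
    """
    import logging

    counts: Counter[str] = Counter({c: 0 for c in CODON_TO_AA})
    for idx, seq in enumerate(cds_seqs):
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            logging.getLogger(__name__).warning(
                "CDS %d length %d not divisible by 3; skipped", idx, len(seq)
            )
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in CODON_TO_AA:
                counts[codon] += 1
    aa_totals = {
        aa: sum(counts[c] for c in codons) for aa, codons in _AA_TO_CODONS.items()
    }
    rscu: dict[str, Optional[float]] = {}
    for aa, codons in _AA_TO_CODONS.items():
        total = aa_totals[aa]
        k = len(codons)
        for c in codons:
            rscu[c] = (counts[c] * k / total) if total > 0 else None
    return CodonUsage(codon_counts=dict(counts), aa_totals=aa_totals, rscu=rscu)
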