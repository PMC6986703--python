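"""Synthetic inputs for desk-scale testing of the whole pipeline.

Three closely related circular genomes are derived from a random ancestor:
independent background substitutions per lineage, one or more implanted
marker windows with elevated interspecific divergence and species-specific
short insertions (a TATAT-like tail in one species, a TCTTAC-like head in
another — the canonical diagnostic-indel geometry), and homopolymer decoy
runs that a marker scan must learn to avoid.  Heteroplasmic read pools are
drawn per species from a configurable allele pool with i.i.d. substitution
errors.  Every edit is recorded in a machine-readable truth log, and the
true multiple alignment is emitted alongside the genomes so downstream
statistics can be checked against ground truth without re-aligning.

All randomness flows through ``numpy.random.default_rng(seed)``; fixed seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .allele_profiler import TargetFragment
from .seqio import GenomeRecord, MultipleAlignment, ReadSet

BASES = np.array(list("ACGT"))

DEFAULT_SPECIES = ("species1", "species2", "species3")


@dataclass(frozen=True)
class ImplantSpec:
    """One implanted marker window on the ancestor.

    ``divergence`` is the target pairwise substitution divergence inside the
    window (each lineage mutates sites independently at divergence/2).
    ``insertions`` maps species label -> (placement, motif) with placement
    'head' (inserted at window start), 'tail' (at window end) or an integer
    offset from the window start.
    """

    interval: tuple[int, int]
    divergence: float = 0.05
    insertions: dict[str, tuple[str | int, str]] = field(default_factory=dict)


@dataclass
class TrioConfig:
    genome_length: int = 20_000
    background_snp_rate: float = 0.005  # pairwise, between each species pair
    implants: Sequence[ImplantSpec] = ()
    homopolymers: Sequence[tuple[int, str, int]] = ()  # (position, base, run length)
    conserved_margin: int = 60  # mutation-free margin flanking each implant
    species: Sequence[str] = DEFAULT_SPECIES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_snp_rate <= 0.2:
            raise ValueError("background_snp_rate must be in [0, 0.2]")
        iv = sorted(im.interval for im in self.implants)
        for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError("implant windows overlap")
        for im in self.implants:
            if not (0 <= im.interval[0] < im.interval[1] <= self.genome_length):
                raise ValueError("implant window outside genome")
        for pos, base, run in self.homopolymers:
            if run < 1:
                raise ValueError("homopolymer run length must be >= 1")


def default_trio_config(seed: int = 0, genome_length: int = 20_000) -> TrioConfig:
    """The standard desk-scale study emulation: 20 kb circular genomes, 0.5%
    background divergence, one 160 bp marker implant at 5% divergence carrying
    a 5 bp TATAT-like and a 6 bp TCTTAC-like species-specific insertion, and
    two homopolymer decoy runs elsewhere.  The implant plus its insertions
    (171 alignment columns) fits inside one default 200-column scan window
    with conserved flanks on the step grid."""
    mid = genome_length * 3 // 5
    mid -= mid % 50  # align the implant to the default window step
    sp = DEFAULT_SPECIES
    return TrioConfig(
        genome_length=genome_length,
        background_snp_rate=0.005,
        implants=(
            ImplantSpec(
                interval=(mid, mid + 160),
                divergence=0.05,
                insertions={sp[0]: (75, "TATAT"), sp[1]: (110, "TCTTAC")},
            ),
        ),
        homopolymers=((genome_length // 5, "A", 12), (genome_length * 2 // 5, "T", 10)),
        species=sp,
        seed=seed,
    )


@dataclass
class TruthLog:
    """Machine-readable record of everything the simulators did."""

    ancestor: str = ""
    substitutions: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    insertions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    implants: list[dict] = field(default_factory=list)
    homopolymers: list[tuple[int, str, int]] = field(default_factory=list)
    alignment: Optional[MultipleAlignment] = None
    read_alleles: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    allele_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "ancestor": self.ancestor,
            "substitutions": self.substitutions,
            "insertions": self.insertions,
            "implants": self.implants,
            "homopolymers": [list(h) for h in self.homopolymers],
            "alignment": (
                {"row_ids": self.alignment.row_ids, "rows": self.alignment.rows}
                if self.alignment
                else None
            ),
            "read_alleles": self.read_alleles,
            "allele_counts": self.allele_counts,
        }
        Path(path).write_text(json.dumps(doc) + "\n")


def simulate_genome_trio(config: TrioConfig) -> tuple[list[GenomeRecord], TruthLog]:
    """Generate three related circular genomes plus the truth log.

    The ancestor is uniform random; homopolymer decoys are written into it
    verbatim.  Each lineage receives independent substitutions (background
    rate/2 per site outside implants and their conserved margins, implant
    divergence/2 inside implants) and its configured diagnostic insertions.
    The true alignment (one column block per ancestor position, insertion
    blocks padded with '-') is stored in the truth log.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    ancestor = list(BASES[rng.integers(0, 4, size=L)])
    for pos, base, run in config.homopolymers:
        ancestor[pos : pos + run] = [base] * min(run, L - pos)
    # markers are implanted in homopolymer-free context: break any chance
    # run of >= 5 identical bases inside an implant or its conserved margin
    for im in config.implants:
        s = max(0, im.interval[0] - config.conserved_margin)
        e = min(L, im.interval[1] + config.conserved_margin)
        run = 1
        for i in range(s + 1, e):
            run = run + 1 if ancestor[i] == ancestor[i - 1] else 1
            if run >= 5:
                nxt = ancestor[i + 1] if i + 1 < L else ""
                ancestor[i] = next(
                    b for b in "ACGT" if b != ancestor[i] and b != nxt
                )
                run = 1
    ancestor_str = "".join(ancestor)

    log = TruthLog(ancestor=ancestor_str, homopolymers=list(config.homopolymers))

    in_implant = np.zeros(L, dtype=bool)
    protected = np.zeros(L, dtype=bool)
    for im in config.implants:
        s, e = im.interval
        in_implant[s:e] = True
        m = config.conserved_margin
        protected[max(0, s - m) : min(L, e + m)] = True

    per_site_rate = np.full(L, config.background_snp_rate / 2.0)
    per_site_rate[protected] = 0.0
    for im in config.implants:
        s, e = im.interval
        per_site_rate[s:e] = im.divergence / 2.0

    subs: dict[str, dict[int, str]] = {}
    for label in config.species:
        hit = np.nonzero(rng.random(L) < per_site_rate)[0]
        edits: dict[int, str] = {}
        for pos in hit:
            choices = [b for b in "ACGT" if b != ancestor[pos]]
            edits[int(pos)] = choices[int(rng.integers(0, 3))]
        subs[label] = edits
        log.substitutions[label] = sorted(
            (p, ancestor[p], b) for p, b in edits.items()
        )

    insertions: dict[str, dict[int, str]] = {label: {} for label in config.species}
    for im in config.implants:
        s, e = im.interval
        for label, (placement, motif) in im.insertions.items():
            if placement == "head":
                pos = s
            elif placement == "tail":
                pos = e
            else:
                pos = s + int(placement)
            insertions[label][pos] = motif
        log.implants.append(
            {
                "interval": list(im.interval),
                "divergence": im.divergence,
                "insertions": {
                    lab: {"placement": pl, "motif": mo}
                    for lab, (pl, mo) in im.insertions.items()
                },
            }
        )
    for label in config.species:
        log.insertions[label] = sorted(insertions[label].items())

    rows: dict[str, list[str]] = {label: [] for label in config.species}
    for pos in range(L + 1):
        ins_width = max(
            (len(insertions[lab].get(pos, "")) for lab in config.species), default=0
        )
        if ins_width:
            for lab in config.species:
                motif = insertions[lab].get(pos, "")
                rows[lab].append(motif + "-" * (ins_width - len(motif)))
        if pos < L:
            for lab in config.species:
                rows[lab].append(subs[lab].get(pos, ancestor[pos]))

    msa = MultipleAlignment(
        row_ids=list(config.species),
        rows=["".join(rows[lab]) for lab in config.species],
    )
    log.alignment = msa
    genomes = [
        GenomeRecord(id=lab, sequence=msa.ungapped(i), circular=True)
        for i, lab in enumerate(config.species)
    ]

    # implant intervals in each species' own genome coordinates
    for entry, im in zip(log.implants, config.implants):
        entry["genome_intervals"] = {
            lab: _genome_interval(im.interval, insertions[lab])
            for lab in config.species
        }
    return genomes, log


def _genome_interval(
    ancestor_interval: tuple[int, int], row_insertions: dict[int, str]
) -> list[int]:
    """Shift an ancestor interval by the insertions this lineage carries
    before/within it (insertions at the end position are inside)."""
    s, e = ancestor_interval
    off_s = s + sum(len(m) for p, m in row_insertions.items() if p < s)
    off_e = e + sum(len(m) for p, m in row_insertions.items() if p <= e)
    return [off_s, off_e]


# ---------------------------------------------------------------------------
# heteroplasmic read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleEdit:
    """One edit defining a minor allele relative to the genome."""

    kind: str  # 'sub' | 'ins' | 'del'
    position: int
    seq: str = ""  # replacement base(s) for sub/ins
    length: int = 1  # deletion length


@dataclass
class ReadSimConfig:
    depth: float = 100.0
    read_length: int = 250
    error_rate: float = 0.01
    allele_pool: dict[str, tuple[tuple[AlleleEdit, ...], float]] = field(
        default_factory=lambda: {"major": ((), 1.0)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        total = sum(f for _, f in self.allele_pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")


def apply_allele_edits(sequence: str, edits: Sequence[AlleleEdit]) -> str:
    out = sequence
    for edit in sorted(edits, key=lambda e: -e.position):
        if edit.kind == "sub":
            out = out[: edit.position] + edit.seq + out[edit.position + len(edit.seq) :]
        elif edit.kind == "ins":
            out = out[: edit.position] + edit.seq + out[edit.position :]
        elif edit.kind == "del":
            out = out[: edit.position] + out[edit.position + edit.length :]
        else:
            raise ValueError(f"unknown edit kind {edit.kind!r}")
    return out


def simulate_heteroplasmic_reads(
    genome: GenomeRecord, config: ReadSimConfig
) -> tuple[ReadSet, TruthLog]:
    """Draw reads uniformly along the (circular) genome from an allele pool.

    Each read's template allele is chosen by pool frequency, its start is
    uniform, its strand is random, and each base is substituted i.i.d. with
    probability ``error_rate``.  The truth log records every read's source
    allele, start and the per-allele totals.
    """
    if config.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(config.seed)
    allele_ids = sorted(config.allele_pool)
    freqs = np.array([config.allele_pool[a][1] for a in allele_ids])
    templates = {
        a: apply_allele_edits(genome.sequence, config.allele_pool[a][0])
        for a in allele_ids
    }
    n_reads = int(round(config.depth * len(genome) / config.read_length))
    reads: list[tuple[str, str, Optional[str]]] = []
    log = TruthLog()
    entries: list[tuple[str, str, int]] = []
    counts = {a: 0 for a in allele_ids}
    qual = "I" * config.read_length
    from .seqio import reverse_complement

    for i in range(n_reads):
        allele = allele_ids[int(rng.choice(len(allele_ids), p=freqs))]
        template = templates[allele]
        tl = len(template)
        if genome.circular:
            start = int(rng.integers(0, tl))
            raw = (template + template[: config.read_length])[
                start : start + config.read_length
            ]
        else:
            start = int(rng.integers(0, tl - config.read_length + 1))
            raw = template[start : start + config.read_length]
        if config.error_rate > 0:
            errs = np.nonzero(rng.random(len(raw)) < config.error_rate)[0]
            if len(errs):
                chars = list(raw)
                for p in errs:
                    alt = [b for b in "ACGT" if b != chars[p]]
                    chars[p] = alt[int(rng.integers(0, 3))]
                raw = "".join(chars)
        if rng.random() < 0.5:
            raw = reverse_complement(raw)
        rid = f"{genome.id}_r{i}"
        reads.append((rid, raw, qual))
        entries.append((rid, allele, start))
        counts[allele] += 1
    log.read_alleles[genome.id] = entries
    log.allele_counts[genome.id] = counts
    return ReadSet(species_label=genome.id, reads=reads), log


# ---------------------------------------------------------------------------
# cz11 published-allele fixture
# ---------------------------------------------------------------------------

#: The published cz11 marker allele table: per species, the observed allele
#: strings (38-column frame: a 6 bp TCTTAC head, a 27 bp shared core, a 5 bp
#: TATAT tail) with their read counts, plus the total mapped reads per
#: species.  Rows with identical underlying (ungapped) sequence merge when
#: re-tabulated, since gap placement inside a periodic stretch is arbitrary.
CZ11_ALLELE_TABLE: dict[str, tuple[int, tuple[tuple[str, int], ...]]] = {
    "A_lancea": (
        445,
        (
            ("------AAGGAAAGGGAAAAAATGACATTATATTATAT", 356),
            ("------AAGGAAAGGGAAAAAATGACATTATAT-----", 8),
            ("------AAGGAAAAGGAAAAAATGACATTATATTATAT", 3),
            ("------AAGGAAAGAGAAAAAATGACATTATATTATAT", 3),
            ("------AAGGAAAGGGAAAAAAAGACATTATATTATAT", 3),
            ("------AAAGAAAGGGAAAAAATGACATTATATTATAT", 2),
            ("------AAGGAAAGGAAAAAAATGACATTATATTATAT", 2),
            ("------AAGGAAAGGGAAAAAAGGACATTATATTATAT", 2),
            ("------AAGGAAAGGGAAAAAATGACATTATAATATAT", 2),
            ("------AAGGAAAGGGAAAAAATGACATTATA-----T", 2),
            ("------AAGGAAAGGGAAAAAATGACATTATATTAT--", 2),
            ("------AAGGAAAGGGAAAAAATGACATTATATTATCT", 2),
            ("------AAGGAAAGGGAAAAAATGACCTTATATTATAT", 2),
            ("------AAGGAAAGGGAAACAATGACATTATATTATAT", 2),
            ("------AAGGCAAGGGAAAAAATGACATTATATTATAT", 2),
            ("------AAGGTAAGGGAAAAAATGACATTATATTATAT", 2),
            ("------AATGAAAGGGAAAAAATGACATTATATTATAT", 2),
            ("------CAGGAAAGGGAAAAAATGACATTATATTATAT", 2),
        ),
    ),
    "A_macrocephala": (
        620,
        (
            ("TCTTACAAGGAAAGGGAAAAAATGACATTATAT-----", 588),
            ("TCTTAAAAGGAAAGGGAAAAAATGACATTATAT-----", 2),
            ("TCTTACAAGGAAAGAGAAAAAATGACATTATAT-----", 2),
            ("TCTTACAAGGAAAGGGAAAAAATTACATTATAT-----", 2),
        ),
    ),
    "A_chinensis": (
        762,
        (
            ("------AAGGAAAGGTAAAAAATGACATTATAT-----", 420),
            ("------AAGGAAAGGGAAAAAATGACATTATAT-----", 309),
            ("------AAGGAAAGGGAAAAAAAGACATTATAT-----", 3),
            ("------AAGGAAAGGGAAAAA-TGACATTATAT-----", 3),
            ("------AAGGAAAGAGAAAAAATGACATTATAT-----", 2),
            ("------AAGGAAAGATAAAAAATGACATTATAT-----", 2),
        ),
    ),
}

#: The 38-base union frame all table rows are written in.
CZ11_FRAME = "TCTTACAAGGAAAGGGAAAAAATGACATTATATTATAT"

#: Per-species dominant (most frequent) ungapped alleles of the cz11 locus.
CZ11_DOMINANT_ALLELES: dict[str, str] = {
    label: rows[0][0].replace("-", "")
    for label, (_, rows) in CZ11_ALLELE_TABLE.items()
}


def _cz11_flanks(flank_len: int = 281, seed: int = 11) -> tuple[str, str]:
    """Deterministic fragment flanks.  The junction bases are pinned so the
    optimal placement of head/tail indels against the frame is unique."""
    rng = np.random.default_rng(seed)
    left = "".join(BASES[rng.integers(0, 4, size=flank_len)])
    right = "".join(BASES[rng.integers(0, 4, size=flank_len)])
    left = left[:-1] + "G"
    right = "C" + right[1:]
    for flank in (left, right):
        run, prev = 0, ""
        for ch in flank:
            run = run + 1 if ch == prev else 1
            prev = ch
            assert run < 8, "decoy homopolymer in generated flank"
    return left, right


def make_cz11_fixture(
    read_length: int = 250, fragment_len: int = 600
) -> tuple[TargetFragment, dict[str, ReadSet], dict]:
    """Embed the published cz11 allele table in a synthetic 600 bp fragment.

    The frame super-allele sits centered in deterministic random flanks; each
    table row is emitted as exactly its printed number of error-free reads
    spanning the target, padded with distinct singleton substitution variants
    of the dominant allele so the per-species totals match the published
    totals (445 / 620 / 762).  Re-profiling this fixture reproduces the
    printed dominant counts and shares.
    """
    pad = (fragment_len - len(CZ11_FRAME)) // 2
    left, right = _cz11_flanks(pad)
    fragment_seq = left + CZ11_FRAME + right
    fragment = TargetFragment(
        genome_id="cz11_fragment",
        fragment_interval=(0, fragment_len),
        target_interval=(pad, pad + len(CZ11_FRAME)),
        fragment_seq=fragment_seq,
    )
    readsets: dict[str, ReadSet] = {}
    expected: dict = {"totals": {}, "dominant_counts": {}}
    for label, (total, rows) in CZ11_ALLELE_TABLE.items():
        pool: list[tuple[str, int]] = [
            (allele.replace("-", ""), count) for allele, count in rows
        ]
        listed = sum(c for _, c in pool)
        seen = {seq for seq, _ in pool}
        dominant = pool[0][0]
        deficit = total - listed
        made = 0
        pos = 0
        while made < deficit:
            base = dominant[pos % len(dominant)]
            for alt in "ACGT":
                if alt == base:
                    continue
                variant = (
                    dominant[: pos % len(dominant)]
                    + alt
                    + dominant[pos % len(dominant) + 1 :]
                )
                if variant not in seen:
                    seen.add(variant)
                    pool.append((variant, 1))
                    made += 1
                    break
            pos += 1
        reads: list[tuple[str, str, Optional[str]]] = []
        i = 0
        for seq, count in pool:
            k = (read_length - len(seq)) // 2
            read = left[-k:] + seq + right[: read_length - k - len(seq)]
            assert len(read) == read_length
            for _ in range(count):
                reads.append((f"{label}_r{i}", read, None))
                i += 1
        assert len(reads) == total
        readsets[label] = ReadSet(species_label=label, reads=reads)
        expected["totals"][label] = total
        expected["dominant_counts"][label] = rows[0][1]
    return fragment, readsets, expected
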