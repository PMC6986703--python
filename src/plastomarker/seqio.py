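"""Input/output for the standard formats the pipeline touches.

Everything downstream works with the small set of containers defined here:
:class:`GenomeRecord` (a possibly circular plastome), :class:`MultipleAlignment`
(gapped rows over a common column coordinate system) and :class:`ReadSet`
(a bag of sequencing reads from one species).

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open.  GenBank's 1-based inclusive
locations are converted on read; user-facing reports convert back.  Circular
genomes are handled with an explicit wrap flag — nothing wraps silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Characters a normalized genome sequence may contain.
ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, context: str = "") -> str:
    """Upper-case, map U->T and collapse non-ACGT IUPAC codes to N."""
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        for ch in bad:
            if not ch.isalpha():
                raise FormatError(
                    f"non-sequence character {ch!r} in {context or 'sequence'}"
                )
        logger.warning(
            "ambiguity codes %s in %s mapped to N", "".join(bad), context or "sequence"
        )
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature (gene/CDS/tRNA/rRNA) with exon intervals.

    ``intervals`` are 0-based half-open and ordered along the genome;
    ``strand`` is '+' or '-'.
    """

    name: str
    kind: str  # CDS / tRNA / rRNA / other
    strand: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty interval in feature {self.name}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0][0], self.intervals[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass(frozen=True)
class Partition:
    """The quadripartite plastome partition (LSC / IRa / SSC / IRb)."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]

    def validate(self, genome_length: int) -> None:
        parts = sorted([self.lsc, self.ira, self.ssc, self.irb])
        if parts[0][0] != 0 or parts[-1][1] != genome_length:
            raise ValueError("partition does not tile the genome")
        for (s0, e0), (s1, e1) in zip(parts, parts[1:]):
            if e0 != s1:
                raise ValueError("partition intervals overlap or leave gaps")
        if (self.ira[1] - self.ira[0]) != (self.irb[1] - self.irb[0]):
            raise ValueError("inverted repeats differ in length")

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"lsc": self.lsc, "ira": self.ira, "ssc": self.ssc, "irb": self.irb}


@dataclass
class GenomeRecord:
    """One genome sequence, optionally circular and annotated."""

    id: str
    sequence: str
    circular: bool = False
    features: list[FeatureAnnotation] = field(default_factory=list)
    partition: Optional[Partition] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        if not set(self.sequence) <= ALPHABET:
            self.sequence = normalize_sequence(self.sequence, f"genome {self.id}")
        if self.partition is not None:
            self.partition.validate(len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MultipleAlignment:
    """Gapped rows over a shared column coordinate system."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{rid}:{len(r)}" for rid, r in zip(self.row_ids, self.rows)
            )
            raise FormatError(f"alignment rows have unequal lengths ({detail})")
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in number")

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace("-", "")

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)

    def column_to_seq_pos(self, row: int) -> list[int]:
        """Per column, the 0-based ungapped position in this row's source
        sequence (for a gap column: the position of the next real base)."""
        out = []
        pos = 0
        for ch in self.rows[row]:
            out.append(pos)
            if ch != "-":
                pos += 1
        return out


@dataclass
class ReadSet:
    """Reads from one species; qualities are carried but never used."""

    species_label: str
    reads: list[tuple[str, str, Optional[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.reads]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into normalized :class:`GenomeRecord` objects."""
    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    if not parsed:
        raise FormatError(f"{path}: empty or not FASTA")
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), f"{path}:{rec.id}")
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path, species_label: str | None = None) -> ReadSet:
    path = Path(path)
    label = species_label or path.stem
    reads = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations.get("phred_quality", [])
            )
            reads.append((rec.id, normalize_sequence(str(rec.seq), rec.id), qual or None))
    return ReadSet(species_label=label, reads=reads)


def read_reads(path: str | Path, species_label: str | None = None) -> ReadSet:
    """Read FASTA or FASTQ reads, sniffing the format from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path, species_label)
    recs = read_fasta(path)
    return ReadSet(
        species_label=species_label or path.stem,
        reads=[(r.id, r.sequence, None) for r in recs],
    )


def read_genbank(path: str | Path) -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    1-based inclusive locations become 0-based half-open; ``join()`` locations
    become multi-interval features, ``complement()`` sets strand '-'.
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a parseable GenBank record ({exc})") from exc
    seq = normalize_sequence(str(rec.seq), f"{path}:{rec.id}")
    if not seq:
        raise FormatError(f"{path}: missing ORIGIN sequence")
    circular = rec.annotations.get("topology", "") == "circular"
    features: list[FeatureAnnotation] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        if feat.type == "gene" and any(
            f.type in ("CDS", "tRNA", "rRNA")
            and f.qualifiers.get("gene") == feat.qualifiers.get("gene")
            for f in rec.features
        ):
            continue  # prefer the typed child feature over its gene parent
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        try:
            parts = sorted(
                (int(p.start), int(p.end)) for p in feat.location.parts
            )
            strand = "-" if feat.location.strand == -1 else "+"
        except (AttributeError, TypeError) as exc:
            raise FormatError(f"{path}: unparseable location for feature {name}") from exc
        kind = feat.type if feat.type in ("CDS", "tRNA", "rRNA") else "other"
        features.append(
            FeatureAnnotation(name=name, kind=kind, strand=strand, intervals=tuple(parts))
        )
    return GenomeRecord(id=rec.id or path.stem, sequence=seq, circular=circular, features=features)


def extract_feature_sequence(genome: GenomeRecord, feature: FeatureAnnotation) -> str:
    """Spliced feature sequence, reverse-complemented for '-' strand."""
    spliced = "".join(genome.sequence[s:e] for s, e in feature.intervals)
    return reverse_complement(spliced) if feature.strand == "-" else spliced


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA (gaps preserved, everything else normalized)."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            ids.append(rec.id)
            row = str(rec.seq).upper().replace("U", "T")
            row = "".join(c if (c in ALPHABET or c == "-") else "N" for c in row)
            rows.append(row)
    if len(rows) < 2:
        raise FormatError(f"{path}: an alignment needs at least two rows")
    return MultipleAlignment(row_ids=ids, rows=rows)


def write_alignment(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def slice_region(
    genome: GenomeRecord, interval: tuple[int, int], allow_wrap: bool = False
) -> str:
    """Extract ``[start, end)`` from a genome, optionally wrapping the origin.

    On a circular genome with ``allow_wrap`` the slice continues from position
    0 when ``end`` exceeds the length; otherwise it is clipped with a warning.
    Negative starts wrap the other way on circular genomes.
    """
    start, end = interval
    n = len(genome)
    if end - start > n:
        raise ValueError(f"slice longer than genome ({end - start} > {n})")
    if start < 0 or end < start:
        if genome.circular and allow_wrap and start < 0:
            return genome.sequence[start % n :] + slice_region(genome, (0, end), allow_wrap)
        raise ValueError(f"bad interval [{start}, {end})")
    if start >= n:
        raise ValueError(f"start {start} beyond genome length {n}")
    if end <= n:
        return genome.sequence[start:end]
    # end > n: wrap or clip
    if allow_wrap:
        if not genome.circular:
            raise ValueError(f"wrap requested on non-circular genome {genome.id}")
        return genome.sequence[start:] + genome.sequence[: end - n]
    logger.warning(
        "interval [%d,%d) clipped at linear end of %s (length %d)", start, end, genome.id, n
    )
    return genome.sequence[start:n]


def to_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    """Internal half-open 0-based -> user-facing 1-based inclusive."""
    return (interval[0] + 1, interval[1])


def from_one_based(interval: tuple[int, int]) -> tuple[int, int]:
    return (interval[0] - 1, interval[1])
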