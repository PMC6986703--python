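"""Diagnostic-indel species identification.

From the per-species dominant alleles of a marker locus, derive the indel
regions that distinguish the species (short species-specific insertions such
as a 5 bp TATAT tail or a 6 bp TCTTAC head) and classify query amplicon
sequences by the presence/absence of those insertions.  Substitutions
outside the diagnostic regions never change a call — they only feed a
background-divergence sanity check — because real amplicon sets routinely
contain intraspecific SNP variants of the same species pattern.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._align import overlap_affine_alignment, star_msa

UNCLASSIFIED = "unclassified"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class DiagnosticRegion:
    region_id: str
    columns: tuple[int, int]  # columns in the rule frame, half-open
    motif: str  # the inserted bases (from the species carrying them)
    present_in: tuple[str, ...]  # species with bases in these columns
    absent_in: tuple[str, ...]


@dataclass
class MarkerRuleSet:
    species: list[str]
    frame_rows: dict[str, str]  # per-species gapped allele in the frame
    regions: list[DiagnosticRegion]
    source_alleles: dict[str, str] = field(default_factory=dict)

    @property
    def frame_length(self) -> int:
        return len(next(iter(self.frame_rows.values())))

    def consensus(self) -> str:
        """Union 'super-allele': per column, the base of any non-gap species
        (majority on disagreement).  Anchor for aligning queries."""
        cols = []
        for i in range(self.frame_length):
            bases = [row[i] for row in self.frame_rows.values() if row[i] != "-"]
            cols.append(max(sorted(set(bases)), key=bases.count) if bases else "-")
        return "".join(c for c in cols if c != "-")

    def consensus_columns(self) -> list[int]:
        """Frame column of each consensus base (no all-gap columns remain)."""
        return [
            i
            for i in range(self.frame_length)
            if any(row[i] != "-" for row in self.frame_rows.values())
        ]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "species": self.species,
            "frame_rows": self.frame_rows,
            "source_alleles": self.source_alleles,
            "regions": [
                {
                    "region_id": r.region_id,
                    "columns": list(r.columns),
                    "motif": r.motif,
                    "present_in": list(r.present_in),
                    "absent_in": list(r.absent_in),
                }
                for r in self.regions
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerRuleSet":
        doc = json.loads(Path(path).read_text())
        return cls(
            species=doc["species"],
            frame_rows=doc["frame_rows"],
            source_alleles=doc.get("source_alleles", {}),
            regions=[
                DiagnosticRegion(
                    region_id=r["region_id"],
                    columns=tuple(r["columns"]),
                    motif=r["motif"],
                    present_in=tuple(r["present_in"]),
                    absent_in=tuple(r["absent_in"]),
                )
                for r in doc["regions"]
            ],
        )


@dataclass
class ClassificationResult:
    label: str  # species, "ambiguous" or "unclassified"
    matched_regions: list[str]
    background_divergence: float | None


class IndistinguishableSpeciesError(ValueError):
    pass


def derive_rules(dominant_alleles: dict[str, str]) -> MarkerRuleSet:
    """Derive diagnostic indel regions from per-species dominant alleles.

    The alleles are globally aligned into a common frame; every maximal run
    of columns with a constant, non-uniform gap/non-gap species pattern
    becomes one diagnostic region.  Raises
    :class:`IndistinguishableSpeciesError` if some species pair shares its
    gap pattern at every region.
    """
    if len(dominant_alleles) < 2:
        raise ValueError("need at least two species")
    alleles = {k: v.upper().replace("-", "") for k, v in dominant_alleles.items()}
    ids, rows = star_msa(alleles)
    frame = dict(zip(ids, rows))
    ncols = len(rows[0])

    regions: list[DiagnosticRegion] = []
    run_start = None
    run_pattern: tuple[bool, ...] | None = None

    def close(run_start: int, end: int, pattern: tuple[bool, ...]) -> None:
        present = tuple(s for s, p in zip(ids, pattern) if p)
        absent = tuple(s for s, p in zip(ids, pattern) if not p)
        carrier = present[0]
        motif = frame[carrier][run_start:end].replace("-", "")
        regions.append(
            DiagnosticRegion(
                region_id=chr(ord("A") + len(regions)),
                columns=(run_start, end),
                motif=motif,
                present_in=present,
                absent_in=absent,
            )
        )

    for col in range(ncols + 1):
        if col < ncols:
            pattern = tuple(frame[s][col] != "-" for s in ids)
            informative = any(pattern) and not all(pattern)
        else:
            pattern, informative = None, False
        if run_pattern is not None and (not informative or pattern != run_pattern):
            close(run_start, col, run_pattern)
            run_start, run_pattern = None, None
        if informative and run_pattern is None:
            run_start, run_pattern = col, pattern

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if not any(
                (a in r.present_in) != (b in r.present_in) for r in regions
            ):
                raise IndistinguishableSpeciesError(
                    f"no diagnostic region between {a} and {b}"
                )
    return MarkerRuleSet(
        species=ids, frame_rows=frame, regions=regions, source_alleles=alleles
    )


def _query_frame_row(query: str, rules: MarkerRuleSet) -> str:
    """Project a query into the rule frame by overlap-aligning the frame's
    union consensus to the query: terminal absence and amplicon flank
    overhangs are both free, interior indels affine."""
    consensus = rules.consensus()
    cols = rules.consensus_columns()
    row_c, row_q = overlap_affine_alignment(consensus, query)
    out = ["-"] * rules.frame_length
    cpos = 0
    for cc, qc in zip(row_c, row_q):
        if cc != "-":
            out[cols[cpos]] = qc
            cpos += 1
        # query bases inserted relative to the consensus do not enter region calls
    return "".join(out)


def classify(
    query: str,
    rules: MarkerRuleSet,
    max_background_divergence: float = 0.15,
    motif_min_identity: float = 0.8,
) -> ClassificationResult:
    """Classify a query amplicon by its diagnostic indel pattern.

    Presence/absence of each region's insertion selects the compatible
    species; exactly one compatible species whose background (substitution)
    divergence outside diagnostic regions is within tolerance gives a species
    label.  Conflicting positive indications (e.g. a query carrying two
    mutually exclusive insertions) give "ambiguous"; no compatible species
    gives "unclassified".

    A region counts as present only when the query both covers a majority of
    its columns and matches the carrier species' motif at ``motif_min_identity``
    — this tolerates a SNP inside the motif while rejecting chance alignment
    of unrelated flanking sequence into a free terminal region.
    """
    min_len = min(len(a) for a in rules.source_alleles.values())
    query = query.upper().replace("-", "")
    if len(query) < min_len / 2:
        raise ValueError("query shorter than half the rule allele length")
    qrow = _query_frame_row(query, rules)

    compatible = set(rules.species)
    positives: set[str] = set()
    matched: list[str] = []
    for region in rules.regions:
        s, e = region.columns
        carrier_row = rules.frame_rows[region.present_in[0]]
        covered = sum(1 for c in qrow[s:e] if c != "-")
        matches = sum(
            1 for qc, cc in zip(qrow[s:e], carrier_row[s:e]) if qc == cc != "-"
        )
        present = covered > (e - s) / 2 and matches / (e - s) >= motif_min_identity
        if present:
            compatible &= set(region.present_in)
            positives |= set(region.present_in)
            matched.append(f"{region.region_id}:present")
        else:
            compatible &= set(region.absent_in)
            matched.append(f"{region.region_id}:absent")

    if not compatible:
        label = AMBIGUOUS if len(positives) >= 2 else UNCLASSIFIED
        return ClassificationResult(label=label, matched_regions=matched, background_divergence=None)
    if len(compatible) > 1:
        return ClassificationResult(
            label=AMBIGUOUS, matched_regions=matched, background_divergence=None
        )
    species = next(iter(compatible))

    diag_cols = set()
    for region in rules.regions:
        diag_cols.update(range(*region.columns))
    srow = rules.frame_rows[species]
    core_total = compared = mismatches = 0
    for i in range(rules.frame_length):
        if i in diag_cols:
            continue
        if srow[i] != "-":
            core_total += 1
            if qrow[i] != "-":
                compared += 1
                if srow[i] != qrow[i]:
                    mismatches += 1
    if core_total == 0 or compared / core_total < 0.6:
        # the query barely touches the marker core: absence of every motif
        # is then meaningless, not evidence for the all-absent species
        return ClassificationResult(
            label=UNCLASSIFIED, matched_regions=matched, background_divergence=None
        )
    divergence = mismatches / compared if compared else 0.0
    if divergence > max_background_divergence:
        return ClassificationResult(
            label=UNCLASSIFIED, matched_regions=matched, background_divergence=divergence
        )
    return ClassificationResult(
        label=species, matched_regions=matched, background_divergence=divergence
    )
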