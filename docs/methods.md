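# Methods

## The problem

Plastomes of congeneric plants are often > 99.5% identical, and the few
regions variable enough to distinguish species tend to be variable *within*
species too (heteroplasmy: a cell carries many plastids, and deep sequencing
of one individual routinely shows several alleles at a locus).  A marker
that is interspecifically divergent but intraspecifically heterogeneous
amplifies a mixture of templates and yields unreadable Sanger traces.  The
useful loci are therefore those with a large **diversity gap**: high
divergence *between* species, low diversity *within* each species, and
clean flanking sequence for primers.

## The diversity-gap statistic

For a window *w* of alignment columns over a set of aligned genomes:

- **π_inter(w)** — nucleotide diversity in the Nei–Li sense: over gap-free,
  N-free columns in *w*, the mean over genome pairs of the per-site
  mismatch fraction.  Columns with a gap or N in any row are excluded
  (conservative, DnaSP-like); the count of remaining columns is reported as
  `usable_sites`, and the window is dropped when fewer than `min_sites`
  (default 20) remain.
- **π_intra,s(w)** — intraspecific diversity of species *s*, estimated from
  *s*'s reads mapped to its own genome.  Per qualifying pileup site the
  heterozygosity h = Σ_{b<b′} c_b·c_{b′} / (n(n−1)/2), with c_b the count of
  reads carrying base b and n = Σ c_b; π_intra is the mean h over qualifying
  sites.  A site qualifies at coverage ≥ `min_cov` (default 10) and deletion
  fraction ≤ 0.5.  We divide by pairs of *base-carrying* reads rather than
  raw coverage so deleted reads are not counted as silent matches; the two
  conventions coincide when no deletions are present.
- **G(w) = π_inter(w) − max_s π_intra,s(w)** — the gap score.  The maximum
  over species is the conservative aggregation (one heteroplasmic species is
  enough to ruin a marker); mean aggregation is available as an option.

Windows default to 200 columns with a 50-column step.  A window becomes a
**candidate** only if G > 0, no row contains a single-base run ≥
`homopolymer_max` (default 8, matching the mononucleotide SSR threshold —
polynucleotide stretches are length-unstable and break Sanger reads) inside
the window or its flanks, and both `flank_len` (default 20) flanks are
gap-free with π_inter ≤ `flank_max_pi` (default 0.0, i.e. perfectly
conserved primer-landing sites).  Candidates are sorted by G descending
(ties to the smaller coordinate) and overlapping candidates are merged
keeping the higher-G window.

π_intra estimated this way absorbs sequencing error: with error rate ε a
homogeneous locus still shows π_intra ≈ 2ε.  No error correction is
attempted; since the same inflation applies to every window, ranking is
unaffected, and the G > 0 filter simply becomes more conservative.  This is
a documented limitation, not a bug.

## Read mapping

Reads are placed by best semi-global (infix) edit-distance alignment on
either strand (edlib), with reads below `min_identity` (default 0.9) over
their aligned span discarded.  Circular references are handled by extending
the reference with a read-length of wrap-around sequence.  Aligned bases and
deletions accumulate into per-site counts; read insertions relative to the
reference are tallied separately and never enter π.  Pre-mapped SAM text is
accepted as an alternative source (fields QNAME/FLAG/RNAME/POS/CIGAR/SEQ;
CIGAR ops M/=/X/I/D/S), parsed with pysam, and produces identical pileups on
error-free input — this two-path equivalence is tested.

## Allele profiling

A fragment of `fragment_len` (default 600) bp is cut with the target region
centered (left pad = ⌊(fragment−target)/2⌋), wrapping on circular genomes.
Reads are recruited when their best local alignment to the fragment (either
strand) has aligned length ≥ `min_hit_len` (50) and identity ≥
`min_score_identity` (0.8) — an explicit, database-free replacement for a
BLAST e-value cutoff, chosen so a 250 bp read with up to ~20% divergence is
recruited.  An 11-mer seed prefilter and an edit-distance screen accept or
reject the clear cases; borderline reads get a full Smith–Waterman-style
local alignment.

Each recruited read is then aligned to the fragment with affine gap costs
(match 2, mismatch −3, open −6, extend −1, free end gaps on the read), so a
multi-base indel stays contiguous, and gap runs are slid as far right as
score allows — a deterministic canonical placement inside repetitive
stretches.  Reads fully spanning the target window contribute one allele
string (deletions as '-', insertions appended at the preceding column);
counts aggregate into the allele table.  `total_mapped` is fixed *before*
any `min_count` filter, so shares always refer to all spanning reads.

Note that two printed rows of the published cz11 table have identical
underlying DNA and differ only in arbitrary gap placement inside the
TATAT-periodic stretch; under canonical gap placement they merge into one
record (counts add), which changes no totals and no dominant shares.

## Diagnostic rules and classification

Dominant alleles are aligned into a common frame by star alignment around
the longest allele (affine pairwise alignments, right-normalized, insertion
columns merged).  Every maximal column run whose gap/non-gap species pattern
is constant and non-uniform becomes a diagnostic region with the carrier's
inserted motif; a rule set is rejected if some species pair is not separated
by any region.

A query is projected into the frame by overlap alignment to the frame's
union consensus (free end gaps on both sides: terminal absence of an
insertion and amplicon flank overhangs both cost nothing).  A region counts
as *present* when the query covers a majority of its columns **and** matches
the carrier's motif at ≥ 80% identity — tolerant of one SNP inside a 5–6 bp
motif, but rejecting chance alignment of unrelated flanking bases into a
free terminal region.  Presence/absence across regions intersects the
compatible species:

- exactly one compatible species → its label, provided the query covers ≥
  60% of that species' non-diagnostic core and its substitution divergence
  there is ≤ `max_background_divergence`;
- conflicting positive indications (e.g. both mutually exclusive insertions
  present, as in a template mixture) → `ambiguous`;
- anything else → `unclassified`.

Substitutions outside diagnostic regions never flip a call — field amplicon
sets contain intraspecific SNP variants (including a triple-substitution
pattern) that must stay with their species.  The background-divergence
default is 0.15: the documented triple-substitution variant amounts to 3
mismatches over a ~27 bp comparable core (≈ 0.11), which a 0.10 cutoff would
wrongly reject; 0.15 accepts it while still rejecting unrelated sequence
(which fails the motif and coverage gates long before this check).

## Synthetic data

`simulate_genome_trio` draws a uniform-random circular ancestor, writes
homopolymer decoys verbatim, then gives each of three lineages independent
substitutions: background rate μ/2 per site (so pairwise divergence ≈ μ,
default μ = 0.005, a realistic congeneric plastome distance) outside
implants, and divergence/2 inside each implant window (default 0.05 — the
divergent-locus regime).  Implants carry species-specific short insertions
(defaults: a 5 bp TATAT-like motif in one species, a 6 bp TCTTAC-like motif
in another — the canonical diagnostic geometry).  Two generator design
choices encode the marker model rather than tune any test: (i) a conserved,
mutation-free margin (default 60 bp) flanks each implant, because a usable
marker by definition has conserved primer sites; (ii) the implant
neighborhood is kept homopolymer-free, because markers are only sought in
sequence the homopolymer screen would not reject.  The exact multiple
alignment implied by the edits is emitted in the truth log, so downstream
statistics are tested against ground truth rather than a re-aligner.

`simulate_heteroplasmic_reads` draws uniform single-end reads (default
250 bp, matching common amplicon-scale read lengths; depth default 100×)
from an allele pool with configured frequencies, applies i.i.d. substitution
errors (default ε = 0.01), flips strands at random, and logs every read's
source allele.  Paired-end structure is deliberately ignored — no
implemented statistic uses pairing.  Indel sequencing errors are not
simulated by default (substitution-only error model).

`make_cz11_fixture` embeds the published cz11 allele table in a 600 bp
synthetic fragment: the 38-column union frame (TCTTAC head + 27 bp core +
TATAT tail) sits in deterministic random flanks whose junction bases are
pinned so indel placement against the frame is unambiguous; every table row
becomes exactly its printed number of error-free spanning reads, padded with
distinct singleton substitution variants so per-species totals equal the
published 445 / 620 / 762.

What the generator does *not* emulate: coverage and GC bias, quality-score
profiles, chimeric reads, structural variation beyond short insertions, and
real mapping ambiguity in the inverted repeats.  Passing tests therefore
demonstrate correctness of the statistics and the discovery logic under the
stated model, not robustness to every artifact of real sequencing data.

## Problem sizes and determinism

Tests and the acceptance script run the simulation stack at desk scale —
6 kb genomes, 30× depth, 20 recovery seeds, 50 conservation seeds — chosen
so the full suite completes in about a minute while every statistical check
retains comfortable margins (e.g. the implant's gap score exceeds background
scores by an order of magnitude at these sizes).  All randomness flows
through `numpy.random.default_rng` with explicit seeds; fixed seeds give
byte-identical genomes, reads, and pipeline artifacts, and re-running the
pipeline with the same config produces byte-identical TSV/JSON outputs.

## Conventions for the deposited-accession checks

Counts on the three deposited *Atractylodes* plastomes (SSR totals, indel
and SNP-site totals, per-gene hotspots) are convention-sensitive.  Ours:
perfect SSRs only, thresholds 8/4/4/3/3/3, smallest-period reporting;
exact-match repeats only (forward + palindromic; the 90%-similarity and
reverse/complement classes of REPuter-style scans are out of scope); SNP =
gap-free, N-free alignment column with ≥ 2 distinct bases; indel = maximal
gap-column run with a constant row pattern (a 5-column gap is one 5 bp
event); three-way alignment built with MAFFT.  Exact agreement with counts
produced under other tools' conventions (approximate repeats, DnaSP's
handling of sites adjacent to indels) is expected but not guaranteed; any
residual discrepancy should be read against this list.  The GenBank records
themselves are not shipped (~153 kb each) and must be placed under
`data/accessions/` for these checks to run.

## Known limitations

- π_intra conflates heteroplasmy with sequencing error (see above).
- The window scan treats the genome linearly from its deposited origin;
  windows do not wrap across the origin.
- The repeat finder reports exact repeats only; similarity-tolerant repeat
  families are undercounted relative to approximate-matching tools.
- Star MSA is adequate for amplicon-scale, near-identical alleles; it is
  not a general multiple aligner.
- The classifier keys only on indel-defined regions; a species pair
  distinguished solely by substitutions cannot be ruled apart by design
  (rule derivation fails loudly in that case).
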