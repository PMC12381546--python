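# Methods

This note documents the models, parameter choices and numerical conventions
behind `panfam`, and what the synthetic benchmark does and does not
demonstrate about real pangenome data.

## Synthetic pangenome model

The generator (`panfam.simpan`) builds a founder genome and evolves one
assembly per genotype from it.

**Domain library.** Five peptide "domain" templates (labels CCT, BBOX, PRR,
ZF, GATA) of 24 residues are drawn at random under the constraint that every
pair is < 40% identical under global alignment, so motif scans cannot
confuse them. Each template carries a per-column substitution tolerance
(uniform on [0, 0.12], with a third of columns pinned to 0); instances used
for founder proteins and for PSSM training are sampled under that
tolerance. Templates deliberately contain no methionine, so in-frame ATG
codons appear only where the protein layout puts them.

**Founder genes.** Family architectures cycle through CCT-only (CMF),
CCT+B-box (CO), CCT+PRR, CCT+GATA and CCT+ZF (ZCCT), so any run with ≥ 3
families contains the three canonical subfamilies. Each founder protein is
laid out as: Met — linker — companion domain (if any) — linker — a single
internal Met — linker — CCT domain — short tail. The companion domain sits
entirely in the first exon and the CCT domain in the last, so removing the
first and last exon from the annotation removes both domains from the
annotated protein (the misannotation analogue); the internal Met provides a
downstream in-frame alternative start 5′ of the CCT-coding region. CDSs are
reverse-translated with uniformly random synonymous codons; introns
(80–200 bp, GT…AG) split the CDS at boundaries confined to the
linker-coding window between companion end and CCT start. Genes are placed
on an i.i.d.-uniform background with ≥ 2 kb spacing (~4 kb minimum spacer),
which avoids accidental homology that could confound seed search.

**Per-genotype evolution.** Each genotype gets its own RNG stream derived
from the master seed, so genotypes are reproducible independently.
Substitutions are applied at `substitution_rate` to every spacer and gene
copy; inside CDSs they are codon-aware: the start/stop codons, the internal
Met codon and splice dinucleotides are protected, and substitutions that
would create an in-frame stop are skipped. This keeps annotated proteins
full length unless an event says otherwise, so every non-CONSISTENT status
in the output is attributable to a planted event rather than to background
noise.

**Events** are drawn independently per gene per genotype at `event_rates`.
Conflicting draws resolve by precedence: deletion wins outright; among the
sequence/annotation edits, 1-bp indel > 3-bp indel > domain deletion >
annotation truncation (one per gene per genotype); duplications combine
freely with the non-deletion edits. Specifics:

- *deletion* — the gene segment is removed; the truth row records the
  junction.
- *tandem duplication* — a diverged copy (`duplicate_divergence` per site,
  unconstrained) lands 200–2000 bp downstream; *dispersed duplication* —
  in a non-adjacent spacer, ≥ ~50 kb away. Copies are deliberately left
  unannotated, emulating assembly-only copies; copy indices are contiguous
  from 2 in the truth table.
- *1-bp indel* — planted in linker-coding sequence upstream of the internal
  Met, ≥ 6 bp from any exon boundary, at a site where the edit is
  positionally unambiguous (the edited sequence differs from the same edit
  applied at any position within ±4), so alignment recovers sign and
  position exactly. *3-bp indel* — same site rules, any linker window.
- *domain deletion* — an in-frame 42-bp excision of CCT-coding sequence
  (codons 4–18 of the domain), leaving the rest of the gene intact.
- *annotation truncation* — the genomic sequence is untouched; the first
  and last exon are dropped from the GFF3 (skipped for genes with < 3
  exons), with the phase of the new first CDS set accordingly.

**What the simulation does not model:** transposable elements,
recombination and synteny, reverse-strand genes, UTRs and non-coding exons,
sequencing/assembly error, GC bias, and realistic codon usage. Passing the
benchmark therefore demonstrates that the *method logic* is correct under
clean planted variation at realistic divergence — not that the thresholds
are optimal for any particular real assembly set.

### Default study conditions

12 genotypes × 8 families on 0.5 Mb per genotype, `substitution_rate` 0.01,
`duplicate_divergence` 0.02, event rates (per gene per genotype): deletion
0.08, tandem duplication 0.06, dispersed duplication 0.05, 1-bp indel 0.10,
3-bp indel 0.05, domain deletion 0.06, annotation truncation 0.08. These
sizes keep a full simulate–validate–frameshift cycle under ~30 s on one CPU
while planting several instances of every event kind per run; the rates
echo a gene family in which roughly a third of members show
presence/absence or structural variation.

## Homology search and copy counting

The genomic search is a seed-and-extend design: an exact k-mer index
(k = 15) of each assembly, queried with both strands of the gene sequence;
seeds are grouped into diagonal bands (half-width 20 + 0.05 × query
length), and each band is resolved by local alignment of the query against
the banded subject window. Hits require identity ≥ 0.90 and query coverage
≥ 0.80 — the thresholds are package decisions, exposed in configuration,
since presence cut-offs for this kind of survey are rarely published. DNA
scoring is BLAST-like: match +1, mismatch −1, gap open −5, extend −1, with
the convention that a gap of length L costs `open + L·ext`.

Hits merge into loci (= copies) when they lie on the same replicon and
strand within `max_gap` = 2 kb *and* their query spans are compatible
(< 50% mutual overlap). The compatibility clause is what distinguishes
fragments of one diverged copy (which cover different parts of the query
and must merge) from two genuine tandem copies closer than `max_gap` (which
both cover the whole query and must not). At 1% background divergence a
≥ 200 bp copy essentially always retains exact 15-mers, which is why
planted-copy recall is exact in the benchmark.

## Domain scanning and the calibrated exclusion rule

Domains are modeled as fixed-length ungapped PSSMs in bits:
`log2((count + pc·bg) / ((n + pc)·bg))` with pseudocount 1 and a uniform
background; non-standard residues score 0 in every column. A profile HMM
would handle length variation, but the family's domains are fixed-length
here and the ungapped scan is exact and fast.

The inclusion threshold comes from a Monte-Carlo null: ~100 k residues of
background-generated decoys are scanned, and the threshold is the score at
which the expected number of decoy windows at or above it — rescaled to the
real query-set size (default 10 000 windows) — equals 1. Individual hits
additionally carry `expect_like`, the same rescaled expectation at their
own score, and hits with `expect_like` > 1 are excluded; this mirrors the
practice of discarding motif hits with E-value above 1. Overlapping windows
resolve greedily, best score first, ties to the leftmost start.

Classification by domain-set overlap: CCT alone → CMF; with B-box → CO;
with PRR → PRR; with GATA → GATA; with ZF → ZCCT; companion precedence
PRR > BBOX > ZF > GATA when several co-occur; a companion without CCT is
reported as BBOX_ONLY/PRR_ONLY and flagged as a potential CCT-domain
deletion.

## Exon-aware frameshift analysis

Each reference exon's CDS chunk is anchored in the locus by local alignment
downstream of the previous anchor (anchor requires identity ≥ 0.7, span
≥ 50% of the chunk, and score ≥ 0.5 × chunk length), then re-aligned
end-to-end against its window with free subject overhangs so internal
indels are called over the full exon. Unanchored exons are reported as
missing intervals. The variant CDS is the concatenation of the aligned
subject segments.

A frameshift is called iff the summed signed indel lengths ≢ 0 (mod 3). A
premature stop is the first stop in the variant translation before 90% of
the reference protein length — the 90% cut-off is a package decision that
tolerates C-terminal tail loss without flagging it.

**Alternative-start rescue** scans ATG codons downstream of the last
frame-disrupting indel, in the frame of the reference stop codon, and takes
the 5′-most one whose ORF runs uninterrupted to the original stop
(maximizing the retained product). Near-cognate starts are not considered.
The rescued protein is re-scanned for domains; if no ATG qualifies, the
retained domains are those of the truncated prefix product.

**Status reconciliation** is a total function applied in fixed order: no
locus → TRUE_DELETION; frameshift or premature stop → NATURAL_VARIANT;
CCT-coding region absent from the locus (a deletion covering ≥ 50% of the
domain interval, a missing exon over it, or overall identity below the
presence threshold) → PARTIAL_DOMAIN_LOSS; otherwise the genomic copy is
intact and the annotation decides: absent or domain-truncated annotated
protein → MISANNOTATION_CANDIDATE, full-length (≥ 90% of reference) with
the expected domains → CONSISTENT.

Extra copies are labeled against reference paralog sequences by highest
global-alignment identity, with an AMBIGUOUS call when the margin over the
runner-up is below 0.5 percentage points.

## Phylogenetics

Distances are p-distances (1 − identity) over global alignments (BLOSUM62,
open −11, extend −1 for proteins) with no rate correction — monotone with
divergence at the scales involved. Trees are built by classical
neighbor-joining on the Q criterion: ties in Q break to the smallest index
pair, negative branch-length estimates clamp to 0, the final three nodes
join at an unrooted trifurcation, and the two-taxon case is the single
edge (represented as two half-length pendant edges). NJ is consistent on
additive matrices, which is what the tests certify (exact patristic
recovery to 1e-9 on random 6–10-leaf trees); bootstrap support and
likelihood models are out of scope because the package's claims are about
clade membership and copy classification, not branch support.

## k-mer PCA

Per genotype, overlapping amino-acid 3-mers are counted across the
genotype's full protein complement (k-mers containing X/\*/gaps skipped)
and the row is normalized by its total count, so deletions, partial losses
and copy-number changes all shift the profile. PCA retains all non-trivial
dimensions (min(n − 1, columns)), which makes each off-centroid genotype's
cos² sum to exactly 1; cos² over Dims 1–2 (the plotted plane) is also
reported, since that is the quantity used for point coloring. Columns are
centered but not scaled by default: rows are already normalized
frequencies, and unit-variance scaling of near-zero-variance k-mer columns
is numerically unstable; a `scale` flag is provided because PCA tooling in
this field often standardizes by default, and neither behavior is asserted
as canonical. Identical rows yield a degenerate result (all coordinates and
cos² zero) with an explicit flag.

The driver ranking replaces a manual contrast-phylogeny step with a
statistic: for each family, each group's centroid k-mer profile is computed
from that family's sequences only and the family's divergence is the
Euclidean distance between centroids; families sort descending, ties
alphabetically, and a family absent from an entire group is scored against
the zero profile and flagged.

## Numerical conventions and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; GFF3 converts to
  1-based inclusive at the I/O boundary, and phases are validated to chain
  correctly across CDS records.
- Gap cost is `open + L·ext` (the opening penalty does not absorb the first
  extension); the alignment engine's parameters are mapped to this
  convention.
- Among equal-scoring alignments the engine's canonical traceback is taken;
  it is deterministic, which is what the reproducibility contract needs.
- Empty sequences: global alignment of an empty string is a single gap;
  local alignment with no positive-scoring pair returns the empty alignment
  with score 0.
- All randomness flows from one master seed; per-genotype and per-stage
  streams are derived from it, and a pipeline rerun with the same seed is
  hash-identical file for file (the manifest, which carries a timestamp, is
  excluded from that comparison).

## Problem sizes used in the test and acceptance runs

Module tests use 4 genotypes × 5 families on 80 kb; the planted-recovery
and acceptance checks use the default study conditions (12 × 8 × 0.5 Mb);
NJ consistency uses 50 random 6–10-leaf trees; driver ranking uses 20
seeded replicates of 5 + 5 genotypes; determinism uses two full pipeline
runs at 4 × 4 × 70 kb. These sizes were chosen so the full suite completes
in well under a minute of compute per stage on a single CPU while every
event kind still occurs multiple times per run.

## Known limitations

- The genomic search assumes assemblies small enough for an in-memory
  Python k-mer index; it is a desk-scale stand-in, not a BLAST replacement.
- Ungapped PSSMs cannot detect domain instances with internal indels; a
  1-residue loss inside a domain reads as domain absence (which is exactly
  how the partial-domain-loss status uses it, but limits generality).
- Exon anchoring can fail for very short exons (< ~14 bp) at high
  divergence; the simulator does not generate such exons.
- The alternative-start search is ATG-only and assumes the reference stop
  survives in the variant.
- p-distances saturate at high divergence; trees over distant families are
  interpreted for clade membership only.
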