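"""Assembly-level validation of gene families across a pangenome.

Annotation-independent checks per gene and genotype: genomic homology search
and copy counting, core/dispensable classification of the presence/absence
matrix, exon-aware CDS alignment for frameshift detection, alternative
translation-start rescue, reconciliation of genomic evidence with the
annotation (misannotation vs. natural variant vs. true deletion), labeling
of extra copies against reference paralog sequences, and the cross-tabulation
of gene presence against a genotype-level phenotype such as growth habit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import (
    Alignment,
    KmerIndex,
    Locus,
    ScoringScheme,
    dna_default,
    fit_align,
    local_align,
    global_align,
    merge_hits,
    reverse_complement,
    seed_extend_search,
    translate,
)
from .domains import PSSM, NullCalibration, scan


def _threshold_for(threshold, label: str):
    """Per-domain threshold: a mapping of label -> threshold/calibration, or
    one shared value."""
    if isinstance(threshold, Mapping):
        return threshold[label]
    return threshold

__all__ = [
    "SearchParams",
    "PresenceMatrix",
    "ExonAlignment",
    "FrameshiftReport",
    "CopyLabel",
    "GENE_STATUSES",
    "validate_gene",
    "build_presence_matrix",
    "extract_locus",
    "exon_aware_align_cds",
    "detect_frameshift",
    "rescue_alternative_start",
    "reconcile_with_annotation",
    "classify_copies_by_reference",
    "crosstab_presence_phenotype",
]

GENE_STATUSES = (
    "CONSISTENT",
    "MISANNOTATION_CANDIDATE",
    "NATURAL_VARIANT",
    "PARTIAL_DOMAIN_LOSS",
    "TRUE_DELETION",
)


@dataclass(frozen=True)
class SearchParams:
    """Thresholds for genomic presence calls.  Presence cut-offs for surveys
    of this kind are rarely published; these defaults are package decisions,
    exposed in configuration."""

    k_seed: int = 15
    min_identity: float = 0.90
    min_coverage: float = 0.80
    max_gap: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise ValueError("identity/coverage thresholds must lie in (0, 1]")


@dataclass
class PresenceMatrix:
    """Gene x genotype copy counts with core/dispensable classification.

    A gene is *core* iff it is present (count >= 1) in every genotype,
    *dispensable* otherwise.
    """

    counts: pd.DataFrame  # genes x genotypes, int

    @property
    def presence_counts(self) -> pd.Series:
        return (self.counts >= 1).sum(axis=1)

    @property
    def classes(self) -> pd.Series:
        core = self.presence_counts == self.counts.shape[1]
        return core.map({True: "core", False: "dispensable"})

    @property
    def n_core(self) -> int:
        return int((self.classes == "core").sum())

    @property
    def n_dispensable(self) -> int:
        return int((self.classes == "dispensable").sum())

    def presence_histogram(self) -> pd.Series:
        """Number of genes per presence count (supports statements such as
        'present in at least k genotypes')."""
        return self.presence_counts.value_counts().sort_index()


def validate_gene(
    query_id: str,
    query_seq: str,
    genotype_indexes: Mapping[str, KmerIndex],
    params: SearchParams = SearchParams(),
    scheme: Optional[ScoringScheme] = None,
) -> Dict[str, List[Locus]]:
    """Search one gene's genomic sequence across all genotype assemblies and
    merge hits into loci; the locus count per genotype is the copy count."""
    scheme = scheme or dna_default()
    out: Dict[str, List[Locus]] = {}
    for gid, index in genotype_indexes.items():
        hits = seed_extend_search(
            query_seq,
            index,
            k_seed=params.k_seed,
            scheme=scheme,
            min_identity=params.min_identity,
            min_coverage=params.min_coverage,
            query_id=query_id,
            genotype_id=gid,
        )
        out[gid] = merge_hits(hits, max_gap=params.max_gap)
    return out


def build_presence_matrix(
    validation: Mapping[str, Mapping[str, Sequence[Locus]]]
) -> PresenceMatrix:
    """``validation[gene][genotype]`` -> loci.  Requires every gene to carry
    the same genotype set."""
    genes = list(validation)
    genotype_sets = {frozenset(validation[g]) for g in genes}
    if len(genotype_sets) > 1:
        raise ValueError("inconsistent genotype columns across genes")
    genotypes = sorted(validation[genes[0]]) if genes else []
    counts = pd.DataFrame(
        [[len(validation[g][gt]) for gt in genotypes] for g in genes],
        index=genes,
        columns=genotypes,
        dtype=int,
    )
    return PresenceMatrix(counts)


def extract_locus(assembly: Mapping[str, str], locus: Locus, pad: int = 50) -> str:
    seq = assembly[locus.replicon_id]
    s = max(0, locus.start - pad)
    e = min(len(seq), locus.end + pad)
    sub = seq[s:e]
    return sub if locus.strand == "+" else reverse_complement(sub)


@dataclass
class ExonAlignment:
    """Concatenated exon-anchored alignment of a reference CDS to a locus."""

    per_exon: List[Optional[Alignment]]
    exon_offsets: List[int]              # CDS offset of each reference exon
    missing_exons: List[int]
    indels: List[Tuple[int, int, int]]   # (ref_cds_pos, variant_pos, signed_len)
    identity: float
    variant_cds: str                     # spliced subject sequence
    ref_cds_len: int

    @property
    def net_shift(self) -> int:
        return sum(l for _, _, l in self.indels) % 3


def exon_aware_align_cds(
    cds_chunks: Sequence[str],
    locus_seq: str,
    scheme: Optional[ScoringScheme] = None,
    min_anchor_identity: float = 0.7,
) -> ExonAlignment:
    """Anchor each reference exon in the locus and concatenate the alignments.

    Each exon chunk is located by local alignment downstream of the previous
    anchor, then re-aligned end-to-end against its window (subject overhangs
    free) so internal indels are called over the full exon.  Exons that fail
    to anchor are reported as missing.
    """
    scheme = scheme or dna_default()
    per_exon: List[Optional[Alignment]] = []
    offsets: List[int] = []
    missing: List[int] = []
    indels: List[Tuple[int, int, int]] = []
    var_parts: List[str] = []
    matches = 0
    columns = 0
    search_start = 0
    cds_offset = 0
    for idx, chunk in enumerate(cds_chunks):
        offsets.append(cds_offset)
        window_seq = locus_seq[search_start:]
        anchor = local_align(chunk, window_seq, scheme)
        span = anchor.query_span
        match_score = (scheme.substitution[0]
                       if isinstance(scheme.substitution, tuple) else 1.0)
        anchored = (
            bool(anchor.aligned_a)
            and anchor.identity >= min_anchor_identity
            and (span[1] - span[0]) >= 0.5 * len(chunk)
            and anchor.score >= 0.5 * len(chunk) * match_score
        )
        if not anchored:
            per_exon.append(None)
            missing.append(idx)
            cds_offset += len(chunk)
            continue
        # Window around the anchor sized to admit the unaligned chunk ends.
        w0 = max(0, search_start + anchor.subject_span[0] - span[0] - 10)
        w1 = min(len(locus_seq),
                 search_start + anchor.subject_span[1] + (len(chunk) - span[1]) + 10)
        aln = fit_align(chunk, locus_seq[w0:w1], scheme)
        per_exon.append(aln)
        var_before = sum(len(p) for p in var_parts)
        seg = aln.aligned_b.replace("-", "")
        var_parts.append(seg)
        apos = 0  # position within chunk
        bpos = 0  # position within aligned subject segment
        i = 0
        n = len(aln.aligned_a)
        while i < n:
            ca, cb = aln.aligned_a[i], aln.aligned_b[i]
            if ca == "-":
                j = i
                while j < n and aln.aligned_a[j] == "-":
                    j += 1
                indels.append((cds_offset + apos, var_before + bpos, j - i))
                bpos += j - i
                i = j
            elif cb == "-":
                j = i
                while j < n and aln.aligned_b[j] == "-":
                    j += 1
                indels.append((cds_offset + apos, var_before + bpos, -(j - i)))
                apos += j - i
                i = j
            else:
                if ca == cb:
                    matches += 1
                apos += 1
                bpos += 1
                i += 1
        columns += n
        search_start = w0 + aln.subject_span[1]
        cds_offset += len(chunk)
    return ExonAlignment(
        per_exon=per_exon,
        exon_offsets=offsets,
        missing_exons=missing,
        indels=indels,
        identity=matches / columns if columns else 0.0,
        variant_cds="".join(var_parts),
        ref_cds_len=sum(len(c) for c in cds_chunks),
    )


@dataclass
class FrameshiftReport:
    """Indel inventory for one (gene, genotype) locus, with frame effect,
    premature-stop call and (after rescue) the alternative-start fields."""

    gene: str
    genotype: str
    indels: List[Tuple[int, int]]        # (ref CDS position, signed length)
    net_shift: int
    frameshift: bool
    premature_stop: Optional[int]        # aa index of the first early stop
    alt_start: Optional[int] = None      # variant-CDS position of rescue ATG
    rescued_protein: Optional[str] = None
    retained_domains: List[str] = field(default_factory=list)


def detect_frameshift(
    alignment: ExonAlignment,
    ref_protein_len: int,
    gene: str = "",
    genotype: str = "",
    premature_fraction: float = 0.9,
) -> FrameshiftReport:
    """Frameshift iff the summed indel lengths are not 0 mod 3; the premature
    stop is the first stop in the variant translation that falls before
    ``premature_fraction`` of the reference protein length."""
    net = alignment.net_shift
    pep = translate(alignment.variant_cds)
    stop = pep.find("*")
    premature: Optional[int] = None
    if 0 <= stop < premature_fraction * ref_protein_len:
        premature = stop
    return FrameshiftReport(
        gene=gene,
        genotype=genotype,
        indels=[(rp, ln) for rp, _, ln in alignment.indels],
        net_shift=net,
        frameshift=net != 0,
        premature_stop=premature,
    )


def rescue_alternative_start(
    report: FrameshiftReport,
    alignment: ExonAlignment,
    pssms: Sequence[PSSM],
    threshold,
) -> FrameshiftReport:
    """Look for a downstream in-frame ATG restoring the reference frame.

    Scans ATG codons downstream of the last frame-disrupting indel, in the
    frame of the reference stop codon, and selects the 5'-most one whose ORF
    runs uninterrupted to the original stop.  The rescued protein is
    re-scanned for domains; without a qualifying ATG, the retained domains
    are those of the truncated prefix product.
    """
    var = alignment.variant_cds
    L = len(var)

    def _domains(protein: str) -> List[str]:
        if not protein:
            return []
        found = []
        for pssm in pssms:
            if scan(pssm, protein, _threshold_for(threshold, pssm.label)):
                found.append(pssm.label)
        return found

    if not report.frameshift:
        return report
    shifting = [vp for _, vp, ln in alignment.indels if ln % 3 != 0]
    search_from = (max(shifting) + 1) if shifting else 0
    alt = None
    rescued = None
    for p in range(search_from, L - 2):
        if (L - p) % 3 != 0 or var[p:p + 3] != "ATG":
            continue
        pep = translate(var[p:])
        body = pep[:-1] if pep.endswith("*") else pep
        if "*" in body:
            continue
        alt, rescued = p, body
        break
    report.alt_start = alt
    report.rescued_protein = rescued
    if rescued is not None:
        report.retained_domains = _domains(rescued)
    else:
        pep = translate(var)
        stop = pep.find("*")
        prefix = pep if stop < 0 else pep[:stop]
        report.retained_domains = _domains(prefix)
    return report


def reconcile_with_annotation(
    loci: Sequence[Locus],
    alignment: Optional[ExonAlignment],
    report: Optional[FrameshiftReport],
    annotated_protein: Optional[str],
    ref_protein: str,
    architecture: Sequence[str],
    domain_cds: Mapping[str, Tuple[int, int]],
    pssms: Sequence[PSSM],
    threshold,
    identity_threshold: float = 0.9,
) -> str:
    """Assign exactly one status per (gene, genotype).

    Decision order: no locus at all -> TRUE_DELETION; genomic frameshift or
    premature stop -> NATURAL_VARIANT; CCT-coding region absent from the
    locus (large in-frame deletion or missing exon over the domain) ->
    PARTIAL_DOMAIN_LOSS; otherwise the genomic copy is intact and the status
    follows the annotation: a missing or domain-truncated annotated protein
    is a MISANNOTATION_CANDIDATE, a full-length one with the expected domain
    architecture is CONSISTENT.
    """
    if not loci or alignment is None:
        return "TRUE_DELETION"
    if not alignment.per_exon or all(a is None for a in alignment.per_exon):
        return "TRUE_DELETION"
    if report is not None and (report.frameshift or report.premature_stop is not None):
        return "NATURAL_VARIANT"

    d0, d1 = domain_cds.get("CCT", (0, 0))
    domain_absent = False
    for ref_pos, _vp, ln in alignment.indels:
        if ln < 0:
            ov = min(d1, ref_pos - ln) - max(d0, ref_pos)
            if d1 > d0 and ov >= 0.5 * (d1 - d0):
                domain_absent = True
    for idx in alignment.missing_exons:
        s = alignment.exon_offsets[idx]
        e = (alignment.exon_offsets[idx + 1]
             if idx + 1 < len(alignment.exon_offsets) else alignment.ref_cds_len)
        ov = min(d1, e) - max(d0, s)
        if d1 > d0 and ov >= 0.5 * (d1 - d0):
            domain_absent = True
    if domain_absent or alignment.identity < identity_threshold:
        return "PARTIAL_DOMAIN_LOSS"

    if annotated_protein is None:
        return "MISANNOTATION_CANDIDATE"
    found = (
        {p.label for p in pssms
         if scan(p, annotated_protein, _threshold_for(threshold, p.label))}
        if annotated_protein else set()
    )
    full_length = len(annotated_protein) >= 0.9 * len(ref_protein)
    if set(architecture) <= found and full_length:
        return "CONSISTENT"
    return "MISANNOTATION_CANDIDATE"


@dataclass
class CopyLabel:
    locus_id: str
    label: str                  # reference label or "AMBIGUOUS"
    best_identity: float
    second_identity: float


def classify_copies_by_reference(
    loci_seqs: Mapping[str, str],
    references: Mapping[str, str],
    scheme: Optional[ScoringScheme] = None,
    margin: float = 0.005,
) -> List[CopyLabel]:
    """Assign each locus the reference paralog with the highest global
    alignment identity; within ``margin`` (0.5 percentage points) of the
    runner-up the call is AMBIGUOUS."""
    if not references:
        raise ValueError("empty reference set")
    if len(references) < 2:
        raise ValueError("need >= 2 references")
    scheme = scheme or dna_default()
    out: List[CopyLabel] = []
    for locus_id, seq in loci_seqs.items():
        idents = sorted(
            ((global_align(seq, ref, scheme).identity, label)
             for label, ref in references.items()),
            key=lambda t: (-t[0], t[1]),
        )
        best, second = idents[0], idents[1]
        label = best[1] if best[0] - second[0] >= margin else "AMBIGUOUS"
        out.append(CopyLabel(locus_id, label, best[0], second[0]))
    return out


def crosstab_presence_phenotype(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    gene: str,
) -> pd.DataFrame:
    """Contingency table of presence/absence of ``gene`` against a genotype
    phenotype label (e.g. growth habit); unlabeled genotypes count under
    'unknown'."""
    counts = matrix.counts.loc[gene]
    presence = counts.map(lambda c: "present" if c >= 1 else "absent")
    phenotype = pd.Series(
        {gt: labels.get(gt, "unknown") for gt in counts.index}, name="phenotype"
    )
    table = pd.crosstab(presence, phenotype)
    table.index.name = "presence"
    for row in ("present", "absent"):
        if row not in table.index:
            table.loc[row] = 0
    return table.loc[["present", "absent"]].sort_index(axis=1)
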