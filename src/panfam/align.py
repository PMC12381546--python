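"""Sequence primitives: affine-gap alignment, translation, ORF finding, and
seed-and-extend genomic homology search.

The pairwise aligners wrap :class:`Bio.Align.PairwiseAligner`; the gap cost
convention used throughout the package is that a gap of length ``L`` costs
``gap_open + L * gap_extend`` (the opening penalty does *not* absorb the first
extension step).  The seed-and-extend search is a light-weight BLASTn-style
homolog finder: an exact k-mer index of the subject replicons is chained per
diagonal band and candidate regions are resolved by local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from Bio import Align as _bio_align
from Bio.Align import substitution_matrices as _submat
from Bio.Data import CodonTable as _codon_table

__all__ = [
    "ScoringScheme",
    "Alignment",
    "GenomicHit",
    "Locus",
    "KmerIndex",
    "dna_default",
    "protein_default",
    "global_align",
    "local_align",
    "reverse_complement",
    "translate",
    "find_orfs",
    "seed_extend_search",
    "merge_hits",
]

DNA_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_STANDARD_TABLE = _codon_table.standard_dna_table
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    ``substitution`` is either a ``(match, mismatch)`` pair or the name of a
    Biopython substitution matrix (e.g. ``"BLOSUM62"``).  ``gap_open`` and
    ``gap_extend`` are non-positive; a gap of length L costs
    ``gap_open + L * gap_extend``.
    """

    substitution: Union[Tuple[float, float], str]
    gap_open: float
    gap_extend: float
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be <= gap_extend")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")


def dna_default() -> ScoringScheme:
    """BLASTn-like DNA scheme: match +1, mismatch -1, gap open -5, extend -1."""
    return ScoringScheme((1.0, -1.0), -5.0, -1.0, "dna")


def protein_default() -> ScoringScheme:
    """BLASTp-like protein scheme: BLOSUM62, gap open -11, extend -1."""
    return ScoringScheme("BLOSUM62", -11.0, -1.0, "protein")


@dataclass
class Alignment:
    """A pairwise alignment of a (query) against b (subject).

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; ``identity``
    is the fraction of aligned columns whose residues are equal (gap columns
    count in the denominator); spans are 0-based half-open on the inputs.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    query_span: Tuple[int, int]
    subject_span: Tuple[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def indels(self) -> List[Tuple[int, int]]:
        """Indels as ``(position_on_a, signed_length)``.

        A gap run in ``aligned_a`` is an insertion in the subject (+length,
        anchored at the a-position the run follows); a gap run in
        ``aligned_b`` is a deletion from the subject (-length, anchored at the
        first deleted a-position).
        """
        out: List[Tuple[int, int]] = []
        apos = self.query_span[0]
        i = 0
        n = self.n_columns
        while i < n:
            ca, cb = self.aligned_a[i], self.aligned_b[i]
            if ca == "-":
                j = i
                while j < n and self.aligned_a[j] == "-":
                    j += 1
                out.append((apos, j - i))
                i = j
            elif cb == "-":
                j = i
                while j < n and self.aligned_b[j] == "-":
                    j += 1
                out.append((apos, -(j - i)))
                apos += j - i
                i = j
            else:
                apos += 1
                i += 1
        return out


@dataclass
class GenomicHit:
    """One seed-and-extend hit of a query on a subject replicon."""

    query_id: str
    genotype_id: Optional[str]
    replicon_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float
    query_span: Optional[Tuple[int, int]] = None


@dataclass
class Locus:
    """A merged interval of hits; one locus corresponds to one gene copy."""

    replicon_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float
    score: float


def _make_aligner(scheme: ScoringScheme, mode: str) -> _bio_align.PairwiseAligner:
    al = _bio_align.PairwiseAligner()
    al.mode = mode
    if isinstance(scheme.substitution, str):
        al.substitution_matrix = _submat.load(scheme.substitution)
    else:
        match, mismatch = scheme.substitution
        al.match_score = match
        al.mismatch_score = mismatch
    # Biopython's open score is the cost of the first gap position; map the
    # gap_open + L*gap_extend convention onto it.
    al.open_gap_score = scheme.gap_open + scheme.gap_extend
    al.extend_gap_score = scheme.gap_extend
    return al


def _column_identity(a: str, b: str) -> float:
    if not a:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def _from_bio(a: str, b: str, bio_alignment) -> Alignment:
    ga, gb = str(bio_alignment[0]), str(bio_alignment[1])
    blocks_a, blocks_b = bio_alignment.aligned
    if len(blocks_a):
        span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
        span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    else:
        span_a = (0, 0)
        span_b = (0, 0)
    return Alignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(bio_alignment.score),
        identity=_column_identity(ga, gb),
        query_span=span_a,
        subject_span=span_b,
    )


def global_align(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> Alignment:
    """Optimal affine-gap global (Needleman-Wunsch/Gotoh) alignment."""
    scheme = scheme or dna_default()
    if not a or not b:
        # One row is a single gap spanning the other sequence.
        other = a or b
        score = 0.0 if not other else scheme.gap_open + len(other) * scheme.gap_extend
        ga = a or "-" * len(b)
        gb = b or "-" * len(a)
        return Alignment(ga, gb, score, 0.0, (0, len(a)), (0, len(b)))
    res = _make_aligner(scheme, "global").align(a, b)
    return _from_bio(a, b, res[0])


def local_align(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> Alignment:
    """Optimal affine-gap local (Smith-Waterman) alignment; empty alignment
    with score 0 is allowed."""
    scheme = scheme or dna_default()
    if not a or not b:
        return Alignment("", "", 0.0, 0.0, (0, 0), (0, 0))
    res = _make_aligner(scheme, "local").align(a, b)
    try:
        best = res[0]
    except IndexError:  # no positive-scoring pair at all
        return Alignment("", "", 0.0, 0.0, (0, 0), (0, 0))
    if best.score <= 0:
        return Alignment("", "", 0.0, 0.0, (0, 0), (0, 0))
    # In local mode Biopython renders only the aligned region.
    return _from_bio(a, b, best)


def fit_align(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> Alignment:
    """Align all of ``a`` end-to-end against a window of ``b``.

    Unaligned overhangs of ``b`` are free, so internal indels within ``a``
    are called over its full length (used for per-exon CDS alignment)."""
    scheme = scheme or dna_default()
    if not a or not b:
        return Alignment("", "", 0.0, 0.0, (0, 0), (0, 0))
    al = _make_aligner(scheme, "global")
    al.end_insertion_score = 0.0  # b overhangs beyond a cost nothing
    res = al.align(a, b)
    full = res[0]
    ga, gb = str(full[0]), str(full[1])
    blocks_a, blocks_b = full.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    # Trim the free b-overhang columns so the gapped strings cover only the
    # aligned window.
    lead = 0
    while lead < len(ga) and ga[lead] == "-":
        lead += 1
    tail = len(ga)
    while tail > lead and ga[tail - 1] == "-":
        tail -= 1
    ga, gb = ga[lead:tail], gb[lead:tail]
    return Alignment(
        aligned_a=ga,
        aligned_b=gb,
        score=float(full.score),
        identity=_column_identity(ga, gb),
        query_span=span_a,
        subject_span=span_b,
    )


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, strand: str = "+") -> str:
    """Translate with the standard genetic code.

    Stops render as ``'*'``; any codon containing a non-ACGT base renders as
    ``'X'``; a trailing partial codon is ignored.  ``strand == '-'`` translates
    the reverse complement, with ``frame`` counted from its 5' end.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    s = dna.upper() if strand == "+" else reverse_complement(dna.upper())
    s = s[frame:]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def find_orfs(dna: str, min_aa: int) -> List[Tuple[int, str, int, int, str]]:
    """All ATG-to-stop ORFs in six frames.

    Returns ``(frame, strand, start, end, peptide)`` tuples; coordinates are
    0-based half-open on the *forward* strand and include the stop codon; the
    peptide excludes the stop.  Only ORFs with a stop codon are reported.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    dna = dna.upper()
    n = len(dna)
    out: List[Tuple[int, str, int, int, str]] = []
    for strand in "+-":
        s = dna if strand == "+" else reverse_complement(dna)
        for frame in range(3):
            starts: List[int] = []
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                aa = _CODON_TO_AA.get(codon, "X")
                if codon == "ATG":
                    starts.append(i)
                if aa == "*":
                    for st in starts:
                        pep = translate(s[st : i + 3])[:-1]
                        if len(pep) >= min_aa:
                            if strand == "+":
                                out.append((frame, "+", st, i + 3, pep))
                            else:
                                out.append((frame, "-", n - (i + 3), n - st, pep))
                    starts = []
    out.sort(key=lambda t: (t[2], t[3], t[1]))
    return out


class KmerIndex:
    """Exact k-mer position index over a set of subject replicons."""

    def __init__(self, replicons: Mapping[str, str], k: int = 15):
        if k < 8:
            raise ValueError("k_seed must be >= 8")
        self.k = k
        self.replicons = {rid: seq.upper() for rid, seq in replicons.items()}
        self._index: dict = {}
        for rid, seq in self.replicons.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((rid, i))

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _band_width(query_len: int) -> int:
    # Tolerates planted indels without a full-matrix DP.
    return int(20 + 0.05 * query_len)


def _cluster_seeds(
    seeds: List[Tuple[int, int]], band: int, max_seed_gap: int
) -> List[List[Tuple[int, int]]]:
    """Group (diagonal, subject_pos) seeds into diagonal-band clusters."""
    seeds = sorted(seeds)
    clusters: List[List[Tuple[int, int]]] = []
    for d, pos in seeds:
        placed = False
        for cl in clusters:
            if abs(d - cl[-1][0]) <= band and abs(pos - cl[-1][1]) <= max_seed_gap:
                cl.append((d, pos))
                placed = True
                break
        if not placed:
            clusters.append([(d, pos)])
    return clusters


def seed_extend_search(
    query: str,
    subject: Union[KmerIndex, Mapping[str, str]],
    k_seed: int = 15,
    scheme: Optional[ScoringScheme] = None,
    min_identity: float = 0.9,
    min_coverage: float = 0.8,
    query_id: str = "query",
    genotype_id: Optional[str] = None,
) -> List[GenomicHit]:
    """BLASTn-style search of ``query`` against subject replicons.

    Exact ``k_seed``-mers of the query (both strands) are looked up in the
    subject index, chained per diagonal band, and each candidate region is
    scored by local alignment.  Hits are reported iff
    ``identity >= min_identity`` and ``coverage >= min_coverage`` and are
    sorted by score descending.
    """
    query = query.upper()
    index = subject if isinstance(subject, KmerIndex) else KmerIndex(subject, k_seed)
    k = index.k
    if len(query) < k:
        raise ValueError("query shorter than k_seed")
    scheme = scheme or dna_default()
    band = _band_width(len(query))
    hits: List[GenomicHit] = []
    for strand in "+-":
        q = query if strand == "+" else reverse_complement(query)
        by_replicon: dict = {}
        for i in range(len(q) - k + 1):
            for rid, pos in index.lookup(q[i : i + k]):
                by_replicon.setdefault(rid, []).append((pos - i, pos))
        for rid, seeds in by_replicon.items():
            subj = index.replicons[rid]
            for cl in _cluster_seeds(seeds, band, len(q) + band):
                diags = [d for d, _ in cl]
                lo = min(p for _, p in cl)
                hi = max(p for _, p in cl) + k
                est_start = min(diags)
                est_end = max(diags) + len(q)
                w0 = max(0, min(lo, est_start) - band)
                w1 = min(len(subj), max(hi, est_end) + band)
                window = subj[w0:w1]
                aln = local_align(q, window, scheme)
                if not aln.aligned_a:
                    continue
                qspan = aln.query_span
                coverage = (qspan[1] - qspan[0]) / len(q)
                if aln.identity < min_identity or coverage < min_coverage:
                    continue
                s0 = w0 + aln.subject_span[0]
                s1 = w0 + aln.subject_span[1]
                if strand == "+":
                    fwd_qspan = qspan
                else:
                    fwd_qspan = (len(q) - qspan[1], len(q) - qspan[0])
                hits.append(
                    GenomicHit(
                        query_id=query_id,
                        genotype_id=genotype_id,
                        replicon_id=rid,
                        start=s0,
                        end=s1,
                        strand=strand,
                        identity=aln.identity,
                        coverage=coverage,
                        score=aln.score,
                        query_span=fwd_qspan,
                    )
                )
    # Deduplicate near-identical hits from adjacent seed clusters.
    hits.sort(key=lambda h: (-h.score, h.replicon_id, h.start))
    kept: List[GenomicHit] = []
    for h in hits:
        redundant = False
        for other in kept:
            if other.replicon_id != h.replicon_id or other.strand != h.strand:
                continue
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov > 0.5 * min(h.end - h.start, other.end - other.start):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def _query_overlap_fraction(
    span: Optional[Tuple[int, int]], covered: List[Tuple[int, int]]
) -> float:
    if span is None or not covered:
        return 0.0
    ov = 0
    for s, e in covered:
        ov += max(0, min(e, span[1]) - max(s, span[0]))
    return ov / max(1, span[1] - span[0])


def merge_hits(hits: Sequence[GenomicHit], max_gap: int = 2000) -> List[Locus]:
    """Merge hits into loci; one locus per gene copy.

    Hits on the same replicon and strand whose subject intervals overlap or
    lie within ``max_gap`` merge into one locus *provided* their query spans
    are compatible (fragments of one copy cover different parts of the query).
    Two full-length hits -- two genuine copies -- are never merged, even when
    they sit closer than ``max_gap`` (the tandem-duplication case).  The
    result is independent of input order and idempotent.
    """
    groups: dict = {}
    for h in hits:
        groups.setdefault((h.replicon_id, h.strand), []).append(h)
    loci: List[Locus] = []
    for (rid, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: (h.start, h.end))
        current: Optional[Locus] = None
        covered: List[Tuple[int, int]] = []
        for h in group:
            if current is not None and h.start - current.end <= max_gap:
                if _query_overlap_fraction(h.query_span, covered) < 0.5:
                    current.end = max(current.end, h.end)
                    current.identity = max(current.identity, h.identity)
                    current.coverage = max(current.coverage, h.coverage)
                    current.score = max(current.score, h.score)
                    if h.query_span is not None:
                        covered.append(h.query_span)
                    continue
            if current is not None:
                loci.append(current)
            current = Locus(rid, h.start, h.end, strand, h.identity, h.coverage, h.score)
            covered = [h.query_span] if h.query_span is not None else []
        if current is not None:
            loci.append(current)
    loci.sort(key=lambda l: (l.replicon_id, l.start, l.strand))
    return loci
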