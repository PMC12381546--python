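"""Synthetic pangenome generator with planted, machine-readable variation.

The generator emulates the variation phenomena reported for cereal CCT-motif
gene families at desk scale: a founder set of gene families sharing domain
motifs (CCT plus optional B-box/PRR/GATA/zinc-finger companions) is placed on
a random genomic background, and each simulated genotype then accumulates
per-gene events -- whole-gene deletions (PAV), tandem and dispersed
duplications (CNV), 1-bp coding indels (frameshifts), in-frame 3-bp indels,
partial deletions of the CCT domain, and annotation truncations that leave
the genomic sequence intact while dropping the first and last exon from the
annotation (the misannotation case).  Every planted event is recorded in a
truth table so the downstream validation pipeline can be scored exactly.

Founder proteins follow a fixed layout: Met, N-linker, companion domain (if
any), a linker containing a single internal Met (the alternative-start codon
that rescues downstream frames), the CCT domain near the C terminus, and a
short tail.  1-bp indels are planted upstream of that internal Met so that
every planted frameshift has a qualifying downstream in-frame ATG preceding
an intact CCT-coding region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .align import global_align, protein_default, translate
from .domains import AMINO_ACIDS

__all__ = [
    "EVENT_KINDS",
    "SimConfig",
    "DomainTemplate",
    "TruthRow",
    "FounderGene",
    "FounderSet",
    "Genotype",
    "SyntheticPangenome",
    "make_domain_library",
    "sample_instance",
    "build_founder_genes",
    "evolve_genotype",
    "simulate_pangenome",
    "write_pangenome",
    "read_pangenome",
    "mutate_protein",
    "founder_protein_cohort",
    "driver_cohort",
]

EVENT_KINDS = (
    "deletion",
    "tandem_duplication",
    "dispersed_duplication",
    "indel_1bp",
    "indel_3bp",
    "domain_deletion",
    "annotation_truncation",
)

DOMAIN_LABELS = ("CCT", "BBOX", "PRR", "ZF", "GATA")
_ARCHITECTURES = (("CCT",), ("CCT", "BBOX"), ("CCT", "PRR"), ("CCT", "GATA"), ("CCT", "ZF"))
_ARCH_TAG = {("CCT",): "CMF", ("CCT", "BBOX"): "CO", ("CCT", "PRR"): "PRR",
             ("CCT", "GATA"): "GATA", ("CCT", "ZF"): "ZCCT"}
_COMPANION = {"CO": "BBOX", "PRR": "PRR", "GATA": "GATA", "ZCCT": "ZF"}

_DNA = np.frombuffer(b"ACGT", dtype="S1")

# Codon choices per residue (standard code), in a fixed order for determinism.
_CODONS: Dict[str, List[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = translate(_codon)
            _CODONS.setdefault(_aa, []).append(_codon)
_STOP_CODONS = tuple(_CODONS["*"])


@dataclass
class SimConfig:
    """Simulation parameters; the defaults define the study conditions used
    throughout the tests (12 genotypes, 8 families, 0.5 Mb per genotype)."""

    n_genotypes: int = 12
    n_families: int = 8
    genome_length: int = 500_000
    exons_per_gene: Tuple[int, int] = (3, 4)
    substitution_rate: float = 0.01
    event_rates: Dict[str, float] = field(default_factory=lambda: {
        "deletion": 0.08,
        "tandem_duplication": 0.06,
        "dispersed_duplication": 0.05,
        "indel_1bp": 0.10,
        "indel_3bp": 0.05,
        "domain_deletion": 0.06,
        "annotation_truncation": 0.08,
    })
    duplicate_divergence: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[0] > self.exons_per_gene[1]:
            raise ValueError("invalid exons_per_gene range")
        unknown = set(self.event_rates) - set(EVENT_KINDS)
        if unknown:
            raise ValueError(f"unknown event kinds: {sorted(unknown)}")
        for kind in EVENT_KINDS:
            self.event_rates.setdefault(kind, 0.0)
        for name, rate in [("substitution_rate", self.substitution_rate),
                           ("duplicate_divergence", self.duplicate_divergence),
                           *self.event_rates.items()]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {name} out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_genotypes": self.n_genotypes,
            "n_families": self.n_families,
            "genome_length": self.genome_length,
            "exons_per_gene": list(self.exons_per_gene),
            "substitution_rate": self.substitution_rate,
            "event_rates": {k: self.event_rates[k] for k in EVENT_KINDS},
            "duplicate_divergence": self.duplicate_divergence,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["exons_per_gene"] = tuple(d["exons_per_gene"])
        return cls(**d)


@dataclass
class DomainTemplate:
    label: str
    consensus: str
    per_position_variability: np.ndarray  # per-column substitution probability


@dataclass
class TruthRow:
    family_id: str
    genotype_id: str
    event: str
    chrom: str
    start: int
    end: int
    detail: dict = field(default_factory=dict)


@dataclass
class FounderGene:
    family_id: str
    architecture: Tuple[str, ...]
    protein: str          # without the terminal stop
    cds: str              # including the stop codon
    exon_lengths: List[int]
    intron_seqs: List[str]
    domain_aa: Dict[str, Tuple[int, int]]
    mid_met_aa: int
    safe_windows_upstream: List[Tuple[int, int]]  # CDS nt windows before mid Met
    safe_windows_all: List[Tuple[int, int]]

    @property
    def cds_len(self) -> int:
        return len(self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)

    def exon_cds_bounds(self) -> List[Tuple[int, int]]:
        out, pos = [], 0
        for L in self.exon_lengths:
            out.append((pos, pos + L))
            pos += L
        return out

    def gene_seq(self, cds: Optional[str] = None,
                 exon_lengths: Optional[List[int]] = None) -> str:
        cds = self.cds if cds is None else cds
        exon_lengths = self.exon_lengths if exon_lengths is None else exon_lengths
        parts, pos = [], 0
        for i, L in enumerate(exon_lengths):
            parts.append(cds[pos:pos + L])
            pos += L
            if i < len(self.intron_seqs):
                parts.append(self.intron_seqs[i])
        return "".join(parts)

    def exons_rel(self, exon_lengths: Optional[List[int]] = None) -> List[Tuple[int, int]]:
        exon_lengths = self.exon_lengths if exon_lengths is None else exon_lengths
        out, pos = [], 0
        for i, L in enumerate(exon_lengths):
            out.append((pos, pos + L))
            pos += L
            if i < len(self.intron_seqs):
                pos += len(self.intron_seqs[i])
        return out

    def cds_chunks(self) -> List[str]:
        return [self.cds[s:e] for s, e in self.exon_cds_bounds()]


@dataclass
class FounderSet:
    templates: List[DomainTemplate]
    genes: List[FounderGene]
    spacers: List[str]

    def assembly(self) -> Dict[str, str]:
        parts = []
        for i, sp in enumerate(self.spacers):
            parts.append(sp)
            if i < len(self.genes):
                parts.append(self.genes[i].gene_seq())
        return {"chr1": "".join(parts)}

    def gene_models(self) -> List[pio.GeneModel]:
        models, pos = [], 0
        for i, sp in enumerate(self.spacers):
            pos += len(sp)
            if i < len(self.genes):
                g = self.genes[i]
                seq = g.gene_seq()
                models.append(_make_model(g, g.exon_lengths, pos, first_phase=0))
                pos += len(seq)
        return models

    def proteins(self) -> Dict[str, str]:
        return {g.family_id: g.protein for g in self.genes}


@dataclass
class Genotype:
    genotype_id: str
    assembly: Dict[str, str]
    genes: List[pio.GeneModel]
    proteins: Dict[str, str]
    truth: List[TruthRow]


@dataclass
class SyntheticPangenome:
    config: SimConfig
    founder: FounderSet
    genotypes: List[Genotype]

    @property
    def truth(self) -> pd.DataFrame:
        rows = [
            {"family_id": r.family_id, "genotype": r.genotype_id, "event": r.event,
             "chrom": r.chrom, "start": r.start, "end": r.end,
             "detail": json.dumps(r.detail, sort_keys=True)}
            for g in self.genotypes for r in g.truth
        ]
        return pd.DataFrame(
            rows, columns=["family_id", "genotype", "event", "chrom", "start",
                           "end", "detail"],
        )


# ---------------------------------------------------------------------------
# Domain library and founder construction
# ---------------------------------------------------------------------------

def _random_peptide(rng: np.random.Generator, length: int, forbid: str = "") -> str:
    alphabet = [a for a in AMINO_ACIDS if a not in forbid]
    return "".join(rng.choice(alphabet) for _ in range(length))


def make_domain_library(seed: int = 0, length: int = 24) -> List[DomainTemplate]:
    """Five mutually dissimilar domain consensus peptides (pairwise
    global-alignment identity < 0.4), with per-column substitution tolerance."""
    rng = np.random.default_rng(seed)
    scheme = protein_default()
    templates: List[DomainTemplate] = []
    for label in DOMAIN_LABELS:
        for _attempt in range(100):
            consensus = _random_peptide(rng, length, forbid="M")
            ok = all(
                global_align(consensus, t.consensus, scheme).identity < 0.4
                for t in templates
            )
            if ok:
                break
        else:  # pragma: no cover - random peptides essentially never collide
            raise RuntimeError("could not generate dissimilar domain consensus")
        variability = rng.uniform(0.0, 0.12, size=length)
        variability[rng.choice(length, size=length // 3, replace=False)] = 0.0
        templates.append(DomainTemplate(label, consensus, variability))
    return templates


def sample_instance(template: DomainTemplate, rng: np.random.Generator) -> str:
    """One domain instance: the consensus with per-column tolerant substitutions."""
    out = []
    for aa, p in zip(template.consensus, template.per_position_variability):
        if rng.random() < p:
            choices = [a for a in AMINO_ACIDS if a != aa and a != "M"]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def build_founder_genes(templates: Sequence[DomainTemplate],
                        config: SimConfig) -> FounderSet:
    """Construct founder genes (one per family) and the genomic background.

    Each founder has an exon/intron model, a CDS starting with ATG and ending
    at a stop codon, and a protein containing its architecture's domains; the
    companion domain lies entirely in the first exon and the CCT domain in
    the last, so removing those exons from the annotation removes the domains
    from the annotated protein.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    by_label = {t.label: t for t in templates}
    rng = np.random.default_rng([config.seed % (2**31), 104729])
    genes: List[FounderGene] = []
    tag_counts: Dict[str, int] = {}
    for i in range(config.n_families):
        arch = _ARCHITECTURES[i % len(_ARCHITECTURES)]
        tag = _ARCH_TAG[arch]
        tag_counts[tag] = tag_counts.get(tag, 0) + 1
        family_id = f"{tag}{tag_counts[tag]}"
        companion = _COMPANION.get(tag)

        linker1 = _random_peptide(rng, int(rng.integers(10, 17)), forbid="M")
        linker2a = _random_peptide(rng, int(rng.integers(12, 17)), forbid="M")
        linker2b = _random_peptide(rng, int(rng.integers(12, 21)), forbid="M")
        linker3 = _random_peptide(rng, int(rng.integers(6, 13)), forbid="M")

        parts = ["M", linker1]
        domain_aa: Dict[str, Tuple[int, int]] = {}
        pos = 1 + len(linker1)
        if companion is not None:
            inst = sample_instance(by_label[companion], rng)
            parts.append(inst)
            domain_aa[companion] = (pos, pos + len(inst))
            pos += len(inst)
        parts.append(linker2a)
        pos += len(linker2a)
        mid_met_aa = pos
        parts.append("M")
        pos += 1
        parts.append(linker2b)
        pos += len(linker2b)
        cct = sample_instance(by_label["CCT"], rng)
        parts.append(cct)
        domain_aa["CCT"] = (pos, pos + len(cct))
        pos += len(cct)
        parts.append(linker3)
        protein = "".join(parts)

        cds = _reverse_translate(protein, rng)
        cds += _STOP_CODONS[rng.integers(len(_STOP_CODONS))]

        companion_dna_end = (domain_aa[companion][1] * 3) if companion else (1 + len(linker1)) * 3
        cct_dna_start = domain_aa["CCT"][0] * 3
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        window = cct_dna_start - companion_dna_end
        while n_ex > 1 and window < (n_ex - 1) * 20 + 10:
            n_ex -= 1
        if n_ex > 1:
            base = np.linspace(companion_dna_end + 5, cct_dna_start - 5, n_ex + 1)[1:-1]
            jitter = rng.integers(-4, 5, size=n_ex - 1)
            boundaries = sorted(int(b) + int(j) for b, j in zip(base, jitter))
            exon_lengths = []
            prev = 0
            for b in boundaries:
                exon_lengths.append(b - prev)
                prev = b
            exon_lengths.append(len(cds) - prev)
        else:
            exon_lengths = [len(cds)]
        introns = []
        for _ in range(n_ex - 1):
            L = int(rng.integers(80, 201))
            introns.append("GT" + "".join(rng.choice(["A", "C", "G", "T"]) for _ in range(L - 4)) + "AG")

        # Safe CDS windows for indels: linker-coding regions away from the
        # start/stop, the internal Met, and the domains.
        up: List[Tuple[int, int]] = [(6, (1 + len(linker1)) * 3 - 3)]
        l2a_start = (companion_dna_end // 3) * 3 if companion else (1 + len(linker1)) * 3
        up.append((l2a_start + 3, mid_met_aa * 3 - 3))
        down: List[Tuple[int, int]] = [
            ((mid_met_aa + 1) * 3 + 3, cct_dna_start - 3),
            (domain_aa["CCT"][1] * 3 + 3, len(cds) - 6),
        ]
        genes.append(FounderGene(
            family_id=family_id,
            architecture=arch if companion is None else ("CCT", companion),
            protein=protein,
            cds=cds,
            exon_lengths=exon_lengths,
            intron_seqs=introns,
            domain_aa=domain_aa,
            mid_met_aa=mid_met_aa,
            safe_windows_upstream=[(s, e) for s, e in up if e - s >= 4],
            safe_windows_all=[(s, e) for s, e in up + down if e - s >= 4],
        ))

    total_gene = sum(len(g.gene_seq()) for g in genes)
    n_spacers = config.n_families + 1
    remaining = config.genome_length - total_gene
    min_spacer = 4000
    if remaining < n_spacers * min_spacer:
        raise ValueError(
            f"genome_length {config.genome_length} too short for "
            f"{config.n_families} families (need >= {total_gene + n_spacers * min_spacer})"
        )
    base_len = remaining // n_spacers
    spacer_lens = [base_len] * n_spacers
    spacer_lens[-1] += remaining - base_len * n_spacers
    spacers = [
        "".join(_DNA[rng.integers(0, 4, size=L)].astype(str)) for L in spacer_lens
    ]
    return FounderSet(templates=list(templates), genes=genes, spacers=spacers)


# ---------------------------------------------------------------------------
# Genotype evolution
# ---------------------------------------------------------------------------

def _substitute_free(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions with no constraints (spacers, duplicate copies)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < rate
    idx = np.nonzero(mask)[0]
    if idx.size:
        shifts = rng.integers(1, 4, size=idx.size)
        lut = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
        for i, sh in zip(idx, shifts):
            cur = lut.get(arr[i].tobytes(), 0)
            arr[i] = _DNA[(cur + sh) % 4]
    return arr.tobytes().decode()


def _substitute_gene(gene: FounderGene, rate: float,
                     rng: np.random.Generator) -> Tuple[List[str], List[str]]:
    """Substitute within a gene copy while keeping it a valid gene model:
    start/stop codons, the internal Met codon, and splice dinucleotides are
    protected, and substitutions that would create an in-frame stop are
    skipped.  Returns (cds as list of chars, intron seqs)."""
    cds = list(gene.cds)
    n = len(cds)
    protected = set(range(0, 3)) | set(range(n - 3, n))
    protected |= set(range(gene.mid_met_aa * 3, gene.mid_met_aa * 3 + 3))
    if rate > 0:
        mask = rng.random(n) < rate
        for p in np.nonzero(mask)[0]:
            p = int(p)
            if p in protected:
                continue
            old = cds[p]
            new = "ACGT"[(("ACGT".index(old) if old in "ACGT" else 0)
                          + int(rng.integers(1, 4))) % 4]
            c0 = (p // 3) * 3
            codon = cds[c0:c0 + 3]
            codon[p - c0] = new
            if "".join(codon) in _STOP_CODONS:
                continue
            cds[p] = new
    introns = []
    for intr in gene.intron_seqs:
        if rate > 0 and len(intr) > 4:
            body = _substitute_free(intr[2:-2], rate, rng)
            introns.append(intr[:2] + body + intr[-2:])
        else:
            introns.append(intr)
    return cds, introns


def _exon_interior_windows(
    windows: List[Tuple[int, int]],
    bounds: List[Tuple[int, int]],
    margin: int = 6,
) -> List[Tuple[int, int]]:
    """Intersect CDS windows with exon interiors; indels planted within
    ``margin`` of an exon boundary would be ambiguous against the intron."""
    out = []
    for ws, we in windows:
        for bs, be in bounds:
            s, e = max(ws, bs + margin), min(we, be - margin)
            if e - s >= 2:
                out.append((s, e))
    return out


def _pick_indel_site(
    cds: List[str],
    windows: List[Tuple[int, int]],
    rng: np.random.Generator,
    sign: int,
    length: int = 1,
) -> Tuple[int, Optional[List[str]]]:
    """Pick an indel site whose edit is positionally unambiguous: the edited
    sequence differs from the same edit applied at any nearby position, so
    alignment recovers the planted coordinate."""
    n = len(cds)
    for _ in range(300):
        s0, e0 = windows[int(rng.integers(len(windows)))]
        p = int(rng.integers(s0, e0))
        if sign < 0:
            edited = cds[:p] + cds[p + length:]
            unique = all(
                cds[:q] + cds[q + length:] != edited
                for q in range(max(0, p - 4), min(n - length, p + 4) + 1)
                if q != p
            )
            if unique:
                return p, None
        else:
            for _attempt in range(8):
                ins = ["ACGT"[int(rng.integers(4))] for _ in range(length)]
                edited = cds[:p] + ins + cds[p:]
                unique = all(
                    cds[:q] + ins + cds[q:] != edited
                    for q in range(max(0, p - 4), min(n, p + 4) + 1)
                    if q != p
                )
                if unique:
                    return p, ins
    raise RuntimeError("no unambiguous indel site found")


def _make_model(gene: FounderGene, exon_lengths: List[int], gstart: int,
                first_phase: int, exons_rel: Optional[List[Tuple[int, int]]] = None,
                truncated: bool = False) -> pio.GeneModel:
    rel = exons_rel if exons_rel is not None else gene.exons_rel(exon_lengths)
    exons_abs = [(gstart + s, gstart + e) for s, e in rel]
    cds = []
    consumed = 0
    for s, e in exons_abs:
        phase = first_phase if consumed == 0 else (3 - (consumed - first_phase) % 3) % 3
        cds.append((s, e, phase))
        consumed += e - s
    attrs = {"family": gene.family_id}
    if truncated:
        attrs["truncated_annotation"] = "1"
    return pio.GeneModel(
        gene_id=gene.family_id,
        replicon="chr1",
        start=exons_abs[0][0],
        end=exons_abs[-1][1],
        strand="+",
        exons=exons_abs,
        cds=cds,
        attributes=attrs,
    )


def evolve_genotype(founder: FounderSet, config: SimConfig,
                    genotype_id: str, genotype_index: int) -> Genotype:
    """Apply substitutions and per-gene events to produce one genotype.

    Events are drawn independently per gene from ``event_rates``; when drawn
    events conflict they are resolved by precedence (deletion wins outright;
    among the sequence/annotation edits: 1-bp indel > 3-bp indel > domain
    deletion > annotation truncation; duplications combine freely with the
    non-deletion edits).  One RNG stream per genotype derives from the master
    seed, so each genotype is reproducible independently.
    """
    rng = np.random.default_rng([config.seed % (2**31), 7919 + genotype_index])
    rates = config.event_rates
    n_genes = len(founder.genes)

    gene_builds: List[Optional[dict]] = []
    spacer_insertions: List[List[Tuple[int, str, str, str]]] = [
        [] for _ in founder.spacers
    ]  # (offset, seq, family_id, kind)

    for gi, gene in enumerate(founder.genes):
        draws = {kind: bool(rng.random() < rates[kind]) for kind in EVENT_KINDS}
        if draws["deletion"]:
            gene_builds.append({"deleted": True, "gene": gene})
            continue

        cds, introns = _substitute_gene(gene, config.substitution_rate, rng)
        exon_lengths = list(gene.exon_lengths)
        bounds = gene.exon_cds_bounds()
        events: List[Tuple[str, dict]] = []

        edit = next(
            (k for k in ("indel_1bp", "indel_3bp", "domain_deletion",
                         "annotation_truncation") if draws[k]),
            None,
        )
        if edit == "annotation_truncation" and gene.n_exons < 3:
            edit = None

        if edit == "indel_1bp":
            windows = _exon_interior_windows(gene.safe_windows_upstream, bounds)
            sign = int(rng.choice([-1, 1]))
            if not windows:
                edit = None
            else:
                p, ins = _pick_indel_site(cds, windows, rng, sign)
                if sign < 0:
                    del cds[p]
                else:
                    cds[p:p] = ins
                ei = next(i for i, (s, e) in enumerate(bounds) if s <= p < e)
                exon_lengths[ei] += sign
                events.append(("indel_1bp", {"cds_pos": p, "sign": sign, "exon": ei}))
        elif edit == "indel_3bp":
            windows = _exon_interior_windows(gene.safe_windows_all, bounds, margin=8)
            sign = int(rng.choice([-1, 1]))
            if not windows:
                edit = None
            else:
                p, ins = _pick_indel_site(cds, windows, rng, sign, length=3)
                ei = next(i for i, (s, e) in enumerate(bounds) if s <= p < e)
                if sign < 0:
                    del cds[p:p + 3]
                    exon_lengths[ei] -= 3
                else:
                    cds[p:p] = ins
                    exon_lengths[ei] += 3
                events.append(("indel_3bp",
                               {"cds_pos": p, "sign": 3 * sign, "exon": ei}))
        elif edit == "domain_deletion":
            a0, a1 = gene.domain_aa["CCT"]
            d0, d1 = (a0 + 4) * 3, (a0 + 18) * 3
            ei = next(i for i, (s, e) in enumerate(bounds) if s <= d0 < e)
            del cds[d0:d1]
            exon_lengths[ei] -= d1 - d0
            events.append(("domain_deletion", {"cds_start": d0, "cds_end": d1}))

        truncated = edit == "annotation_truncation"
        if truncated:
            events.append(("annotation_truncation",
                           {"removed_exons": [0, gene.n_exons - 1]}))

        copies: List[Tuple[str, str, int]] = []  # (kind, seq, placement)
        gene_seq = gene.gene_seq("".join(cds), exon_lengths)
        if draws["tandem_duplication"]:
            copy = _substitute_free(gene_seq, config.duplicate_divergence, rng)
            offset = int(rng.integers(200, 2001))
            spacer_insertions[gi + 1].append((offset, copy, gene.family_id,
                                              "tandem_duplication"))
        if draws["dispersed_duplication"]:
            copy = _substitute_free(gene_seq, config.duplicate_divergence, rng)
            candidates = [j for j in range(len(founder.spacers))
                          if abs(j - (gi + 1)) >= 2]
            j = candidates[int(rng.integers(len(candidates)))]
            offset = int(rng.integers(1000, max(1001, len(founder.spacers[j]) - 1000)))
            spacer_insertions[j].append((offset, copy, gene.family_id,
                                         "dispersed_duplication"))

        gene_builds.append({
            "deleted": False,
            "gene": gene,
            "cds": "".join(cds),
            "introns": introns,
            "exon_lengths": exon_lengths,
            "gene_seq": gene_seq,
            "events": events,
            "truncated": truncated,
        })

    # Substitute spacers, then assemble the chromosome left to right while
    # resolving absolute coordinates for annotations and truth rows.
    spacers = [_substitute_free(sp, config.substitution_rate, rng)
               for sp in founder.spacers]

    parts: List[str] = []
    pos = 0
    truth: List[TruthRow] = []
    models: List[pio.GeneModel] = []
    copy_counts: Dict[str, int] = {g.family_id: 1 for g in founder.genes}

    for i, sp in enumerate(spacers):
        inserts = sorted(spacer_insertions[i], key=lambda t: t[0])
        cursor = 0
        for offset, seq, family_id, kind in inserts:
            offset = min(offset, len(sp))
            parts.append(sp[cursor:offset])
            pos += offset - cursor
            copy_counts[family_id] += 1
            truth.append(TruthRow(
                family_id, genotype_id, kind, "chr1", pos, pos + len(seq),
                {"copy_index": copy_counts[family_id]},
            ))
            parts.append(seq)
            pos += len(seq)
            cursor = offset
        parts.append(sp[cursor:])
        pos += len(sp) - cursor

        if i < n_genes:
            build = gene_builds[i]
            gene = build["gene"]
            if build["deleted"]:
                truth.append(TruthRow(
                    gene.family_id, genotype_id, "deletion", "chr1", pos, pos, {},
                ))
                continue
            gstart = pos
            gene_seq = build["gene_seq"]
            exons_rel = gene.exons_rel(build["exon_lengths"])
            for kind, detail in build["events"]:
                if kind in ("indel_1bp", "indel_3bp"):
                    ei = detail["exon"]
                    bounds = gene.exon_cds_bounds()
                    within = detail["cds_pos"] - bounds[ei][0]
                    g = exons_rel[ei][0] + within
                    start, end = gstart + g, gstart + g + 1
                elif kind == "domain_deletion":
                    bounds = [(s, e) for s, e in _cds_bounds(build["exon_lengths"])]
                    ei = next(i2 for i2, (s, e) in enumerate(bounds)
                              if s <= detail["cds_start"] < e or e >= detail["cds_start"])
                    g = _cds_to_gene(detail["cds_start"], build["exon_lengths"],
                                     gene.intron_seqs)
                    start, end = gstart + g, gstart + g
                else:
                    start, end = gstart, gstart + len(gene_seq)
                truth.append(TruthRow(gene.family_id, genotype_id, kind, "chr1",
                                      start, end, detail))
            if build["truncated"]:
                kept = exons_rel[1:-1]
                first_phase = (3 - build["exon_lengths"][0] % 3) % 3
                model = _make_model(gene, build["exon_lengths"][1:-1], gstart,
                                    first_phase, exons_rel=kept, truncated=True)
            else:
                model = _make_model(gene, build["exon_lengths"], gstart,
                                    first_phase=0)
            models.append(model)
            parts.append(gene_seq)
            pos += len(gene_seq)

    assembly = {"chr1": "".join(parts)}
    proteins: Dict[str, str] = {}
    for model in models:
        cds_seq = model.spliced_cds(assembly["chr1"])
        pep = translate(cds_seq[model.first_cds_phase:])
        stop = pep.find("*")
        proteins[model.gene_id] = pep if stop < 0 else pep[:stop]
    return Genotype(genotype_id, assembly, models, proteins, truth)


def _cds_bounds(exon_lengths: List[int]) -> List[Tuple[int, int]]:
    out, pos = [], 0
    for L in exon_lengths:
        out.append((pos, pos + L))
        pos += L
    return out


def _cds_to_gene(cds_pos: int, exon_lengths: List[int],
                 intron_seqs: List[str]) -> int:
    pos = 0
    g = 0
    for i, L in enumerate(exon_lengths):
        if cds_pos < pos + L:
            return g + (cds_pos - pos)
        pos += L
        g += L
        if i < len(intron_seqs):
            g += len(intron_seqs[i])
    return g


def simulate_pangenome(config: Optional[SimConfig] = None) -> SyntheticPangenome:
    """Generate a full synthetic pangenome: founder plus evolved genotypes."""
    config = config or SimConfig()
    templates = make_domain_library(config.seed)
    founder = build_founder_genes(templates, config)
    genotypes = [
        evolve_genotype(founder, config, f"G{i + 1:02d}", i)
        for i in range(config.n_genotypes)
    ]
    return SyntheticPangenome(config, founder, genotypes)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_pangenome(pangenome: SyntheticPangenome, out_dir) -> List[Path]:
    """Emit per-genotype assembly FASTA, GFF3 and protein FASTA, the founder
    reference files, the domain template table and the truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _fa(path: Path, records: Dict[str, str]) -> None:
        pio.write_fasta([pio.FastaRecord(k, v) for k, v in records.items()], path)
        written.append(path)

    founder = pangenome.founder
    _fa(out / "founder.fasta", founder.assembly())
    _fa(out / "founder.proteins.fasta", founder.proteins())
    pio.write_gff3(founder.gene_models(), out / "founder.gff3")
    written.append(out / "founder.gff3")

    tmpl_lines = ["label\tconsensus\tper_position_variability"]
    for t in founder.templates:
        var = ",".join(f"{v:.6f}" for v in t.per_position_variability)
        tmpl_lines.append(f"{t.label}\t{t.consensus}\t{var}")
    (out / "templates.tsv").write_text("\n".join(tmpl_lines) + "\n")
    written.append(out / "templates.tsv")

    for g in pangenome.genotypes:
        _fa(out / f"{g.genotype_id}.fasta", g.assembly)
        _fa(out / f"{g.genotype_id}.proteins.fasta", g.proteins)
        pio.write_gff3(g.genes, out / f"{g.genotype_id}.gff3")
        written.append(out / f"{g.genotype_id}.gff3")

    pangenome.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    written.append(out / "truth.tsv")
    (out / "sim_config.json").write_text(
        json.dumps(pangenome.config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    written.append(out / "sim_config.json")
    return written


def read_pangenome(out_dir) -> dict:
    """Re-read an emitted pangenome directory into plain containers."""
    out = Path(out_dir)
    config = SimConfig.from_dict(json.loads((out / "sim_config.json").read_text()))
    truth = pd.read_csv(out / "truth.tsv", sep="\t")

    def _fa(path: Path) -> Dict[str, str]:
        return {r.id: r.sequence for r in pio.read_fasta(path)}

    templates = []
    for line in (out / "templates.tsv").read_text().strip().splitlines()[1:]:
        label, consensus, var = line.split("\t")
        templates.append(DomainTemplate(
            label, consensus, np.array([float(x) for x in var.split(",")])
        ))
    genotypes = {}
    for i in range(config.n_genotypes):
        gid = f"G{i + 1:02d}"
        genotypes[gid] = {
            "assembly": _fa(out / f"{gid}.fasta"),
            "proteins": _fa(out / f"{gid}.proteins.fasta"),
            "genes": pio.read_gff3(out / f"{gid}.gff3"),
        }
    return {
        "config": config,
        "templates": templates,
        "founder_assembly": _fa(out / "founder.fasta"),
        "founder_proteins": _fa(out / "founder.proteins.fasta"),
        "founder_genes": pio.read_gff3(out / "founder.gff3"),
        "genotypes": genotypes,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Protein-level cohorts for the k-mer PCA analyses
# ---------------------------------------------------------------------------

def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != aa]
            out.append(choices[int(rng.integers(len(choices)))])
        else:
            out.append(aa)
    return "".join(out)


def founder_protein_cohort(
    founder: FounderSet,
    n_genotypes: int,
    mutation_rate: float = 0.01,
    drop_family: Optional[str] = None,
    drop_fraction: float = 0.5,
    seed: int = 0,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Protein sets per genotype, with one family deleted in a fraction of
    genotypes -- the presence/absence contrast behind the genotype-level PCA.

    Returns ``(frame, genotypes_with_family, genotypes_without_family)``.
    """
    rng = np.random.default_rng(seed)
    n_absent = int(round(n_genotypes * drop_fraction)) if drop_family else 0
    rows = []
    with_fam, without_fam = [], []
    for i in range(n_genotypes):
        gid = f"G{i + 1:02d}"
        absent = drop_family is not None and i < n_absent
        (without_fam if absent else with_fam).append(gid)
        for gene in founder.genes:
            if absent and gene.family_id == drop_family:
                continue
            rows.append({
                "genotype": gid,
                "family": gene.family_id,
                "sequence": mutate_protein(gene.protein, mutation_rate, rng),
            })
    return pd.DataFrame(rows), with_fam, without_fam


def driver_cohort(
    founder: FounderSet,
    n_per_group: int,
    driver_family: str,
    driver_divergence: float = 0.2,
    mutation_rate: float = 0.005,
    seed: int = 0,
) -> Tuple[pd.DataFrame, List[str], List[str]]:
    """Two genotype groups where one family carries all the between-group
    divergence: group B's copies of ``driver_family`` descend from a diverged
    allele, every other family varies only by background noise."""
    rng = np.random.default_rng(seed)
    by_family = {g.family_id: g.protein for g in founder.genes}
    if driver_family not in by_family:
        raise ValueError(f"unknown family {driver_family!r}")
    diverged = mutate_protein(by_family[driver_family], driver_divergence, rng)
    rows = []
    group_a, group_b = [], []
    for i in range(2 * n_per_group):
        gid = f"G{i + 1:02d}"
        in_b = i >= n_per_group
        (group_b if in_b else group_a).append(gid)
        for fam, protein in by_family.items():
            base = diverged if (in_b and fam == driver_family) else protein
            rows.append({
                "genotype": gid,
                "family": fam,
                "sequence": mutate_protein(base, mutation_rate, rng),
            })
    return pd.DataFrame(rows), group_a, group_b
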