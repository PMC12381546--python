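"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Bio.SeqIO.  GFF3 files carry a plain gene/mRNA/exon/CDS
hierarchy; coordinates are 1-based inclusive on disk and converted to the
package-internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaRecord",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]


@dataclass
class FastaRecord:
    id: str
    sequence: str
    description: str = ""


@dataclass
class GeneModel:
    """One gene with its exon/CDS structure.

    All coordinates are 0-based half-open on ``replicon``.  ``cds`` entries
    are ``(start, end, phase)``; exons here are fully coding, so exon and CDS
    intervals coincide but phases are tracked on the CDS records.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str = "+"
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int, int]] = field(default_factory=list)
    attributes: Dict[str, str] = field(default_factory=dict)

    def spliced_cds(self, replicon_seq: str) -> str:
        chunks = [replicon_seq[s:e] for s, e, _ in sorted(self.cds)]
        seq = "".join(chunks)
        if self.strand == "-":
            from .align import reverse_complement

            seq = reverse_complement(seq)
        return seq

    @property
    def first_cds_phase(self) -> int:
        return sorted(self.cds)[0][2] if self.cds else 0


def read_fasta(path: Union[str, Path]) -> List[FastaRecord]:
    """Read FASTA; sequences are normalized to uppercase (with a warning when
    lowercase input is seen); duplicate ids are an error."""
    records: List[FastaRecord] = []
    seen: Dict[str, int] = {}
    lowercase = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            lowercase = True
            seq = seq.upper()
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(FastaRecord(rec.id, seq, desc))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = [rid for rid, n in seen.items() if n > 1]
    if dups:
        raise ValueError(f"duplicate FASTA ids: {', '.join(sorted(dups))}")
    if lowercase:
        warnings.warn(f"lowercase residues in {path} normalized to uppercase")
    return records


def write_fasta(records: List[FastaRecord], path: Union[str, Path]) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")  # wraps at 60 columns


_GFF_COLUMNS = 9


def _parse_attributes(text: str) -> Dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def _fmt_attributes(attrs: Dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: Union[str, Path]) -> List[GeneModel]:
    """Parse a GFF3 file with a gene/mRNA/exon/CDS hierarchy (via gffutils).

    Raises on malformed coordinates (``end < start``) and on child features
    lying outside their parent's span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    for gf in db.features_of_type("gene", order_by="start"):
        if gf.end < gf.start:
            raise ValueError(f"gene {gf.id}: end < start")
        gene = GeneModel(
            gene_id=gf.id,
            replicon=gf.seqid,
            start=gf.start - 1,
            end=gf.end,
            strand=gf.strand,
            attributes={
                k: v[0] for k, v in gf.attributes.items() if k != "ID"
            },
        )
        for child in db.children(gf.id, featuretype=("exon", "CDS"), order_by="start"):
            if child.end < child.start:
                raise ValueError(f"{child.featuretype} under gene {gf.id}: end < start")
            start, end = child.start - 1, child.end
            if start < gene.start or end > gene.end:
                raise ValueError(
                    f"{child.featuretype} at {child.start}-{child.end} lies outside "
                    f"the span of gene {gf.id}"
                )
            if child.featuretype == "exon":
                gene.exons.append((start, end))
            else:
                phase = 0 if child.frame in (".", None) else int(child.frame)
                gene.cds.append((start, end, phase))
        gene.exons.sort()
        gene.cds.sort()
        _validate_phases(gene)
        models.append(gene)
    return models


def _validate_phases(gene: GeneModel) -> None:
    """CDS phases must chain: next phase = (3 - (len_so_far - phase0) % 3) % 3."""
    if not gene.cds:
        return
    cds = sorted(gene.cds, reverse=(gene.strand == "-"))
    consumed = 0
    first_phase = cds[0][2]
    for s, e, phase in cds:
        expected = (3 - (consumed - first_phase) % 3) % 3 if consumed else first_phase
        if phase != expected:
            raise ValueError(
                f"gene {gene.gene_id}: CDS at {s + 1}-{e} has phase {phase}, "
                f"expected {expected}"
            )
        consumed += e - s


def write_gff3(models: List[GeneModel], path: Union[str, Path]) -> None:
    lines = ["##gff-version 3"]
    for g in models:
        attrs = {"ID": g.gene_id, **g.attributes}
        lines.append(
            "\t".join(
                [
                    g.replicon,
                    "panfam",
                    "gene",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    _fmt_attributes(attrs),
                ]
            )
        )
        mid = f"{g.gene_id}.1"
        lines.append(
            "\t".join(
                [
                    g.replicon,
                    "panfam",
                    "mRNA",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    _fmt_attributes({"ID": mid, "Parent": g.gene_id}),
                ]
            )
        )
        for s, e in g.exons:
            lines.append(
                "\t".join(
                    [g.replicon, "panfam", "exon", str(s + 1), str(e), ".", g.strand,
                     ".", _fmt_attributes({"Parent": mid})]
                )
            )
        for s, e, phase in g.cds:
            lines.append(
                "\t".join(
                    [g.replicon, "panfam", "CDS", str(s + 1), str(e), ".", g.strand,
                     str(phase), _fmt_attributes({"Parent": mid})]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
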