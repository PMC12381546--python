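"""Top-level pipeline: simulate -> identify -> validate -> frameshift ->
phylogeny -> PCA, with a run manifest for reproducibility.

Stage order mirrors the identification workflow the package models: motif
search and overlap classification of annotated proteins, nomenclature by
best hit against the reference (founder) protein set, genomic validation of
presence/absence and copy number, frameshift/rescue/status reconciliation,
the family phylogeny, and the genotype-level k-mer PCA.  Every stage writes
its outputs before the next starts, and stages communicate only through
those documented files.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .align import KmerIndex, Locus, dna_default, protein_default, global_align
from .domains import (
    NullCalibration,
    PSSM,
    build_pssm,
    calibrate_null,
    classify,
    scan,
)
from .pangene import (
    SearchParams,
    build_presence_matrix,
    classify_copies_by_reference,
    crosstab_presence_phenotype,
    detect_frameshift,
    exon_aware_align_cds,
    extract_locus,
    reconcile_with_annotation,
    rescue_alternative_start,
    validate_gene,
)
from .phylo import distance_matrix, newick_write, nj
from .simpan import (
    SimConfig,
    SyntheticPangenome,
    sample_instance,
    simulate_pangenome,
    write_pangenome,
)
from .variation import kmer_profile, pca

logger = logging.getLogger("panfam")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_THRESHOLD_RANGES = {
    "identity": (0.0, 1.0),
    "coverage": (0.0, 1.0),
    "substitution_rate": (0.0, 1.0),
    "duplicate_divergence": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """All module thresholds plus the simulation block; flat key=value
    sections in an INI file map onto these fields and unknown keys are
    rejected."""

    out_dir: str = "panfam_run"
    seed: int = 0
    verbosity: int = 1
    # simulate
    n_genotypes: int = 12
    n_families: int = 8
    genome_length: int = 500_000
    substitution_rate: float = 0.01
    duplicate_divergence: float = 0.02
    event_rates: Optional[Dict[str, float]] = None
    # search
    k_seed: int = 15
    identity: float = 0.90
    coverage: float = 0.80
    max_gap: int = 2000
    # domains
    pssm_pseudocount: float = 1.0
    pssm_instances: int = 30
    calibration_windows: int = 10_000
    # pca
    kmer: int = 3
    phenotype_labels: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("identity", "coverage"):
            value = getattr(self, name)
            lo, hi = _THRESHOLD_RANGES[name]
            if not lo < value <= hi:
                raise ValueError(f"{name}={value} outside ({lo}, {hi}]")
        for name in ("substitution_rate", "duplicate_divergence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.k_seed < 8:
            raise ValueError("k_seed must be >= 8")
        if self.kmer < 1:
            raise ValueError("kmer must be >= 1")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Plain-text config: ``key = value`` under [paths], [simulate],
        [search], [domains] and [pca] sections; CLI overrides win."""
        parser = configparser.ConfigParser()
        parser.read(str(path))
        known = set(cls.__dataclass_fields__)
        values: Dict[str, object] = {}
        for section in parser.sections():
            for key, raw in parser.items(section):
                if key == "event_rates":
                    values[key] = json.loads(raw)
                    continue
                if key not in known:
                    raise ValueError(f"unknown config key {key!r} in [{section}]")
                ftype = cls.__dataclass_fields__[key].type
                if key in ("out_dir", "phenotype_labels"):
                    values[key] = raw
                elif "int" in str(ftype):
                    values[key] = int(raw)
                else:
                    values[key] = float(raw)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def sim_config(self) -> SimConfig:
        kwargs = dict(
            n_genotypes=self.n_genotypes,
            n_families=self.n_families,
            genome_length=self.genome_length,
            substitution_rate=self.substitution_rate,
            duplicate_divergence=self.duplicate_divergence,
            seed=self.seed,
        )
        if self.event_rates is not None:
            kwargs["event_rates"] = dict(self.event_rates)
        return SimConfig(**kwargs)

    def search_params(self) -> SearchParams:
        return SearchParams(
            k_seed=self.k_seed,
            min_identity=self.identity,
            min_coverage=self.coverage,
            max_gap=self.max_gap,
        )


@dataclass
class RunManifest:
    config: dict
    input_checksums: Dict[str, str]
    stage_counts: Dict[str, Dict[str, int]]
    version: str
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _data_dir(cfg: PipelineConfig) -> Path:
    return Path(cfg.out_dir) / "data"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> SyntheticPangenome:
    pangenome = simulate_pangenome(cfg.sim_config())
    write_pangenome(pangenome, _data_dir(cfg))
    logger.info(
        "simulate: %d genotypes, %d families, %d planted events",
        cfg.n_genotypes, cfg.n_families, len(pangenome.truth),
    )
    return pangenome


def _build_pssms(
    pangenome: SyntheticPangenome, cfg: PipelineConfig
) -> Tuple[List[PSSM], Dict[str, NullCalibration]]:
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    pssms: List[PSSM] = []
    calibrations: Dict[str, NullCalibration] = {}
    for i, template in enumerate(pangenome.founder.templates):
        instances = [
            sample_instance(template, rng) for _ in range(cfg.pssm_instances)
        ]
        pssm = build_pssm(instances, pseudocount=cfg.pssm_pseudocount,
                          label=template.label)
        pssms.append(pssm)
        calibrations[template.label] = calibrate_null(
            pssm, decoy_length_total=100_000, n_samples=200,
            seed=(cfg.seed % (2**31)) + 23 + i,
            query_windows=cfg.calibration_windows,
        )
    return pssms, calibrations


def stage_identify(pangenome: SyntheticPangenome, cfg: PipelineConfig) -> pd.DataFrame:
    """Domain scan + overlap classification of every annotated protein, and
    best-hit nomenclature against the founder reference proteins."""
    out = Path(cfg.out_dir)
    pssms, calibrations = _build_pssms(pangenome, cfg)
    founder_proteins = pangenome.founder.proteins()
    scheme = protein_default()
    rows = []
    protein_sets = [("founder", founder_proteins)] + [
        (g.genotype_id, g.proteins) for g in pangenome.genotypes
    ]
    for genotype_id, proteins in protein_sets:
        for pid, seq in proteins.items():
            if not seq:
                hits = []
            else:
                hits = [
                    h for pssm in pssms
                    for h in scan(pssm, seq, calibrations[pssm.label])
                ]
            cls = classify(hits)
            if genotype_id == "founder" or not seq:
                best_name = pid
            else:
                idents = sorted(
                    ((global_align(seq, fseq, scheme).identity, fid)
                     for fid, fseq in founder_proteins.items()),
                    key=lambda t: (-t[0], t[1]),
                )
                best_name = idents[0][1]
            rows.append({
                "genotype": genotype_id,
                "protein": pid,
                "family_class": cls.family,
                "flag": cls.flag or "",
                "domains": ",".join(sorted({h.label for h in hits})),
                "assigned_name": best_name,
            })
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "families.tsv", sep="\t", index=False)
    counts = frame[frame.genotype != "founder"]["family_class"].value_counts()
    logger.info("identify: %d proteins classified (%s)",
                len(frame), ", ".join(f"{k}={v}" for k, v in counts.items()))
    return frame


def stage_validate(
    pangenome: SyntheticPangenome, cfg: PipelineConfig
) -> Tuple[Dict[str, Dict[str, List[Locus]]], "pd.DataFrame"]:
    """Genomic search of every founder gene across all genotype assemblies."""
    out = Path(cfg.out_dir)
    params = cfg.search_params()
    indexes = {
        g.genotype_id: KmerIndex(g.assembly, params.k_seed)
        for g in pangenome.genotypes
    }
    validation: Dict[str, Dict[str, List[Locus]]] = {}
    rows = []
    for gene in pangenome.founder.genes:
        result = validate_gene(gene.family_id, gene.gene_seq(), indexes, params)
        validation[gene.family_id] = result
        for gid, loci in result.items():
            for locus in loci:
                rows.append({
                    "gene": gene.family_id, "genotype": gid,
                    "replicon": locus.replicon_id, "start": locus.start,
                    "end": locus.end, "strand": locus.strand,
                    "identity": round(locus.identity, 6),
                    "coverage": round(locus.coverage, 6),
                    "score": locus.score,
                })
    pd.DataFrame(
        rows, columns=["gene", "genotype", "replicon", "start", "end",
                       "strand", "identity", "coverage", "score"],
    ).to_csv(out / "loci.tsv", sep="\t", index=False)
    matrix = build_presence_matrix(validation)
    matrix.counts.to_csv(out / "presence_matrix.tsv", sep="\t")
    summary = pd.DataFrame({
        "presence_count": matrix.presence_counts,
        "class": matrix.classes,
    })
    summary.to_csv(out / "gene_classes.tsv", sep="\t")
    logger.info("validate: %d loci; %d core / %d dispensable genes",
                len(rows), matrix.n_core, matrix.n_dispensable)
    if cfg.phenotype_labels:
        labels = {}
        for line in Path(cfg.phenotype_labels).read_text().strip().splitlines()[1:]:
            gt, lab = line.split("\t")[:2]
            labels[gt] = lab
        target = matrix.presence_counts.idxmin()
        table = crosstab_presence_phenotype(matrix, labels, target)
        table.to_csv(out / "crosstab.tsv", sep="\t")
    return validation, matrix.counts


def stage_frameshift(
    pangenome: SyntheticPangenome,
    validation: Mapping[str, Mapping[str, List[Locus]]],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Exon-aware CDS alignment of each recovered locus, frameshift and
    premature-stop detection, alternative-start rescue, and reconciliation of
    genomic evidence with the annotation."""
    out = Path(cfg.out_dir)
    pssms, calibrations = _build_pssms(pangenome, cfg)
    scheme = dna_default()
    fs_rows, status_rows = [], []
    by_genotype = {g.genotype_id: g for g in pangenome.genotypes}
    for gene in pangenome.founder.genes:
        chunks = gene.cds_chunks()
        domain_cds = {lab: (s * 3, e * 3) for lab, (s, e) in gene.domain_aa.items()}
        for gid, loci in validation[gene.family_id].items():
            genotype = by_genotype[gid]
            ea = report = None
            if loci:
                best = max(loci, key=lambda l: l.score)
                locus_seq = extract_locus(genotype.assembly, best)
                ea = exon_aware_align_cds(chunks, locus_seq, scheme)
                report = detect_frameshift(ea, len(gene.protein),
                                           gene=gene.family_id, genotype=gid)
                report = rescue_alternative_start(report, ea, pssms, calibrations)
                fs_rows.append({
                    "gene": gene.family_id, "genotype": gid,
                    "n_indels": len(report.indels),
                    "indels": ";".join(f"{p}:{l:+d}" for p, l in report.indels),
                    "net_shift": report.net_shift,
                    "frameshift": int(report.frameshift),
                    "premature_stop": "" if report.premature_stop is None
                                      else report.premature_stop,
                    "alt_start": "" if report.alt_start is None else report.alt_start,
                    "retained_domains": ",".join(report.retained_domains),
                })
            status = reconcile_with_annotation(
                loci, ea, report,
                genotype.proteins.get(gene.family_id),
                gene.protein, gene.architecture, domain_cds,
                pssms, calibrations,
                identity_threshold=cfg.identity,
            )
            status_rows.append({"gene": gene.family_id, "genotype": gid,
                                "status": status})
    pd.DataFrame(fs_rows).to_csv(out / "frameshift.tsv", sep="\t", index=False)
    status = pd.DataFrame(status_rows)
    status.to_csv(out / "status.tsv", sep="\t", index=False)
    logger.info("frameshift: %d loci aligned; statuses: %s",
                len(fs_rows),
                ", ".join(f"{k}={v}" for k, v in
                          status["status"].value_counts().items()))
    return status


def stage_phylo(pangenome: SyntheticPangenome, cfg: PipelineConfig) -> str:
    """NJ tree over all annotated family proteins across genotypes."""
    out = Path(cfg.out_dir)
    proteins = {
        f"{pid}@{g.genotype_id}": seq
        for g in pangenome.genotypes
        for pid, seq in g.proteins.items()
        if len(seq) >= 10
    }
    dm = distance_matrix(proteins)
    (out / "distances.tsv").write_text(dm.to_tsv())
    tree = nj(dm)
    newick = newick_write(tree)
    (out / "tree.nwk").write_text(newick)
    logger.info("phylo: %d proteins in tree", len(proteins))
    return newick


def stage_pca(pangenome: SyntheticPangenome, cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    frame = pd.DataFrame([
        {"genotype": g.genotype_id, "family": pid, "sequence": seq}
        for g in pangenome.genotypes
        for pid, seq in g.proteins.items()
        if seq
    ])
    matrix = kmer_profile(frame, k=cfg.kmer)
    matrix.frequencies.to_csv(out / "kmer_matrix.tsv", sep="\t")
    result = pca(matrix)
    combined = result.coordinates.copy()
    for col in result.cos2.columns:
        combined[f"cos2_{col}"] = result.cos2[col]
    combined["cos2_12"] = result.cos2_12
    combined.to_csv(out / "pca_coordinates.tsv", sep="\t")
    pd.DataFrame({
        "dimension": [f"Dim{i + 1}" for i in range(len(result.explained_variance))],
        "explained_variance_pct": result.explained_variance,
    }).to_csv(out / "pca_explained.tsv", sep="\t", index=False)
    logger.info("pca: %d dimensions retained; Dim1 %.1f%%",
                len(result.explained_variance),
                result.explained_variance[0] if len(result.explained_variance) else 0)
    return result


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute all stages in order; any stage failure propagates with the
    stage name attached."""
    logging.basicConfig(level=logging.INFO if cfg.verbosity else logging.WARNING)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Dict[str, Dict[str, int]] = {}

    def _run(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    pangenome = _run("simulate", stage_simulate, cfg)
    counts["simulate"] = {
        "genotypes": cfg.n_genotypes,
        "families": cfg.n_families,
        "planted_events": int(len(pangenome.truth)),
    }
    families = _run("identify", stage_identify, pangenome, cfg)
    counts["identify"] = {"proteins_classified": int(len(families))}
    validation, matrix = _run("validate", stage_validate, pangenome, cfg)
    counts["validate"] = {
        "genes": int(matrix.shape[0]),
        "loci": int(matrix.to_numpy().sum()),
    }
    status = _run("frameshift", stage_frameshift, pangenome, validation, cfg)
    counts["frameshift"] = {
        "statuses_assigned": int(len(status)),
    }
    newick = _run("phylo", stage_phylo, pangenome, cfg)
    counts["phylo"] = {"newick_bytes": len(newick)}
    result = _run("pca", stage_pca, pangenome, cfg)
    counts["pca"] = {"dimensions": int(len(result.explained_variance))}

    checksums = {
        p.name: _sha256(p) for p in sorted(_data_dir(cfg).iterdir())
    }
    manifest = RunManifest(
        config={**{k: v for k, v in asdict(cfg).items()}},
        input_checksums=checksums,
        stage_counts=counts,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
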