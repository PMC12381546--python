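"""Validation pipeline: copy counting, presence matrix, frameshift detection,
alternative-start rescue, status reconciliation, reference copy labels."""

import json

import numpy as np
import pandas as pd
import pytest

from panfam.align import KmerIndex, dna_default
from panfam.pangene import (
    PresenceMatrix,
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
from panfam.simpan import mutate_protein


def _expected_count(truth, fam, gid):
    t = truth[(truth.family_id == fam) & (truth.genotype == gid)]
    if (t.event == "deletion").any():
        return 0
    return 1 + int(t.event.isin(
        ["tandem_duplication", "dispersed_duplication"]).sum())


class TestValidateGene:
    def test_copy_counts_match_truth(self, study_pangenome, study_validation):
        truth = study_pangenome.truth
        for gene in study_pangenome.founder.genes:
            for g in study_pangenome.genotypes:
                expected = _expected_count(truth, gene.family_id, g.genotype_id)
                got = len(study_validation[gene.family_id][g.genotype_id])
                assert got == expected, (gene.family_id, g.genotype_id)

    def test_event_free_genes_present_once_everywhere(self, study_pangenome,
                                                      study_validation):
        truth = study_pangenome.truth
        quiet = [
            gene.family_id for gene in study_pangenome.founder.genes
            if truth[truth.family_id == gene.family_id].empty
        ]
        for fam in quiet:
            assert all(len(v) == 1 for v in study_validation[fam].values())


class TestPresenceMatrix:
    def test_core_dispensable_partition(self, study_validation):
        m = build_presence_matrix(study_validation)
        assert m.n_core + m.n_dispensable == m.counts.shape[0]
        n_genotypes = m.counts.shape[1]
        for gene in m.counts.index:
            is_core = (m.counts.loc[gene] >= 1).all()
            assert (m.classes[gene] == "core") == is_core
        assert m.presence_histogram().sum() == m.counts.shape[0]
        assert m.presence_counts.max() <= n_genotypes

    def test_rules_on_constructed_matrix(self):
        counts = pd.DataFrame(
            [[1, 1, 1], [1, 0, 1], [0, 0, 0]],
            index=["a", "b", "c"], columns=["g1", "g2", "g3"],
        )
        m = PresenceMatrix(counts)
        assert m.classes["a"] == "core"
        assert m.classes["b"] == "dispensable"
        assert m.presence_counts["b"] == 2
        assert m.presence_counts["c"] == 0 and m.classes["c"] == "dispensable"


class TestExonAwareAlignment:
    def test_identical_locus_is_clean(self, small_pangenome):
        gene = small_pangenome.founder.genes[0]
        ea = exon_aware_align_cds(gene.cds_chunks(), "TT" + gene.gene_seq() + "AA")
        assert ea.indels == []
        assert ea.missing_exons == []
        assert ea.identity == 1.0
        assert ea.variant_cds == gene.cds

    def test_planted_3bp_deletion_called_in_frame(self, small_pangenome):
        gene = small_pangenome.founder.genes[0]
        p = gene.exon_lengths[0] // 2
        cds = gene.cds[:p] + gene.cds[p + 3:]
        lengths = list(gene.exon_lengths)
        lengths[0] -= 3
        locus = gene.gene_seq(cds, lengths)
        ea = exon_aware_align_cds(gene.cds_chunks(), locus)
        assert len(ea.indels) == 1
        ref_pos, _, signed = ea.indels[0]
        assert signed == -3
        assert abs(ref_pos - p) <= 3
        assert ea.net_shift == 0

    def test_unrelated_sequence_has_no_anchors(self, small_pangenome):
        gene = small_pangenome.founder.genes[0]
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=2000))
        ea = exon_aware_align_cds(gene.cds_chunks(), junk)
        assert len(ea.missing_exons) == gene.n_exons


class TestDetectFrameshift:
    def test_planted_1bp_indels_detected(self, study_pangenome, study_validation):
        truth = study_pangenome.truth
        by_gid = {g.genotype_id: g for g in study_pangenome.genotypes}
        founders = {g.family_id: g for g in study_pangenome.founder.genes}
        cases = truth[truth.event == "indel_1bp"]
        assert len(cases) > 0
        for _, row in cases.iterrows():
            gene = founders[row.family_id]
            loci = study_validation[row.family_id][row.genotype]
            best = max(loci, key=lambda l: l.score)
            locus_seq = extract_locus(by_gid[row.genotype].assembly, best)
            ea = exon_aware_align_cds(gene.cds_chunks(), locus_seq)
            rep = detect_frameshift(ea, len(gene.protein))
            detail = json.loads(row.detail)
            assert rep.frameshift and rep.net_shift in (1, 2)
            ones = [(p, s) for p, s in rep.indels if abs(s) == 1]
            assert len(ones) == 1
            pos, signed = ones[0]
            assert np.sign(signed) == detail["sign"]
            assert abs(pos - detail["cds_pos"]) <= 1

    def test_compensating_indels_not_a_frameshift(self, small_pangenome):
        gene = small_pangenome.founder.genes[1]
        p1 = 9
        p2 = gene.exon_lengths[0] - 12
        cds = gene.cds
        edited = cds[:p1] + "A" + cds[p1:p2] + cds[p2 + 1:]  # +1 then -1
        locus = gene.gene_seq(edited, list(gene.exon_lengths))
        ea = exon_aware_align_cds(gene.cds_chunks(), locus)
        rep = detect_frameshift(ea, len(gene.protein))
        assert rep.net_shift == 0
        assert not rep.frameshift
        assert sorted(s for _, s in rep.indels) == [-1, 1]


class TestRescue:
    def test_planted_frameshifts_rescue_cct(self, study_pangenome,
                                            study_validation, pssm_library):
        """Every planted upstream 1-bp indel leaves a downstream in-frame ATG
        ahead of an intact CCT region; rescue must recover it."""
        pssms, calibrations = pssm_library
        truth = study_pangenome.truth
        by_gid = {g.genotype_id: g for g in study_pangenome.genotypes}
        founders = {g.family_id: g for g in study_pangenome.founder.genes}
        cases = truth[truth.event == "indel_1bp"]
        for _, row in cases.iterrows():
            gene = founders[row.family_id]
            best = max(study_validation[row.family_id][row.genotype],
                       key=lambda l: l.score)
            ea = exon_aware_align_cds(
                gene.cds_chunks(),
                extract_locus(by_gid[row.genotype].assembly, best))
            rep = detect_frameshift(ea, len(gene.protein))
            rep = rescue_alternative_start(rep, ea, pssms, calibrations)
            assert rep.alt_start is not None
            assert "CCT" in rep.retained_domains
            assert rep.rescued_protein.startswith("M")

    def test_no_downstream_atg_returns_none(self, pssm_library):
        pssms, calibrations = pssm_library
        # Frameshift followed by no in-frame ATG at all before the stop.
        ref = "ATG" + "GAA" * 20 + "TAA"
        variant = ref[:9] + "T" + ref[9:]  # +1 insertion, no ATG downstream
        ea = exon_aware_align_cds([ref], "CC" + variant + "GG")
        rep = detect_frameshift(ea, 21)
        assert rep.frameshift
        rep = rescue_alternative_start(rep, ea, pssms, calibrations)
        assert rep.alt_start is None
        assert rep.rescued_protein is None

    def test_non_frameshift_report_unchanged(self, small_pangenome, pssm_library):
        pssms, calibrations = pssm_library
        gene = small_pangenome.founder.genes[0]
        ea = exon_aware_align_cds(gene.cds_chunks(), gene.gene_seq())
        rep = detect_frameshift(ea, len(gene.protein))
        rep = rescue_alternative_start(rep, ea, pssms, calibrations)
        assert rep.alt_start is None and not rep.frameshift


class TestReconcile:
    def test_statuses_match_planted_events(self, study_pangenome,
                                           study_validation, pssm_library):
        pssms, calibrations = pssm_library
        truth = study_pangenome.truth
        by_gid = {g.genotype_id: g for g in study_pangenome.genotypes}
        expectations = {
            "deletion": "TRUE_DELETION",
            "annotation_truncation": "MISANNOTATION_CANDIDATE",
            "indel_1bp": "NATURAL_VARIANT",
            "domain_deletion": "PARTIAL_DOMAIN_LOSS",
        }
        seen = {k: 0 for k in expectations}
        for gene in study_pangenome.founder.genes:
            chunks = gene.cds_chunks()
            domain_cds = {lab: (s * 3, e * 3)
                          for lab, (s, e) in gene.domain_aa.items()}
            for g in study_pangenome.genotypes:
                loci = study_validation[gene.family_id][g.genotype_id]
                ea = rep = None
                if loci:
                    best = max(loci, key=lambda l: l.score)
                    ea = exon_aware_align_cds(
                        chunks, extract_locus(g.assembly, best))
                    rep = detect_frameshift(ea, len(gene.protein))
                    rep = rescue_alternative_start(rep, ea, pssms, calibrations)
                status = reconcile_with_annotation(
                    loci, ea, rep, g.proteins.get(gene.family_id),
                    gene.protein, gene.architecture, domain_cds,
                    pssms, calibrations)
                events = set(truth[(truth.family_id == gene.family_id)
                                   & (truth.genotype == g.genotype_id)].event)
                for event, expected in expectations.items():
                    if event in events:
                        assert status == expected, \
                            (gene.family_id, g.genotype_id, event, status)
                        seen[event] += 1
                if not (events - {"tandem_duplication",
                                  "dispersed_duplication"}) and loci:
                    assert status == "CONSISTENT", \
                        (gene.family_id, g.genotype_id, status)
        assert all(n > 0 for n in seen.values()), seen  # every event exercised


class TestCopyLabels:
    def _diverge(self, seq, rate, seed):
        rng = np.random.default_rng(seed)
        return "".join(
            "ACGT"[("ACGT".index(c) + 1 + rng.integers(3)) % 4]
            if rng.random() < rate else c
            for c in seq
        )

    def test_identical_to_reference(self):
        rng = np.random.default_rng(0)
        ref_a = "".join(rng.choice(list("ACGT"), size=400))
        ref_b = self._diverge(ref_a, 0.3, 1)
        labels = classify_copies_by_reference(
            {"q": ref_a}, {"Ha": ref_a, "Hb": ref_b})
        assert labels[0].label == "Ha"
        assert labels[0].best_identity == 1.0

    def test_simulated_paralogs_all_correct(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=500))
        refs = {
            "Ha": base,
            "Hb": self._diverge(base, 0.25, 10),
            "Hc": self._diverge(base, 0.25, 11),
        }
        queries, expected = {}, {}
        n = 0
        for label, ref in refs.items():
            for i in range(5):
                qid = f"q{n}"
                queries[qid] = self._diverge(ref, 0.08, 100 + n)
                expected[qid] = label
                n += 1
        for cl in classify_copies_by_reference(queries, refs):
            assert cl.label == expected[cl.locus_id]

    def test_exact_tie_is_ambiguous(self):
        ref_a = "ACGTACGTACGTACGTACGT"
        ref_b = ref_a[:-2] + "TA"  # differs at two positions
        query = ref_a[:-1] + "A"   # one mismatch to each reference
        out = classify_copies_by_reference({"q": query},
                                           {"A": ref_a, "B": ref_b})
        assert out[0].label == "AMBIGUOUS"

    def test_single_reference_rejected(self):
        with pytest.raises(ValueError):
            classify_copies_by_reference({"q": "ACGT"}, {"A": "ACGT"})


class TestCrosstab:
    def test_marginals_conserved(self):
        counts = pd.DataFrame(
            [[1, 0, 2, 1, 0, 1]],
            index=["vrn"], columns=[f"g{i}" for i in range(6)],
        )
        m = PresenceMatrix(counts)
        labels = {"g0": "spring", "g1": "spring", "g2": "winter",
                  "g3": "winter", "g4": "facultative"}
        table = crosstab_presence_phenotype(m, labels, "vrn")
        assert table.to_numpy().sum() == 6
        assert "unknown" in table.columns  # g5 unlabeled
        assert table.loc["absent", "spring"] == 1
        assert table.loc["present", "winter"] == 2

    def test_all_present_gives_empty_absent_row(self):
        counts = pd.DataFrame([[1, 1, 1]], index=["g"],
                              columns=["a", "b", "c"])
        table = crosstab_presence_phenotype(
            PresenceMatrix(counts), {"a": "x", "b": "x", "c": "y"}, "g")
        assert (table.loc["absent"] == 0).all()
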