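"""Translation core: effect annotation, mutant proteins, chaining, phasing, fusions."""
from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    cds_effect,
    make_reads,
    oracle_mutant_protein,
    random_coding_locus,
    random_edits,
    toy_locus,
)
from neopept.consensus import ConsensusVariant
from neopept.errors import ReferenceMismatchError, UnresolvableOverlapError
from neopept.formats import FusionRecord, read_bedpe
from neopept.fixtures import FUSION_FLANK3, FUSION_FLANK5, compose_protein
from neopept.transcript import TranscriptModel
from neopept.transgene import (
    FusionFilterOptions,
    annotate_coding_effects,
    build_fusion_iar,
    chain_events,
    filter_expressed,
    filter_fusions,
    mutant_protein,
    pair_evidence,
    peptide_window,
    phase_group,
)

PROT = compose_protein(40, {5: "F"})  # F at residue 5 for SNV tests


def snv_variant(model, genome, cds_off, alt_tx_base):
    """Genomic SNV touching ``cds_off`` (transcript-strand alt given)."""
    from neopept.transcript import revcomp

    gpos = model.cds_positions[cds_off]
    ref = genome[model.chrom][gpos]
    alt = alt_tx_base if model.strand == "+" else revcomp(alt_tx_base)
    return ConsensusVariant(model.chrom, gpos, ref, alt, frozenset({"t"}), "snv")


class TestAnnotateCodingEffects:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_missense_strand_aware(self, strand):
        model, genome, _ = toy_locus(PROT, strand=strand)
        # F (TTT) -> V (GTT) at residue 5: transcript base T->G at offset 12
        variant = snv_variant(model, genome, 12, "G")
        (eff,) = annotate_coding_effects(variant, [model], genome)
        assert eff.effect_class == "missense"
        assert (eff.ref_aa, eff.alt_aa_or_tail) == ("F", "V")
        assert eff.protein_pos == 5 and eff.cds_offset == 12

    def test_synonymous(self):
        model, genome, _ = toy_locus(PROT)
        # residue 5 F: TTT -> TTC is still F (offset 14, T->C)
        variant = snv_variant(model, genome, 14, "C")
        (eff,) = annotate_coding_effects(variant, [model], genome)
        assert eff.effect_class == "synonymous"

    def test_two_bp_deletion_is_frameshift(self):
        model, genome, _ = toy_locus(PROT)
        gpos = model.cds_positions[20]
        ref = genome[model.chrom][gpos : gpos + 2]
        variant = ConsensusVariant("chr1", gpos, ref, "", frozenset({"t"}), "deletion")
        (eff,) = annotate_coding_effects(variant, [model], genome)
        assert eff.effect_class == "frameshift"

    def test_inframe_insertion(self):
        model, genome, _ = toy_locus(PROT)
        gpos = model.cds_positions[21]
        variant = ConsensusVariant("chr1", gpos, "", "GCT", frozenset({"t"}), "insertion")
        (eff,) = annotate_coding_effects(variant, [model], genome)
        assert eff.effect_class == "inframe_ins"

    def test_reference_mismatch_raises(self):
        model, genome, _ = toy_locus(PROT)
        gpos = model.cds_positions[12]
        wrong = "A" if genome["chr1"][gpos] != "A" else "C"
        variant = ConsensusVariant("chr1", gpos, wrong, "G", frozenset({"t"}), "snv")
        with pytest.raises(ReferenceMismatchError):
            annotate_coding_effects(variant, [model], genome)

    def test_noncoding_transcript_omitted(self):
        model, genome, _ = toy_locus(PROT)
        linc = TranscriptModel("L.t1", "L", "L", "lincRNA", "chr1", "+",
                               exons=model.exons, cds=[])
        variant = snv_variant(model, genome, 12, "G")
        effects = annotate_coding_effects(variant, [model, linc], genome)
        assert [e.transcript_id for e in effects] == [model.transcript_id]

    def test_utr_snv_has_no_effect(self):
        model, genome, _ = toy_locus(PROT)
        gpos = model.exons[0][0] + 2  # inside the 5' UTR
        ref = genome["chr1"][gpos]
        alt = "A" if ref != "A" else "C"
        variant = ConsensusVariant("chr1", gpos, ref, alt, frozenset({"t"}), "snv")
        assert annotate_coding_effects(variant, [model], genome) == []


class TestFilterExpressed:
    def _effects(self, tids):
        model, genome, _ = toy_locus(PROT)
        base = snv_variant(model, genome, 12, "G")
        (eff,) = annotate_coding_effects(base, [model], genome)
        import dataclasses

        return [dataclasses.replace(eff, transcript_id=t) for t in tids]

    def test_tpm_boundaries(self):
        import pandas as pd

        expr = pd.DataFrame(
            {"gene_id": ["G"] * 3, "tpm": [5.2, 0.0, 1.0]},
            index=pd.Index(["T_hi", "T_zero", "T_low"], name="transcript_id"),
        )
        effects = self._effects(["T_hi", "T_zero", "T_low", "T_missing"])
        kept = filter_expressed(effects, expr, min_tpm=0.0)
        assert [e.transcript_id for e in kept] == ["T_hi", "T_low"]
        # strict inequality at the threshold
        kept = filter_expressed(effects, expr, min_tpm=5.2)
        assert kept == []


class TestMutantProtein:
    def test_single_missense_differs_at_one_residue(self):
        model, genome, _ = toy_locus(PROT)
        eff = cds_effect(model, 12, "T", "G", genome)
        mp = mutant_protein(model, [eff], genome)
        assert sum(a != b for a, b in zip(mp.seq, mp.wt_seq)) == 1
        assert mp.mutant_indices == {4}
        assert mp.frameshift_start is None

    def test_frameshift_tail_stops_after_seven_novel_residues(self):
        # dual-frame block: deleting its first two bases exposes seven
        # novel codons then a stop in the shifted frame
        from neopept.fixtures import PREF_CODON, codons

        part1 = compose_protein(10)
        block = "AA" + "GCTGCAGAAGGACATAAACCTTAA" + "A"
        cds_nt = codons(part1) + block + codons("GG")
        from neopept.fixtures import build_gene

        gene = build_gene("G1", "chr1", "+", 50, random.Random(3), part1, cds_nt=cds_nt)
        genome = {"chr1": "T" * 50 + gene.genomic_chunk() + "T" * 400}
        off = 30  # start of the block
        ref = gene.model.spliced_cds(genome)[off : off + 2]
        eff = cds_effect(gene.model, off, ref, "", genome)
        mp = mutant_protein(gene.model, [eff], genome)
        assert mp.frameshift_start == 10
        assert mp.seq == gene.protein[:10] + "AAEGHKP"

    def test_frameshift_without_stop_hits_max_tail(self):
        # poly-alanine CDS is stop-free in every frame, as is the GCA tail
        model, genome, layout = toy_locus("M" + "A" * 19, utr3=0, tail=0)
        genome = {"chr1": genome["chr1"] + "GCA" * 200}
        cds = layout["cds"]
        eff = cds_effect(model, 30, cds[30], "", genome)
        mp = mutant_protein(model, [eff], genome, max_tail=12)
        assert mp.frameshift_start == 10
        assert len(mp.seq) == 10 + 12

    def test_overlapping_effects_raise(self):
        model, genome, layout = toy_locus(PROT)
        cds = layout["cds"]
        e1 = cds_effect(model, 12, cds[12 : 12 + 3], "", genome)
        e2 = cds_effect(model, 13, cds[13], "G", genome)
        with pytest.raises(UnresolvableOverlapError):
            mutant_protein(model, [e1, e2], genome)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_edits_match_independent_retranslation(self, seed):
        rng = random.Random(seed)
        for _ in range(5):
            model, genome, layout = random_coding_locus(rng)
            effects = random_edits(rng, model, genome)
            mp = mutant_protein(model, effects, genome)
            assert mp.seq == oracle_mutant_protein(layout, effects)


class TestChainEvents:
    def _effects_at(self, offsets):
        model, genome, _ = toy_locus(compose_protein(80))
        cds = model.spliced_cds(genome)
        return [cds_effect(model, o, cds[o], "G" if cds[o] != "G" else "A", genome)
                for o in offsets]

    @pytest.mark.parametrize("gap,n,n_groups", [
        (12, 9, 1), (40, 10, 2), (40, 15, 1), (27, 9, 1), (28, 9, 2),
        (30, 10, 1), (45, 15, 1), (46, 15, 2),
    ])
    def test_window_thresholds(self, gap, n, n_groups):
        effects = self._effects_at([10, 10 + gap])
        assert len(chain_events(effects, n)) == n_groups

    def test_transitive_single_linkage(self):
        effects = self._effects_at([0, 25, 50])
        groups = chain_events(effects, 9)
        assert len(groups) == 1 and len(groups[0]) == 3

    @given(offsets=st.lists(st.integers(0, 200), min_size=1, max_size=8, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_order_invariant_and_idempotent(self, offsets):
        effects = self._effects_at(sorted(offsets))
        shuffled = list(effects)
        random.Random(0).shuffle(shuffled)
        groups_a = chain_events(effects, 10)
        groups_b = chain_events(shuffled, 10)
        assert [[e.key for e in g] for g in groups_a] == [[e.key for e in g] for g in groups_b]
        regrouped = [chain_events(g, 10) for g in groups_a]
        assert all(len(r) == 1 for r in regrouped)


class TestPhasing:
    def _pair(self):
        model, genome, _ = toy_locus(compose_protein(80), utr3=100)
        cds = model.spliced_cds(genome)
        e1 = cds_effect(model, 30, cds[30], "G" if cds[30] != "G" else "A", genome)
        e2 = cds_effect(model, 42, cds[42], "G" if cds[42] != "G" else "A", genome)
        return model, genome, e1, e2

    def _subs(self, effects):
        return {e.variant.pos: e.variant.alt for e in effects}

    def test_cis_reads_join(self):
        model, genome, e1, e2 = self._pair()
        start = e1.variant.pos - 5
        reads = make_reads(genome, [(f"r{i}", "chr1", start, self._subs([e1, e2]))
                                    for i in range(5)])
        ((group, status),) = phase_group([e1, e2], reads)
        assert len(group) == 2 and status == "cis_confirmed"
        ev = pair_evidence(e1, e2, reads)
        assert (ev.cis_reads, ev.trans_reads) == (5, 0)

    def test_trans_majority_splits(self):
        model, genome, e1, e2 = self._pair()
        start = e1.variant.pos - 5
        reads = make_reads(genome, [
            ("cis", "chr1", start, self._subs([e1, e2])),
            ("t1", "chr1", start, self._subs([e1])),
            ("t2", "chr1", start, self._subs([e1])),
            ("t3", "chr1", start, self._subs([e2])),
        ])
        result = phase_group([e1, e2], reads)
        assert [len(g) for g, _ in result] == [1, 1]
        assert all(status == "no_evidence" for _, status in result)

    def test_zero_coverage_splits_conservatively(self):
        model, genome, e1, e2 = self._pair()
        result = phase_group([e1, e2], [])
        assert [len(g) for g, _ in result] == [1, 1]
        assert all(status == "no_evidence" for _, status in result)

    def test_singleton_not_applicable(self):
        model, genome, e1, _ = self._pair()
        ((group, status),) = phase_group([e1], [])
        assert status == "not_applicable"


class TestPeptideWindows:
    def _mp(self, residue, n_len=60):
        model, genome, _ = toy_locus(compose_protein(n_len, {residue: "F"}))
        off = (residue - 1) * 3
        eff = cds_effect(model, off, "T", "G", genome)  # F -> V
        return mutant_protein(model, [eff], genome)

    @pytest.mark.parametrize("n,length", [(9, 17), (10, 19), (15, 29)])
    def test_flank_law_single_missense(self, n, length):
        mp = self._mp(30)
        mut, wt, positions = peptide_window(mp, n)
        assert len(mut) == length and len(wt) == length
        assert positions == (n - 1,)
        assert mut[n - 1] == "V" and wt[n - 1] == "F"

    def test_clipped_at_n_terminus(self):
        mp = self._mp(3)
        mut, wt, positions = peptide_window(mp, 10)
        assert len(mut) == 12  # residues 1..12: 2 upstream + mutant + 9 downstream
        assert positions == (2,)

    def test_difference_positions_only_at_mutant_sites(self):
        mp = self._mp(30)
        mut, wt, positions = peptide_window(mp, 10)
        diffs = tuple(i for i, (a, b) in enumerate(zip(mut, wt)) if a != b)
        assert diffs == positions


def mini_model(name, chrom, start, biotype="protein_coding", coding=True,
               length=300, strand="+"):
    cds = [(start + 60, start + 240)] if coding else []
    return TranscriptModel(f"{name}.t1", name, name, biotype, chrom, strand,
                           exons=[(start, start + length)], cds=cds)


def fusion(name, c5, bp5, c3, bp3, support=5):
    return FusionRecord(c5, bp5, bp5 + 1, c3, bp3, bp3 + 1, name, support)


class TestFilterFusions:
    @pytest.fixture()
    def models(self):
        return [
            mini_model("UP", "chr9", 1000),
            mini_model("DOWN", "chr22", 1000),
            mini_model("NEAR1", "chr5", 10_000),
            mini_model("NEAR2", "chr5", 410_000),
            mini_model("FAR", "chr5", 610_100),
            mini_model("MITO1", "chrM", 100),
            mini_model("MITO2", "chrM", 700),
            mini_model("IGX", "chr14", 100, biotype="IG_V_gene", coding=False),
            mini_model("IGY", "chr14", 600, biotype="IG_C_gene", coding=False),
            mini_model("LNC", "chr7", 100, biotype="lincRNA", coding=False),
        ]

    def reasons(self, fusions, models, **opts):
        _, rejected = filter_fusions(fusions, models, FusionFilterOptions(**opts))
        return {f.name: r for f, r in rejected}

    def test_readthrough_boundary(self, models):
        near = fusion("NEAR1--NEAR2", "chr5", 10_050, "chr5", 410_050)   # 400 kb
        far = fusion("NEAR1--FAR", "chr5", 10_050, "chr5", 610_050)      # 600 kb
        exact = fusion("NEAR1--FAR", "chr5", 110_050, "chr5", 610_050)   # 500 kb
        kept, rejected = filter_fusions([near, far, exact], models)
        assert [f.name for f in kept] == ["NEAR1--FAR"]
        assert all(r == ["readthrough"] for _, r in rejected)

    def test_mito_ig_linc_reasons(self, models):
        out = self.reasons([
            fusion("MITO1--MITO2", "chrM", 150, "chrM", 750),
            fusion("IGX--IGY", "chr14", 150, "chr14", 650),
            fusion("LNC--DOWN", "chr7", 150, "chr22", 1100),
        ], models)
        # the close same-contig mitochondrial pair also trips readthrough
        assert set(out["MITO1--MITO2"]) == {"mito_mito", "readthrough"}
        assert set(out["IGX--IGY"]) == {"ig_ig", "readthrough"}
        assert out["LNC--DOWN"] == ["linc_5p"]

    def test_unresolved_gene(self, models):
        out = self.reasons([fusion("GHOST--DOWN", "chr1", 5, "chr22", 1100)], models)
        assert out["GHOST--DOWN"] == ["unresolved_gene"]

    def test_multiple_reasons_single_emission(self, models):
        # same-chromosome immunoglobulin pair: ig_ig and readthrough
        _, rejected = filter_fusions(
            [fusion("IGX--IGY", "chr14", 150, "chr14", 650)], models)
        assert len(rejected) == 1
        assert set(rejected[0][1]) == {"ig_ig", "readthrough"}

    def test_disabling_all_filters_keeps_everything(self, models):
        fusions = [
            fusion("MITO1--MITO2", "chrM", 150, "chrM", 750),
            fusion("IGX--IGY", "chr14", 150, "chr14", 650),
            fusion("LNC--DOWN", "chr7", 150, "chr22", 1100),
            fusion("NEAR1--NEAR2", "chr5", 10_050, "chr5", 410_050),
        ]
        kept, rejected = filter_fusions(
            fusions, models,
            FusionFilterOptions(filter_mito=False, filter_ig=False,
                                filter_readthrough=False, filter_linc=False))
        assert kept == fusions and rejected == []


class TestBuildFusionIar:
    @pytest.fixture()
    def fixture_fusions(self, fixture_set):
        return {f.key: f for f in read_bedpe(fixture_set.path("bedpe"))}

    def _get(self, fixture_fusions, name):
        return next(f for f in fixture_fusions.values() if f.name == name)

    @pytest.mark.parametrize("n,length", [(9, 16), (10, 18), (15, 28)])
    def test_flank_law_untruncated(self, n, length, fixture_fusions,
                                   fixture_models, fixture_genome):
        fus = self._get(fixture_fusions, "FUS5--FUS3")
        build = build_fusion_iar(fus, fixture_models, fixture_genome, n)
        assert build.ok and len(build.peptide) == length
        if n == 10:
            assert build.peptide == FUSION_FLANK5 + FUSION_FLANK3

    def test_early_stop_truncates(self, fixture_fusions, fixture_models, fixture_genome):
        fus = self._get(fixture_fusions, "FUS5--FUS3S")
        build = build_fusion_iar(fus, fixture_models, fixture_genome, 10)
        assert build.ok and build.peptide == "DNSKMALNSELS"

    def test_utr_breakpoint_yields_no_region(self, fixture_fusions,
                                             fixture_models, fixture_genome):
        fus = self._get(fixture_fusions, "RT1--RT3")
        build = build_fusion_iar(fus, fixture_models, fixture_genome, 10)
        assert not build.ok and build.reason == "utr_5p"

    def test_intronic_breakpoint_unsupported(self, fixture_fusions,
                                             fixture_models, fixture_genome):
        fus = self._get(fixture_fusions, "GENEA--FUS3")
        build = build_fusion_iar(fus, fixture_models, fixture_genome, 10)
        assert not build.ok and build.reason == "intronic_5p"

    def test_junction_sequences_take_precedence(self):
        seq5 = "GATAACAGCAAAATGGCTCTGAATAGC"  # DNSKMALNS
        seq3 = "GAAGCTCTGAGCGTTGTTAGCGAAGATGGT"
        fus = FusionRecord("chrX", 10, 11, "chrY", 20, 21, "A--B", 1,
                           junction_seq5=seq5, junction_seq3=seq3)
        build = build_fusion_iar(fus, [], {}, 10)
        assert build.ok and build.peptide == FUSION_FLANK5 + FUSION_FLANK3

    def test_mutant_positions_cover_novel_portion(self, fixture_fusions,
                                                  fixture_models, fixture_genome):
        fus = self._get(fixture_fusions, "FUS5--FUS3")
        build = build_fusion_iar(fus, fixture_models, fixture_genome, 10)
        assert build.positions == tuple(range(9, 18))
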