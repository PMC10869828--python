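"""Mining procedures: exon inference, model selection, family assignment,
LoF detection, status assignment, TM screening, contamination screening."""

import numpy as np
import pytest

from chemomine import miner
from chemomine._align import revcomp, translate_dna
from chemomine.miner import (
    FamilyParams,
    GeneModel,
    LoFEvent,
    RefRecord,
    ReferenceDB,
    Repertoire,
    assign_status,
    classify_family,
    count_tm_helices,
    default_family_params,
    detect_lof,
    infer_exon_count,
    predict_gene_models,
    screen_contamination,
    select_gene_models,
)
from chemomine.seqcore import Genome, GenomicInterval
from chemomine.synthdata import (
    PlantSpec,
    _reverse_translate,
    build_reference_db,
    generate_synthetic_genome,
)
from conftest import match_candidates_to_truth, receptor_and_cds


class TestInferExonCount:
    def test_merge_rule_example(self):
        # gap 140 separates the first block; gap 10 merges the last two
        assert infer_exon_count([(0, 60), (200, 290), (300, 360)]) == 2

    def test_short_hit_dropped(self):
        assert infer_exon_count([(0, 40)]) == 0

    def test_empty(self):
        assert infer_exon_count([]) == 0

    def test_matches_brute_force(self):
        def brute(spans, min_bp=50, gap_bp=100):
            kept = sorted((s, e) for s, e in spans if e - s >= min_bp)
            count = 0
            prev_end = None
            for s, e in kept:
                if prev_end is None or s - prev_end >= gap_bp:
                    count += 1
                prev_end = max(prev_end or e, e)
            return count

        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(0, 8))
            spans = []
            pos = 0
            for _ in range(n):
                pos += int(rng.integers(0, 300))
                ln = int(rng.integers(10, 200))
                spans.append((pos, pos + ln))
                pos += ln
            assert infer_exon_count(spans) == brute(spans)


def _model(start, end, cds_len, score, exons=1, ref="r"):
    span = end - start
    per = span // exons
    exon_list = [
        GenomicInterval("sc", start + i * per,
                        start + (i + 1) * per if i < exons - 1 else end)
        for i in range(exons)
    ]
    return GeneModel(exon_list, "A" * cds_len, score, ref)


class TestSelectGeneModels:
    def setup_method(self):
        self.params = default_family_params("V2R", "multi")  # L starts at 2700

    def test_overlapping_pair_keeps_best_score(self):
        p1 = _model(0, 4000, 2700, 120, exons=2, ref="a")
        p2 = _model(100, 4100, 2700, 90, exons=2, ref="b")
        assert select_gene_models([p1, p2], 3, self.params) == [p1]

    def test_exon_cap_discards(self):
        p = _model(0, 4000, 2700, 120, exons=5)
        assert select_gene_models([p], 3, self.params) == []

    def test_second_iteration_accepts_shorter_disjoint_model(self):
        p1 = _model(0, 4000, 2700, 120, exons=2, ref="a")
        p3 = _model(10_000, 12_000, 1500, 80, exons=1, ref="c")
        accepted = select_gene_models([p1, p3], 3, self.params)
        assert accepted == sorted([p1, p3], key=lambda m: m.span.start)

    def test_order_invariance_and_disjoint_output(self):
        rng = np.random.default_rng(5)
        models = []
        for i in range(12):
            s = int(rng.integers(0, 20_000))
            e = s + int(rng.integers(500, 5000))
            models.append(
                _model(s, e, int(rng.integers(300, 2800)),
                       float(rng.integers(10, 200)), ref=f"r{i}")
            )
        ref_out = select_gene_models(models, 4, self.params)
        for perm_seed in range(5):
            perm = list(np.random.default_rng(perm_seed).permutation(len(models)))
            out = select_gene_models([models[i] for i in perm], 4, self.params)
            assert [m.span for m in out] == [m.span for m in ref_out]
        for a, b in zip(ref_out, ref_out[1:]):
            assert not a.span.overlaps(b.span)


class TestClassifyFamily:
    def setup_method(self):
        self.db, self.base = build_reference_db(["OR", "TAAR"], seed=0)

    def test_exact_copy_assigned_to_family(self):
        fam, ref, score = classify_family(self.base["OR"], self.db)
        assert fam == "OR" and ref == "OR_ref1"

    def test_decoy_best_match_rejected(self):
        decoy = self.db["DECOY_1"].protein
        fam, ref, _ = classify_family(decoy, self.db)
        assert fam is None and ref == "DECOY_1"

    def test_tie_broken_lexicographically(self):
        shared = self.base["OR"]
        db = ReferenceDB([
            RefRecord("B_ref", shared, "OR", "family_query"),
            RefRecord("A_ref", shared, "TAAR", "family_query"),
        ])
        fam, ref, _ = classify_family(shared, db)
        assert ref == "A_ref" and fam == "TAAR"

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            classify_family("", self.db)


class TestDetectLof:
    def test_premature_stop_at_reference_codon(self):
        prot, cds = receptor_and_cds(0)
        mut = cds[: 49 * 3] + "TAA" + cds[50 * 3 :]
        events = detect_lof(mut, prot)
        assert [e.key for e in events] == ["premature_stop@50"]

    def test_single_nt_deletion_locates_codon_34(self):
        prot, cds = receptor_and_cds(0)
        mut = cds[:99] + cds[100:]  # delete nt 100 (1-based)
        events = detect_lof(mut, prot)
        assert [e.key for e in events] == ["frameshift_deletion@34"]

    def test_insertion_detected(self):
        prot, cds = receptor_and_cds(0)
        mut = cds[:300] + "G" + cds[300:]
        events = detect_lof(mut, prot)
        assert len(events) == 1 and events[0].kind == "frameshift_insertion"
        assert abs(events[0].ref_codon_position - 101) <= 1

    def test_unmutated_copy_is_clean(self):
        prot, cds = receptor_and_cds(0)
        assert detect_lof(cds, prot) == []

    def test_every_shipped_reference_is_clean_against_itself(self):
        db, _ = build_reference_db(["OR", "V2R"], seed=3)
        rng = np.random.default_rng(0)
        for rec in db.records:
            if rec.role != "family_query":
                continue
            cds = _reverse_translate(rec.protein, rng)
            assert detect_lof(cds, rec.protein) == []

    def test_stop_inside_margin_not_called(self):
        prot, cds = receptor_and_cds(0)
        n = len(prot)
        mut = cds[: (n - 5) * 3] + "TAA" + cds[(n - 4) * 3 :]
        assert detect_lof(mut, prot) == []

    def test_unalignable_sequence_raises(self):
        prot, _ = receptor_and_cds(0)
        with pytest.raises(ValueError):
            detect_lof("ACGT" * 50, prot[:0] or "MKKLLL" * 50)


class TestAssignStatus:
    def setup_method(self):
        self.params = default_family_params("OR", "single")

    def test_intact_long_orf_is_complete(self):
        prot, cds = receptor_and_cds(0)  # 933 nt with stop
        assert assign_status(cds + "TAA", [], False, self.params) == "complete"

    def test_fragment_with_stop_is_pseudogene(self):
        assert (
            assign_status("ATG" + "A" * 300, [LoFEvent("premature_stop", 50)],
                          False, self.params)
            == "pseudogene"
        )

    def test_edge_vs_truncated_contrast(self):
        frag = "ATG" + "GCA" * 199  # 600 nt intact fragment, no stop
        assert assign_status(frag, [], True, self.params) == "edge"
        assert assign_status(frag, [], False, self.params) == "truncated"

    def test_ambiguity_dominates(self):
        prot, cds = receptor_and_cds(0)
        dirty = cds[:100] + "N" + cds[101:]
        assert assign_status(dirty + "TAA", [], False, self.params) == "ambiguous"

    def test_lof_dominates_border(self):
        assert (
            assign_status("ATG" + "A" * 300, [LoFEvent("premature_stop", 40)],
                          True, self.params)
            == "pseudogene"
        )


class TestCountTmHelices:
    def test_seven_leucine_stretches(self):
        protein = "S" * 10 + ("L" * 21 + "S" * 10) * 7
        count, ok = count_tm_helices(protein)
        assert count == 7 and ok

    def test_poly_glutamate_fails(self):
        assert count_tm_helices("E" * 300) == (0, False)

    def test_generator_template_passes(self):
        prot, _ = receptor_and_cds(0)
        count, ok = count_tm_helices(prot)
        assert ok and count >= 6

    def test_short_protein_zero(self):
        assert count_tm_helices("LLLL") == (0, False)


class TestPredictGeneModels:
    def _region_genome(self, seq):
        g = Genome({"r": seq})
        return g, GenomicInterval("r", 0, len(seq))

    def test_two_exon_gtag_plant_recovered_exactly(self):
        prot, cds = receptor_and_cds(2, aa_len=300)
        full = cds + "TAA"
        rng = np.random.default_rng(4)
        bg = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        intron = "GT" + bg(200) + "AG"
        seq = bg(800) + full[:450] + intron + full[450:] + bg(800)
        g, region = self._region_genome(seq)
        params = default_family_params("V1R", "multi")
        models = predict_gene_models(g, region, prot, params)
        best = max(models, key=lambda m: m.score)
        assert best.exon_count == 2
        assert best.cds_nt == full

    def test_single_exact_copy_one_exon(self):
        prot, cds = receptor_and_cds(2, aa_len=300)
        rng = np.random.default_rng(4)
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        g, region = self._region_genome(bg + cds + "TAA" + bg)
        models = predict_gene_models(
            g, region, prot, default_family_params("V1R", "multi")
        )
        best = max(models, key=lambda m: m.score)
        assert best.exon_count == 1
        assert best.cds_nt == cds + "TAA"

    def test_reversed_genomic_order_not_chained(self):
        prot, cds = receptor_and_cds(2, aa_len=300)
        half = len(cds) // 2
        half -= half % 3
        rng = np.random.default_rng(4)
        bg = lambda n: "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        # second protein half upstream of the first: order violation
        seq = bg(500) + cds[half:] + bg(500) + cds[:half] + bg(500)
        g, region = self._region_genome(seq)
        models = sorted(
            predict_gene_models(
                g, region, prot, default_family_params("V1R", "multi")
            ),
            key=lambda m: -m.score,
        )
        # the two planted halves come out as separate single-exon models;
        # the order-violating join is never made
        assert len(models) >= 2
        assert models[0].exon_count == 1 and models[1].exon_count == 1
        spans = {(m.span.start, m.span.end) for m in models[:2]}
        assert spans == {(500, 950), (1450, 1900)}


class TestMineSingleExon:
    def test_benchmark_counts_match_truth(self, benchmark_genome):
        genome, truth, refdb = benchmark_genome
        cands = miner.mine_single_exon(genome, "OR", refdb)
        sub = truth[(truth.family == "OR")]
        expected = sub.target_status.value_counts().to_dict()
        got = {}
        for c in cands:
            got[c.status] = got.get(c.status, 0) + 1
        assert got == expected

    def test_taar_plant_excluded_from_or_run(self, benchmark_genome):
        genome, truth, refdb = benchmark_genome
        cands = miner.mine_single_exon(genome, "OR", refdb)
        taar_rows = truth[truth.family == "TAAR"]
        for _, row in taar_rows.iterrows():
            for c in cands:
                span = c.model.span
                assert not (
                    span.scaffold_id == row.scaffold
                    and span.start < row.end
                    and row.start < span.end
                )

    def test_pure_random_genome_yields_nothing(self):
        rng = np.random.default_rng(9)
        g = Genome(
            {"s": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100_000)])}
        )
        db, _ = build_reference_db(["OR"], seed=0)
        assert miner.mine_single_exon(g, "OR", db) == []

    def test_status_partition_conserved(self, benchmark_genome):
        genome, truth, refdb = benchmark_genome
        rep = Repertoire()
        cands = miner.mine_single_exon(genome, "OR", refdb)
        rep.add_candidates("sp1", cands)
        frame = rep.to_frame()
        row = frame[frame.family == "OR"].iloc[0]
        assert row.total == sum(
            row[s] for s in ("complete", "pseudogene", "truncated", "edge",
                             "ambiguous")
        )
        assert all(c.status in miner.STATUSES for c in cands)


class TestMineMultiExon:
    def test_benchmark_v2r_statuses(self, benchmark_genome):
        genome, truth, refdb = benchmark_genome
        cands = miner.mine_multi_exon(genome, "V2R", refdb)
        pairs = match_candidates_to_truth(cands, truth[truth.family == "V2R"])
        for row, matches in pairs:
            assert len(matches) == 1
            assert matches[0].status == row.target_status

    def test_sub_400_fragment_absent(self):
        specs = [
            PlantSpec("V2R", "multi", "complete", "+", intron_count=3),
            PlantSpec("V2R", "multi", "truncated", "+", intron_count=0,
                      fragment_nt=351),
        ]
        genome, truth, refdb = generate_synthetic_genome(
            specs, background_kb=300, seed=8
        )
        cands = miner.mine_multi_exon(genome, "V2R", refdb)
        frag = truth[truth.cds_len < 400].iloc[0]
        for c in cands:
            span = c.model.span
            assert not (
                span.scaffold_id == frag.scaffold
                and span.start < frag.end
                and frag.start < span.end
            )

    def test_intact_multi_exon_v1r_above_810_complete(self):
        specs = [PlantSpec("V1R", "multi", "complete", "+", intron_count=2)]
        genome, truth, refdb = generate_synthetic_genome(
            specs, background_kb=300, seed=8
        )
        cands = miner.mine_multi_exon(genome, "V1R", refdb)
        assert len(cands) == 1
        assert cands[0].status == "complete"
        assert len(cands[0].model.cds_nt) >= 810


class TestStrandSymmetry:
    def test_reverse_complemented_genome_yields_same_cds_set(self):
        specs = [
            PlantSpec("OR", "single", "complete", "+"),
            PlantSpec("OR", "single", "pseudogene", "-",
                      lof=[("premature_stop", 110)]),
        ]
        genome, truth, refdb = generate_synthetic_genome(
            specs, background_kb=120, seed=4
        )
        flipped = Genome({k: revcomp(v) for k, v in genome.scaffolds.items()})
        fwd = miner.mine_single_exon(genome, "OR", refdb)
        rev = miner.mine_single_exon(flipped, "OR", refdb)
        assert sorted(c.model.cds_nt for c in fwd) == sorted(
            c.model.cds_nt for c in rev
        )


class TestScreenContamination:
    def _cds(self):
        prot, cds = receptor_and_cds(0)
        return cds

    def test_identical_flagged(self):
        cds = self._cds()
        table = screen_contamination({"c1": cds}, {"f1": cds})
        assert len(table) == 1
        assert table.iloc[0].identity == pytest.approx(1.0)
        assert bool(table.iloc[0].suspect)

    def test_no_match_absent(self):
        cds = self._cds()
        rng = np.random.default_rng(1)  # shares no seed word with the query
        foreign = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 600)])
        table = screen_contamination({"c1": cds}, {"f1": foreign})
        assert len(table) == 0

    def test_eighty_percent_identity_not_flagged(self):
        # replace every 5th codon with one differing at all three positions
        # (and coding a different residue): exactly 80% of aligned
        # nucleotide columns stay identical
        cds = self._cds()
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        all_codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
        for i in range(0, len(codons) - 1, 5):
            orig = codons[i]
            for cand in all_codons:
                if (
                    all(x != y for x, y in zip(cand, orig))
                    and translate_dna(cand) not in ("*", translate_dna(orig))
                ):
                    codons[i] = cand
                    break
        mutated = "".join(codons)
        table = screen_contamination({"c1": cds}, {"f1": mutated})
        assert len(table) == 1
        assert table.iloc[0].identity == pytest.approx(0.80, abs=0.01)
        assert not bool(table.iloc[0].suspect)


class TestFamilyParamsValidation:
    def test_reporting_floor_cannot_exceed_complete_floor(self):
        with pytest.raises(ValueError):
            FamilyParams("V2R", "multi", min_complete_nt=300, flank_bp=100,
                         min_report_nt=400)

    def test_published_defaults(self):
        assert default_family_params("OR").min_complete_nt == 750
        assert default_family_params("TAAR").min_complete_nt == 850
        assert default_family_params("V1R").min_complete_nt == 810
        assert default_family_params("V2R").min_complete_nt == 2100
        assert default_family_params("T1R").min_complete_nt == 2200
        assert default_family_params("V2R").flank_bp == 30000
        assert default_family_params("OR").flank_bp == 1000
        assert default_family_params("T1R").min_report_nt == 400
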