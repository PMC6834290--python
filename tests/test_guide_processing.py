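"""Exhaustive alignment, multi-target rules, mapping, scoring and QC."""

import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from paralethal import guide_processing as gp
from paralethal import synthetic_data as sd


def _hit(start=0, n_mm=0, positions=(), chrom="chr1", strand="+"):
    return gp.AlignmentHit(
        chromosome=chrom, strand=strand, start=start, end=start + 20,
        n_mismatches=n_mm, mismatch_positions=frozenset(positions),
        pam="AGG", pam_canonical=True,
    )


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plant(seq, site, pos):
    return seq[:pos] + site + seq[pos + len(site):]


PROTO = "ACGTACGTACGTACGTACGT"


def _clean_background(rng, length):
    """Random sequence with no accidental <=2-mismatch hit of PROTO."""
    while True:
        seq = _random_seq(rng, length)
        if not orc.scan_guide(PROTO, {"chr1": seq}):
            return seq


class TestAlignGuide:
    def test_planted_unique_site(self):
        rng = np.random.default_rng(0)
        seq = _plant(_clean_background(rng, 10_000), PROTO + "AGG", 4000)
        hits = gp.align_guide(PROTO, {"chr1": seq})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.n_mismatches, h.strand) == (4000, 4020, 0, "+")
        assert h.pam == "AGG" and h.pam_canonical

    def test_copied_site_on_second_chromosome(self):
        rng = np.random.default_rng(1)
        site = PROTO + "AGG"
        c1 = _plant(_clean_background(rng, 8_000), site, 1000)
        c2 = _plant(_clean_background(rng, 8_000), site, 5000)
        hits = gp.align_guide(PROTO, {"chr1": c1, "chr2": c2})
        perfect = [h for h in hits if h.n_mismatches == 0]
        assert len(perfect) == 2
        assert {h.chromosome for h in perfect} == {"chr1", "chr2"}

    def test_mismatch_positions_pam_distal(self):
        rng = np.random.default_rng(2)
        # second occurrence differs at PAM-distal positions 1 and 2, PAM TGG
        variant = "GT" + PROTO[2:]
        assert variant != PROTO
        seq = _plant(_clean_background(rng, 12_000), PROTO + "AGG", 2000)
        seq = _plant(seq, variant + "TGG", 9000)
        hits = gp.align_guide(PROTO, {"chr1": seq})
        by_start = {h.start: h for h in hits}
        assert by_start[2000].n_mismatches == 0
        assert by_start[9000].mismatch_positions == frozenset({1, 2})
        assert by_start[9000].pam == "TGG"

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(3)
        site = orc.revcomp(PROTO + "CGG")  # revcomp site: PAM 5' of window
        seq = _plant(_clean_background(rng, 6_000), site, 3000)
        hits = gp.align_guide(PROTO, {"chr1": seq})
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].pam == "CGG"

    def test_non_ngg_pam_discarded(self):
        rng = np.random.default_rng(4)
        seq = _plant(_clean_background(rng, 6_000), PROTO + "AGT", 3000)
        assert gp.align_guide(PROTO, {"chr1": seq}) == []

    def test_contig_edge_hit_discarded(self):
        rng = np.random.default_rng(5)
        seq = _clean_background(rng, 5_000) + PROTO  # no room for a PAM
        assert gp.align_guide(PROTO, {"chr1": seq}) == []

    def test_invalid_protospacer_rejected(self):
        with pytest.raises(ValueError):
            gp.align_guide("ACGTN" + "A" * 15, {"chr1": "ACGT" * 100})
        with pytest.raises(ValueError):
            gp.align_guide("ACGT", {"chr1": "ACGT" * 100})

    def test_removing_chromosome_never_adds_hits(self, toy_genome, toy_guides):
        genome = toy_genome["genome"]
        smaller = {k: v for k, v in list(genome.items())[:1]}
        for proto in toy_guides["guides"]["protospacer"][:10]:
            assert len(gp.align_guide(proto, smaller)) <= len(
                gp.align_guide(proto, genome)
            )


class TestClassifyMultiTargeting:
    @pytest.mark.parametrize(
        "hits,expected,reason",
        [
            ([_hit(0)], False, ""),
            ([_hit(0), _hit(500)], True, "multiple perfect"),
            ([_hit(0), _hit(500, 1, {7})], True, "single mismatch"),
            ([_hit(0), _hit(500, 2, {1, 2})], True, "double mismatch PAM-distal"),
            ([_hit(0), _hit(500, 2, {1, 19})], False, ""),
            ([_hit(0), _hit(500, 2, {3, 4})], False, ""),
            ([_hit(0, 1, {5})], False, ""),  # no perfect hit at all
        ],
    )
    def test_rules(self, hits, expected, reason):
        is_multi, why = gp.classify_multi_targeting(hits)
        assert is_multi is expected
        if expected:
            assert why == reason

    def test_empty_hits_flagged_unalignable(self):
        assert gp.classify_multi_targeting([]) == (False, gp.DROP_UNALIGNABLE)

    def test_oracle_equivalence_on_toy_library(self, toy_genome, toy_guides):
        """Package verdicts equal a literal all-offset scan for every guide."""
        genome = toy_genome["genome"]
        for rec in toy_guides["guides"].itertuples():
            hits = gp.align_guide(rec.protospacer, genome)
            verdict, _ = gp.classify_multi_targeting(hits)
            oracle = orc.is_multi_target(orc.scan_guide(rec.protospacer, genome))
            assert verdict == oracle, rec.guide_id

    def test_planted_duplicates_all_flagged(self, toy_genome, toy_guides):
        """Every guide in an exact-copy duplicated gene is caught."""
        genes = set(
            toy_genome["dupmap"][["source_gene", "target_gene"]].to_numpy().ravel()
        )
        genome = toy_genome["genome"]
        caught = []
        for rec in toy_guides["guides"].itertuples():
            if rec.intended_gene in genes:
                hits = gp.align_guide(rec.protospacer, genome)
                caught.append(gp.classify_multi_targeting(hits)[0])
        assert caught and all(caught)


class TestGuideGeneMap:
    GENES = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 100, "end": 300, "name": "GA",
             "score": 0, "strand": "+"},
            {"chrom": "chr1", "start": 280, "end": 500, "name": "GB",
             "score": 0, "strand": "+"},
        ]
    )

    def _map_for(self, hits):
        guides = pd.DataFrame(
            [{"guide_id": "g1", "protospacer": PROTO, "intended_gene": "GA"}]
        )
        return gp.build_guide_gene_map(guides, {"g1": hits}, self.GENES)

    def test_single_gene_locus_retained(self):
        table = self._map_for([_hit(150)]).table
        assert table.loc[0, "retained"]
        assert table.loc[0, "gene"] == "GA"

    def test_overlapping_genes_dropped(self):
        table = self._map_for([_hit(285)]).table
        assert not table.loc[0, "retained"]
        assert table.loc[0, "reason"] == gp.DROP_MULTI_GENE

    def test_intergenic_dropped(self):
        table = self._map_for([_hit(700)]).table
        assert table.loc[0, "reason"] == gp.DROP_INTERGENIC

    def test_multi_target_dropped(self):
        table = self._map_for([_hit(150), _hit(700)]).table
        assert table.loc[0, "reason"] == gp.DROP_MULTI

    def test_no_perfect_hit_dropped(self):
        table = self._map_for([_hit(150, 1, {4})]).table
        assert table.loc[0, "reason"] == gp.DROP_NO_PERFECT

    def test_map_matches_per_guide_rescan(self, toy_genome, toy_guides):
        genome, genes = toy_genome["genome"], toy_genome["genes"]
        guides = toy_guides["guides"]
        hit_lists = {
            r.guide_id: gp.align_guide(r.protospacer, genome)
            for r in guides.itertuples()
        }
        gmap = gp.build_guide_gene_map(guides, hit_lists, genes)
        for rec in gmap.table.itertuples():
            oracle_hits = orc.scan_guide(
                guides.set_index("guide_id").loc[rec.sgRNA, "protospacer"], genome
            )
            if orc.is_multi_target(oracle_hits):
                assert not rec.retained and rec.reason == gp.DROP_MULTI


class TestGateAndScore:
    def _gmap(self, counts):
        rows = []
        for gene, n in counts.items():
            for j in range(n):
                rows.append((f"{gene}_{j}", gene, True, ""))
        return gp.GuideGeneMap(
            pd.DataFrame(rows, columns=["sgRNA", "gene", "retained", "reason"])
        )

    def test_guide_count_gate(self):
        gmap = self._gmap({"G4": 4, "G2": 2, "G3": 3})
        gmap.table = pd.concat(
            [gmap.table,
             pd.DataFrame([("G0_0", "G0", False, gp.DROP_MULTI)],
                          columns=gmap.table.columns)],
            ignore_index=True,
        )
        retained, dropped = gp.gate_genes_by_guide_count(gmap)
        assert retained == ["G3", "G4"]
        reasons = dropped.set_index("gene")["reason"]
        assert reasons["G2"] == "too few guides"
        assert reasons["G0"] == "no guides"

    def test_mean_scoring_and_missing_handling(self):
        gmap = self._gmap({"GA": 3})
        lfc = pd.DataFrame(
            {"l1": [-1.0, -2.0, -3.0], "l2": [0.0, 0.0, 0.0],
             "l3": [-1.0, np.nan, -3.0]},
            index=["GA_0", "GA_1", "GA_2"],
        )
        scores = gp.score_genes(lfc, gmap, ["GA"])
        assert scores.loc["GA", "l1"] == pytest.approx(-2.0)
        assert scores.loc["GA", "l2"] == 0.0
        assert np.isnan(scores.loc["GA", "l3"])  # < 3 informative guides

    def test_score_recovery_on_toy_cohort(self, small_cohort):
        by_gene = small_cohort.guide_map.set_index("sgRNA")["gene"]
        lfc = small_cohort.lfc.copy()
        lfc.index = by_gene.loc[lfc.index].to_numpy()
        scores = lfc.groupby(level=0).mean()
        truth = small_cohort.truth.true_scores.loc[scores.index]
        r = np.corrcoef(scores.to_numpy().ravel(), truth.to_numpy().ravel())[0, 1]
        assert r > 0.9


class TestPrecisionRecallQC:
    def _scores(self, values):
        return pd.DataFrame({"line": values})

    def test_perfect_separation(self):
        scores = pd.DataFrame(
            {"l": [-3.0, -2.0, 1.0, 2.0]}, index=["e1", "e2", "n1", "n2"]
        )
        _, mean_auc = gp.precision_recall_qc(scores, {"e1", "e2"}, {"n1", "n2"})
        assert mean_auc == 1.0

    def test_hand_average_precision(self):
        # positives at ranks 1 and 3 -> AP = (1/1 + 2/3) / 2
        scores = pd.DataFrame(
            {"l": [-3.0, -2.0, -1.0, 0.0]}, index=["e1", "n1", "e2", "n2"]
        )
        _, mean_auc = gp.precision_recall_qc(scores, {"e1", "e2"}, {"n1", "n2"})
        assert mean_auc == pytest.approx(5 / 6)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        pos = set(genes[:10])
        neg = set(genes[10:])
        scores = pd.DataFrame(
            {"l1": rng.normal(size=30), "l2": rng.normal(size=30)}, index=genes
        )
        per_line, mean_auc = gp.precision_recall_qc(scores, pos, neg)
        for line in scores.columns:
            ranked = scores[line].sort_values().index
            expected = orc.average_precision([g in pos for g in ranked])
            assert per_line[line] == pytest.approx(expected)

    def test_disjointness_and_coverage_errors(self):
        scores = pd.DataFrame({"l": [-1.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            gp.precision_recall_qc(scores, {"a"}, {"a"})
        with pytest.raises(ValueError):
            gp.precision_recall_qc(scores, {"zz"}, {"b"})


class TestFilteringBias:
    def test_high_identity_pairs_dropped_more(self, toy_genome, toy_guides):
        """Genes duplicated verbatim (identity ~100%) lose guides to the
        multi-target filter more often than the gene set overall."""
        genome, genes = toy_genome["genome"], toy_genome["genes"]
        guides = toy_guides["guides"]
        hit_lists = {
            r.guide_id: gp.align_guide(r.protospacer, genome)
            for r in guides.itertuples()
        }
        gmap = gp.build_guide_gene_map(guides, hit_lists, genes)
        retained, dropped = gp.gate_genes_by_guide_count(gmap)
        dropped_set = set(dropped["gene"]) | (
            set(genes["name"]) - set(retained) - set(dropped["gene"])
        )
        high_identity = set(
            toy_genome["dupmap"][["source_gene", "target_gene"]].to_numpy().ravel()
        )
        rate_high = len(high_identity & dropped_set) / len(high_identity)
        rate_all = len(dropped_set) / len(genes)
        assert rate_high > rate_all
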