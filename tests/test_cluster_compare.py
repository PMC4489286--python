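"""Dereplication engine: bundle I/O, alignment, significance filtering,
synteny scoring and ranking."""

import pytest

from bgcmine.compare import (ClusterComparison, ReferenceCluster,
                             SimilarityHit, align_pair, align_proteins,
                             attach_links, compare_cluster,
                             filter_significant, load_reference_bundle,
                             parse_tabular_alignments, rank,
                             reference_from_genes, save_reference_bundle,
                             score_comparison)
from bgcmine.records import BgcmineError, Gene

from _oracles import brute_comparison
from conftest import make_gene

PROT_A = "MKLVINSGSSSIKYQLIDAETGEEL"
PROT_B = "MTEYKLVVVGAGGVGKSALTIQLIQ"
PROT_C = "MSDNELKQRLAAYLDGELSAEEQAE"


def _ref(ref_id="refX", seqs=(PROT_A, PROT_B, PROT_C), strands=(1, 1, 1),
         source="known"):
    genes = [(f"{ref_id}_g{i}", s, strand)
             for i, (s, strand) in enumerate(zip(seqs, strands))]
    return ReferenceCluster(ref_id, f"label {ref_id}", source, genes)


def _query(seqs=(PROT_A, PROT_B, PROT_C), strands=None):
    strands = strands or [1] * len(seqs)
    return [make_gene(f"q{i}", i * 2000, i * 2000 + 1000,
                      strand=strands[i], translation=s)
            for i, s in enumerate(seqs)]


class TestBundleIO:
    def test_round_trip_identity(self, tmp_path):
        refs = [_ref("alpha"), _ref("beta", strands=(1, -1, 1))]
        fasta, sidecar = tmp_path / "b.faa", tmp_path / "b.tsv"
        save_reference_bundle(refs, fasta, sidecar)
        loaded = load_reference_bundle(fasta, sidecar)
        assert [r.ref_id for r in loaded] == ["alpha", "beta"]
        for a, b in zip(refs, loaded):
            assert a.genes == b.genes and a.label == b.label

    def test_missing_sidecar_entry_falls_back_to_ref_id(self, tmp_path):
        fasta = tmp_path / "b.faa"
        save_reference_bundle([_ref("solo")], fasta)
        (ref,) = load_reference_bundle(fasta)
        assert ref.label == "solo"

    def test_duplicate_gene_rejected(self, tmp_path):
        fasta = tmp_path / "b.faa"
        fasta.write_text(">r|g|0|1\nMKV\n>r|g|1|1\nMKV\n")
        with pytest.raises(BgcmineError, match="duplicate"):
            load_reference_bundle(fasta)

    def test_malformed_header_names_line(self, tmp_path):
        fasta = tmp_path / "b.faa"
        fasta.write_text(">justonefield\nMKV\n")
        with pytest.raises(BgcmineError, match="line 1"):
            load_reference_bundle(fasta)


class TestAlignment:
    def test_identical_sequences_full_identity_and_coverage(self):
        identity, coverage, score = align_pair(PROT_A, PROT_A)
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(100.0)
        assert score > 0

    def test_unrelated_sequences_no_significant_hit(self):
        result = align_pair("MKKKKKKKKKKK", "WDWDWDWDWDWD")
        if result is not None:
            identity, coverage, _ = result
            assert coverage < 25 or identity < 30

    def test_exact_prefix_has_full_coverage_of_shorter(self):
        half = PROT_A[:12]
        identity, coverage, _ = align_pair(half, PROT_A)
        assert identity == pytest.approx(100.0)
        assert coverage == pytest.approx(100.0)

    def test_align_proteins_emits_hits_for_homologs(self):
        hits = align_proteins(_query(), [_ref()])
        pairs = {(h.query_gene, h.subject_gene) for h in hits}
        assert ("q0", "refX_g0") in pairs and ("q2", "refX_g2") in pairs


class TestFilterSignificant:
    def _hit(self, identity, coverage, query="q0", subject="s0", score=50.0):
        return SimilarityHit(query, "refX", subject, identity, coverage,
                             score)

    def test_identity_just_below_threshold_dropped(self):
        assert filter_significant([self._hit(29.9, 80.0)]) == []

    def test_inclusive_bounds_kept(self):
        assert len(filter_significant([self._hit(30.0, 25.0)])) == 1

    def test_best_subject_gene_per_query_kept(self):
        a = self._hit(90, 90, subject="s0", score=10)
        b = self._hit(95, 90, subject="s1", score=99)
        assert filter_significant([a, b]) == [b]


class TestScoring:
    def test_self_comparison_is_maximal(self):
        query = _query()
        ref = reference_from_genes("self", "itself", query)
        hits = filter_significant(align_proteins(query, [ref]))
        comp = score_comparison(query, ref, hits,
                                core_query_genes=frozenset({"q0"}))
        assert comp.hit_gene_count == 3
        assert comp.synteny_score == 2  # n - 1
        assert comp.core_bonus == 3
        assert comp.percent_query_genes_hit == pytest.approx(100.0)
        assert comp.total_score == 3 + 2 + 3

    def test_permuted_reference_order_zeroes_synteny(self):
        """Query genes hitting reference genes in order (1,3,2) conserve no
        adjacency."""
        query = _query()
        ref = _ref("perm", seqs=(PROT_A, PROT_C, PROT_B))
        # q0->perm_g0, q1->perm_g2, q2->perm_g1
        hits = filter_significant(align_proteins(query, [ref]))
        by_query = {h.query_gene: h.subject_gene for h in hits}
        assert by_query == {"q0": "perm_g0", "q1": "perm_g2",
                            "q2": "perm_g1"}
        comp = score_comparison(query, ref, hits)
        assert comp.synteny_score == 0

    def test_no_hits_scores_zero(self):
        comp = score_comparison(_query(), _ref(), [])
        assert comp.total_score == 0
        assert comp.percent_query_genes_hit == 0.0

    def test_score_invariant_under_gene_renaming(self):
        query = _query()
        ref = reference_from_genes("self", "itself", query)
        hits = filter_significant(align_proteins(query, [ref]))
        comp = score_comparison(query, ref, hits)
        renamed_query = [Gene(f"zz_{g.gene_id}", g.record_id, g.parts,
                              g.strand, g.translation) for g in query]
        renamed_hits = [SimilarityHit(f"zz_{h.query_gene}", h.subject_ref_id,
                                      h.subject_gene, h.percent_identity,
                                      h.coverage, h.score) for h in hits]
        comp2 = score_comparison(renamed_query, ref, renamed_hits)
        assert (comp2.hit_gene_count, comp2.synteny_score,
                comp2.total_score) == (comp.hit_gene_count,
                                       comp.synteny_score, comp.total_score)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pipeline(self, seed):
        """filter -> score equals an independent naive reimplementation on
        random small bundles."""
        import numpy as np
        rng = np.random.default_rng(3000 + seed)
        n_q = int(rng.integers(2, 6))
        query = [make_gene(f"q{i}", i * 2000, i * 2000 + 1000,
                           strand=int(rng.choice([1, -1])))
                 for i in range(n_q)]
        refs = []
        for r in range(int(rng.integers(1, 6))):
            n_g = int(rng.integers(1, 6))
            refs.append(ReferenceCluster(
                f"ref{r}", f"ref {r}", "known",
                [(f"ref{r}_g{i}", "MKV", int(rng.choice([1, -1])))
                 for i in range(n_g)]))
        hits = []
        for q in query:
            for ref in refs:
                for gid, _, _ in ref.genes:
                    if rng.random() < 0.5:
                        hits.append(SimilarityHit(
                            q.gene_id, ref.ref_id, gid,
                            float(rng.uniform(10, 100)),
                            float(rng.uniform(10, 100)),
                            float(rng.uniform(1, 200))))
        core = frozenset(g.gene_id for g in query if rng.random() < 0.3)
        kept = filter_significant(hits)
        for ref in refs:
            comp = score_comparison(query, ref, kept, core_query_genes=core)
            expected = brute_comparison(query, ref, hits, core)
            assert (comp.hit_gene_count, comp.synteny_score, comp.core_bonus,
                    comp.total_score, comp.percent_query_genes_hit
                    ) == pytest.approx(expected)


class TestRanking:
    def _comp(self, ref_id, count, synteny, core=0, percent=50.0):
        return ClusterComparison(ref_id, ref_id, count, synteny, core,
                                 percent)

    def test_self_hit_ranks_first(self):
        query = _query()
        refs = [reference_from_genes("self", "itself", query),
                _ref("partial", seqs=(PROT_A, PROT_B, "MWWWWWWWWWWWWWW"))]
        ranked = compare_cluster(query, refs)
        assert ranked[0].ref_id == "self"
        assert ranked[0].percent_query_genes_hit == pytest.approx(100.0)

    def test_tie_breaks_by_percent_then_ref_id(self):
        a = self._comp("b", 3, 1, percent=60)
        b = self._comp("a", 3, 1, percent=60)
        c = self._comp("c", 3, 0, percent=90)
        ranked = rank([a, b, c])
        assert [x.ref_id for x in ranked] == ["a", "b", "c"]

    def test_stable_under_permutation_and_top_n(self, rng):
        comps = [self._comp(f"r{i}", int(rng.integers(0, 6)),
                            int(rng.integers(0, 3)))
                 for i in range(8)]
        base = [c.ref_id for c in rank(comps)]
        for _ in range(5):
            perm = [comps[i] for i in rng.permutation(8)]
            assert [c.ref_id for c in rank(perm)] == base
        assert rank(comps, top_n=0) == []

    def test_attach_links_only_for_known(self):
        known = attach_links(self._comp("BGC001", 1, 0), "http://x/")
        assert known.hyperlink == "http://x/BGC001"
        genomic = self._comp("g1", 1, 0)
        genomic.source = "genomic"
        assert attach_links(genomic, "http://x/").hyperlink is None


class TestTabularAdapter:
    def test_parse_twelve_columns(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("q0\trefX|refX_g0|0|1\t95.0\t20\t1\t0\t1\t20\t1\t20"
                        "\t1e-20\t80.5\n")
        (h,) = parse_tabular_alignments(path, ["refX"])
        assert h.query_gene == "q0" and h.subject_gene == "refX_g0"
        assert h.percent_identity == 95.0 and h.score == 80.5
        assert h.coverage == pytest.approx(100.0)

    def test_bad_subject_id_reported(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("q0\tnostructure\t95.0\t20\t1\t0\t1\t20\t1\t20"
                        "\t1e-20\t80.5\n")
        with pytest.raises(BgcmineError, match="line 1"):
            parse_tabular_alignments(path, ["refX"])
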