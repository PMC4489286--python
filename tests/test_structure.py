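"""Module splitting, monomer prediction, reduction states and SMILES
scaffold assembly."""

import pytest
from rdkit import Chem

from bgcmine import data as bundled
from bgcmine.hmm import filter_hits, scan_protein
from bgcmine.records import DomainHit
from bgcmine.structure import (BiosynModule, MonomerPrediction,
                               UNKNOWN_MONOMER, assemble_scaffold,
                               build_architecture, canonical_smiles,
                               detect_trans_at, load_code_table,
                               load_monomer_fragments, predict_a_specificity,
                               predict_at_specificity,
                               predict_cluster_structure, reduction_state,
                               split_modules)
from bgcmine.synthetic import consensus_protein

from conftest import make_gene


def _hit(name, start, gene="g1"):
    return DomainHit(gene, name, start, start + 10, 40.0)


def _arch(names, gene="g1"):
    gene_obj = make_gene(gene, 0, 3000)
    hits = [_hit(n, i * 20, gene) for i, n in enumerate(names)]
    return build_architecture(gene_obj, hits)


def _module(kind, names, monomer=None, gene="g1"):
    return BiosynModule(1, kind, [(n, _hit(n, i * 20, gene))
                                  for i, n in enumerate(names)],
                        gene_id=gene,
                        monomer=monomer or UNKNOWN_MONOMER)


def canon(s):
    return Chem.MolToSmiles(Chem.MolFromSmiles(s))


class TestArchitecture:
    def test_empty_when_no_assembly_domains(self):
        gene = make_gene("g1", 0, 3000)
        arch = build_architecture(gene, [_hit("Terpene", 0),
                                         _hit("ABC_tran", 30)])
        assert arch.domains == []

    def test_order_preserved_by_coordinate(self):
        arch = _arch(["KS", "AT", "KR", "ACP"])
        assert arch.names() == ["KS", "AT", "KR", "ACP"]

    def test_interleaved_profiles_sorted_by_envelope(self):
        gene = make_gene("g1", 0, 3000)
        hits = [_hit("AT", 50), _hit("KS", 10), _hit("ACP", 90)]
        arch = build_architecture(gene, hits)
        assert arch.names() == ["KS", "AT", "ACP"]


class TestSplitModules:
    def test_hand_walked_two_module_pks(self):
        """KS-AT-ACP-KS-AT-KR-ACP-TE: no loading, 2 extensions, second
        reduction-capable and terminal."""
        modules = split_modules([_arch(
            ["KS", "AT", "ACP", "KS", "AT", "KR", "ACP", "TE"])])
        assert [m.kind for m in modules] == ["pks_extension", "pks_extension"]
        assert [m.module_index for m in modules] == [1, 2]
        assert "KR" in modules[1].domain_names()
        assert not modules[0].terminal and modules[1].terminal

    def test_single_a_pcp_is_nrps_loading(self):
        modules = split_modules([_arch(["A", "PCP"])])
        assert [m.kind for m in modules] == ["nrps_loading"]

    def test_loading_at_acp_before_first_ks(self):
        modules = split_modules([_arch(["AT", "ACP", "KS", "AT", "ACP"])])
        assert [m.kind for m in modules] == ["pks_loading", "pks_extension"]

    def test_empty_input(self):
        assert split_modules([]) == []

    def test_modules_cross_gene_boundaries(self):
        modules = split_modules([_arch(["KS", "AT"], gene="g1"),
                                 _arch(["KR", "ACP", "TE"], gene="g2")])
        assert len(modules) == 1
        assert modules[0].domain_names() == {"KS", "AT", "KR", "ACP", "TE"}


class TestTransAt:
    def test_cis_cluster_unchanged(self):
        module = _module("pks_extension", ["KS", "ACP"])
        (out,) = detect_trans_at([module], ["t1pks"])
        assert not out.trans_at and out.monomer.call == "unknown"

    def test_transat_marks_atless_module(self):
        module = _module("pks_extension", ["KS", "ACP"])
        (out,) = detect_trans_at([module], ["transatpks"])
        assert out.trans_at
        assert out.monomer.call == "mal"
        assert out.monomer.confidence == "partial"

    def test_module_with_own_at_keeps_cis_call(self):
        module = _module("pks_extension", ["KS", "AT", "ACP"],
                         monomer=MonomerPrediction("YASH", "mmal", "exact"))
        (out,) = detect_trans_at([module], ["transatpks"])
        assert not out.trans_at and out.monomer.call == "mmal"


class TestMonomerPrediction:
    def _a_hit(self, code):
        overrides = {("A", 10 + i): aa for i, aa in enumerate(code)}
        seq = "M" + consensus_protein(["A"], overrides=overrides)
        profiles = bundled.toy_profiles()
        hits = filter_hits(scan_protein(seq, profiles["A"], gene_id="g1"),
                           profiles)
        return hits[0], seq

    def test_exact_code_match(self):
        hit, seq = self._a_hit("DLLFGIAV")  # ala row of the bundled table
        pred = predict_a_specificity(hit, seq, range(10, 18),
                                     load_code_table())
        assert pred.call == "ala" and pred.confidence == "exact"

    def test_partial_match_at_seven_of_eight(self):
        hit, seq = self._a_hit("DLLFGIAW")
        pred = predict_a_specificity(hit, seq, range(10, 18),
                                     load_code_table())
        assert pred.call == "ala" and pred.confidence == "partial"

    def test_all_gap_extraction_is_unknown(self):
        hit = DomainHit("g1", "A", 0, 5, 40.0, alignment={})
        pred = predict_a_specificity(hit, "MKV", range(10, 18),
                                     load_code_table())
        assert pred.call == "unknown" and pred.confidence == "none"

    def _at_hit(self, code):
        overrides = {("AT", 17 + i): aa for i, aa in enumerate(code)}
        seq = "M" + consensus_protein(["AT"], overrides=overrides)
        profiles = bundled.toy_profiles()
        hits = filter_hits(scan_protein(seq, profiles["AT"], gene_id="g1"),
                           profiles)
        return hits[0], seq

    @pytest.mark.parametrize("code,call,confidence", [
        ("HAFH", "mal", "exact"), ("YASH", "mmal", "exact"),
        ("AAAA", "mal", "partial")])
    def test_at_specificity_motif(self, code, call, confidence):
        hit, seq = self._at_hit(code)
        pred = predict_at_specificity(hit, seq)
        assert (pred.call, pred.confidence) == (call, confidence)


class TestReductionState:
    @pytest.mark.parametrize("present,expected", [
        (set(), "keto"),
        ({"DH"}, "keto"), ({"ER"}, "keto"), ({"DH", "ER"}, "keto"),
        ({"KR"}, "hydroxyl"), ({"KR", "ER"}, "hydroxyl"),
        ({"KR", "DH"}, "enoyl"),
        ({"KR", "DH", "ER"}, "methylene"),
    ])
    def test_all_presence_combinations(self, present, expected):
        module = _module("pks_extension",
                         ["KS", "AT", "ACP"] + sorted(present))
        assert reduction_state(module) == expected

    def test_inactive_kr_downgrades_to_keto(self):
        module = _module("pks_extension", ["KS", "AT", "KR", "DH", "ACP"])
        kr = module.hit_for("KR")
        inactive = frozenset({(kr.gene_id, "KR", kr.env_start)})
        assert reduction_state(module, inactive) == "keto"
        assert reduction_state(module) == "enoyl"

    def test_nrps_module_not_applicable(self):
        module = _module("nrps_extension", ["C", "A", "PCP"])
        assert reduction_state(module) == "n/a"


class TestScaffoldAssembly:
    def _pks(self, reduction, monomer="mal", terminal=False):
        m = _module("pks_extension", ["KS", "AT", "ACP"],
                    monomer=MonomerPrediction("", monomer, "partial"))
        m.reduction = reduction
        m.terminal = terminal
        return m

    def _loading(self):
        return _module("pks_loading", ["CAL", "ACP"],
                       monomer=MonomerPrediction("", "acetyl", "partial"))

    def test_acetyl_plus_methylene_is_butyric_acid(self):
        scaffold = assemble_scaffold([self._loading(),
                                      self._pks("methylene", terminal=True)])
        assert scaffold.smiles == canon("CCCC(O)=O")
        assert len(scaffold.units) == 2

    def test_acetyl_plus_keto_is_acetoacetic_acid(self):
        scaffold = assemble_scaffold([self._loading(), self._pks("keto")])
        assert scaffold.smiles == canon("CC(=O)CC(O)=O")

    def test_hydroxyl_and_enoyl_states(self):
        assert assemble_scaffold(
            [self._loading(), self._pks("hydroxyl")]).smiles == canon(
                "CC(O)CC(O)=O")
        assert assemble_scaffold(
            [self._loading(), self._pks("enoyl")]).smiles == canon(
                "CC=CC(O)=O")

    def test_methylmalonyl_adds_alpha_methyl(self):
        scaffold = assemble_scaffold([self._loading(),
                                      self._pks("keto", monomer="mmal")])
        assert scaffold.smiles == canon("CC(=O)C(C)C(O)=O")

    def test_ala_gly_dipeptide(self):
        loading = _module("nrps_loading", ["A", "PCP"],
                          monomer=MonomerPrediction("", "ala", "exact"))
        ext = _module("nrps_extension", ["C", "A", "PCP", "TE"],
                      monomer=MonomerPrediction("", "gly", "exact"))
        scaffold = assemble_scaffold([loading, ext])
        assert scaffold.smiles == canon("CC(N)C(=O)NCC(O)=O")

    def test_colinearity_note_always_present(self):
        scaffold = assemble_scaffold([self._pks("keto")])
        assert any("co-linearity" in a for a in scaffold.assumptions)

    def test_empty_modules_give_none(self):
        assert assemble_scaffold([]) is None

    def test_neutral_domains_do_not_alter_scaffold(self):
        plain = assemble_scaffold([self._loading(), self._pks("keto")])
        decorated = self._pks("keto")
        decorated.domains += [("MT", _hit("MT", 200)),
                              ("Crotonase", _hit("Crotonase", 220))]
        with_extras = assemble_scaffold([self._loading(), decorated])
        assert plain.smiles == with_extras.smiles


class TestRandomizedArchitectures:
    REDUCTION_SETS = {
        "keto": (), "hydroxyl": ("KR",), "enoyl": ("KR", "DH"),
        "methylene": ("KR", "DH", "ER")}

    def _random_modules(self, rng):
        fragments = load_monomer_fragments()
        aa_calls = sorted(fragments)
        modules = []
        n_ext = int(rng.integers(1, 6))
        has_loading = bool(rng.random() < 0.5)
        if has_loading:
            if rng.random() < 0.5:
                modules.append(_module(
                    "pks_loading", ["CAL", "ACP"],
                    monomer=MonomerPrediction("", "acetyl", "partial")))
            else:
                modules.append(_module(
                    "nrps_loading", ["A", "PCP"],
                    monomer=MonomerPrediction(
                        "", aa_calls[int(rng.integers(len(aa_calls)))],
                        "exact")))
        for _ in range(n_ext):
            if rng.random() < 0.5:
                red = list(self.REDUCTION_SETS)[int(rng.integers(4))]
                m = _module("pks_extension",
                            ["KS", "AT", "ACP",
                             *self.REDUCTION_SETS[red]],
                            monomer=MonomerPrediction(
                                "", "mmal" if rng.random() < 0.3 else "mal",
                                "exact"))
                m.reduction = red
            else:
                m = _module("nrps_extension", ["C", "A", "PCP"],
                            monomer=MonomerPrediction(
                                "", aa_calls[int(rng.integers(len(aa_calls)))],
                                "exact"))
            modules.append(m)
        return modules, n_ext, has_loading

    def test_unit_count_parse_and_canonical_idempotence(self, rng):
        """200 random architectures: units = extensions (+ loading); every
        SMILES parses; canonicalization is idempotent."""
        for _ in range(200):
            modules, n_ext, has_loading = self._random_modules(rng)
            scaffold = assemble_scaffold(modules)
            assert len(scaffold.units) == n_ext + (1 if has_loading else 0)
            assert Chem.MolFromSmiles(scaffold.smiles) is not None
            assert canonical_smiles(scaffold.smiles) == scaffold.smiles

    def test_er_never_increases_oxygen_count(self):
        """Completing the reductive loop strips oxygens, never adds them."""
        for base_red, full_red in (("enoyl", "methylene"),
                                   ("hydroxyl", "enoyl")):
            without = assemble_scaffold([self._loading_module(),
                                         self._ext(base_red)])
            with_er = assemble_scaffold([self._loading_module(),
                                         self._ext(full_red)])
            assert with_er.smiles.count("O") <= without.smiles.count("O")

    def _loading_module(self):
        return _module("pks_loading", ["CAL"],
                       monomer=MonomerPrediction("", "acetyl", "partial"))

    def _ext(self, red):
        m = _module("pks_extension", ["KS", "AT", "ACP"],
                    monomer=MonomerPrediction("", "mal", "exact"))
        m.reduction = red
        return m


class TestClusterStructurePipeline:
    def test_planted_pks_gene_yields_scaffold(self):
        seq = "M" + consensus_protein(["CAL", "ACP"])
        seq2 = "M" + consensus_protein(["KS", "AT", "KR", "DH", "ER", "ACP",
                                        "TE"])
        genes = [make_gene("g1", 0, 3000, translation=seq),
                 make_gene("g2", 4000, 9000, translation=seq2)]
        profiles = bundled.toy_profiles()
        hits = []
        for g in genes:
            for name in ("CAL", "ACP", "KS", "AT", "KR", "DH", "ER", "TE"):
                hits.extend(scan_protein(g.translation, profiles[name],
                                         gene_id=g.gene_id))
        hits = filter_hits(hits, profiles)
        modules, scaffold = predict_cluster_structure(genes, hits, ["t1pks"])
        assert [m.kind for m in modules] == ["pks_loading", "pks_extension"]
        assert modules[1].reduction == "methylene"
        assert scaffold.smiles == canon("CCCC(O)=O")
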