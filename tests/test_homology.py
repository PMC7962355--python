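"""Whole-model homolog translation and orphan resolution."""

import pytest

from gsmforge.fba import blocked_reactions, fba
from gsmforge.homology import (
    EMPTIED,
    FULLY_MAPPED,
    HomologMap,
    HomologTableError,
    parse_homolog_table,
    resolve_orphans,
    translate_model,
)
from gsmforge.synth import (
    GenerationError,
    ToyModelSpec,
    make_homolog_fixture,
    make_toy_model,
    write_homolog_tsv,
)


class TestTableParsing:
    def test_two_column_no_header(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\ng2\th2\n")
        assert parse_homolog_table(str(p)).mapping == {"g1": "h1", "g2": "h2"}

    def test_named_columns_with_extras(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            "source\tidentity\ttarget\n"
            "g1\t93.1\th1\n"
            "g2\t40.0\t*\n"
            "g3\t88.8\t\n"
        )
        hm = parse_homolog_table(str(p), source_column="source",
                                 target_column="target")
        assert hm.mapping == {"g1": "h1"}

    def test_comments_and_duplicates_tolerated(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("# comment\ng1\th1\ng1\th1\n")
        assert parse_homolog_table(str(p)).mapping == {"g1": "h1"}

    def test_conflicting_duplicate_raises(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("g1\th1\ng1\th2\n")
        with pytest.raises(HomologTableError, match="conflicting"):
            parse_homolog_table(str(p))

    def test_tsv_roundtrip_of_fixture(self, toy_model, tmp_path):
        homologs, _ = make_homolog_fixture(toy_model, 0.25, 2, seed=5)
        p = tmp_path / "h.tsv"
        write_homolog_tsv(homologs, toy_model.genes, str(p))
        back = parse_homolog_table(
            str(p), source_column="source", target_column="target"
        )
        assert back.mapping == homologs.mapping


class TestTranslateModel:
    def test_identity_map_changes_nothing_functional(self, toy_model):
        out, report = translate_model(
            toy_model, HomologMap.identity(toy_model.genes)
        )
        assert report.unmapped_genes == set()
        assert report.sole_catalyst_reactions == set()
        assert out.genes == toy_model.genes
        assert fba(out).objective_value == pytest.approx(
            fba(toy_model).objective_value
        )

    def test_empty_map_empties_every_gpr(self, toy_model):
        out, report = translate_model(toy_model, HomologMap({}))
        assert report.n_gprs_rewritten == 0
        assert out.genes == set()
        gpr_rxns = {
            rid for rid, r in toy_model.reactions.items() if not r.gpr.is_empty
        }
        assert report.sole_catalyst_reactions == gpr_rxns

    def test_stoichiometry_and_bounds_untouched(self, toy_model):
        homologs, _ = make_homolog_fixture(toy_model, 0.3, 3, seed=1)
        out, _ = translate_model(toy_model, homologs)
        for rid, rxn in toy_model.reactions.items():
            assert out.reactions[rid].stoichiometry == rxn.stoichiometry
            assert out.reactions[rid].lower_bound == rxn.lower_bound
            assert out.reactions[rid].upper_bound == rxn.upper_bound
            assert out.reactions[rid].kind is rxn.kind

    def test_planted_partition_recovered(self, toy_model):
        homologs, truth = make_homolog_fixture(toy_model, 0.3, 3, seed=7)
        _, report = translate_model(toy_model, homologs)
        assert report.sole_catalyst_genes == truth.sole_catalyst_genes
        assert report.sole_catalyst_reactions == truth.sole_catalyst_reactions
        assert report.genes_covered_by_alternatives == truth.covered_genes
        assert report.unmapped_genes == (
            truth.sole_catalyst_genes | truth.covered_genes
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_recovery_across_seeds(self, toy_model, seed):
        homologs, truth = make_homolog_fixture(toy_model, 0.25, 2, seed=seed)
        _, report = translate_model(toy_model, homologs)
        assert report.sole_catalyst_genes == truth.sole_catalyst_genes
        assert report.genes_covered_by_alternatives == truth.covered_genes

    def test_rewrite_status_values(self, toy_model):
        homologs, truth = make_homolog_fixture(toy_model, 0.25, 2, seed=3)
        _, report = translate_model(toy_model, homologs)
        for rid in truth.sole_catalyst_reactions:
            assert report.rewrite_status[rid] == EMPTIED
        # reactions without any unmapped gene are fully mapped
        untouched = set(toy_model.reactions) - set(
            rid
            for rid, r in toy_model.reactions.items()
            if r.gpr.genes() & (truth.sole_catalyst_genes | truth.covered_genes)
        )
        for rid in untouched:
            assert report.rewrite_status[rid] == FULLY_MAPPED

    def test_report_json_is_serializable(self, toy_model):
        import json

        homologs, _ = make_homolog_fixture(toy_model, 0.25, 2, seed=0)
        _, report = translate_model(toy_model, homologs)
        payload = json.loads(report.to_json())
        assert set(payload["sole_catalyst_reactions"]) == report.sole_catalyst_reactions


class TestFixtureErrors:
    def test_too_many_sole_catalysts(self, toy_model):
        with pytest.raises(GenerationError):
            make_homolog_fixture(toy_model, 0.1, 5, seed=0)

    def test_bad_fraction(self, toy_model):
        with pytest.raises(GenerationError):
            make_homolog_fixture(toy_model, 1.5, 0, seed=0)

    def test_fraction_one_degenerate_design(self, toy_model):
        homologs, truth = make_homolog_fixture(toy_model, 1.0, 0, seed=0)
        assert len(homologs) == 0
        assert truth.sole_catalyst_genes == toy_model.genes


class TestResolveOrphans:
    def test_dead_end_deleted_bridge_retained(self, toy_model):
        out, res = resolve_orphans(toy_model, {"DEAD1", "GLCt"})
        assert res["DEAD1"].action == "deleted"
        assert res["DEAD1"].reason == "blocked"
        assert res["GLCt"].action == "retained"
        assert res["GLCt"].reason == "gap-creating"
        assert "DEAD1" not in out.reactions
        assert "GLCt" in out.reactions

    def test_retained_orphan_records_newly_blocked(self, toy_model):
        _, res = resolve_orphans(toy_model, {"GLCt"})
        # without the glucose transporter the whole trunk stalls
        assert "GLYC" in res["GLCt"].newly_blocked
        assert "BIOMASS" in res["GLCt"].newly_blocked

    def test_empty_orphan_set_is_noop(self, toy_model):
        out, res = resolve_orphans(toy_model, set())
        assert res == {}
        assert out.reactions.keys() == toy_model.reactions.keys()

    def test_unknown_orphan_rejected(self, toy_model):
        with pytest.raises(KeyError, match="nope"):
            resolve_orphans(toy_model, {"nope"})

    def test_planted_fates_recovered(self, toy_model):
        homologs, truth = make_homolog_fixture(toy_model, 1 / 3, 4, seed=11)
        translated, report = translate_model(toy_model, homologs)
        _, res = resolve_orphans(translated, report.sole_catalyst_reactions)
        fates = {rid: r.action for rid, r in res.items()}
        assert fates == truth.orphan_fates

    def test_growth_preserved_after_resolution(self, toy_model):
        """Deleting only blocked orphans can never change the optimum."""
        homologs, _ = make_homolog_fixture(toy_model, 0.3, 3, seed=2)
        translated, report = translate_model(toy_model, homologs)
        resolved, _ = resolve_orphans(translated, report.sole_catalyst_reactions)
        assert fba(resolved).objective_value == pytest.approx(
            fba(toy_model).objective_value, abs=1e-8
        )

    def test_blocked_set_shrinks_or_holds(self, toy_model):
        resolved, _ = resolve_orphans(toy_model, {"DEAD1", "DEAD2"})
        assert blocked_reactions(resolved) <= blocked_reactions(toy_model)
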