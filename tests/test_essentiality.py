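"""Gene/reaction deletion screens and subsystem summaries."""

import pytest

from acarflux.essentiality import (
    essentiality_summary,
    product_essential_genes,
    single_gene_deletion,
    single_reaction_deletion,
)
from acarflux.fba import FBAError
from acarflux.synthetic import (
    MINI_ACB_PRODUCT_GENES,
    make_branched_tradeoff,
    make_linear_chain,
)


class TestGeneDeletionScreen:
    def test_chain_genes_all_essential(self):
        model = make_linear_chain(3, 0.5, 10.0)
        results = {r.target_id: r for r in single_gene_deletion(model)}
        assert len(results) == 3
        for gene in ("g1", "g2", "g3"):
            assert results[gene].essential
            assert results[gene].gr_ratio == pytest.approx(0.0)

    def test_gene_outside_gprs_reports_ratio_one(self, mini, synthesis):
        model = mini.copy()
        model.genes = set(model.genes) | {"orphan_gene"}
        results = {r.target_id: r for r in single_gene_deletion(model, synthesis)}
        assert results["orphan_gene"].gr_ratio == pytest.approx(1.0)
        assert not results["orphan_gene"].essential
        assert len(results) == len(model.genes)

    def test_redundant_transporter_pair_not_essential(self):
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        results = {r.target_id: r for r in single_gene_deletion(model)}
        assert results["gT1"].gr_ratio == pytest.approx(1.0)
        assert results["gT2"].gr_ratio == pytest.approx(1.0)
        assert results["gB"].essential

    def test_gr_ratio_never_exceeds_one(self, mini, synthesis):
        for res in single_gene_deletion(mini, synthesis):
            assert res.gr_ratio <= 1.0 + 1e-6

    def test_nested_media_containment(self, mini, synthesis, rich):
        """Genes essential on the richer medium are a subset of those
        essential on the synthesis minimal medium — with a strict gap from
        the amino-acid-supply genes."""
        ess_syn = {
            r.target_id for r in single_gene_deletion(mini, synthesis) if r.essential
        }
        ess_rich = {
            r.target_id for r in single_gene_deletion(mini, rich) if r.essential
        }
        assert ess_rich <= ess_syn
        assert "gdh1" in ess_syn - ess_rich  # glutamate synthesis dispensable when fed

    def test_wild_type_infeasible_aborts(self, mini):
        from acarflux.medium import MediumSpec

        with pytest.raises(FBAError):
            single_gene_deletion(mini, MediumSpec(name="empty"))


class TestReactionDeletionScreen:
    def test_sole_carbon_exchange_essential(self, mini, synthesis):
        results = {
            r.target_id: r for r in single_reaction_deletion(mini, synthesis)
        }
        assert results["EX_malt"].essential
        assert results["MALTabc"].essential

    def test_redundant_branch_ratio_one(self):
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        results = {r.target_id: r for r in single_reaction_deletion(model)}
        assert results["T1"].gr_ratio == pytest.approx(1.0)

    def test_gene_and_reaction_screens_agree_for_single_reaction_genes(
        self, mini, synthesis
    ):
        """A gene whose deletion disables exactly one reaction has the
        same grRatio as that reaction's deletion."""
        gene_res = {r.target_id: r for r in single_gene_deletion(mini, synthesis)}
        rxn_res = {
            r.target_id: r for r in single_reaction_deletion(mini, synthesis)
        }
        pairs = [("zwf1", "PPPOX"), ("gdh1", "GDH"), ("acbC", "ACBC"),
                 ("resp1", "RESP"), ("tca1", "AKGS")]
        for gene, rxn in pairs:
            assert gene_res[gene].gr_ratio == pytest.approx(
                rxn_res[rxn].gr_ratio, abs=1e-6
            )


class TestProductEssentiality:
    def test_pathway_genes_product_essential_growth_nonessential(
        self, mini, synthesis
    ):
        product = {
            r.target_id: r
            for r in product_essential_genes(mini, synthesis, "EX_acb")
        }
        growth = {
            r.target_id: r for r in single_gene_deletion(mini, synthesis)
        }
        for gene in MINI_ACB_PRODUCT_GENES:
            assert product[gene].essential, gene
            assert not growth[gene].essential, gene

    def test_isozyme_pair_members_not_product_essential(self, mini, synthesis):
        product = {
            r.target_id: r
            for r in product_essential_genes(mini, synthesis, "EX_acb")
        }
        assert not product["acbB"].essential
        assert not product["rmlB"].essential

    def test_trey_deletion_neutral_for_growth_and_product(
        self, mini, synthesis
    ):
        from acarflux.fba import solve_fba
        from acarflux.model import apply_gene_deletion

        ko = apply_gene_deletion(mini, {"treY"})
        assert solve_fba(ko, synthesis).objective_value == pytest.approx(
            solve_fba(mini, synthesis).objective_value
        )
        assert solve_fba(ko, synthesis, objective="EX_acb").objective_value == \
            pytest.approx(
                solve_fba(mini, synthesis, objective="EX_acb").objective_value
            )
        # while byproduct capability vanishes
        assert solve_fba(ko, synthesis, objective="EX_compc").objective_value == \
            pytest.approx(0.0, abs=1e-9)
        assert solve_fba(mini, synthesis, objective="EX_compc").objective_value > 0.1

    def test_unproducible_product_raises(self, mini):
        from acarflux.medium import MediumSpec

        with pytest.raises(FBAError):
            product_essential_genes(
                mini, MediumSpec(name="empty"), "EX_acb"
            )


class TestSummary:
    def test_single_subsystem_toy(self):
        model = make_linear_chain(2, 0.5, 10.0)
        df = essentiality_summary(single_gene_deletion(model))
        row = df[df.subsystem == "Chain"].iloc[0]
        assert row.percent_of_essential == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self, mini, synthesis):
        df = essentiality_summary(single_gene_deletion(mini, synthesis))
        assert df.percent_of_essential.sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_essential_set_all_zero(self):
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        results = [
            r for r in single_gene_deletion(model) if r.target_id in ("gT1", "gT2")
        ]
        df = essentiality_summary(results)
        assert (df.percent_of_essential == 0).all()
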