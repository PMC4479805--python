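"""Stoichiometric assembly, balance checking and gene-deletion logic."""

import numpy as np
import pytest

from acarflux.gpr import GPR
from acarflux.model import (
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
    apply_gene_deletion,
    build_stoichiometric_matrix,
    check_balance,
)

from _oracles import element_balance_by_columns


def _two_met_model():
    return MetabolicModel(
        id="tiny",
        metabolites=[Metabolite("A[c]"), Metabolite("B[c]")],
        reactions=[Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0})],
    )


class TestStoichiometricMatrix:
    def test_single_reaction_column(self):
        S, met_index, rxn_index = build_stoichiometric_matrix(_two_met_model())
        assert S.shape == (2, 1)
        assert S[met_index["A[c]"], rxn_index["R1"]] == -1.0
        assert S[met_index["B[c]"], rxn_index["R1"]] == 1.0

    def test_empty_model(self):
        S, met_index, rxn_index = build_stoichiometric_matrix(MetabolicModel())
        assert S.shape == (0, 0)
        assert met_index == {} and rxn_index == {}

    def test_round_trip_reproduces_stoichiometries(self, mini):
        S, met_index, rxn_index = build_stoichiometric_matrix(mini)
        met_ids = {i: m for m, i in met_index.items()}
        for rxn in mini.reactions:
            col = S[:, rxn_index[rxn.id]]
            rebuilt = {
                met_ids[i]: col[i] for i in np.nonzero(col)[0]
            }
            assert rebuilt == rxn.stoichiometry

    def test_dangling_reference_raises(self):
        with pytest.raises(ModelStructureError):
            MetabolicModel(
                metabolites=[Metabolite("A[c]")],
                reactions=[Reaction("R1", stoichiometry={"ghost[c]": 1.0})],
            )


class TestBalance:
    def test_balanced_reaction_not_reported(self):
        model = MetabolicModel(
            metabolites=[
                Metabolite("glc[c]", formula={"C": 6, "H": 12, "O": 6}),
                Metabolite("lac[c]", formula={"C": 3, "H": 6, "O": 3}),
            ],
            reactions=[
                Reaction("R1", stoichiometry={"glc[c]": -1.0, "lac[c]": 2.0})
            ],
        )
        assert check_balance(model).ok

    def test_imbalance_named_per_element(self):
        model = MetabolicModel(
            metabolites=[
                Metabolite("A[c]", formula={"C": 1, "H": 4}),
                Metabolite("B[c]", formula={"C": 1, "H": 3}),
            ],
            reactions=[Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0})],
        )
        report = check_balance(model)
        assert len(report.violations) == 1
        assert report.violations[0].reaction_id == "R1"
        assert report.violations[0].imbalance == {"H": -1.0}

    def test_unknown_formula_skipped_and_listed(self):
        model = MetabolicModel(
            metabolites=[Metabolite("A[c]"), Metabolite("B[c]", formula={"C": 1})],
            reactions=[Reaction("R1", stoichiometry={"A[c]": -1.0, "B[c]": 1.0})],
        )
        report = check_balance(model)
        assert report.ok
        assert report.skipped == ["R1"]

    def test_mini_model_balanced_vs_independent_summation(self, mini):
        assert check_balance(mini).ok
        # brute-force per-column element sums agree: all zero
        oracle = element_balance_by_columns(mini)
        assert all(not imbalance for imbalance in oracle.values())


class TestGeneDeletion:
    def test_unused_gene_changes_nothing(self, mini):
        derived = apply_gene_deletion(mini, {"not_a_gene"})
        for a, b in zip(mini.reactions, derived.reactions):
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_sole_gene_disables_reaction(self, chain):
        derived = apply_gene_deletion(chain, {"g1"})
        rxn = derived.reaction("R1")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        # original untouched
        assert chain.reaction("R1").upper_bound > 0

    def test_or_pair_member_keeps_reaction_open(self, mini):
        derived = apply_gene_deletion(mini, {"acbB"})
        rxn = derived.reaction("ACBB")
        assert rxn.upper_bound > 0
        both = apply_gene_deletion(mini, {"acbB", "rmlB"})
        assert both.reaction("ACBB").upper_bound == 0.0

    def test_and_pair_member_disables_complex(self, mini):
        derived = apply_gene_deletion(mini, {"acbW"})
        assert derived.reaction("ACBT").upper_bound == 0.0

    def test_idempotent_and_monotone(self, mini):
        genes = sorted(mini.genes)
        subsets = [set(genes[:k]) for k in (1, 3, 7, len(genes))]
        for deleted in subsets:
            once = apply_gene_deletion(mini, deleted)
            twice = apply_gene_deletion(once, deleted)
            disabled_once = {
                r.id for r in once.reactions if r.upper_bound == r.lower_bound == 0
            }
            disabled_twice = {
                r.id for r in twice.reactions if r.upper_bound == r.lower_bound == 0
            }
            assert disabled_once == disabled_twice
        # monotone: larger deletion sets never re-enable a reaction
        for small, large in zip(subsets, subsets[1:]):
            dis_small = {
                r.id
                for r in apply_gene_deletion(mini, small).reactions
                if r.upper_bound == 0 and r.lower_bound == 0
            }
            dis_large = {
                r.id
                for r in apply_gene_deletion(mini, large).reactions
                if r.upper_bound == 0 and r.lower_bound == 0
            }
            assert dis_small <= dis_large


class TestInvariants:
    def test_duplicate_reaction_id_rejected(self):
        with pytest.raises(ModelStructureError):
            MetabolicModel(
                metabolites=[Metabolite("A[c]")],
                reactions=[
                    Reaction("R", stoichiometry={"A[c]": 1.0}),
                    Reaction("R", stoichiometry={"A[c]": -1.0}),
                ],
            )

    def test_exchange_must_have_single_metabolite(self):
        with pytest.raises(ModelStructureError):
            Reaction(
                "EX_bad",
                stoichiometry={"A[e]": -1.0, "B[e]": 1.0},
                is_exchange=True,
            )

    def test_gpr_gene_must_be_in_gene_set(self):
        with pytest.raises(ModelStructureError):
            MetabolicModel(
                metabolites=[Metabolite("A[c]")],
                reactions=[
                    Reaction(
                        "R", stoichiometry={"A[c]": 1.0}, gpr=GPR.parse("gX")
                    )
                ],
                genes=set(),
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelStructureError):
            Reaction("R", lower_bound=5.0, upper_bound=1.0)
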