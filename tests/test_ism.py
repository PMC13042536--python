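"""PISM engine: proposal counts, greedy optimality on additive landscapes,
epistatic traps, determinism, lineage reconstruction."""

import itertools

import pytest

from passdesign import study
from passdesign.assays import ActivityPair
from passdesign.ism import (
    ISMConfig,
    Objective,
    OracleMissError,
    TableOracle,
    lineage_mutation_steps,
    propose_round,
    reconstruct_paths,
    run_pism,
    score_round,
)
from passdesign.mutations import (
    AMINO_ACIDS,
    MutationSpec,
    VariantGenotype,
    parse_variant,
)
from passdesign.synthetic import LandscapeDesign, LandscapeOracle


SITES_2 = {5: "A", 9: "G"}


def tiny_landscape(**kw) -> LandscapeOracle:
    defaults = dict(sites=SITES_2, effect_sd=0.5, seed=42)
    defaults.update(kw)
    return LandscapeOracle(LandscapeDesign.random(**defaults))


class TestProposeRound:
    def test_three_sites_give_57(self):
        base = VariantGenotype()
        sites = {115: "F", 118: "L", 293: "Y"}
        assert len(propose_round(base, sites)) == 57

    def test_counts_match_alphabet_closed_form(self):
        """Explicit-enumeration oracle over assorted alphabets."""
        base = VariantGenotype()
        sites = {1: "A", 2: "C", 3: "D"}
        alphabet = {1: "AGV", 2: "C", 3: AMINO_ACIDS}
        props = propose_round(base, sites, alphabet)
        expected = sum(
            len([a for a in alphabet[p] if a != sites[p]]) for p in sites
        )
        assert len(props) == expected
        assert len({str(g) for g in props}) == expected

    def test_single_site_single_residue(self):
        props = propose_round(VariantGenotype(), {7: "G"}, {7: "A"})
        assert [str(g) for g in props] == ["G7A"]

    def test_empty_open_sites_rejected(self):
        with pytest.raises(ValueError):
            propose_round(VariantGenotype(), {})

    def test_resaturation_replaces_existing_substitution(self):
        template = parse_variant("A5C")
        props = propose_round(template, {5: "A"})
        strs = {str(g) for g in props}
        assert "A5C" not in strs          # current residue skipped
        assert "WT" in strs               # reversion to wild type offered
        assert len(props) == 19


class TestScoreRound:
    def test_flat_oracle_all_selectivity_zero(self):
        props = propose_round(VariantGenotype(), {5: "A"})
        oracle = TableOracle({str(g): ActivityPair(1.0, 1.0) for g in props})
        scores = score_round(props, oracle)
        assert (scores.selectivity_value == 0.0).all()

    def test_additive_landscape_matches_hand_sum(self):
        import numpy as np

        design = LandscapeDesign(
            sites=SITES_2,
            effects={(5, "V"): (0.7, -0.2), (9, "W"): (0.3, 0.1)},
            base_cis=2.0, base_trans=1.0,
        )
        oracle = LandscapeOracle(design)
        g = parse_variant("A5V/G9W")
        pair = oracle.evaluate(g)
        assert pair.sa_cis == pytest.approx(2.0 * np.exp(0.7 + 0.3))
        assert pair.sa_trans == pytest.approx(1.0 * np.exp(-0.2 + 0.1))

    def test_oracle_miss_lists_genotype(self):
        props = propose_round(VariantGenotype(), {5: "A"}, {5: "AVG"})
        oracle = TableOracle({})
        with pytest.raises(OracleMissError, match="A5"):
            score_round(props, oracle)


class TestRunPism:
    def test_round_sizes_57_38_19(self):
        oracle = LandscapeOracle(
            LandscapeDesign.random(sites={115: "F", 118: "L", 293: "Y"}, seed=1)
        )
        cfg = ISMConfig(
            base=VariantGenotype(),
            sites={115: "F", 118: "L", 293: "Y"},
            objectives=[Objective("act", "activity_cis", "max")],
            rounds=3,
        )
        trace = run_pism(cfg, oracle)
        assert [len(r.proposals) for r in trace.rounds] == [57, 38, 19]

    def test_zero_rounds_trace_is_base_only(self):
        cfg = ISMConfig(
            base=VariantGenotype(), sites=SITES_2,
            objectives=[Objective("act", "activity_cis", "max")], rounds=0,
        )
        trace = run_pism(cfg, tiny_landscape())
        assert trace.rounds == []
        assert trace.terminal_templates() == [(VariantGenotype(), "base")]

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_attains_additive_optimum(self, seed):
        """On purely additive landscapes the greedy walk must reach the
        brute-force optimum of the full combinatorial space."""
        oracle = tiny_landscape(seed=seed)
        cfg = ISMConfig(
            base=VariantGenotype(), sites=SITES_2,
            objectives=[Objective("act", "activity_cis", "max")],
            rounds=2,
        )
        trace = run_pism(cfg, oracle)
        final = trace.terminal_templates()[0][0]
        # exhaustive 20^2 oracle
        best, best_v = None, -1.0
        for a5, a9 in itertools.product(AMINO_ACIDS, repeat=2):
            muts = set()
            if a5 != "A":
                muts.add(MutationSpec(5, "A", a5))
            if a9 != "G":
                muts.add(MutationSpec(9, "G", a9))
            g = VariantGenotype(mutations=frozenset(muts))
            v = oracle.evaluate(g).sa_cis
            if v > best_v:
                best, best_v = g, v
        assert oracle.evaluate(final).sa_cis == pytest.approx(best_v)
        assert final == oracle.additive_optimum("activity_cis") == best

    def test_sign_epistasis_traps_greedy_walk(self):
        """A planted reciprocal-sign-epistasis pair makes the double mutant
        the optimum while both single steps look bad; greedy must miss it
        and the trace records the shortfall (rugged-landscape behaviour)."""
        design = LandscapeDesign(
            sites=SITES_2,
            effects={(5, "V"): (-1.0, 0.0), (9, "W"): (-1.0, 0.0)},
            epistasis={frozenset({(5, "V"), (9, "W")}): (5.0, 0.0)},
        )
        oracle = LandscapeOracle(design)
        double = parse_variant("A5V/G9W")
        singles_and_wt = [VariantGenotype(), parse_variant("A5V"), parse_variant("G9W")]
        assert oracle.evaluate(double).sa_cis > max(
            oracle.evaluate(g).sa_cis for g in singles_and_wt
        )
        cfg = ISMConfig(
            base=VariantGenotype(), sites=SITES_2,
            objectives=[Objective("act", "activity_cis", "max")], rounds=2,
        )
        trace = run_pism(cfg, oracle)
        final = trace.terminal_templates()[0][0]
        assert final != double
        assert oracle.evaluate(final).sa_cis < oracle.evaluate(double).sa_cis

    def test_identical_config_and_oracle_give_identical_trace(self):
        cfg = ISMConfig(
            base=VariantGenotype(), sites=SITES_2,
            objectives=[
                Objective("cis", "activity_cis", "max"),
                Objective("sel", "selectivity_value", "min"),
            ],
            rounds=2,
        )
        t1 = run_pism(cfg, tiny_landscape())
        t2 = run_pism(cfg, tiny_landscape())
        assert [str(g) for r in t1.rounds for g, _ in r.chosen] == \
               [str(g) for r in t2.rounds for g, _ in r.chosen]
        for r1, r2 in zip(t1.rounds, t2.rounds):
            assert r1.proposals.equals(r2.proposals)


@pytest.fixture(scope="module")
def trace():
    reg = study.named_variant_registry()
    cfg = ISMConfig(
        base=parse_variant("6M2", reg),
        sites=dict(study.PISM_SITES),
        objectives=[
            Objective("cis_selectivity", "selectivity_value", "max"),
            Objective("trans_selectivity", "selectivity_value", "min"),
            Objective("cis_activity", "activity_cis", "max"),
        ],
        rounds=3,
    )
    return run_pism(cfg, study.synthetic_screen_oracle(reg))


class TestStudyCampaign:
    """The three-round campaign over the synthetic screen table must
    reproduce the published template choices and lineage."""

    def test_round1_counts_and_template_choices(self, trace):
        reg = study.named_variant_registry()
        assert len(trace.rounds[0].proposals) == 57
        chosen = {obj: str(g) for g, obj in trace.rounds[0].chosen}
        assert chosen["cis_selectivity"] == str(parse_variant("6M2/Y293S", reg))
        assert chosen["trans_selectivity"] == str(parse_variant("6M2/F115L", reg))
        assert chosen["cis_activity"] == str(parse_variant("6M2/F115C", reg))

    def test_round2_proposal_count_114(self, trace):
        assert len(trace.rounds[1].proposals) == 114

    def test_ltf_lineage_path(self, trace):
        reg = study.named_variant_registry()
        ltf = parse_variant("LTF", reg)
        terminals = {str(g) for g, _ in trace.terminal_templates()}
        assert str(ltf) in terminals
        assert lineage_mutation_steps(trace, ltf) == ["F115L", "L118T", "Y293F"]

    def test_paths_share_prefix_structure(self, trace):
        paths = reconstruct_paths(trace)
        assert len(paths) == 3
        for path in paths.values():
            assert len(path) == 3  # three rounds, one substitution per round
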