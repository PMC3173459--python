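"""The classifier family: NB, epsilon-NB, NN, BLAST best hit, LCA, NB-BL
and the consensus hybrids, plus their algebraic properties."""

import math

import pytest

from fragtax.classifiers import (
    BlastHit,
    ClassifierParams,
    Prediction,
    blast_best_hit_classify,
    consensus_classify,
    conservative_lca_classify,
    epsilon_nb_classify,
    epsilon_nb_classify_from_scores,
    epsilon_set,
    lca_classify,
    nb_classify,
    nb_classify_from_scores,
    nbbl_classify,
    nbbl_score,
    nn_classify,
)
from fragtax.composition import build_nb_model, count_nmers, to_frequency
from fragtax.taxonomy import EMPTY_LINEAGE, Lineage, Rank


def hit(q, g, e, bits=100.0):
    return BlastHit(query_id=q, genome_id=g, evalue=e, bitscore=bits)


@pytest.fixture
def toy_models():
    # A-rich vs C-rich genomes at n=1
    return [
        build_nb_model("g1", ["AAAAAAAAAA"], 1),
        build_nb_model("g2", ["CCCCCCCCCC"], 1),
    ]


class TestNB:
    def test_fragment_goes_to_compositionally_matching_genome(
        self, toy_models, toy_tree
    ):
        pred = nb_classify(toy_models, toy_tree, "f1", "AAAAAAAA")
        assert pred.assigned == toy_tree.lineage("g1")
        assert pred.classified_rank == Rank.STRAIN

    def test_single_model_always_wins(self, toy_models, toy_tree):
        pred = nb_classify(toy_models[:1], toy_tree, "f1", "CCCC")
        assert pred.assigned == toy_tree.lineage("g1")

    def test_tie_breaks_to_smallest_genome_id(self, toy_tree):
        models = [
            build_nb_model("g2", ["ACGT"], 1),
            build_nb_model("g1", ["ACGT"], 1),
        ]
        pred = nb_classify(models, toy_tree, "f1", "ACAC")
        assert pred.assigned.labels[-1] == "g1"

    def test_unscorable_fragment_unclassified(self, toy_models, toy_tree):
        pred = nb_classify(toy_models, toy_tree, "f1", "NNNN")
        assert pred.assigned == EMPTY_LINEAGE

    def test_invariant_under_constant_score_shift(self, toy_tree):
        scores = {"g1": -40.0, "g2": -45.0, "g3": -41.0}
        base = nb_classify_from_scores(scores, toy_tree, "f")
        shifted = nb_classify_from_scores(
            {g: s + 123.4 for g, s in scores.items()}, toy_tree, "f"
        )
        assert base == shifted


class TestEpsilonNB:
    def test_interval_membership_arithmetic(self):
        scores = {"g1": -10.0, "g2": -11.0, "g3": -30.0}
        assert epsilon_set(scores, 1e5) == {"g1", "g2"}

    def test_interval_ltr_assignment(self, toy_tree):
        # g1 and g2 share genus gen1 but differ at species
        scores = {"g1": -10.0, "g2": -11.0, "g4": -30.0}
        pred = epsilon_nb_classify_from_scores(scores, toy_tree, "f", epsilon=1e5)
        assert pred.classified_rank == Rank.GENUS
        assert pred.assigned.labels[-1] == "gen1"

    def test_epsilon_one_equals_nb(self, toy_models, toy_tree):
        # fragments with a unique maximum-likelihood genome
        for frag in ("AAAA", "CCCC", "AAAC"):
            assert epsilon_nb_classify(
                toy_models, toy_tree, "f", frag, epsilon=1.0
            ) == nb_classify(toy_models, toy_tree, "f", frag)

    def test_huge_epsilon_gives_ltr_of_all_genomes(self, toy_tree):
        scores = {"g1": -10.0, "g5": -500.0}
        pred = epsilon_nb_classify_from_scores(scores, toy_tree, "f", epsilon=1e300)
        # g1 (phylum p1) and g5 (phylum p2) agree only at domain
        assert pred.classified_rank == Rank.DOMAIN

    def test_monotone_in_epsilon(self, toy_tree):
        scores = {"g1": -10.0, "g2": -14.0, "g3": -25.0, "g5": -80.0}
        ranks = []
        for eps in (1.0, 10.0, 1e5, 1e10, 1e40):
            pred = epsilon_nb_classify_from_scores(scores, toy_tree, "f", eps)
            ranks.append(
                pred.classified_rank.value if pred.classified_rank is not None else -1
            )
        assert ranks == sorted(ranks, reverse=True)


class TestNN:
    def test_identical_profile_is_distance_zero(self, toy_tree):
        profiles = {
            "g1": to_frequency(count_nmers("AAAACCCC", 1)),
            "g2": to_frequency(count_nmers("GGGGTTTT", 1)),
        }
        pred = nn_classify(profiles, toy_tree, "f", "AAAACCCC")
        assert pred.assigned == toy_tree.lineage("g1")

    def test_hand_l1_arithmetic(self, toy_tree):
        # profiles {A:1} vs {C:1}; all-A fragment: distances 0 vs 2
        profiles = {
            "g1": to_frequency(count_nmers("AAAA", 1)),
            "g2": to_frequency(count_nmers("CCCC", 1)),
        }
        pred = nn_classify(profiles, toy_tree, "f", "AAA")
        assert pred.assigned.labels[-1] == "g1"

    def test_equidistant_tie_breaks_lexicographically(self, toy_tree):
        profiles = {
            "g2": to_frequency(count_nmers("ACGT", 1)),
            "g1": to_frequency(count_nmers("ACGT", 1)),
        }
        pred = nn_classify(profiles, toy_tree, "f", "GGCC")
        assert pred.assigned.labels[-1] == "g1"


class TestBlastBestHit:
    def test_single_hit_full_depth(self, toy_tree):
        pred = blast_best_hit_classify([hit("f", "g1", 1e-20)], toy_tree, "f")
        assert pred.assigned == toy_tree.lineage("g1")

    def test_tied_top_evalue_goes_to_ltr(self, toy_tree):
        # g1, g2 are congeneric species
        hits = [hit("f", "g1", 1e-20), hit("f", "g2", 1e-20)]
        pred = blast_best_hit_classify(hits, toy_tree, "f")
        assert pred.classified_rank == Rank.GENUS

    def test_no_hit_below_threshold_unclassified(self, toy_tree):
        pred = blast_best_hit_classify(
            [hit("f", "g1", 1e-3)], toy_tree, "f", evalue_max=1e-5
        )
        assert pred.assigned == EMPTY_LINEAGE

    def test_threshold_is_strict(self, toy_tree):
        pred = blast_best_hit_classify(
            [hit("f", "g1", 1e-5)], toy_tree, "f", evalue_max=1e-5
        )
        assert pred.assigned == EMPTY_LINEAGE

    def test_zero_evalue_passes_any_threshold(self, toy_tree):
        pred = blast_best_hit_classify(
            [hit("f", "g1", 0.0)], toy_tree, "f", evalue_max=1e-300
        )
        assert pred.assigned == toy_tree.lineage("g1")


class TestLCA:
    def test_bitscore_window_arithmetic(self, toy_tree):
        # p=15: threshold 85; keeps g1 (100) and g2 (90), drops g3 (80)
        hits = [
            hit("f", "g1", 1e-30, 100.0),
            hit("f", "g2", 1e-28, 90.0),
            hit("f", "g3", 1e-25, 80.0),
        ]
        pred = lca_classify(hits, toy_tree, "f", p=15.0)
        assert pred.classified_rank == Rank.GENUS  # ltr(g1, g2) = gen1

    def test_p_zero_keeps_only_max_bitscore_ties(self, toy_tree):
        hits = [
            hit("f", "g1", 1e-30, 100.0),
            hit("f", "g2", 1e-28, 100.0),
            hit("f", "g3", 1e-25, 99.9),
        ]
        pred = lca_classify(hits, toy_tree, "f", p=0.0)
        assert pred.classified_rank == Rank.GENUS

    def test_boundary_bitscore_inclusive(self, toy_tree):
        hits = [hit("f", "g1", 1e-30, 100.0), hit("f", "g3", 1e-28, 85.0)]
        pred = lca_classify(hits, toy_tree, "f", p=15.0)
        assert pred.classified_rank == Rank.FAMILY  # g3 kept at exactly 85

    def test_monotone_in_p(self, toy_tree):
        hits = [
            hit("f", "g1", 1e-30, 100.0),
            hit("f", "g2", 1e-28, 93.0),
            hit("f", "g3", 1e-25, 70.0),
            hit("f", "g5", 1e-20, 52.0),
        ]
        ranks = []
        for p in (0.0, 5.0, 15.0, 50.0, 100.0):
            pred = lca_classify(hits, toy_tree, "f", p=p)
            ranks.append(pred.classified_rank.value if pred.classified_rank else -1)
        assert ranks == sorted(ranks, reverse=True)

    def test_conservative_variant_pools_all_surviving_hits(self, toy_tree):
        hits = [hit("f", "g1", 1e-3, 100.0), hit("f", "g2", 1e-8, 50.0)]
        pred = conservative_lca_classify(hits, toy_tree, "f")
        assert pred.classified_rank == Rank.GENUS  # both below 1e-2

    def test_no_hits_unclassified(self, toy_tree):
        assert lca_classify([], toy_tree, "f").assigned == EMPTY_LINEAGE


class TestNBBL:
    def test_score_arithmetic(self):
        params = ClassifierParams()
        expected = -100.0 - 12.0 * math.log(1e-10) + 4.8
        assert math.isclose(nbbl_score(-100.0, 1e-10, params), expected, rel_tol=1e-12)
        assert math.isclose(expected, 181.110, abs_tol=1e-3)

    def test_fallback_to_nb_when_no_usable_hit(self, toy_models, toy_tree):
        hits = [hit("f", "g2", 10.0), hit("f", "g2", 50.0)]  # all E >= 10
        pred = nbbl_classify(toy_models, toy_tree, hits, "f", "AAAA")
        assert pred == nb_classify(toy_models, toy_tree, "f", "AAAA")

    def test_zero_evalue_rule_picks_best_nb_among_zero_hits(
        self, toy_models, toy_tree
    ):
        # fragment is A-rich: NB(g1) > NB(g2); both have E=0.0 hits
        hits = [hit("f", "g1", 0.0), hit("f", "g2", 0.0)]
        pred = nbbl_classify(toy_models, toy_tree, hits, "f", "AAAA")
        assert pred.assigned.labels[-1] == "g1"

    def test_strong_hit_outweighs_composition(self, toy_models, toy_tree):
        # fragment is A-rich (favours g1) but g2 has a very strong hit
        hits = [hit("f", "g2", 1e-40)]
        pred = nbbl_classify(toy_models, toy_tree, hits, "f", "AAAAAAAA")
        assert pred.assigned.labels[-1] == "g2"

    def test_hitless_genomes_compete_on_plain_nb(self, toy_models, toy_tree):
        # weak hit to g2 barely helps; g1's composition advantage dominates
        hits = [hit("f", "g2", 5.0)]
        pred = nbbl_classify(
            toy_models, toy_tree, hits, "f", "AAAAAAAAAAAAAAAAAAAAAAAA"
        )
        assert pred.assigned.labels[-1] == "g1"


class TestConsensus:
    def p(self, fid, labels):
        return Prediction(fragment_id=fid, assigned=Lineage(tuple(labels)))

    def test_prefix_rule(self, toy_tree):
        a = self.p("f", toy_tree.lineage("g1").labels)  # full depth, gen1/sp1
        b = self.p("f", toy_tree.lineage("g1").labels[:6])  # down to genus
        result = consensus_classify(a, b)
        assert result.classified_rank == Rank.GENUS

    def test_unclassified_partner_wipes_prediction(self, toy_tree):
        a = self.p("f", toy_tree.lineage("g1").labels)
        b = self.p("f", ())
        assert consensus_classify(a, b).assigned == EMPTY_LINEAGE

    def test_divergent_species_meet_at_family(self, toy_tree):
        a = self.p("f", toy_tree.lineage("g1").labels)  # f1/gen1/sp1
        b = self.p("f", toy_tree.lineage("g3").labels)  # f1/gen2/sp3
        assert consensus_classify(a, b).classified_rank == Rank.FAMILY

    def test_commutative_idempotent_never_deeper(self, toy_tree):
        a = self.p("f", toy_tree.lineage("g1").labels)
        b = self.p("f", toy_tree.lineage("g2").labels[:6])
        ab, ba = consensus_classify(a, b), consensus_classify(b, a)
        assert ab == ba
        assert consensus_classify(a, a) == a
        depth = ab.assigned.depth
        assert depth <= a.assigned.depth and depth <= b.assigned.depth

    def test_fragment_mismatch_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            consensus_classify(self.p("f1", ()), self.p("f2", ()))
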