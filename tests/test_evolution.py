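"""Evolution tests: exhaustive parsimony oracle, similarity, filters."""

import itertools

import dendropy
import numpy as np
import pytest

from devsplice.evolution import (
    DEFAULT_TREE_NEWICK,
    Candidate,
    InterspacedExon,
    SpeciesTree,
    apply_birth_filters,
    cassette_status,
    detect_alternification,
    find_interspaced_candidates,
    interval_overlap_flag,
    parsimony_age,
    similar,
)


# --- exhaustive single-event oracle ----------------------------------------

def oracle_single_event(presence, newick=DEFAULT_TREE_NEWICK):
    """Enumerate every (edge, event-type) assignment and simulate the
    resulting leaf pattern by tree traversal; independent of the package's
    clade-matching shortcut."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = {t.label for t in tree.taxon_namespace}
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    scenarios = []
    for node in edges:
        below = {lf.taxon.label for lf in node.leaf_iter()}
        # gain on this edge with ancestral absence: present exactly below it
        if {sp: sp in below for sp in leaves} == dict(presence):
            scenarios.append(("gain", frozenset(below)))
        # loss on this edge with ancestral presence: absent exactly below it
        if {sp: sp not in below for sp in leaves} == dict(presence):
            scenarios.append(("loss", frozenset(below)))
    return scenarios


class TestParsimonyAge:
    def test_mouse_specific_gain(self, tree):
        event = parsimony_age({sp: sp == "mouse" for sp in tree.leaves}, tree)
        assert event.event == "gain"
        assert event.branch == frozenset({"mouse"})
        assert event.age_class == "mouse-specific"

    def test_eutherian_gain(self, tree):
        eutherians = {"human", "macaque", "mouse", "rat", "rabbit"}
        event = parsimony_age({sp: sp in eutherians for sp in tree.leaves}, tree)
        assert event.event == "gain"
        assert event.age_class == "eutherian"

    def test_scattered_pattern_discarded(self, tree):
        pattern = {sp: sp in {"human", "mouse"} for sp in tree.leaves}
        assert parsimony_age(pattern, tree) is None

    def test_root_split_ambiguous_discarded(self, tree):
        pattern = {sp: sp != "chicken" for sp in tree.leaves}
        assert parsimony_age(pattern, tree) is None

    def test_constant_pattern_no_event(self, tree):
        assert parsimony_age({sp: True for sp in tree.leaves}, tree) is None

    def test_rodent_loss(self, tree):
        pattern = {sp: sp not in {"mouse", "rat"} for sp in tree.leaves}
        event = parsimony_age(pattern, tree)
        assert event.event == "loss" and event.age_class == "rodent"

    def test_incomplete_vector_raises(self, tree):
        with pytest.raises(ValueError):
            parsimony_age({"mouse": True}, tree)

    def test_exhaustive_oracle_all_patterns(self, tree):
        species = sorted(tree.leaves)
        checked = 0
        for bits in itertools.product([False, True], repeat=7):
            presence = dict(zip(species, bits))
            if all(bits) or not any(bits):
                continue
            checked += 1
            scenarios = oracle_single_event(presence)
            got = parsimony_age(presence, tree)
            if len(scenarios) == 1:
                etype, clade = scenarios[0]
                assert got is not None
                assert got.event == etype and got.branch == clade
            else:
                assert got is None
        assert checked == 126

    def test_label_reversal_symmetry(self, tree):
        for clade in tree.clades:
            if (tree.leaves - clade) in tree.clades or clade == tree.leaves:
                continue
            gain = parsimony_age({sp: sp in clade for sp in tree.leaves}, tree)
            loss = parsimony_age({sp: sp not in clade for sp in tree.leaves}, tree)
            assert gain.event == "gain" and loss.event == "loss"
            assert gain.branch == loss.branch == clade


class TestSimilar:
    def test_identical_sequences(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        assert similar(seq, seq)

    def test_disjoint_alphabets_no_seed(self):
        query = "AC" * 30  # only A/C 8-mers
        target = "GT" * 100  # only G/T 8-mers
        assert not similar(query, target)

    def test_shared_20nt_block_detected(self, rng):
        block = "".join(rng.choice(list("ACGT"), 20))
        query = "AC" * 15 + block + "CA" * 15
        target = "GT" * 40 + block + "TG" * 40
        assert similar(query, target)

    def test_empty_target(self):
        assert not similar("ACGTACGTACGT", "")

    def test_min_score_threshold(self):
        # exact shared 8-mer alone scores 8 < default threshold 14
        shared = "ACGTTGCA"
        query = "CC" * 10 + shared + "CC" * 10
        target = "GG" * 10 + shared + "GG" * 10
        assert not similar(query, target)
        assert similar(query, target, min_score=8)


def _exon(seq, exon_id="x"):
    return InterspacedExon(exon_id=exon_id, sequence=seq, flank5="ACGT", flank3="ACGT")


class TestFindInterspacedCandidates:
    def test_single_species_candidate(self):
        recs = [
            {
                "pair_id": "p1",
                "useg_id": "u",
                "dseg_id": "d",
                "interspaced": {"mouse": [_exon("ACGT" * 20)]},
            }
        ]
        cands = find_interspaced_candidates(recs, ["mouse", "rat"])
        assert len(cands) == 1
        assert cands[0].presence == {"mouse": True, "rat": False}
        assert cands[0].excluded is None

    def test_no_interspaced_exon_no_candidate(self):
        recs = [{"pair_id": "p1", "interspaced": {}}]
        assert find_interspaced_candidates(recs, ["mouse", "rat"]) == []

    def test_multi_exon_excluded(self):
        recs = [
            {
                "pair_id": "p1",
                "interspaced": {"mouse": [_exon("AAAA" * 10), _exon("CCCC" * 10)]},
            }
        ]
        cands = find_interspaced_candidates(recs, ["mouse", "rat"])
        assert cands[0].excluded == "multi_exon"

    def test_non_consecutive_pair_skipped(self):
        recs = [
            {
                "pair_id": "p1",
                "interspaced": {"mouse": [_exon("ACGT" * 20)]},
                "non_consecutive": {"rat"},
            }
        ]
        assert find_interspaced_candidates(recs, ["mouse", "rat"]) == []


class TestBirthFilters:
    def make_candidate(self, rng, n_species=2, length=80):
        seq = "".join(rng.choice(list("ACGT"), length))
        species = [f"s{k}" for k in range(n_species)]
        return Candidate(
            pair_id="p",
            useg_id="u",
            dseg_id="d",
            presence={**{sp: True for sp in species}, "absent1": False},
            exons={sp: _exon(seq, f"{sp}.x") for sp in species},
        )

    def test_clean_candidate_passes(self, rng):
        cand = self.make_candidate(rng)
        regions = {"absent1": "".join(rng.choice(list("ACGT"), 300))}
        assert apply_birth_filters(cand, regions)

    def test_alignment_to_absent_region_rejected(self, rng):
        cand = self.make_candidate(rng)
        exon_seq = cand.exons["s0"].sequence
        regions = {"absent1": "GT" * 50 + exon_seq + "TG" * 50}
        assert not apply_birth_filters(cand, regions)

    def test_mutual_alignment_failure_rejected(self, rng):
        cand = self.make_candidate(rng)
        cand.exons["s1"] = _exon("AC" * 40, "s1.x")  # unrelated sequence
        cand.exons["s0"] = _exon("GT" * 40, "s0.x")
        assert not apply_birth_filters(cand, {})

    def test_long_exon_rejected(self, rng):
        cand = self.make_candidate(rng, length=520)
        assert not apply_birth_filters(cand, {})

    def test_excluded_candidate_never_passes(self, rng):
        cand = self.make_candidate(rng)
        cand.excluded = "multi_exon"
        assert not apply_birth_filters(cand, {})


class TestAlternification:
    def test_four_pairs_cassette(self):
        assert cassette_status([0.85, 0.85, 0.85, 0.85, 0.95]) is True

    def test_three_pairs_constitutive(self):
        assert cassette_status([0.85, 0.85, 0.85, 0.95, 0.95]) is False

    def test_no_defined_psi_unknown(self):
        assert cassette_status([float("nan")]) is None
        assert cassette_status([]) is None

    def test_primate_gain(self, tree):
        tables = {}
        for sp in tree.leaves:
            if sp in {"human", "macaque"}:
                tables[sp] = [0.5] * 6
            else:
                tables[sp] = [0.95] * 6
        status, event = detect_alternification(tables, tree)
        assert status["human"] is True and status["mouse"] is False
        assert event.event == "alternification_gain"
        assert event.age_class == "primate"

    def test_unknown_species_discards_vector(self, tree):
        tables = {sp: [0.5] * 6 for sp in tree.leaves}
        tables["rat"] = []
        status, event = detect_alternification(tables, tree)
        assert status["rat"] is None and event is None


class TestIntervalOverlap:
    def test_nine_nt_below_ten_min(self):
        assert not interval_overlap_flag((100, 200), [(191, 250)], min_overlap=10)

    def test_contained_exon(self):
        assert interval_overlap_flag((100, 200), [(50, 300)], min_overlap=10)

    def test_single_nt_cds_overlap(self):
        assert interval_overlap_flag((100, 200), [(199, 250)], min_overlap=1)

    def test_overlap_must_be_with_single_feature(self):
        # two features overlapping 5 nt each do not satisfy a 10-nt minimum
        assert not interval_overlap_flag(
            (100, 200), [(95, 105), (195, 205)], min_overlap=10
        )

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError):
            interval_overlap_flag((100, 100), [(0, 10)])
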