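"""Pairwise scoring, reciprocal best hits, set declaration and refinement."""

import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthotx.orthologs import (
    OrthologMember,
    OrthologSet,
    SimilarityHit,
    assign_reference_protein,
    best_hits,
    declare_ortholog_sets,
    extract_member_cds,
    make_scorer,
    read_blast_tab,
    reciprocal_best_pairs,
    refine_ortholog_set,
    score_pair,
)

from _oracles import gotoh_overlap_score

AA = "ACDEFGHIKLMNPQRSTVWY"
B62 = substitution_matrices.load("BLOSUM62")


def random_protein(rng, lo=20, hi=60):
    return "".join(rng.choice(list(AA), size=int(rng.integers(lo, hi))))


def mutated_copy(seq, rng, n_sub=3):
    chars = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(len(chars)))
        chars[i] = rng.choice(list(AA))
    return "".join(chars)


class TestScorePair:
    def test_self_alignment_is_perfect(self):
        h = score_pair("MKVLLTA", "MKVLLTA")
        assert h.identity == 1.0 and h.query_coverage == 1.0
        assert h.score == sum(B62[c, c] for c in "MKVLLTA")

    def test_score_monotone_in_matches(self):
        assert score_pair("MKV", "MKV").score > score_pair("MKV", "MAV").score

    def test_wrong_alphabet_rejected(self):
        with pytest.raises(ValueError):
            score_pair("MKV", "MKV", mode="nucleotide")
        with pytest.raises(ValueError):
            score_pair("ACGT!", "ACGT", mode="nucleotide")

    def test_matches_independent_dp_oracle(self, rng):
        for _ in range(20):
            a, b = random_protein(rng), random_protein(rng)
            expected = gotoh_overlap_score(a, b, -11.0, -1.0, sub=B62)
            assert score_pair(a, b).score == pytest.approx(expected, abs=1e-9)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 80))))
            expected = gotoh_overlap_score(a, b, -5.0, -2.0, match=2.0, mismatch=-3.0)
            assert score_pair(a, b, mode="nucleotide").score == pytest.approx(expected, abs=1e-9)


# hand-built 3x3 score matrix: q1's best subject is s2, but s2's best query
# is q3 — mutuality must not be enforced inside best_hits
FIXTURE_SCORES = {
    ("q1", "s1"): 5.0, ("q1", "s2"): 9.0, ("q1", "s3"): 2.0,
    ("q2", "s1"): 8.0, ("q2", "s2"): 3.0, ("q2", "s3"): 1.0,
    ("q3", "s1"): 4.0, ("q3", "s2"): 10.0, ("q3", "s3"): 6.0,
}


def fixture_scorer(a, b):
    key = (a, b) if (a, b) in FIXTURE_SCORES else (b, a)
    return FIXTURE_SCORES[key]


class TestBestHits:
    def test_identity_mapping_on_same_set(self, rng):
        prots = {f"p{i}": random_protein(rng, 30, 50) for i in range(5)}
        scorer = make_scorer("protein")
        assert best_hits(prots, prots, scorer) == {k: k for k in prots}

    def test_non_mutual_best_is_still_reported(self):
        queries = {q: q for q in ("q1", "q2", "q3")}
        subjects = {s: s for s in ("s1", "s2", "s3")}
        assert best_hits(queries, subjects, fixture_scorer)["q1"] == "s2"

    def test_tie_breaks_to_lexicographically_smaller_subject(self):
        queries = {"q": "q"}
        subjects = {"sb": "sb", "sa": "sa"}
        assert best_hits(queries, subjects, lambda a, b: 1.0) == {"q": "sa"}

    def test_invariant_under_subject_input_order(self, rng):
        queries = {f"q{i}": random_protein(rng) for i in range(4)}
        subjects = {f"s{i}": random_protein(rng) for i in range(4)}
        scorer = make_scorer("protein")
        ref = best_hits(queries, subjects, scorer)
        shuffled = dict(reversed(list(subjects.items())))
        assert best_hits(queries, shuffled, scorer) == ref


class TestReciprocalBestPairs:
    def test_non_mutual_query_left_unpaired(self):
        queries = {q: q for q in ("q1", "q2", "q3")}
        subjects = {s: s for s in ("s1", "s2", "s3")}
        pairs = reciprocal_best_pairs(queries, subjects, fixture_scorer, "spX")
        paired_refs = {p.reference_gene_id for p in pairs}
        assert "q1" not in paired_refs  # q1->s2 but s2's best is q3

    def test_single_planted_pair_among_unrelated_sequences(self, rng):
        refs = {f"g{i}": random_protein(rng, 40, 60) for i in range(6)}
        txs = {f"t{i}": random_protein(rng, 40, 60) for i in range(6)}
        txs["t_planted"] = mutated_copy(refs["g3"], rng, n_sub=2)
        # unrelated randoms may pair by chance; the planted near-identical
        # pair must be present and correct
        pairs = reciprocal_best_pairs(refs, txs, make_scorer("protein"), "spX")
        by_gene = {p.reference_gene_id: p.member_transcript_id for p in pairs}
        assert by_gene["g3"] == "t_planted"

    def test_every_pair_reverifies_under_brute_force_all_vs_all(self, rng):
        refs = {f"g{i}": random_protein(rng, 30, 50) for i in range(8)}
        txs = {f"t{i}": mutated_copy(refs[f"g{i}"], rng, 4) for i in range(8)}
        pairs = reciprocal_best_pairs(refs, txs, make_scorer("protein"), "spX")
        # independent oracle: full score matrix + mutual-argmax enumeration
        score = {
            (g, t): gotoh_overlap_score(refs[g], txs[t], -11.0, -1.0, sub=B62)
            for g in refs
            for t in txs
        }
        expected = set()
        for g in refs:
            best_t = min(txs, key=lambda t: (-score[(g, t)], t))
            best_g = min(refs, key=lambda g2: (-score[(g2, best_t)], g2))
            if best_g == g:
                expected.add((g, best_t))
        assert {(p.reference_gene_id, p.member_transcript_id) for p in pairs} == expected


class TestDeclareSets:
    def _pairs(self, assignment):
        from orthotx.orthologs import OrthologPair

        return [OrthologPair(g, sp, f"{g}.{sp}") for g, sps in assignment.items() for sp in sps]

    def test_complete_and_incomplete(self):
        panel = [f"sp{i}" for i in range(10)]
        assignment = {"gA": panel, "gB": panel[:9]}
        sets = {s.reference_gene_id: s for s in declare_ortholog_sets(self._pairs(assignment), panel)}
        assert sets["gA"].status == "complete"
        assert sets["gB"].status == "incomplete"

    def test_complete_count_equals_set_intersection_oracle(self, rng):
        panel = [f"sp{i}" for i in range(6)]
        genes = [f"g{i}" for i in range(30)]
        assignment = {
            g: [sp for sp in panel if rng.random() < 0.8] for g in genes
        }
        sets = declare_ortholog_sets(self._pairs(assignment), panel)
        n_complete = sum(1 for s in sets if s.status == "complete")
        per_species = [
            {g for g in genes if sp in assignment[g]} for sp in panel
        ]
        expected = set.intersection(*per_species)
        assert n_complete == len(expected)


def make_set(lengths, both_flags, gene="gX"):
    members = {
        f"sp{i}": OrthologMember(f"sp{i}", f"t{i}", "A" * L, flag, flag)
        for i, (L, flag) in enumerate(zip(lengths, both_flags))
    }
    return OrthologSet(gene, members, "complete")


class TestRefinement:
    def test_80_percent_boundary_inclusive(self):
        s = make_set([300] * 10, [True] * 8 + [False] * 2)
        assert refine_ortholog_set(s).kept  # 0.8 >= 0.8
        s = make_set([300] * 10, [True] * 7 + [False] * 3)
        rep = refine_ortholog_set(s)
        assert not rep.kept
        assert all(r == "startstop" for _, r in rep.offending_members)

    def test_length_window_boundary_inclusive(self):
        # median of nine 300s and one long member; window [0.5m, 1.5m]
        lengths = [300] * 9 + [450]
        assert refine_ortholog_set(make_set(lengths, [True] * 10)).kept
        rep = refine_ortholog_set(make_set([300] * 9 + [453], [True] * 10))
        assert not rep.kept
        assert ("sp9", "length") in rep.offending_members

    def test_order_invariance(self, rng):
        lengths = [280, 300, 320, 150, 400, 300]
        flags = [True, True, False, True, True, True]
        base = make_set(lengths, flags)
        rep0 = refine_ortholog_set(make_set(lengths, flags))
        order = list(base.members)
        for _ in range(5):
            rng.shuffle(order)
            shuffled = OrthologSet("gX", {sp: base.members[sp] for sp in order}, "complete")
            rep = refine_ortholog_set(shuffled)
            assert rep.kept == rep0.kept
            assert set(rep.offending_members) == set(rep0.offending_members)

    def test_kept_flag_matches_independent_predicate(self, rng):
        import statistics

        for _ in range(200):
            n = int(rng.integers(3, 12))
            lengths = [int(rng.integers(60, 600)) * 3 for _ in range(n)]
            flags = [bool(rng.random() < 0.8) for _ in range(n)]
            rep = refine_ortholog_set(make_set(lengths, flags))
            med = statistics.median(lengths)
            expected = (sum(flags) / n >= 0.8) and all(
                0.5 * med <= L <= 1.5 * med for L in lengths
            )
            assert rep.kept == expected


class TestAssignReferenceProtein:
    def _assign(self, hit):
        return assign_reference_protein({"p1": "M"}, {"r1": "M"}, {"p1": [hit]})["p1"]

    def test_qualifying_hit_assigned(self):
        h = SimilarityHit("p1", "r1", 100.0, identity=0.51, query_coverage=0.76, evalue=1e-6)
        assert self._assign(h) == "r1"

    @pytest.mark.parametrize(
        "identity, coverage, evalue",
        [
            (0.50, 0.76, 1e-6),  # identity not strictly > 50%
            (0.51, 0.75, 1e-6),  # coverage not strictly > 75%
            (0.51, 0.76, 1e-4),  # E-value above cutoff
        ],
    )
    def test_threshold_failures_unassigned(self, identity, coverage, evalue):
        h = SimilarityHit("p1", "r1", 100.0, identity, coverage, evalue)
        assert self._assign(h) is None

    def test_best_scoring_qualifier_wins(self):
        hits = [
            SimilarityHit("p1", "r_low", 50.0, 0.9, 0.9, 1e-30),
            SimilarityHit("p1", "r_high", 80.0, 0.6, 0.8, 1e-10),
        ]
        got = assign_reference_protein({"p1": "M"}, {}, {"p1": hits})
        assert got["p1"] == "r_high"


class TestTabularIngest:
    def test_round_trip_and_best_hit(self, tmp_path):
        rows = [
            "p1\trA\t88.0\t100\t12\t0\t1\t100\t1\t100\t1e-40\t180.0",
            "p1\trB\t95.0\t60\t3\t0\t1\t60\t1\t60\t1e-20\t120.0",
        ]
        f = tmp_path / "hits.tsv"
        f.write_text("\n".join(rows) + "\n")
        hits = read_blast_tab(f, {"p1": 100})
        assert len(hits["p1"]) == 2
        h = hits["p1"][0]
        assert h.identity == pytest.approx(0.88)
        assert h.query_coverage == pytest.approx(1.0)
        from orthotx.orthologs import best_hits_from_table

        assert best_hits_from_table(hits) == {"p1": "rA"}


class TestExtractMemberCds:
    def test_complete_orf_preferred(self):
        from orthotx.simulate import random_cds

        cds = random_cds(80, 7)
        tx = "CCCTTT" + cds + "GGGAAA"
        assert extract_member_cds(tx) == (cds, True, True)

    def test_stopless_transcript_flags_missing_stop(self):
        body = "ATG" + "GCT" * 80  # no stop anywhere in frame
        seq, has_start, has_stop = extract_member_cds("CC" + body)
        assert has_start and not has_stop
        assert seq.startswith("ATG")
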