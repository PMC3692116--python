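import random

import pytest

from associnet.io import ProteinRecord
from associnet.orthologs import (
    AlignmentScorer,
    OrthologPair,
    ScoreSet,
    SimilarityScore,
    all_vs_all_scores,
    cluster_inparalogs,
    load_ortholog_table,
    map_orthologs,
    two_way_best_hits,
    write_ortholog_table,
    TEMPLATE,
    QUERY,
)


def cross(a, b, s):
    return SimilarityScore(a, b, s, TEMPLATE, QUERY)


def within(species, a, b, s):
    return SimilarityScore(a, b, s, species, species)


class TestAlignmentScorer:
    scorer = AlignmentScorer()

    def test_identical_sequences_score_maximally(self):
        seq = "MKVLAAGHTWYERDNQCPFILMKVSSTG" * 3
        self_bits, overlap = self.scorer(seq, seq)
        assert overlap == 1.0
        mutated = "A" + seq[1:]
        assert self.scorer(seq, mutated)[0] < self_bits

    def test_unrelated_short_sequences_fall_below_cutoff(self):
        rng = random.Random(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        s1 = "".join(rng.choice(aa) for _ in range(30))
        s2 = "".join(rng.choice(aa) for _ in range(30))
        bits, _ = self.scorer(s1, s2)
        assert bits < 40.0

    def test_unknown_residues_treated_as_x(self):
        bits, _ = self.scorer("MKVU", "MKVU")  # U not in BLOSUM62
        assert bits > 0


def test_all_vs_all_matches_direct_scorer_rerun():
    rng = random.Random(7)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    base = ["".join(rng.choice(aa) for _ in range(60)) for _ in range(4)]
    template = [ProteinRecord(f"T{i}", s) for i, s in enumerate(base)]
    query = [ProteinRecord(f"Q{i}", s[:55] + "AAAAA") for i, s in enumerate(base)]
    scorer = AlignmentScorer()
    scores = all_vs_all_scores(template, query, scorer)
    for s in scores:
        if s.species_a != s.species_b:
            seq_a = next(r.sequence for r in template if r.id == s.a)
            seq_b = next(r.sequence for r in query if r.id == s.b)
            assert s.score == pytest.approx(scorer(seq_a, seq_b)[0])
    # every protein keeps its self score even below no cutoff concerns
    for i in range(4):
        assert scores.self_score(TEMPLATE, f"T{i}") is not None
        assert scores.self_score(QUERY, f"Q{i}") is not None


class TestTwoWayBestHits:
    def test_diagonal_dominance_gives_diagonal_seeds(self):
        scores = ScoreSet(
            [cross("A", "Ap", 10), cross("A", "Bp", 1), cross("B", "Ap", 1), cross("B", "Bp", 10)]
        )
        seeds = two_way_best_hits(scores)
        assert {(s.template_id, s.query_id) for s in seeds} == {("A", "Ap"), ("B", "Bp")}
        assert all(s.inparalog_score == 1.0 and s.is_seed for s in seeds)

    def test_non_reciprocal_hit_is_not_a_seed(self):
        # A's best is Ap, but Ap's best is B
        scores = ScoreSet([cross("A", "Ap", 5), cross("B", "Ap", 9)])
        seeds = two_way_best_hits(scores)
        assert {(s.template_id, s.query_id) for s in seeds} == {("B", "Ap")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reciprocal_maxima(self, seed):
        rng = random.Random(seed)
        t_ids = [f"T{i}" for i in range(6)]
        q_ids = [f"Q{i}" for i in range(6)]
        matrix = {(t, q): rng.randint(1, 20) for t in t_ids for q in q_ids}
        scores = ScoreSet([cross(t, q, s) for (t, q), s in matrix.items()])

        def best(items):  # brute force: max value, lexicographic tiebreak
            top = max(v for _, v in items)
            return min(k for k, v in items if v == top)

        expected = set()
        for t in t_ids:
            q = best([(q, matrix[(t, q)]) for q in q_ids])
            if best([(t2, matrix[(t2, q)]) for t2 in t_ids]) == t:
                expected.add((t, q))
        got = {(s.template_id, s.query_id) for s in two_way_best_hits(scores)}
        assert got == expected


class TestClusterInparalogs:
    def base_scores(self, extra=()):
        return ScoreSet(
            [
                cross("A", "Ap", 60),
                within(TEMPLATE, "A", "A", 100),
                within(TEMPLATE, "P", "P", 100),
                within(QUERY, "Ap", "Ap", 100),
                *extra,
            ]
        )

    def seed(self):
        return [OrthologPair("A", "Ap", 1.0, "OG1", True)]

    def test_no_paralog_above_threshold_keeps_only_seed(self):
        scores = self.base_scores([within(TEMPLATE, "A", "P", 50)])
        pairs = cluster_inparalogs(scores, self.seed())
        assert len(pairs) == 1 and pairs[0].is_seed

    def test_stated_formula_midpoint(self):
        # sim(A,A)=100, sim(A,Ap)=60, sim(P,A)=80 -> (80-60)/(100-60) = 0.5
        scores = self.base_scores([within(TEMPLATE, "A", "P", 80)])
        pairs = cluster_inparalogs(scores, self.seed())
        inpara = next(p for p in pairs if not p.is_seed)
        assert (inpara.template_id, inpara.query_id) == ("P", "Ap")
        assert inpara.inparalog_score == pytest.approx(0.5)

    def test_paralog_as_similar_as_self_scores_one(self):
        scores = self.base_scores([within(TEMPLATE, "A", "P", 100)])
        (inpara,) = [p for p in cluster_inparalogs(scores, self.seed()) if not p.is_seed]
        assert inpara.inparalog_score == 1.0

    def test_degenerate_denominator_scores_one(self):
        scores = ScoreSet(
            [
                cross("A", "Ap", 100),
                within(TEMPLATE, "A", "A", 100),  # self score equals seed score
                within(TEMPLATE, "A", "P", 100),
                within(TEMPLATE, "P", "P", 100),
                within(QUERY, "Ap", "Ap", 100),
            ]
        )
        (inpara,) = [p for p in cluster_inparalogs(scores, self.seed()) if not p.is_seed]
        assert inpara.inparalog_score == 1.0

    def test_query_side_is_symmetric(self):
        scores = ScoreSet(
            [
                cross("A", "Ap", 60),
                within(TEMPLATE, "A", "A", 100),
                within(QUERY, "Ap", "Ap", 100),
                within(QUERY, "Ap", "Qp", 70),
                within(QUERY, "Qp", "Qp", 100),
            ]
        )
        (inpara,) = [p for p in cluster_inparalogs(scores, self.seed()) if not p.is_seed]
        assert (inpara.template_id, inpara.query_id) == ("A", "Qp")
        assert inpara.inparalog_score == pytest.approx(0.25)

    def test_conflicting_membership_goes_to_closer_seed(self):
        seeds = [
            OrthologPair("A", "Ap", 1.0, "OG1", True),
            OrthologPair("B", "Bp", 1.0, "OG2", True),
        ]
        scores = ScoreSet(
            [
                cross("A", "Ap", 50),
                cross("B", "Bp", 50),
                within(TEMPLATE, "A", "A", 100),
                within(TEMPLATE, "B", "B", 100),
                within(TEMPLATE, "P", "P", 100),
                within(TEMPLATE, "A", "P", 60),
                within(TEMPLATE, "B", "P", 80),
                within(QUERY, "Ap", "Ap", 100),
                within(QUERY, "Bp", "Bp", 100),
            ]
        )
        inparas = [p for p in cluster_inparalogs(scores, seeds) if not p.is_seed]
        assert len(inparas) == 1
        assert inparas[0].group_id == "OG2"  # P is closer to B than to A


class TestFullMapping:
    def test_self_mapping_yields_one_seed_group_per_protein(self, tiny_fixture):
        proteome = tiny_fixture.template_proteome
        pairs = map_orthologs(proteome, proteome)
        assert len(pairs) == len(proteome)
        assert all(p.is_seed and p.template_id == p.query_id for p in pairs)
        assert len({p.group_id for p in pairs}) == len(proteome)

    def test_invariant_to_input_ordering(self, tiny_fixture):
        t, q = list(tiny_fixture.template_proteome), list(tiny_fixture.query_proteome)
        forward = map_orthologs(t, q)
        backward = map_orthologs(list(reversed(t)), list(reversed(q)))
        key = lambda pairs: {(p.template_id, p.query_id, p.inparalog_score) for p in pairs}
        assert key(forward) == key(backward)

    def test_recovers_planted_one_to_one_orthology(self, tiny_fixture):
        pairs = map_orthologs(tiny_fixture.template_proteome, tiny_fixture.query_proteome)
        planted = {(p.template_id, p.query_id) for p in tiny_fixture.ortholog_pairs}
        recovered = {(p.template_id, p.query_id) for p in pairs if p.is_seed}
        assert len(recovered & planted) >= 0.95 * len(planted)


class TestOrthologTable:
    def test_round_trip_is_identity(self, tmp_path, small_fixture):
        p = tmp_path / "orth.tsv"
        write_ortholog_table(small_fixture.ortholog_pairs, p)
        assert tuple(load_ortholog_table(p)) == small_fixture.ortholog_pairs

    def test_score_out_of_range_is_error(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("T1\tQ1\t1.2\tOG1\t1\n")
        with pytest.raises(ValueError, match=r"outside \(0, 1\]"):
            load_ortholog_table(p)

    def test_group_without_seed_is_error(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("T1\tQ1\t0.5\tOG1\t0\n")
        with pytest.raises(ValueError, match="exactly one seed"):
            load_ortholog_table(p)

    def test_seed_must_score_one(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("T1\tQ1\t0.9\tOG1\t1\n")
        with pytest.raises(ValueError, match="seed"):
            load_ortholog_table(p)


def test_ortholog_pair_score_range_enforced():
    with pytest.raises(ValueError):
        OrthologPair("T", "Q", 0.0, "G", False)
    with pytest.raises(ValueError):
        OrthologPair("T", "Q", 1.5, "G", False)
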