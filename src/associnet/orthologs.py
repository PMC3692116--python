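"""InParanoid-style ortholog mapping with inparalog confidence scores.

The mapping proceeds in two stages over all-vs-all pairwise similarity
scores between a template proteome and a query proteome:

1. **Seeds.** A template/query pair (A, A') is an ortholog-group seed iff
   each protein is the other's highest-scoring cross-species hit (two-way
   best hit). Seeds carry an inparalog score of exactly 1.

2. **Inparalogs.** A same-species paralog P of a seed member A joins the
   group as a co-ortholog when it is at least as similar to A as A is to
   its seed partner, with confidence::

       score(P) = (sim(P, A) - sim(A, A')) / (sim(A, A) - sim(A, A'))

   which is 1 when P is indistinguishable from A and approaches 0 as P is
   barely more similar to A than the cross-species ortholog is. Scores are
   clamped to (0, 1].

Similarities come from a pluggable scorer; the default is a full pairwise
local alignment with BLOSUM62 substitution scores and affine gaps,
reported in bits via the Karlin-Altschul transform, mirroring how BLAST
bit scores would be used. Precomputed ortholog tables (e.g. genuine
INPARANOID output reformatted to five columns) can be loaded instead via
:func:`load_ortholog_table`.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from associnet.io import ProteinRecord

log = logging.getLogger(__name__)

TEMPLATE = "template"
QUERY = "query"

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1,
# as published for BLAST protein searches.
_KA_LAMBDA = 0.267
_KA_K = 0.041

DEFAULT_BIT_CUTOFF = 40.0
DEFAULT_OVERLAP_CUTOFF = 0.5


@dataclass(frozen=True)
class SimilarityScore:
    """A pairwise similarity in bits between two proteins.

    ``species_a``/``species_b`` tag which proteome each endpoint belongs
    to (``"template"`` or ``"query"``); identifiers alone are ambiguous
    because the two proteomes may share names (e.g. self-mapping).
    """

    a: str
    b: str
    score: float
    species_a: str = TEMPLATE
    species_b: str = QUERY

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"similarity score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class OrthologPair:
    """One template/query co-ortholog relation with its confidence.

    ``inparalog_score`` lies in (0, 1]; the group seed (the two-way best
    hit that founded the group) scores exactly 1 and is flagged
    ``is_seed``.
    """

    template_id: str
    query_id: str
    inparalog_score: float
    group_id: str
    is_seed: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.inparalog_score <= 1.0):
            raise ValueError(
                f"inparalog score must be in (0, 1], got {self.inparalog_score} "
                f"for ({self.template_id}, {self.query_id})"
            )


class ScoreSet:
    """Container for all-vs-all similarity scores with fast lookups.

    Iterating yields :class:`SimilarityScore` records. Lookup helpers
    expose the cross-species matrix and the within-proteome similarities
    (including each protein's self score) needed for inparalog clustering.
    """

    def __init__(self, scores: Iterable[SimilarityScore]):
        self._scores = list(scores)
        self.cross: dict[tuple[str, str], float] = {}
        self.within: dict[str, dict[tuple[str, str], float]] = {TEMPLATE: {}, QUERY: {}}
        for s in self._scores:
            if s.species_a == s.species_b:
                d = self.within[s.species_a]
                d[(s.a, s.b)] = s.score
                d[(s.b, s.a)] = s.score
            else:
                a, b = (s.a, s.b) if s.species_a == TEMPLATE else (s.b, s.a)
                self.cross[(a, b)] = s.score

    def __iter__(self) -> Iterator[SimilarityScore]:
        return iter(self._scores)

    def __len__(self) -> int:
        return len(self._scores)

    def self_score(self, species: str, pid: str) -> float | None:
        return self.within[species].get((pid, pid))

    def paralogs_of(self, species: str, pid: str) -> dict[str, float]:
        """Same-species similarity partners of ``pid`` (excluding itself)."""
        return {
            b: score
            for (a, b), score in self.within[species].items()
            if a == pid and b != pid
        }


class AlignmentScorer:
    """Pairwise local alignment similarity in bits.

    Uses BLOSUM62 with affine gap penalties (open 11, extend 1 per
    residue) and converts the raw Smith-Waterman score S to bits with the
    Karlin-Altschul transform ``(lambda * S - ln K) / ln 2``. ``overlap``
    is the fraction of the longer sequence covered by the alignment,
    used to reject short spurious local hits.
    """

    def __init__(
        self,
        matrix: str = "BLOSUM62",
        open_gap: float = -11.0,
        extend_gap: float = -1.0,
        ka_lambda: float = _KA_LAMBDA,
        ka_k: float = _KA_K,
    ):
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load(matrix)
        self._aligner.open_gap_score = open_gap
        self._aligner.extend_gap_score = extend_gap
        self._lambda = ka_lambda
        self._k = ka_k
        self._alphabet = set(str(self._aligner.substitution_matrix.alphabet))

    def _sanitize(self, seq: str) -> str:
        return "".join(c if c in self._alphabet else "X" for c in seq.upper())

    def bits(self, raw: float) -> float:
        return (self._lambda * raw - math.log(self._k)) / math.log(2.0)

    def __call__(self, seq_a: str, seq_b: str) -> tuple[float, float]:
        """Return (bit score, alignment overlap fraction of the longer seq)."""
        seq_a, seq_b = self._sanitize(seq_a), self._sanitize(seq_b)
        alignments = self._aligner.align(seq_a, seq_b)
        try:
            best = alignments[0]
        except IndexError:
            return 0.0, 0.0
        raw = best.score
        if raw <= 0:
            return 0.0, 0.0
        longer = max(len(seq_a), len(seq_b))
        blocks_a, blocks_b = best.aligned
        span_a = sum(end - start for start, end in blocks_a)
        span_b = sum(end - start for start, end in blocks_b)
        span = span_a if len(seq_a) >= len(seq_b) else span_b
        return self.bits(raw), span / longer


Scorer = Callable[[str, str], tuple[float, float]]


def all_vs_all_scores(
    proteome_a: Sequence[ProteinRecord],
    proteome_b: Sequence[ProteinRecord],
    scorer: Scorer | None = None,
    bit_cutoff: float = DEFAULT_BIT_CUTOFF,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> ScoreSet:
    """Score all cross-species pairs plus the within-proteome pairs needed
    for inparalog clustering.

    Pairs whose bit score falls below ``bit_cutoff`` or whose alignment
    covers less than ``overlap_cutoff`` of the longer sequence are
    omitted; self-pairs are always kept (they normalize inparalog
    scores). ``proteome_a`` is the template, ``proteome_b`` the query.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scorer = scorer or AlignmentScorer()

    def keep(bits: float, overlap: float) -> bool:
        return bits >= bit_cutoff and overlap >= overlap_cutoff

    scores: list[SimilarityScore] = []
    # deterministic iteration: sorted by id within each proteome
    prot_a = sorted(proteome_a, key=lambda r: r.id)
    prot_b = sorted(proteome_b, key=lambda r: r.id)
    for pa in prot_a:
        for pb in prot_b:
            bits, overlap = scorer(pa.sequence, pb.sequence)
            if keep(bits, overlap):
                scores.append(SimilarityScore(pa.id, pb.id, bits, TEMPLATE, QUERY))
    for species, prots in ((TEMPLATE, prot_a), (QUERY, prot_b)):
        for i, p in enumerate(prots):
            bits, _ = scorer(p.sequence, p.sequence)
            scores.append(SimilarityScore(p.id, p.id, bits, species, species))
            for q in prots[i + 1:]:
                bits, overlap = scorer(p.sequence, q.sequence)
                if keep(bits, overlap):
                    scores.append(SimilarityScore(p.id, q.id, bits, species, species))
    return ScoreSet(scores)


def two_way_best_hits(scores: ScoreSet) -> list[OrthologPair]:
    """Find seed ortholog pairs: reciprocal best cross-species hits.

    Ties for best hit are broken by the lexicographically smallest partner
    identifier and logged, so the mapping is deterministic regardless of
    input order.
    """

    def best_partner(hits: dict[str, float]) -> str:
        top = max(hits.values())
        tied = sorted(p for p, s in hits.items() if s == top)
        if len(tied) > 1:
            log.info("best-hit tie among %s; choosing %s", tied, tied[0])
        return tied[0]

    by_template: dict[str, dict[str, float]] = {}
    by_query: dict[str, dict[str, float]] = {}
    for (t, q), s in scores.cross.items():
        by_template.setdefault(t, {})[q] = s
        by_query.setdefault(q, {})[t] = s

    seeds: list[tuple[str, str]] = []
    for t in sorted(by_template):
        q = best_partner(by_template[t])
        if best_partner(by_query[q]) == t:
            seeds.append((t, q))
    return [
        OrthologPair(t, q, 1.0, f"OG{i:05d}", True)
        for i, (t, q) in enumerate(sorted(seeds), start=1)
    ]


def cluster_inparalogs(scores: ScoreSet, seeds: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Expand seed pairs into co-ortholog groups with inparalog scores.

    For a seed (A, A'), any same-species paralog P of A scoring at least
    ``sim(A, A')`` against A joins the group paired with A', with
    confidence ``(sim(P,A) - sim(A,A')) / (sim(A,A) - sim(A,A'))``;
    symmetrically for the query side. Proteins that are themselves seed
    members never join another group as inparalogs; a protein qualifying
    for several groups is assigned to the one whose seed member it
    resembles most (ties to the lexicographically smallest group id).
    A degenerate denominator (self score equal to the seed score) makes
    every qualifying inparalog score 1, with a log entry.
    """
    seed_members = {TEMPLATE: {s.template_id for s in seeds}, QUERY: {s.query_id for s in seeds}}

    # candidate memberships: (species, paralog id) -> (similarity to seed member, group, pair)
    candidates: dict[tuple[str, str], tuple[float, str, OrthologPair]] = {}

    def consider(species: str, paralog: str, sim: float, group: str, pair: OrthologPair) -> None:
        key = (species, paralog)
        incumbent = candidates.get(key)
        if (
            incumbent is None
            or sim > incumbent[0]
            or (sim == incumbent[0] and group < incumbent[1])
        ):
            candidates[key] = (sim, group, pair)

    result: list[OrthologPair] = list(seeds)
    for seed in seeds:
        seed_sim = scores.cross.get((seed.template_id, seed.query_id))
        if seed_sim is None:
            raise ValueError(
                f"seed ({seed.template_id}, {seed.query_id}) has no cross-species score"
            )
        for species, anchor, mate in (
            (TEMPLATE, seed.template_id, seed.query_id),
            (QUERY, seed.query_id, seed.template_id),
        ):
            self_sim = scores.self_score(species, anchor)
            if self_sim is None:
                raise ValueError(f"missing self score for {species} protein {anchor}")
            denom = self_sim - seed_sim
            for paralog, sim in scores.paralogs_of(species, anchor).items():
                if sim < seed_sim or paralog in seed_members[species]:
                    continue
                if denom <= 0:
                    log.info(
                        "degenerate inparalog denominator for %s in group %s; score set to 1",
                        paralog, seed.group_id,
                    )
                    conf = 1.0
                else:
                    conf = (sim - seed_sim) / denom
                conf = min(max(conf, 1e-6), 1.0)
                if species == TEMPLATE:
                    pair = OrthologPair(paralog, mate, conf, seed.group_id, False)
                else:
                    pair = OrthologPair(mate, paralog, conf, seed.group_id, False)
                consider(species, paralog, sim, seed.group_id, pair)

    result.extend(pair for _, _, pair in candidates.values())
    result.sort(key=lambda p: (p.group_id, not p.is_seed, p.template_id, p.query_id))
    return result


def map_orthologs(
    template_proteome: Sequence[ProteinRecord],
    query_proteome: Sequence[ProteinRecord],
    scorer: Scorer | None = None,
    bit_cutoff: float = DEFAULT_BIT_CUTOFF,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> list[OrthologPair]:
    """Full mapping: all-vs-all scoring, seeds, then inparalog clustering."""
    scores = all_vs_all_scores(
        template_proteome, query_proteome, scorer, bit_cutoff, overlap_cutoff
    )
    seeds = two_way_best_hits(scores)
    return cluster_inparalogs(scores, seeds)


# ---------------------------------------------------------------------------
# Precomputed tables

ORTHOLOG_COLUMNS = ("template_id", "query_id", "inparalog_score", "group_id", "is_seed")


def write_ortholog_table(
    pairs: Sequence[OrthologPair],
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("# " + "\t".join(ORTHOLOG_COLUMNS) + "\n")
        for p in sorted(pairs, key=lambda p: (p.group_id, not p.is_seed, p.template_id, p.query_id)):
            fh.write(
                f"{p.template_id}\t{p.query_id}\t{p.inparalog_score:.9g}"
                f"\t{p.group_id}\t{int(p.is_seed)}\n"
            )


def load_ortholog_table(path: str | os.PathLike) -> list[OrthologPair]:
    """Load a precomputed five-column ortholog table, enforcing invariants.

    Scores outside (0, 1], seeds not scoring 1, or groups without exactly
    one seed pair are hard errors.
    """
    from associnet.io import _data_lines

    pairs: list[OrthologPair] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(cols)}")
        t, q, score_s, group, seed_s = (c.strip() for c in cols)
        try:
            score = float(score_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric inparalog score {score_s!r}") from None
        if not (0.0 < score <= 1.0):
            raise ValueError(f"{path}:{lineno}: inparalog score {score} outside (0, 1]")
        is_seed = seed_s in ("1", "true", "True")
        if is_seed and score != 1.0:
            raise ValueError(f"{path}:{lineno}: seed pair with inparalog score {score} != 1")
        pairs.append(OrthologPair(t, q, score, group, is_seed))

    seeds_per_group: dict[str, int] = {}
    for p in pairs:
        seeds_per_group.setdefault(p.group_id, 0)
        if p.is_seed:
            seeds_per_group[p.group_id] += 1
    bad = {g: n for g, n in seeds_per_group.items() if n != 1}
    if bad:
        raise ValueError(f"{path}: groups without exactly one seed: {sorted(bad)}")
    return pairs
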