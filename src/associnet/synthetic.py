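"""Deterministic synthetic fixtures with known ground truth.

The generator plants a template network with pathway structure (each
pathway a high-LLS clique over a disjoint block of template proteins,
plus sparse random background edges), an orthology map between a
template and a query proteome with chosen inparalog scores, and protein
sequences consistent with that orthology (query sequences are mutated
copies of their template orthologs; divergence grows as the planted
inparalog score falls). A ground-truth ledger records every expected
transferred edge and its expected adjusted LLS, computed by direct
enumeration independent of the pipeline code, so every downstream module
can be tested against it without external data.

All randomness flows from the single integer seed in the spec through
one :class:`numpy.random.Generator`; identical specs produce identical
fixtures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from associnet import io
from associnet.io import AnnotationSet, ProteinRecord, WeightedEdge
from associnet.orthologs import OrthologPair, write_ortholog_table

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# extra per-site substitution applied as the planted inparalog score drops
# below 1; a fixture calibration constant, not an evolutionary model
_DIVERGENCE_PER_SCORE_DEFICIT = 0.35


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture.

    ``orthology_map`` optionally plants explicit (template_id, query_id,
    inparalog_score) triples; by default protein i of the template maps
    one-to-one to protein i of the query with ``inparalog_score``.
    ``within_pathway_lls`` is the (mean, sd) of the normal draw for
    clique edge scores, clipped below at 0.5; background edges draw
    uniformly from ``background_lls``.
    """

    n_template_proteins: int = 60
    n_query_proteins: int = 60
    n_pathways: int = 4
    pathway_sizes: tuple[int, ...] | None = None
    within_pathway_lls: tuple[float, float] = (3.0, 0.5)
    background_edge_rate: float = 0.01
    background_lls: tuple[float, float] = (0.2, 1.2)
    orthology_map: tuple[tuple[str, str, float], ...] | None = None
    inparalog_score: float = 1.0
    sequence_length: int = 90
    divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_template_proteins, self.n_query_proteins) < 1:
            raise ValueError("proteome sizes must be positive")
        if self.n_pathways < 0:
            raise ValueError("n_pathways must be >= 0")
        if not (0.0 <= self.background_edge_rate <= 1.0):
            raise ValueError("background_edge_rate must be a probability")
        if not (0.0 < self.inparalog_score <= 1.0):
            raise ValueError("inparalog_score must be in (0, 1]")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if self.sequence_length < 10:
            raise ValueError("sequence_length must be >= 10")
        sizes = self.resolved_pathway_sizes()
        if sum(sizes) > self.n_template_proteins:
            raise ValueError(
                f"pathways need {sum(sizes)} proteins but the template has "
                f"{self.n_template_proteins}"
            )

    def resolved_pathway_sizes(self) -> tuple[int, ...]:
        if self.pathway_sizes is not None:
            if len(self.pathway_sizes) != self.n_pathways:
                raise ValueError("pathway_sizes length must equal n_pathways")
            if any(s < 2 for s in self.pathway_sizes):
                raise ValueError("every pathway needs at least 2 members")
            return tuple(self.pathway_sizes)
        return (8,) * self.n_pathways


@dataclass(frozen=True)
class Fixture:
    """A generated fixture plus its ground-truth ledger.

    ``expected_candidates`` maps each unordered query pair reachable by
    transfer to its best (max-aggregated) expected adjusted LLS before
    the chance-level filter; ``expected_edges`` is the subset with
    adjusted LLS >= 0, i.e. the exact expected output network.
    ``template_lls_sum`` is bookkeeping for reader tests.
    """

    spec: FixtureSpec
    template_proteome: tuple[ProteinRecord, ...]
    query_proteome: tuple[ProteinRecord, ...]
    template_edges: tuple[WeightedEdge, ...]
    ortholog_pairs: tuple[OrthologPair, ...]
    pathways: tuple[AnnotationSet, ...]
    expected_candidates: dict[tuple[str, str], float]
    expected_edges: dict[tuple[str, str], float]
    template_lls_sum: float


def _expected_network(
    template_edges: Sequence[WeightedEdge],
    pairs: Sequence[OrthologPair],
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Ledger computation: plain enumeration of transfer candidates."""
    targets: dict[str, list[tuple[str, float]]] = {}
    for p in pairs:
        targets.setdefault(p.template_id, []).append((p.query_id, p.inparalog_score))
    best: dict[tuple[str, str], float] = {}
    for e in template_edges:
        for qa, s1 in targets.get(e.a, ()):
            for qb, s2 in targets.get(e.b, ()):
                if qa == qb:
                    continue
                pair = (qa, qb) if qa <= qb else (qb, qa)
                lls = e.lls + math.log(s1) + math.log(s2)
                if pair not in best or lls > best[pair]:
                    best[pair] = lls
    kept = {pair: lls for pair, lls in best.items() if lls >= 0.0}
    return best, kept


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    chars = np.array(list(sequence))
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        options = AMINO_ACIDS[AMINO_ACIDS != chars[i]]
        chars[i] = rng.choice(options)
    return "".join(chars)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete fixture from a spec; deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    t_ids = [f"T{i:04d}" for i in range(spec.n_template_proteins)]
    q_ids = [f"Q{i:04d}" for i in range(spec.n_query_proteins)]

    # pathways: disjoint consecutive blocks of template proteins
    sizes = spec.resolved_pathway_sizes()
    pathways: list[AnnotationSet] = []
    cursor = 0
    for k, size in enumerate(sizes, start=1):
        members = frozenset(t_ids[cursor:cursor + size])
        cursor += size
        pathways.append(
            AnnotationSet(f"PATH:{k:04d}", f"planted pathway {k}", "KEGG", members)
        )

    # template network: cliques within pathways + random background
    mean, sd = spec.within_pathway_lls
    edges: dict[tuple[str, str], float] = {}
    for term in pathways:
        members = sorted(term.members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                edges[(a, b)] = max(float(rng.normal(mean, sd)), 0.5)
    lo, hi = spec.background_lls
    for i, a in enumerate(t_ids):
        for b in t_ids[i + 1:]:
            if (a, b) in edges:
                continue
            if rng.random() < spec.background_edge_rate:
                edges[(a, b)] = float(rng.uniform(lo, hi))
    template_edges = tuple(WeightedEdge(a, b, lls) for (a, b), lls in sorted(edges.items()))

    # orthology: planted map (default one-to-one with a uniform score)
    if spec.orthology_map is not None:
        planted = list(spec.orthology_map)
    else:
        n = min(spec.n_template_proteins, spec.n_query_proteins)
        planted = [(t_ids[i], q_ids[i], spec.inparalog_score) for i in range(n)]
    pairs = tuple(
        OrthologPair(t, q, s, f"OG{i:05d}", s == 1.0)
        for i, (t, q, s) in enumerate(sorted(planted), start=1)
    )

    # sequences: random template proteins; query orthologs are mutated copies
    t_seq = {tid: _random_sequence(rng, spec.sequence_length) for tid in t_ids}
    q_seq: dict[str, str] = {}
    for t, q, s in sorted(planted):
        rate = spec.divergence + _DIVERGENCE_PER_SCORE_DEFICIT * (1.0 - s)
        if q not in q_seq:  # a query protein keeps its first ortholog's sequence
            q_seq[q] = _mutate(rng, t_seq[t], rate)
    for qid in q_ids:
        if qid not in q_seq:
            q_seq[qid] = _random_sequence(rng, spec.sequence_length)

    template_proteome = tuple(ProteinRecord(tid, t_seq[tid]) for tid in t_ids)
    query_proteome = tuple(ProteinRecord(qid, q_seq[qid]) for qid in q_ids)

    candidates, expected = _expected_network(template_edges, pairs)
    return Fixture(
        spec=spec,
        template_proteome=template_proteome,
        query_proteome=query_proteome,
        template_edges=template_edges,
        ortholog_pairs=pairs,
        pathways=tuple(pathways),
        expected_candidates=candidates,
        expected_edges=expected,
        template_lls_sum=float(sum(e.lls for e in template_edges)),
    )


def perturb_orthology(
    fixture: Fixture,
    dropout: float = 0.0,
    score_decay: float = 1.0,
    seed: int | None = None,
) -> Fixture:
    """Weaken a fixture's orthology: drop pairs and decay surviving scores.

    Each ortholog pair is removed with probability ``dropout``; surviving
    inparalog scores are multiplied by ``score_decay`` (a decayed seed is
    no longer flagged as one). The ground-truth ledger is recomputed so
    expected-absent edges (adjusted LLS falling below 0) are tracked.
    """
    if not (0.0 <= dropout <= 1.0) or not (0.0 <= score_decay <= 1.0):
        raise ValueError("dropout and score_decay must lie in [0, 1]")
    rng = np.random.default_rng(fixture.spec.seed + 7919 if seed is None else seed)
    survivors: list[OrthologPair] = []
    for p in fixture.ortholog_pairs:
        if rng.random() < dropout:
            continue
        score = p.inparalog_score * score_decay
        if score <= 0.0:
            continue
        survivors.append(
            OrthologPair(p.template_id, p.query_id, score, p.group_id, p.is_seed and score == 1.0)
        )
    candidates, expected = _expected_network(fixture.template_edges, survivors)
    return replace(
        fixture,
        ortholog_pairs=tuple(survivors),
        expected_candidates=candidates,
        expected_edges=expected,
    )


def random_pathways(
    protein_ids: Sequence[str],
    n_pathways: int,
    size_range: tuple[int, int] = (5, 20),
    seed: int = 0,
) -> list[AnnotationSet]:
    """Random member sets over a protein universe (for null calibration)."""
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(protein_ids))
    lo, hi = size_range
    if lo < 1 or hi > len(ids):
        raise ValueError("size_range incompatible with the protein universe")
    out = []
    for k in range(1, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(ids, size=size, replace=False))
        out.append(AnnotationSet(f"RAND:{k:04d}", f"random pathway {k}", "KEGG", members))
    return out


def write_fixture(fixture: Fixture, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write a fixture to disk in the pipeline's input formats.

    Returns a name -> path map: template/query FASTA, template edge list,
    ortholog table, pathway GMT, and the ground-truth ledger TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "template_fasta": outdir / "template.faa",
        "query_fasta": outdir / "query.faa",
        "template_network": outdir / "template_network.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "pathways": outdir / "pathways.gmt",
        "ledger": outdir / "ledger.tsv",
    }
    io.write_fasta(fixture.template_proteome, paths["template_fasta"])
    io.write_fasta(fixture.query_proteome, paths["query_fasta"])
    io.write_edge_list(fixture.template_edges, paths["template_network"],
                       header_comments=[f"fixture seed={fixture.spec.seed}"])
    write_ortholog_table(fixture.ortholog_pairs, paths["orthologs"])
    io.write_gene_sets(fixture.pathways, paths["pathways"])
    with open(paths["ledger"], "w") as fh:
        fh.write("# query_a\tquery_b\texpected_lls\texpected_present\n")
        for pair in sorted(fixture.expected_candidates):
            lls = fixture.expected_candidates[pair]
            fh.write(f"{pair[0]}\t{pair[1]}\t{lls:.9f}\t{int(pair in fixture.expected_edges)}\n")
    return paths
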