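"""Projection of template network edges onto query ortholog pairs.

Given a template edge (A, B) with log likelihood score LLS(A-B) and
ortholog pairs A-A' and B-B' with inparalog scores s_AA' and s_BB', the
transferred edge (an *associalog*) between query proteins A' and B' is
scored::

    LLS(A'-B') = LLS(A-B) + ln(s_AA') + ln(s_BB')

Weak orthology therefore down-weights the transferred score; associalogs
that fall below chance level (adjusted LLS < 0) are excluded from the
final network, while exactly 0 (chance level) is retained. When several
template edges project onto the same unordered query pair, the maximum
adjusted score is kept (transferred scores from one template are not
independent evidence, so summing would overcount).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from associnet.io import ProteinRecord, WeightedEdge
from associnet.orthologs import OrthologPair

log = logging.getLogger(__name__)

_CONSISTENCY_TOL = 1e-9


def adjust_lls(template_lls: float, s1: float, s2: float) -> float:
    """Adjusted LLS for an associalog: template LLS + ln(s1) + ln(s2).

    ``s1``/``s2`` are the inparalog scores of the two orthologous
    relationships and must lie in (0, 1]; the result never exceeds the
    template LLS and equals it only for two perfect orthologs.
    """
    for s in (s1, s2):
        if not (0.0 < s <= 1.0):
            raise ValueError(f"inparalog score must be in (0, 1], got {s}")
    return template_lls + math.log(s1) + math.log(s2)


def likelihood_ratio(lls: float) -> float:
    """Fold-change over chance implied by an LLS: exp(lls).

    An LLS of 0 corresponds to chance level (ratio 1); an LLS of 4 to a
    likelihood ~55 times higher than expected by chance.
    """
    if not math.isfinite(lls):
        raise ValueError(f"LLS must be finite, got {lls}")
    return math.exp(lls)


@dataclass(frozen=True)
class AssocialogEdge:
    """A transferred query edge with full provenance.

    ``source_edge`` is the template edge the score came from and
    ``source_scores`` the pair of inparalog scores (s for query_a's
    ortholog relation, s for query_b's). Candidate edges before filtering
    may carry a negative adjusted LLS; the network container enforces the
    non-negativity invariant.
    """

    query_a: str
    query_b: str
    adjusted_lls: float
    source_edge: WeightedEdge
    source_scores: tuple[float, float]

    def __post_init__(self) -> None:
        if self.query_a == self.query_b:
            raise ValueError(f"self-loop associalog on {self.query_a!r}")
        expected = self.source_edge.lls + math.log(self.source_scores[0]) + math.log(
            self.source_scores[1]
        )
        if abs(expected - self.adjusted_lls) > 1e-6:
            raise ValueError(
                f"inconsistent associalog score for ({self.query_a}, {self.query_b}): "
                f"{self.adjusted_lls} != {expected}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (
            (self.query_a, self.query_b)
            if self.query_a <= self.query_b
            else (self.query_b, self.query_a)
        )


@dataclass
class AssocialogNetwork:
    """A constructed query network: one edge per unordered query pair.

    ``proteome_size`` (number of proteins in the query proteome) enables
    the coding-genome coverage statistic: distinct network nodes divided
    by proteome size.
    """

    edges: dict[tuple[str, str], AssocialogEdge] = field(default_factory=dict)
    proteome_size: int | None = None

    def __post_init__(self) -> None:
        for pair, e in self.edges.items():
            if pair != e.pair:
                raise ValueError(f"edge keyed by {pair} but canonical pair is {e.pair}")
            if e.adjusted_lls < 0:
                raise ValueError(f"network edge {pair} has negative adjusted LLS")

    def __iter__(self) -> Iterator[AssocialogEdge]:
        return iter(self.edges.values())

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(sorted(pair)) in self.edges

    def get(self, a: str, b: str) -> AssocialogEdge | None:
        return self.edges.get((a, b) if a <= b else (b, a))

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return frozenset(out)

    @property
    def coverage(self) -> float | None:
        """Coding-genome coverage: distinct nodes / query proteome size."""
        if self.proteome_size is None:
            return None
        if self.proteome_size <= 0:
            raise ValueError("proteome_size must be positive")
        return len(self.nodes) / self.proteome_size

    def incident(self, node: str) -> list[AssocialogEdge]:
        return [e for pair, e in self.edges.items() if node in pair]


def project_edges(
    template_edges: Iterable[WeightedEdge],
    orthologs: Sequence[OrthologPair],
) -> list[AssocialogEdge]:
    """Enumerate all candidate associalogs, pre-filtering.

    Every combination of an A-ortholog and a B-ortholog of a template
    edge (A, B) yields a candidate — co-orthologs included — scored by
    :func:`adjust_lls`. Candidates collapsing to a self-loop (both
    template proteins mapping to the same query protein) are dropped.
    Template proteins with no ortholog contribute nothing.
    """
    targets: dict[str, list[tuple[str, float]]] = {}
    for p in orthologs:
        targets.setdefault(p.template_id, []).append((p.query_id, p.inparalog_score))

    candidates: list[AssocialogEdge] = []
    for edge in template_edges:
        for qa, s1 in targets.get(edge.a, ()):
            for qb, s2 in targets.get(edge.b, ()):
                if qa == qb:
                    continue
                candidates.append(
                    AssocialogEdge(
                        query_a=qa,
                        query_b=qb,
                        adjusted_lls=adjust_lls(edge.lls, s1, s2),
                        source_edge=edge,
                        source_scores=(s1, s2),
                    )
                )
    return candidates


def filter_and_aggregate(
    candidates: Iterable[AssocialogEdge],
    aggregation: str = "max",
    lls_floor: float = 0.0,
    proteome_size: int | None = None,
) -> AssocialogNetwork:
    """Drop sub-chance candidates and collapse duplicates per query pair.

    Candidates with adjusted LLS strictly below ``lls_floor`` (default 0,
    i.e. chance level) are removed; a score of exactly the floor is
    retained. With the default ``"max"`` aggregation the best candidate
    per unordered query pair survives with its provenance; ``"sum"`` adds
    the adjusted scores of all surviving candidates for a pair (keeping
    the top contributor's provenance, with ``source_scores`` rescaled so
    the stored edge remains self-consistent).
    """
    if aggregation not in ("max", "sum"):
        raise ValueError(f"unknown aggregation rule {aggregation!r}")
    grouped: dict[tuple[str, str], list[AssocialogEdge]] = {}
    for c in candidates:
        if c.adjusted_lls < lls_floor:
            continue
        grouped.setdefault(c.pair, []).append(c)

    edges: dict[tuple[str, str], AssocialogEdge] = {}
    for pair, group in grouped.items():
        best = max(group, key=lambda e: (e.adjusted_lls, -e.source_edge.lls))
        if aggregation == "max" or len(group) == 1:
            keep = best
        else:
            total = sum(e.adjusted_lls for e in group)
            # rescale provenance scores so the consistency invariant holds
            residual = total - best.source_edge.lls
            s = math.exp(min(residual, 0.0) / 2.0)
            src = best.source_edge
            if residual > 0:
                src = WeightedEdge(src.a, src.b, total)
                s = 1.0
            keep = AssocialogEdge(pair[0], pair[1], total, src, (s, s))
        if (keep.query_a, keep.query_b) != pair:  # canonical orientation
            keep = AssocialogEdge(
                pair[0], pair[1], keep.adjusted_lls, keep.source_edge,
                (keep.source_scores[1], keep.source_scores[0]),
            )
        edges[pair] = keep
    return AssocialogNetwork(edges=edges, proteome_size=proteome_size)


def build_network(
    query_proteome: Sequence[ProteinRecord] | None,
    template_edges: Iterable[WeightedEdge],
    orthologs: Sequence[OrthologPair],
    aggregation: str = "max",
    lls_floor: float = 0.0,
) -> AssocialogNetwork:
    """End-to-end network construction: project, filter, aggregate.

    Reports coding-genome coverage when the query proteome is provided.
    An empty ortholog map yields an empty network with a prominent
    warning rather than an error.
    """
    if not orthologs:
        log.warning("empty ortholog map: the constructed network has no edges")
    proteome_size = len(query_proteome) if query_proteome is not None else None
    candidates = project_edges(template_edges, orthologs)
    net = filter_and_aggregate(
        candidates, aggregation=aggregation, lls_floor=lls_floor, proteome_size=proteome_size
    )
    log.info(
        "network built: %d candidate edges, %d retained, coverage=%s",
        len(candidates), len(net),
        f"{net.coverage:.3f}" if net.coverage is not None else "n/a",
    )
    return net
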