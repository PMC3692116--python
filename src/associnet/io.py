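"""Readers and writers for every file the pipeline touches.

File formats are deliberately plain text so outputs are diffable and
byte-reproducible:

* protein sequences: FASTA (amino acid, ``X`` allowed);
* network edge lists: tab-separated ``a<TAB>b<TAB>lls`` with optional
  ``#``-prefixed comment/header lines;
* gene sets: GMT (``term_id<TAB>description<TAB>member...``) or two-column
  ``term_id<TAB>protein`` — the dialect is auto-detected per file;
* constructed networks: a six-column provenance layout (query pair,
  adjusted LLS, source template pair, template LLS).

All writers emit a commented header line starting with ``#`` naming the
columns; readers skip any leading ``#`` lines.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_CATEGORIES = ("GO:BP", "GO:CC", "GO:MF", "KEGG")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence.

    The identifier is the FASTA header token before the first whitespace;
    anything after it is kept as ``description``. Identifiers are
    case-sensitive and must be unique within a proteome.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be a non-empty token, got {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")


@dataclass(frozen=True)
class WeightedEdge:
    """An undirected network edge with a log likelihood score (LLS).

    The LLS is the natural-log-scaled likelihood of functional association
    between the two proteins relative to chance; 0 means chance level.
    Edges are unordered: ``(a, b)`` and ``(b, a)`` denote the same edge and
    ``key`` gives the canonical (sorted) form.
    """

    a: str
    b: str
    lls: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop edge on {self.a!r}")
        if not math.isfinite(self.lls):
            raise ValueError(f"non-finite LLS on edge ({self.a}, {self.b})")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class AnnotationSet:
    """A named gene set: a GO term or KEGG pathway with its member proteins."""

    term_id: str
    term_name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"term {self.term_id}: category {self.category!r} not one of {VALID_CATEGORIES}"
            )
        if not self.members:
            raise ValueError(f"term {self.term_id}: empty member set")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Record order is preserved. Duplicate identifiers are a hard error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | os.PathLike) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Edge lists


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | os.PathLike, skip_lines: int = 0) -> list[WeightedEdge]:
    """Read a tab-delimited ``a, b, lls`` edge list.

    ``#`` comment lines and the first ``skip_lines`` non-comment lines are
    skipped. Extra columns beyond the third (evidence codes etc.) are
    ignored with a single warning. Self-loops and duplicate unordered pairs
    are hard errors.
    """
    edges: list[WeightedEdge] = []
    seen: dict[tuple[str, str], int] = {}
    warned_extra = False
    skipped = 0
    for lineno, line in _data_lines(path):
        if skipped < skip_lines:
            skipped += 1
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(cols)}")
        if len(cols) > 3 and not warned_extra:
            log.warning("%s:%d: extra columns beyond the third are ignored", path, lineno)
            warned_extra = True
        a, b = cols[0].strip(), cols[1].strip()
        try:
            lls = float(cols[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric LLS column {cols[2]!r}") from None
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop edge on {a!r}")
        edge = WeightedEdge(a, b, lls)
        if edge.key in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate unordered pair ({a}, {b}), "
                f"first seen at line {seen[edge.key]}"
            )
        seen[edge.key] = lineno
        edges.append(edge)
    return edges


def write_edge_list(
    edges: Sequence[WeightedEdge],
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("# protein_a\tprotein_b\tlls\n")
        for e in sorted(edges, key=lambda e: (-e.lls, e.key)):
            a, b = e.key
            fh.write(f"{a}\t{b}\t{e.lls:.6f}\n")


# ---------------------------------------------------------------------------
# Gene sets


def read_gene_sets(
    path: str | os.PathLike,
    category: str | None = None,
) -> list[AnnotationSet]:
    """Read gene sets in GMT or two-column TSV dialect (auto-detected).

    A file whose every line has exactly two columns is treated as
    ``term_id<TAB>protein`` rows; anything else as GMT
    (``term_id<TAB>description<TAB>member...``). Members are deduplicated
    and terms that end up empty are dropped with a warning.

    ``category`` applies to every term in the file; when omitted it is
    inferred from the term id prefix (``GO:`` terms default to the
    biological-process category, everything else to KEGG).
    """
    rows: list[tuple[int, list[str]]] = [
        (lineno, line.split("\t")) for lineno, line in _data_lines(path)
    ]
    if not rows:
        return []
    for lineno, cols in rows:
        if len(cols) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
    two_column = all(len(cols) == 2 for _, cols in rows)

    def infer(term_id: str) -> str:
        if category is not None:
            return category
        return "GO:BP" if term_id.startswith("GO:") else "KEGG"

    sets: list[AnnotationSet] = []
    if two_column:
        members: dict[str, set[str]] = {}
        order: list[str] = []
        for _, (term, protein) in rows:
            term, protein = term.strip(), protein.strip()
            if term not in members:
                members[term] = set()
                order.append(term)
            if protein:
                members[term].add(protein)
        for term in order:
            if not members[term]:
                log.warning("%s: term %s has no members; dropped", path, term)
                continue
            sets.append(AnnotationSet(term, term, infer(term), frozenset(members[term])))
    else:
        for lineno, cols in rows:
            term, desc, *rest = (c.strip() for c in cols)
            mems = frozenset(m for m in rest if m)
            if not mems:
                log.warning("%s:%d: term %s has no members; dropped", path, lineno, term)
                continue
            sets.append(AnnotationSet(term, desc or term, infer(term), mems))
    return sets


def write_gene_sets(
    sets: Sequence[AnnotationSet],
    path: str | os.PathLike,
    header_comments: Sequence[str] = (),
) -> None:
    """Write gene sets in GMT dialect (one term per line)."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("# term_id\tterm_name\tmembers...\n")
        for s in sorted(sets, key=lambda s: s.term_id):
            fh.write("\t".join([s.term_id, s.term_name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Constructed networks (six-column provenance layout)

NETWORK_COLUMNS = (
    "query_a",
    "query_b",
    "adjusted_lls",
    "template_a",
    "template_b",
    "template_lls",
)


def write_network(net, path: str | os.PathLike, header_comments: Sequence[str] = ()) -> None:
    """Write a constructed query network with provenance.

    Columns: query pair, adjusted LLS (6 decimals), the template edge the
    score was transferred from, and the template LLS. Rows are sorted by
    adjusted LLS descending with lexicographic pair tiebreak so output is
    byte-reproducible.
    """
    edges = sorted(net, key=lambda e: (-e.adjusted_lls, e.pair))
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("# " + "\t".join(NETWORK_COLUMNS) + "\n")
        for e in edges:
            src = e.source_edge
            fh.write(
                f"{e.query_a}\t{e.query_b}\t{e.adjusted_lls:.6f}"
                f"\t{src.a}\t{src.b}\t{src.lls:.6f}\n"
            )


def read_network(path: str | os.PathLike, proteome_size: int | None = None):
    """Read back a network written by :func:`write_network`.

    Returns an :class:`associnet.transfer.AssocialogNetwork`. Inparalog
    provenance scores are not serialized, so the reconstructed edges carry
    the pair of scores only implicitly (their product is recoverable from
    ``adjusted_lls - template_lls``); ``source_scores`` is set to the
    symmetric split of that residual.
    """
    from associnet.transfer import AssocialogEdge, AssocialogNetwork

    edges: dict[tuple[str, str], AssocialogEdge] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
        qa, qb, adj, ta, tb, tlls = cols
        try:
            adjusted = float(adj)
            template_lls = float(tlls)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score column") from None
        s = math.exp((adjusted - template_lls) / 2.0)
        edge = AssocialogEdge(
            query_a=qa,
            query_b=qb,
            adjusted_lls=adjusted,
            source_edge=WeightedEdge(ta, tb, template_lls),
            source_scores=(min(s, 1.0), min(s, 1.0)),
        )
        if edge.pair in edges:
            raise ValueError(f"{path}:{lineno}: duplicate query pair ({qa}, {qb})")
        edges[edge.pair] = edge
    return AssocialogNetwork(edges=edges, proteome_size=proteome_size)
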