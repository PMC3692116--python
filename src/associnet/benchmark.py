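"""Network quality assessment against a pathway-based gold standard.

Three evaluations, all driven by KEGG-style pathway gene sets over the
query proteome:

* **Gold standard** — positive pairs share at least one pathway; negative
  pairs are annotated proteins sharing none. Pairs involving unannotated
  proteins are not classifiable and are ignored by the precision metric.
* **Precision vs coding-genome coverage** — network links are sorted by
  adjusted LLS and walked in bins (1000 links by default); after each
  bin, cumulative precision over gold-evaluable links is plotted against
  the fraction of the coding genome covered by the nodes seen so far.
* **Per-pathway ROC AUC** — a guilt-by-association score for every
  protein (sum of adjusted LLS over its edges to pathway members,
  excluding itself) is compared between members and non-members with the
  Mann-Whitney rank statistic; only pathways with at least five members
  are scored and the distribution is summarized as box-plot statistics.
  An AUC of 0.5 is the chance level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from associnet.io import AnnotationSet
from associnet.transfer import AssocialogNetwork

log = logging.getLogger(__name__)

MIN_PATHWAY_MEMBERS = 5
DEFAULT_BIN_SIZE = 1000

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """Pathway co-membership gold standard over annotated proteins."""

    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("a pair cannot be both positive and negative")

    def classify(self, a: str, b: str) -> bool | None:
        """True for a positive pair, False for negative, None if not evaluable."""
        pair = (a, b) if a <= b else (b, a)
        if pair in self.positives:
            return True
        if pair in self.negatives:
            return False
        return None


@dataclass(frozen=True)
class PrecisionCoveragePoint:
    links_considered: int
    precision: float | None
    genome_coverage: float


@dataclass(frozen=True)
class PathwayAUC:
    term_id: str
    n_members: int
    auc: float

    def __post_init__(self) -> None:
        if self.n_members < MIN_PATHWAY_MEMBERS:
            raise ValueError(f"pathway {self.term_id}: fewer than {MIN_PATHWAY_MEMBERS} members")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"pathway {self.term_id}: AUC {self.auc} outside [0, 1]")


@dataclass(frozen=True)
class AucSummary:
    """Box-and-whisker statistics of a set of pathway AUCs.

    Quartiles use linear interpolation (numpy's default, R type 7);
    whiskers reach the most extreme values within 1.5 IQR of the box.
    """

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def build_gold_standard(annotations: Sequence[AnnotationSet]) -> GoldStandard:
    """Enumerate positive and negative pairs from pathway co-membership."""
    terms_of: dict[str, set[str]] = {}
    for term in annotations:
        for p in term.members:
            terms_of.setdefault(p, set()).add(term.term_id)
    universe = sorted(terms_of)
    if len(universe) < 2:
        raise ValueError("need at least 2 annotated proteins to build a gold standard")
    positives: set[Pair] = set()
    negatives: set[Pair] = set()
    for a, b in itertools.combinations(universe, 2):
        (positives if terms_of[a] & terms_of[b] else negatives).add((a, b))
    log.info("gold standard: %d positives, %d negatives over %d proteins",
             len(positives), len(negatives), len(universe))
    return GoldStandard(frozenset(positives), frozenset(negatives), frozenset(universe))


def precision_coverage_curve(
    net: AssocialogNetwork,
    gold: GoldStandard,
    proteome_size: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    cumulative: bool = True,
) -> list[PrecisionCoveragePoint]:
    """Precision as a function of coding-genome coverage.

    Network links are sorted by adjusted LLS descending (lexicographic
    pair tiebreak) and consumed in bins of ``bin_size``; a final partial
    bin is emitted. In the default cumulative mode each point uses every
    link down to the bin boundary; with ``cumulative=False`` precision is
    computed within each bin alone (coverage stays cumulative). Points
    with no gold-evaluable links carry ``precision=None``.
    """
    if len(net) == 0:
        raise ValueError("cannot benchmark an empty network")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if proteome_size < 1:
        raise ValueError("proteome_size must be >= 1")
    edges = sorted(net, key=lambda e: (-e.adjusted_lls, e.pair))

    points: list[PrecisionCoveragePoint] = []
    seen_nodes: set[str] = set()
    cum_pos = cum_eval = 0
    bin_pos = bin_eval = 0
    for i, e in enumerate(edges, start=1):
        seen_nodes.update(e.pair)
        label = gold.classify(e.query_a, e.query_b)
        if label is not None:
            cum_eval += 1
            bin_eval += 1
            if label:
                cum_pos += 1
                bin_pos += 1
        if i % bin_size == 0 or i == len(edges):
            pos, evaluable = (cum_pos, cum_eval) if cumulative else (bin_pos, bin_eval)
            if evaluable == 0:
                log.warning("no gold-evaluable links at %d links; precision undefined", i)
                precision = None
            else:
                precision = pos / evaluable
            points.append(
                PrecisionCoveragePoint(i, precision, len(seen_nodes) / proteome_size)
            )
            bin_pos = bin_eval = 0
    return points


def connectivity_scores(
    net: AssocialogNetwork,
    members: frozenset[str] | set[str],
    universe: Sequence[str],
) -> np.ndarray:
    """Guilt-by-association score per universe protein.

    The score of protein u is the sum of adjusted LLS over its network
    edges to pathway members, excluding any self contribution (membership
    of u itself adds nothing).
    """
    score = {u: 0.0 for u in universe}
    for e in net:
        if e.query_b in members and e.query_a in score:
            score[e.query_a] += e.adjusted_lls
        if e.query_a in members and e.query_b in score:
            score[e.query_b] += e.adjusted_lls
    return np.array([score[u] for u in universe])


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formula; ties contribute 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pathway_auc(
    net: AssocialogNetwork,
    pathway: AnnotationSet,
    universe: Iterable[str],
) -> PathwayAUC | None:
    """AUC for recovering one pathway's members by network connectivity.

    Pathways with fewer than five members present in the universe are
    skipped (returns None, with a log entry), matching the benchmark's
    minimum-size rule.
    """
    universe = sorted(set(universe))
    members = frozenset(pathway.members) & set(universe)
    if len(members) < MIN_PATHWAY_MEMBERS:
        log.info("pathway %s skipped: %d members in universe (< %d)",
                 pathway.term_id, len(members), MIN_PATHWAY_MEMBERS)
        return None
    if len(members) == len(universe):
        log.info("pathway %s skipped: no non-member proteins in universe", pathway.term_id)
        return None
    scores = connectivity_scores(net, members, universe)
    labels = np.array([u in members for u in universe])
    return PathwayAUC(pathway.term_id, len(members), mann_whitney_auc(scores, labels))


def summarize_aucs(aucs: Sequence[PathwayAUC]) -> AucSummary:
    """Median, quartiles, 1.5-IQR whiskers and outliers of pathway AUCs."""
    if not aucs:
        raise ValueError("cannot summarize an empty AUC list")
    values = np.sort(np.array([a.auc for a in aucs]))
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = tuple(float(v) for v in values[(values < lo_fence) | (values > hi_fence)])
    return AucSummary(
        n=len(values),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def plot_benchmark(
    curve: Sequence[PrecisionCoveragePoint],
    aucs: Sequence[PathwayAUC],
    path: str,
    label: str = "network",
) -> None:
    """Two-panel figure: precision vs coverage, and the AUC box plot."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    xs = [p.genome_coverage for p in curve if p.precision is not None]
    ys = [p.precision for p in curve if p.precision is not None]
    ax1.plot(xs, ys, "o-", ms=3, label=label)
    ax1.set_xlabel("coding genome coverage")
    ax1.set_ylabel("KEGG pathway precision")
    ax1.set_ylim(0, 1.02)
    ax1.legend()
    ax2.boxplot([[a.auc for a in aucs]], tick_labels=[label])
    ax2.axhline(0.5, ls="--", c="grey", lw=0.8)
    ax2.set_ylabel("pathway AUC")
    ax2.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
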