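"""Pairwise IBD totals, relationship degree and genetic families.

Degree follows the expected-sharing convention: degree-d relatives share
an expected ``2**-d`` of the diploid genome (parent-offspring and full
siblings are both degree 1), so the estimate from an observed total T is
``round(log2(D / T))`` with D the diploid map length (7,000 cM by
default).  On that arithmetic 280 cM is 4% of the genome and degree 5,
and a 30 cM total is degree 9 or closer.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx

from .genmap import DEFAULT_L_HAP
from .ibd.segments import IBDSegment

#: totals below this carry no degree information; only IBD-connected status
DEGREE_FLOOR_CM = 10.0
MAX_DEGREE = 12
CLOSE_CM = 30.0


@dataclass
class PairSummary:
    id1: str
    id2: str
    total_cM: float
    n_segments: int
    max_segment_cM: float


@dataclass
class DegreeEstimate:
    degree: int | None
    close_relative: bool
    genome_fraction_percent: float


@dataclass(frozen=True)
class Thresholds:
    close_cM: float = CLOSE_CM
    familial_expand_cM: float = 100.0
    network_prune_cM: float = 700.0
    diploid_total_cM: float = 2 * DEFAULT_L_HAP

    def __post_init__(self) -> None:
        if not 0 < self.close_cM < self.familial_expand_cM < self.network_prune_cM:
            raise ValueError("thresholds must be ordered close < expand < prune")


def summarize_pairs(segments: list[IBDSegment]) -> list[PairSummary]:
    """Condense segments to individual-pair totals.

    Lengths sum across chromosomes and all four haplotype pairings, so
    regions IBD on both pairings count twice and a parent-child pair
    totals the haploid map length on the diploid percent scale.
    """
    acc: dict[tuple, list[float]] = defaultdict(list)
    for s in segments:
        key = (s.id1, s.id2) if s.id1 < s.id2 else (s.id2, s.id1)
        acc[key].append(s.length_cM)
    return [PairSummary(a, b, float(sum(v)), len(v), float(max(v)))
            for (a, b), v in sorted(acc.items())]


def genome_fraction(total_cM: float, D: float = 2 * DEFAULT_L_HAP) -> float:
    """Percent of the diploid autosomal genome a total implies."""
    if total_cM < 0:
        raise ValueError("total_cM must be non-negative")
    return 100.0 * total_cM / D


def estimate_degree(total_cM: float, D: float = 2 * DEFAULT_L_HAP,
                    close_cM: float = CLOSE_CM) -> DegreeEstimate:
    """Nearest degree under E[T | d] = D * 2**-d, clamped to [1, 12].

    Half-integer log2 values round toward the smaller (closer) degree.
    Below the 10 cM floor no degree is assigned.
    """
    if total_cM < 0:
        raise ValueError("total_cM must be non-negative")
    frac = genome_fraction(total_cM, D)
    if total_cM < DEGREE_FLOOR_CM:
        return DegreeEstimate(None, total_cM >= close_cM, frac)
    x = math.log2(D / total_cM)
    degree = int(math.ceil(x - 0.5))        # ties -> smaller degree
    degree = min(max(degree, 1), MAX_DEGREE)
    return DegreeEstimate(degree, total_cM >= close_cM, frac)


def degree_label(total_cM: float, D: float = 2 * DEFAULT_L_HAP) -> str:
    """Human-readable degree, as a range when the estimate is ambiguous.

    When the continuous estimate log2(D/T) lies more than 0.25 from the
    nearest integer the label spans the two flanking degrees, mirroring
    the "2nd-3rd-degree relative" style of reporting.
    """
    est = estimate_degree(total_cM, D)
    if est.degree is None:
        return "IBD-connected"
    x = math.log2(D / total_cM)
    lo, hi = int(math.floor(x)), int(math.ceil(x))
    lo, hi = min(max(lo, 1), MAX_DEGREE), min(max(hi, 1), MAX_DEGREE)
    if lo != hi and abs(x - est.degree) > 0.25:
        return f"{lo}-{hi}"
    return str(est.degree)


def build_families(summaries: list[PairSummary], max_family_degree: int = 3,
                   D: float = 2 * DEFAULT_L_HAP,
                   all_ids: list[str] | None = None) -> dict:
    """Partition historical individuals into genetic families.

    Families are connected components of the graph whose edges are pairs
    with estimated degree <= ``max_family_degree``; everyone else is a
    singleton.  ``all_ids`` lists individuals with no IBD at all, so they
    are reported as unrelated too.  Edge degree labels (possibly ranges)
    are retained.
    """
    g = nx.Graph()
    edge_labels = {}
    ids = set(all_ids or ())
    for s in summaries:
        ids.update((s.id1, s.id2))
        est = estimate_degree(s.total_cM, D)
        if est.degree is not None and est.degree <= max_family_degree:
            g.add_edge(s.id1, s.id2, total_cM=s.total_cM, degree=est.degree)
            edge_labels[(s.id1, s.id2)] = degree_label(s.total_cM, D)
    families = sorted((sorted(c) for c in nx.connected_components(g)),
                      key=lambda c: c[0])
    singletons = sorted(ids - set(g.nodes))
    return {"families": families, "singletons": singletons,
            "edge_labels": edge_labels}
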