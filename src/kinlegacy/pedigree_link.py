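"""Attachment-point inference: where does an external relative connect?

Given a historical pedigree (genotyped members plus the un-genotyped
parents/ancestors that must have existed) and the IBD an external
present-day individual shares with each genotyped member, every candidate
attachment point is scored with a composite likelihood in the style of
pedigree-inference tools built on pairwise IBD summaries:

* a candidate is a pedigree node ``v`` plus a lineage degree ``g`` — the
  external descends from ``v`` through ``g`` meioses of an un-modeled
  lineage (or, for nodes with no recorded parents, through an un-modeled
  ancestor ``g`` meioses up);
* the path degree from the external to member ``m`` is then
  ``d = g + d(v, m)`` with ``a`` common ancestors read off the pedigree;
* expected segment count ``nu = a * (r*d + c) * 2**(1-d)`` (``r`` = map
  length in Morgans, ``c`` = chromosome count), segment lengths
  Exponential(mean ``100/d`` cM) truncated at the detection floor; the
  member's likelihood is Poisson in the observed count times the product
  of truncated-exponential densities, and members multiply (conditional
  independence).

Posterior = softmax of candidate log-likelihoods under a flat prior.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic.pedigree import PedigreeSpec
from .utils import derive_rng


@dataclass(frozen=True)
class Candidate:
    node: str
    g: int                  # lineage degree connecting external to node
    via: str                # 'down' (descends from node) or 'up'
    direction: str          # 'downward' | 'upward' (reporting tag)


@dataclass
class AttachmentPosterior:
    candidates: list[Candidate]
    log_liks: np.ndarray
    probs: np.ndarray
    unattachable: bool = False

    @property
    def map_candidate(self) -> Candidate | None:
        if self.unattachable and not len(self.probs):
            return None
        return self.candidates[int(np.argmax(self.probs))]


@dataclass
class HistoricalPedigree:
    ped: PedigreeSpec

    def __post_init__(self) -> None:
        self.ped.validate()

    @property
    def genotyped(self) -> list[str]:
        return self.ped.genotyped()

    def path_degree(self, v: str, m: str) -> tuple[int, int] | None:
        """Meiosis path degree and number of common ancestors (capped 2)."""
        if v == m:
            return 0, 1
        anc_v = self.ped.ancestors(v)
        anc_v[v] = 0
        anc_m = self.ped.ancestors(m)
        anc_m[m] = 0
        common = set(anc_v) & set(anc_m)
        if not common:
            return None
        dists = sorted(anc_v[c] + anc_m[c] for c in common)
        d = dists[0]
        a = min(2, sum(1 for x in dists if x == d))
        return d, a


def enumerate_candidates(hped: HistoricalPedigree, max_g: int = 8
                         ) -> list[Candidate]:
    """All attachment points: descendant lineages below every node (except
    those who died in childhood), and ancestor-side lineages above nodes
    whose parents are not in the pedigree."""
    ped = hped.ped
    genotyped = set(ped.genotyped())
    out: list[Candidate] = []
    for nid in sorted(ped.nodes):
        n = ped.nodes[nid]
        down_dir = "downward" if (
            nid in genotyped or any(a in genotyped for a in ped.ancestors(nid))
        ) else "upward"
        if not n.died_child:
            out.extend(Candidate(nid, g, "down", down_dir)
                       for g in range(1, max_g + 1))
        if n.mother is None and n.father is None:
            out.extend(Candidate(nid, g, "up", "upward")
                       for g in range(1, max_g + 1))
    return out


def attachment_loglik(observed: dict[str, list[float]], cand: Candidate,
                      hped: HistoricalPedigree, L_hap: float = 3500.0,
                      n_chrom: int = 22, min_cM: float = 0.0) -> float:
    """Composite log-likelihood of the observed per-member segment lists
    under one candidate attachment point."""
    r = L_hap / 100.0
    ll = 0.0
    for m, lengths in observed.items():
        pd_ = hped.path_degree(cand.node, m)
        if pd_ is None:
            if lengths:
                return -math.inf
            continue
        d0, a = pd_
        d = cand.g + d0
        if cand.via == "down" and d0 == 0:
            a = 1
        nu = a * (r * d + n_chrom) * 2.0 ** (1 - d)
        lam = nu * math.exp(-d * min_cM / 100.0)
        n_obs = len(lengths)
        ll += n_obs * math.log(lam) - lam - math.lgamma(n_obs + 1)
        rate = d / 100.0
        for x in lengths:
            ll += math.log(rate) - rate * max(x - min_cM, 0.0)
    return ll


def infer_attachment(observed: dict[str, list[float]],
                     hped: HistoricalPedigree, max_g: int = 8,
                     min_cM: float = 0.0, L_hap: float = 3500.0,
                     n_chrom: int = 22) -> AttachmentPosterior:
    """Posterior over attachment points under a flat candidate prior."""
    genotyped = set(hped.genotyped)
    if not genotyped & set(observed):
        raise ValueError("need observations for at least one genotyped member")
    cands = enumerate_candidates(hped, max_g)
    lls = np.array([attachment_loglik(observed, c, hped, L_hap, n_chrom, min_cM)
                    for c in cands])
    finite = np.isfinite(lls)
    if not finite.any():
        return AttachmentPosterior(cands, lls, np.zeros(len(cands)), True)
    x = np.where(finite, lls, -np.inf)
    x = x - x[finite].max()
    probs = np.exp(x)
    probs /= probs.sum()
    no_data = sum(len(v) for v in observed.values()) == 0
    return AttachmentPosterior(cands, lls, probs, unattachable=no_data)


def aggregate_attachments(posteriors: list[AttachmentPosterior]) -> pd.DataFrame:
    """Per-attachment-point share of MAP assignments and mean lineage
    degree — the per-point percentages and average lineage degrees of a
    many-externals summary."""
    rows = []
    for post in posteriors:
        c = post.map_candidate
        if c is None or post.unattachable:
            continue
        rows.append((c.node, c.via, c.direction, c.g))
    df = pd.DataFrame(rows, columns=["node", "via", "direction", "g"])
    if df.empty:
        return pd.DataFrame(columns=["node", "via", "pct_map", "mean_g",
                                     "direction"])
    out = df.groupby(["node", "via"]).agg(
        n=("g", "size"), mean_g=("g", "mean"),
        direction=("direction", "first")).reset_index()
    out["pct_map"] = 100.0 * out["n"] / len(df)
    return out.sort_values("pct_map", ascending=False).reset_index(drop=True)


@dataclass
class AssociationResult:
    observed: int
    n_positive: int
    n_total: int
    p_value: float
    n_reps: int


def ancestry_association_test(map_nodes: list[str], rule_positive: list[bool],
                              focal_nodes: set[str], n_reps: int = 10_000,
                              seed: int = 0) -> AssociationResult:
    """Permutation test: do rule-positive externals preferentially attach
    at the focal node(s)?

    The statistic is the number of rule-positive externals whose MAP
    attachment is in ``focal_nodes``; the null permutes the rule labels
    across externals; p = (b+1)/(R+1).
    """
    nodes = np.asarray(map_nodes)
    flags = np.asarray(rule_positive, dtype=bool)
    if len(nodes) != len(flags):
        raise ValueError("one rule evaluation per external required")
    at_focal = np.isin(nodes, sorted(focal_nodes))
    observed = int((flags & at_focal).sum())
    if flags.sum() == 0:
        warnings.warn("no rule-positive externals; association undefined",
                      RuntimeWarning)
        return AssociationResult(0, 0, len(flags), 1.0, n_reps)
    rng = derive_rng(seed, "ancestry-association")
    b = 0
    n_focal = int(at_focal.sum())
    n_pos = int(flags.sum())
    n = len(flags)
    # permuting labels = hypergeometric draw of positives among focal slots
    null = rng.hypergeometric(n_pos, n - n_pos, n_focal, size=n_reps) \
        if 0 < n_focal < n else np.full(n_reps, observed)
    b = int((null >= observed).sum())
    p = (b + 1) / (n_reps + 1)
    return AssociationResult(observed, n_pos, n, float(p), n_reps)
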