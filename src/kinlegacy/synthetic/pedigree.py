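"""Pedigree specification and gene dropping with exact IBD bookkeeping.

Founder haplotypes are labelled, and every meiosis recombines the parent's
two labelled haplotypes (crossover count Poisson in the chromosome's Morgan
length, positions uniform in cM, no interference).  Because descent labels
are carried along, the true IBD segments between any two pedigree members
are recoverable exactly — the ground truth every detector is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genmap import GeneticMap
from ..panel import HaplotypePanel
from ..utils import derive_rng


class PedigreeError(ValueError):
    """Raised for malformed pedigrees or missing founder data."""


@dataclass
class PedigreeNode:
    id: str
    sex: str = "U"                 # 'F', 'M' or 'U'
    generation: int = 0            # increases downward (founders lowest)
    founder: bool = False
    genotyped: bool = False
    mother: str | None = None
    father: str | None = None
    died_child: bool = False       # admits no descendant attachment points


@dataclass
class PedigreeSpec:
    nodes: dict[str, PedigreeNode] = field(default_factory=dict)
    founder_ancestry: dict[str, tuple] = field(default_factory=dict)

    def add(self, node: PedigreeNode) -> None:
        if node.id in self.nodes:
            raise PedigreeError(f"duplicate node id {node.id}")
        self.nodes[node.id] = node

    def validate(self) -> None:
        for n in self.nodes.values():
            if n.founder:
                if n.mother is not None or n.father is not None:
                    raise PedigreeError(f"founder {n.id} has parents")
            else:
                if n.mother is None or n.father is None:
                    raise PedigreeError(f"non-founder {n.id} needs two parents")
                for p in (n.mother, n.father):
                    if p not in self.nodes:
                        raise PedigreeError(f"unknown parent {p} of {n.id}")
                    if self.nodes[p].generation >= n.generation:
                        raise PedigreeError(
                            f"generation of {n.id} not below parent {p}")
        self.topological_order()  # raises on cycles

    def founders(self) -> list[str]:
        return [i for i, n in self.nodes.items() if n.founder]

    def genotyped(self) -> list[str]:
        return [i for i, n in self.nodes.items() if n.genotyped]

    def children_of(self, node_id: str) -> list[str]:
        return [i for i, n in self.nodes.items()
                if node_id in (n.mother, n.father)]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(i: str) -> None:
            if state.get(i) == 2:
                return
            if state.get(i) == 1:
                raise PedigreeError("pedigree contains a cycle")
            state[i] = 1
            n = self.nodes[i]
            for p in (n.mother, n.father):
                if p is not None:
                    visit(p)
            state[i] = 2
            order.append(i)

        for i in self.nodes:
            visit(i)
        return order

    def ancestors(self, node_id: str) -> dict[str, int]:
        """All ancestors with their minimal meiosis distance."""
        dist: dict[str, int] = {}
        frontier = [(node_id, 0)]
        while frontier:
            i, d = frontier.pop()
            n = self.nodes[i]
            for p in (n.mother, n.father):
                if p is not None and (p not in dist or dist[p] > d + 1):
                    dist[p] = d + 1
                    frontier.append((p, d + 1))
        return dist


# -- gene dropping -------------------------------------------------------

# a haplotype is, per chromosome, an ordered list of (start_cM, end_cM,
# founder-haplotype label) segments covering [chrom_start, chrom_end]
SegList = list[tuple[float, float, str]]


def _slice_segs(segs: SegList, lo: float, hi: float) -> SegList:
    return [(max(s, lo), min(e, hi), lab)
            for s, e, lab in segs if e > lo and s < hi]


def _meiosis(hapA: dict[str, SegList], hapB: dict[str, SegList],
             gmap: GeneticMap, rng: np.random.Generator) -> dict[str, SegList]:
    """One gamete: per chromosome, Poisson crossovers, uniform in cM."""
    gamete: dict[str, SegList] = {}
    for chrom, sl in gmap.chrom_slices().items():
        cm = gmap.sites["cM"].to_numpy()[sl]
        lo, hi = float(cm[0]), float(cm[-1])
        length = hi - lo
        n_cross = rng.poisson(length / 100.0)
        cuts = np.sort(rng.uniform(lo, hi, size=n_cross))
        bounds = np.concatenate([[lo], cuts, [hi]])
        cur = int(rng.integers(2))
        out: SegList = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b > a:
                src = hapA if cur == 0 else hapB
                out.extend(_slice_segs(src[chrom], a, b))
            cur ^= 1
        gamete[chrom] = out
    return gamete


@dataclass
class GeneDropResult:
    ped: PedigreeSpec
    gmap: GeneticMap
    haps: dict[str, tuple[dict[str, SegList], dict[str, SegList]]]
    founder_alleles: dict[str, np.ndarray]   # label -> allele vector

    # -- truth bookkeeping ----------------------------------------------

    def true_ibd(self, a: str, b: str) -> list[tuple]:
        """Maximal shared-descent segments between individuals a and b.

        Returns (chrom, start_cM, end_cM, hap_a, hap_b) tuples; contiguous
        shared stretches on the same haplotype pair are merged, matching
        what an IBD detector observes.
        """
        out = []
        for ha in (0, 1):
            for hb in (0, 1):
                for chrom in self.gmap.chroms:
                    merged = _shared(self.haps[a][ha][chrom],
                                     self.haps[b][hb][chrom])
                    out.extend((chrom, s, e, ha, hb) for s, e in merged)
        return out

    def true_ibd_total(self, a: str, b: str) -> float:
        """Total shared cM summed over all four haplotype pairings.

        Regions IBD on both pairings (IBD2) count twice, so a parent-child
        pair totals the full haploid map length and the scale matches the
        percent-of-diploid-genome arithmetic.
        """
        return float(sum(e - s for _, s, e, _, _ in self.true_ibd(a, b)))

    def true_ibd_table(self, ids: list[str] | None = None) -> pd.DataFrame:
        ids = ids or list(self.haps)
        rows = []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                for chrom, s, e, ha, hb in self.true_ibd(a, b):
                    rows.append((a, b, chrom, s, e))
        return pd.DataFrame(rows, columns=["id1", "id2", "chrom",
                                           "start_cM", "end_cM"])

    # -- materialization -------------------------------------------------

    def materialize(self, ids: list[str]) -> HaplotypePanel:
        """Turn labelled segments into concrete alleles for ``ids``."""
        site_cm = self.gmap.sites["cM"].to_numpy()
        slices = self.gmap.chrom_slices()
        H = np.empty((2 * len(ids), self.gmap.n_sites), dtype=np.uint8)
        for r, ind in enumerate(ids):
            for h in (0, 1):
                row = H[2 * r + h]
                for chrom, sl in slices.items():
                    cm = site_cm[sl]
                    hi = cm[-1]
                    for s, e, lab in self.haps[ind][h][chrom]:
                        i0 = np.searchsorted(cm, s, side="left")
                        i1 = len(cm) if e >= hi else np.searchsorted(cm, e, "left")
                        row[sl.start + i0:sl.start + i1] = \
                            self.founder_alleles[lab][sl.start + i0:sl.start + i1]
        sites = self.gmap.sites.copy()
        sites["ref"] = "A"
        sites["alt"] = "G"
        return HaplotypePanel(sites, H, list(ids))


def _shared(segsA: SegList, segsB: SegList) -> list[tuple[float, float]]:
    """Intersect two labelled segment lists; merge contiguous output."""
    raw = []
    i = j = 0
    while i < len(segsA) and j < len(segsB):
        sA, eA, lA = segsA[i]
        sB, eB, lB = segsB[j]
        s, e = max(sA, sB), min(eA, eB)
        if e > s and lA == lB:
            raw.append((s, e))
        if eA <= eB:
            i += 1
        else:
            j += 1
    merged: list[tuple[float, float]] = []
    for s, e in raw:
        if merged and abs(s - merged[-1][1]) < 1e-9:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def drop_through_pedigree(ped: PedigreeSpec,
                          founder_haps: dict[str, tuple[np.ndarray, np.ndarray]],
                          gmap: GeneticMap, seed: int = 0) -> GeneDropResult:
    """Transmit founder haplotypes down the pedigree.

    ``founder_haps`` maps each founder id to its two allele vectors over
    the map's sites.  Every founder must be present.
    """
    ped.validate()
    for f in ped.founders():
        if f not in founder_haps:
            raise PedigreeError(f"missing founder haplotypes for {f}")
    rng = derive_rng(seed, "genedrop")
    slices = gmap.chrom_slices()
    site_cm = gmap.sites["cM"].to_numpy()

    def whole(label: str) -> dict[str, SegList]:
        out: dict[str, SegList] = {}
        for chrom, sl in slices.items():
            cm = site_cm[sl]
            out[chrom] = [(float(cm[0]), float(cm[-1]), label)]
        return out

    haps: dict[str, tuple] = {}
    founder_alleles: dict[str, np.ndarray] = {}
    for i in ped.topological_order():
        n = ped.nodes[i]
        if n.founder:
            a0, a1 = founder_haps[i]
            founder_alleles[f"{i}|0"] = np.asarray(a0, dtype=np.uint8)
            founder_alleles[f"{i}|1"] = np.asarray(a1, dtype=np.uint8)
            haps[i] = (whole(f"{i}|0"), whole(f"{i}|1"))
        else:
            gm = _meiosis(*haps[n.mother], gmap, rng)
            gf = _meiosis(*haps[n.father], gmap, rng)
            haps[i] = (gm, gf)
    return GeneDropResult(ped, gmap, haps, founder_alleles)
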