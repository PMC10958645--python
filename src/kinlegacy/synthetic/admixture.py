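"""Admixed mosaic haplotypes with recorded true local-ancestry tracts.

An admixed haplotype is a Markov mosaic along the genetic map: ancestry
switch points arrive as a Poisson process with rate ``g`` per Morgan
(``g`` plays the role of generations since admixture), each tract's source
population is drawn from the mixture weights, and alleles over the tract
are either copied from a random donor haplotype of that population
(:func:`simulate_admixed`) or drawn site-wise from the population's
frequencies (:func:`simulate_admixed_fresh`).  The copying variant creates
real shared haplotypes with the donor panel; the frequency-level variant
produces the same ancestry structure with no identity-by-descent to any
other simulated individual, which is what a large outbred cohort looks
like at the scale of a study fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genmap import GeneticMap
from ..panel import HaplotypePanel
from ..utils import derive_rng
from .popmodel import PopulationModel, population_of


@dataclass(frozen=True)
class AncestryTract:
    chrom: str
    start_cM: float
    end_cM: float
    pop: str


def _tract_bounds(length_cM: float, g: float, rng: np.random.Generator) -> np.ndarray:
    """Switch positions (cM) of a rate g-per-Morgan Poisson process."""
    n = rng.poisson(length_cM * g / 100.0)
    return np.sort(rng.uniform(0.0, length_cM, size=n))


def _mosaic_labels(gmap: GeneticMap, weights: np.ndarray, pops: list[str],
                   g: float, rng: np.random.Generator
                   ) -> tuple[np.ndarray, list[AncestryTract]]:
    """Per-site population index plus the generating tract list."""
    pop_idx = np.empty(gmap.n_sites, dtype=np.int64)
    tracts: list[AncestryTract] = []
    for chrom, sl in gmap.chrom_slices().items():
        cm = gmap.sites["cM"].to_numpy()[sl]
        origin, length = cm[0], cm[-1] - cm[0]
        cuts = _tract_bounds(length, g, rng)
        bounds = np.concatenate([[0.0], cuts, [length]])
        ks = rng.choice(len(weights), size=len(bounds) - 1, p=weights)
        tracts.extend(
            AncestryTract(chrom, origin + lo, origin + hi, pops[k])
            for lo, hi, k in zip(bounds[:-1], bounds[1:], ks))
        # site -> tract by position; the final bound is inclusive
        which = np.searchsorted(cuts, cm - origin, side="right")
        pop_idx[sl] = ks[which]
    return pop_idx, tracts


def simulate_admixed(panel: HaplotypePanel, weights, g: float,
                     gmap: GeneticMap, seed: int = 0,
                     ) -> tuple[np.ndarray, list[AncestryTract]]:
    """One mosaic haplotype copied tract-wise from a donor panel.

    Donor populations are read off the panel's ``{pop}_{i}`` id convention.
    Returns the haplotype allele vector and its true tract labels.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if g < 1:
        raise ValueError("admixture generations g must be >= 1")
    rng = derive_rng(seed, "admix")
    pops = sorted({population_of(i) for i in panel.ids})
    donors = {p: [panel.hap_rows(i)[j] for i in panel.ids
                  if population_of(i) == p for j in (0, 1)]
              for p in pops}
    active = [p for k, p in enumerate(pops) if k < len(weights) and weights[k] > 0]
    for p in active:
        if not donors[p]:
            raise ValueError(f"no donor haplotypes for population {p}")
    if len(weights) != len(pops):
        raise ValueError("one weight per donor population required")
    pop_idx, tracts = _mosaic_labels(gmap, weights, pops, g, rng)
    hap = np.empty(gmap.n_sites, dtype=np.uint8)
    # re-draw the donor haplotype independently per tract
    site_cm = gmap.sites["cM"].to_numpy()
    chrom_sl = gmap.chrom_slices()
    for t in tracts:
        sl = chrom_sl[t.chrom]
        cm = site_cm[sl]
        mask = (cm >= t.start_cM) & (cm < t.end_cM)
        if t.end_cM >= cm[-1]:
            mask |= cm >= t.end_cM
        donor = donors[t.pop][rng.integers(len(donors[t.pop]))]
        idx = np.flatnonzero(mask) + sl.start
        hap[idx] = panel.haplotypes[donor, idx]
    return hap, tracts


def simulate_admixed_fresh(model: PopulationModel, weights, g: float,
                           gmap: GeneticMap, rng: np.random.Generator,
                           ) -> tuple[np.ndarray, list[AncestryTract]]:
    """One mosaic haplotype drawn site-wise from population frequencies.

    Same tract process as :func:`simulate_admixed`, but alleles are fresh
    Bernoulli draws, so the haplotype shares no descent with any donor.
    """
    weights = np.asarray(weights, dtype=float)
    model.validate_freqs()
    pop_idx, tracts = _mosaic_labels(gmap, weights, model.pop_labels, g, rng)
    f = model.freqs[pop_idx, np.arange(gmap.n_sites)]
    hap = (rng.random(gmap.n_sites) < f).astype(np.uint8)
    return hap, tracts


def tract_fraction(tracts: list[AncestryTract], pop: str) -> float:
    """Genome-wide fraction of tract length labelled ``pop``."""
    total = sum(t.end_cM - t.start_cM for t in tracts)
    part = sum(t.end_cM - t.start_cM for t in tracts if t.pop == pop)
    return part / total if total > 0 else 0.0
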