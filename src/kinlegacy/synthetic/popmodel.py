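"""Balding–Nichols population model and founder simulation.

K populations diverge from shared ancestral allele frequencies ``p`` by
drift ``F``: per-population frequencies are drawn
``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
``F p (1-p)`` — so ``F`` is the expected Fst between populations.  At
``F = 0`` the model collapses and every population shares ``p`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..genmap import GeneticMap
from ..panel import HaplotypePanel
from ..utils import derive_rng


class ModelError(ValueError):
    """Raised for invalid population models."""


@dataclass
class PopulationModel:
    """Per-population allele frequencies over a map's sites."""

    pop_labels: list[str]
    ancestral_p: np.ndarray            # (n_sites,), in open (0, 1)
    F: np.ndarray                      # (K,), in [0, 1)
    freqs: np.ndarray = field(default=None)  # (K, n_sites), filled on build

    def __post_init__(self) -> None:
        self.ancestral_p = np.asarray(self.ancestral_p, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.F) != len(self.pop_labels):
            raise ModelError("one F per population required")
        if np.any(self.ancestral_p <= 0) or np.any(self.ancestral_p >= 1):
            raise ModelError("ancestral frequencies must lie strictly in (0, 1)")
        if np.any(self.F < 0) or np.any(self.F >= 1):
            raise ModelError("drift F must lie in [0, 1)")

    @property
    def K(self) -> int:
        return len(self.pop_labels)

    @classmethod
    def simulate(cls, pop_labels: list[str], n_sites: int,
                 F: float | list[float] = 0.1, seed: int = 0,
                 p_range: tuple[float, float] = (0.2, 0.8)) -> "PopulationModel":
        """Draw ancestral frequencies uniformly and per-pop drifted ones.

        The default ancestral frequency range (0.2–0.8) keeps sites
        informative while avoiding near-fixed sites whose long identical
        runs would create chance haplotype matches between unrelated
        individuals.
        """
        rng = derive_rng(seed, "popmodel")
        F_arr = np.full(len(pop_labels), F, dtype=float) if np.isscalar(F) \
            else np.asarray(F, dtype=float)
        p = rng.uniform(*p_range, size=n_sites)
        model = cls(list(pop_labels), p, F_arr)
        freqs = np.empty((model.K, n_sites))
        for k in range(model.K):
            f = F_arr[k]
            if f == 0:
                freqs[k] = p
            else:
                a = p * (1 - f) / f
                b = (1 - p) * (1 - f) / f
                freqs[k] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)
        model.freqs = freqs
        return model

    def validate_freqs(self) -> None:
        if self.freqs is None:
            raise ModelError("population frequencies not simulated")
        if np.any(self.freqs < 0) or np.any(self.freqs > 1):
            raise ModelError("population frequency outside [0, 1]")


def simulate_founders(model: PopulationModel, gmap: GeneticMap,
                      n_per_pop: int, seed: int = 0) -> HaplotypePanel:
    """Draw ``2 * n_per_pop`` independent haplotypes per population.

    Alleles are Bernoulli(per-population frequency), independent across
    sites (founders are unrelated, so they carry no IBD by construction).
    Individuals are labelled ``{pop}_{i}``.
    """
    if n_per_pop < 1:
        raise ModelError("n_per_pop must be >= 1")
    model.validate_freqs()
    if gmap.n_sites != model.freqs.shape[1]:
        raise ModelError("model/map site count mismatch")
    rng = derive_rng(seed, "founders")
    ids: list[str] = []
    blocks = []
    for k, pop in enumerate(model.pop_labels):
        draws = rng.random((2 * n_per_pop, gmap.n_sites)) < model.freqs[k]
        blocks.append(draws.astype(np.uint8))
        ids.extend(f"{pop}_{i}" for i in range(n_per_pop))
    sites = gmap.sites.copy()
    sites["ref"] = "A"
    sites["alt"] = "G"
    return HaplotypePanel(sites, np.vstack(blocks), ids)


def population_of(ind_id: str) -> str:
    """Founder id convention ``{pop}_{i}`` -> population label."""
    return ind_id.rsplit("_", 1)[0]
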