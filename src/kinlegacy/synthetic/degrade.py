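"""Degradation channel emulating imputed low-coverage historical genomes.

Two independent error channels: per-haplotype allele flips at
``genotype_error_rate`` (standing in for residual imputation error) and
per-site masking at ``missing_rate`` (standing in for uncovered sites,
refilled downstream by the per-site major allele before matching).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..panel import MISSING, HaplotypePanel
from ..utils import derive_rng


@dataclass(frozen=True)
class DegradationParams:
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    pseudo_coverage: str = ""      # label only, e.g. "1.0x"

    def __post_init__(self) -> None:
        for r in (self.genotype_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("degradation rates must lie in [0, 1]")


def degrade(panel: HaplotypePanel, params: DegradationParams,
            seed: int = 0) -> HaplotypePanel:
    """Flip alleles and mask sites, deterministically under ``seed``."""
    rng = derive_rng(seed, "degrade")
    H = panel.haplotypes.copy()
    if params.genotype_error_rate > 0:
        flips = rng.random(H.shape) < params.genotype_error_rate
        flips &= H != MISSING
        H[flips] ^= 1
    if params.missing_rate > 0:
        # per-site masking hits both haplotypes of an individual at once,
        # as coverage dropout does
        mask = rng.random((panel.n_ind, panel.n_sites)) < params.missing_rate
        H[np.repeat(mask, 2, axis=0)] = MISSING
    return HaplotypePanel(panel.sites, H, list(panel.ids))
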