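"""Brute-force all-pairs maximal-run scan: the oracle PBWT is tested against.

Independent of the PBWT machinery: for every cross-individual haplotype
pair it locates maximal equal runs directly from the allele matrix.
Quadratic in haplotypes — usable only at test scale, by design.
"""

from __future__ import annotations

import numpy as np

from ..panel import HaplotypePanel
from .segments import IBDSegment


def brute_force_matches(panel: HaplotypePanel, min_cM: float,
                        min_sites: int = 2) -> list[IBDSegment]:
    """Maximal allele-identical intervals >= min_cM, by direct scan."""
    out: list[IBDSegment] = []
    H = panel.haplotypes
    bp_all = panel.sites["bp"].to_numpy()
    cm_all = panel.sites["cM"].to_numpy()
    n_haps = H.shape[0]
    for chrom, sl in panel.chrom_slices().items():
        cm = cm_all[sl]
        N = sl.stop - sl.start
        X = H[:, sl]
        for ri in range(n_haps):
            for rj in range(ri + 1, n_haps):
                if ri // 2 == rj // 2:
                    continue
                mism = np.flatnonzero(X[ri] != X[rj])
                starts = np.concatenate([[0], mism + 1])
                ends = np.concatenate([mism, [N]])
                for s, e in zip(starts, ends):
                    if e - s < max(min_sites, 2):
                        continue
                    span = float(cm[e - 1] - cm[s])
                    if span < min_cM - 1e-12:
                        continue
                    i1, h1 = panel.individual_of(ri), ri % 2
                    i2, h2 = panel.individual_of(rj), rj % 2
                    if i2 < i1:
                        i1, i2, h1, h2 = i2, i1, h2, h1
                    out.append(IBDSegment(
                        id1=i1, hap1=h1, id2=i2, hap2=h2, chrom=chrom,
                        start_cM=float(cm[s]), end_cM=float(cm[e - 1]),
                        length_cM=span, n_sites=int(e - s),
                        start_idx=sl.start + int(s), end_idx=sl.start + int(e),
                        start_bp=int(bp_all[sl.start + s]),
                        end_bp=int(bp_all[sl.start + e - 1])))
    return out


def match_key_set(segments: list[IBDSegment]) -> set:
    """Canonical (pair, haplotypes, site interval) keys for set comparison."""
    return {(s.id1, s.hap1, s.id2, s.hap2, s.chrom, s.start_idx, s.end_idx)
            for s in segments}
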