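"""Positional Burrows–Wheeler transform long-match detection.

Implements the exact-match PBWT core: a single left-to-right sweep
maintains the positional prefix array (haplotypes sorted by reversed
prefix) and divergence array (where each adjacent pair's match begins).
Every maximal match of at least ``L`` sites between any two haplotypes is
reported exactly once, at the site where it ends, in O(sites x haplotypes)
plus output.  The cM floor is translated per chromosome into the smallest
site count any qualifying window can have, and candidate matches are then
re-filtered on their actual genetic span.
"""

from __future__ import annotations

import numpy as np

from ..panel import MISSING, HaplotypePanel
from .segments import IBDSegment


class DetectionError(ValueError):
    pass


def _min_sites_for_span(cm: np.ndarray, min_cM: float) -> int | None:
    """Smallest number of sites a window spanning >= min_cM can contain.

    Returns None when no window of the chromosome reaches ``min_cM``.
    """
    t = np.searchsorted(cm, cm + min_cM - 1e-9, side="left")
    valid = t < len(cm)
    if not valid.any():
        return None
    counts = t[valid] - np.flatnonzero(valid) + 1
    return int(counts.min())


def _seg_max(d: np.ndarray, pos: np.ndarray, k: int) -> np.ndarray:
    """Divergence values for one allele group after the PBWT column update:
    element m is max(d[prev_pos+1 .. pos_m]); the group head starts a fresh
    (empty) match at k + 1."""
    if len(pos) == 0:
        return np.empty(0, dtype=d.dtype)
    starts = np.concatenate([[0], pos[:-1] + 1])
    out = np.maximum.reduceat(d[:pos[-1] + 1], starts)
    out[0] = k + 1
    return out


def _long_matches_chrom(X: np.ndarray, L_sites: int, emit) -> None:
    """Report maximal matches of >= L_sites sites on one chromosome.

    ``emit(row_i, row_j, start_site, end_site)`` receives 0-based half-open
    site intervals; row order within a pair is unspecified.
    """
    M, N = X.shape
    X = np.asfortranarray(X)     # column-contiguous: the sweep reads columns
    a = np.arange(M)
    d = np.zeros(M, dtype=np.int64)
    for k in range(N + 1):
        y = X[:, k][a] if k < N else None
        # blocks of rows whose adjacent divergences allow a >= L match
        breaks = d > k - L_sites
        breaks[0] = True
        bidx = np.flatnonzero(breaks)
        ends = np.concatenate([bidx[1:], [M]])
        big = np.flatnonzero(ends - bidx >= 2)
        for t in big:
            s, e = int(bidx[t]), int(ends[t])
            if k < N:
                ys = y[s:e]
                if ys.min() == ys.max():
                    continue        # no match terminates inside this block
            db = d[s:e]
            ab = a[s:e]
            for j in range(1, e - s):
                run_start = 0
                for i in range(j - 1, -1, -1):
                    run_start = max(run_start, int(db[i + 1]))
                    if k - run_start < L_sites:
                        break
                    if k == N or ys[i] != ys[j]:
                        emit(int(ab[i]), int(ab[j]), run_start, k)
        if k == N:
            break
        zpos = np.flatnonzero(y == 0)
        opos = np.flatnonzero(y != 0)
        a = np.concatenate([a[zpos], a[opos]])
        d = np.concatenate([_seg_max(d, zpos, k), _seg_max(d, opos, k)])


def pbwt_long_matches(panel: HaplotypePanel, min_cM: float,
                      min_sites: int = 2,
                      include_ids: set[str] | None = None) -> list[IBDSegment]:
    """All maximal allele-identical intervals >= ``min_cM`` between every
    haplotype pair of the panel.

    The panel must be complete (missing alleles filled) and its sites
    sorted by (chrom, bp).  With fewer than two haplotypes the result is
    empty.  When ``include_ids`` is given, only matches touching at least
    one of those individuals are reported (the one-vs-cohort search
    pattern) — the sweep itself still covers the whole panel.
    """
    if panel.haplotypes.shape[0] < 2:
        return []
    if (panel.haplotypes == MISSING).any():
        raise DetectionError("panel has missing alleles; fill before matching")
    for chrom, grp in panel.sites.groupby("chrom", sort=False):
        if np.any(np.diff(grp["bp"].to_numpy()) <= 0):
            raise DetectionError(f"sites not sorted by bp on {chrom}")
    out: list[IBDSegment] = []
    bp_all = panel.sites["bp"].to_numpy()
    cm_all = panel.sites["cM"].to_numpy()
    inc = None
    if include_ids is not None:
        inc = np.zeros(panel.haplotypes.shape[0], dtype=bool)
        for i, ind in enumerate(panel.ids):
            inc[2 * i] = inc[2 * i + 1] = ind in include_ids
    for chrom, sl in panel.chrom_slices().items():
        cm = cm_all[sl]
        L = _min_sites_for_span(cm, min_cM)
        if L is None:
            continue
        L = max(L, min_sites, 2)

        def emit(ri, rj, s, e, *, chrom=chrom, sl=sl, cm=cm):
            if inc is not None and not (inc[ri] or inc[rj]):
                return
            span = float(cm[e - 1] - cm[s])
            if span < min_cM - 1e-12 or e - s < min_sites:
                return
            i1, i2 = panel.individual_of(ri), panel.individual_of(rj)
            h1, h2 = ri % 2, rj % 2
            if i1 == i2:
                return      # within-individual runs are not IBD calls
            if i2 < i1:
                i1, i2, h1, h2 = i2, i1, h2, h1
            out.append(IBDSegment(
                id1=i1, hap1=h1, id2=i2, hap2=h2, chrom=chrom,
                start_cM=float(cm[s]), end_cM=float(cm[e - 1]),
                length_cM=span, n_sites=e - s,
                start_idx=sl.start + s, end_idx=sl.start + e,
                start_bp=int(bp_all[sl.start + s]),
                end_bp=int(bp_all[sl.start + e - 1])))

        _long_matches_chrom(panel.haplotypes[:, sl], L, emit)
    return out
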