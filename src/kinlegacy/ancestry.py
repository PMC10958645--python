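"""Stand-in global and local ancestry estimation plus cohort filters.

Global ancestry is a simplex-constrained least-squares fit of genotype
dosages on reference allele frequencies (the role an admixture-proportion model
plays upstream); local ancestry assigns each ~1 cM haplotype window to the
reference population with the highest allele log-likelihood (the role of
a production local-ancestry classifier).  Both are deliberately simple,
deterministic estimators whose outputs drive the cohort filters and
network coloring.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

#: cohort filter cutoffs (fractions)
SSA_AFRICAN_MIN = 0.95
EUR_EUROPEAN_MIN = 0.99
SSA_US_FILTER_MIN = 0.05
EUR_US_FILTER_MIN = 0.99

_FREQ_EPS = 1e-3


@dataclass
class AncestryProfile:
    fractions: dict[str, float]              # sums to 1
    windows: pd.DataFrame | None = None      # chrom, start_cM, end_cM, hap, label

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("ancestry fractions must sum to 1")


def _simplex_lstsq(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize ||A w - y||^2 subject to w >= 0, sum(w) = 1.

    Solved exactly by enumerating active sets (faces of the simplex); K is
    small so this is cheap and fully deterministic.
    """
    K = A.shape[1]
    AtA = A.T @ A
    Aty = A.T @ y
    best_w, best_obj = None, np.inf
    for r in range(1, K + 1):
        for face in itertools.combinations(range(K), r):
            idx = list(face)
            # equality-constrained LS on the face via KKT system
            Q = AtA[np.ix_(idx, idx)]
            kkt = np.zeros((r + 1, r + 1))
            kkt[:r, :r] = 2 * Q
            kkt[:r, r] = 1.0
            kkt[r, :r] = 1.0
            rhs = np.concatenate([2 * Aty[idx], [1.0]])
            try:
                sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            except np.linalg.LinAlgError:
                continue
            w_face = sol[:r]
            if np.any(w_face < -1e-9):
                continue
            w = np.zeros(K)
            w[idx] = np.clip(w_face, 0.0, None)
            if w.sum() <= 0:
                continue
            w /= w.sum()
            obj = float(w @ AtA @ w - 2 * Aty @ w)
            if obj < best_obj - 1e-12:
                best_obj, best_w = obj, w
    return best_w


def global_ancestry(dosage: np.ndarray, reference_freqs: np.ndarray,
                    pop_labels: list[str]) -> dict[str, float]:
    """Per-population fractions from diploid dosages (0/1/2).

    Fits dosage/2 as a convex combination of reference frequencies.
    Nearly identical reference populations trigger a degenerate-reference
    warning; the split is then arbitrary but deterministic.
    """
    if reference_freqs.shape[0] < 2:
        raise ValueError("need at least two reference populations")
    A = reference_freqs.T                       # sites x K
    corr = np.corrcoef(reference_freqs)
    off = corr[np.triu_indices_from(corr, k=1)]
    if np.any(off > 0.999):
        warnings.warn("reference populations are nearly identical; "
                      "ancestry split is arbitrary", RuntimeWarning)
    valid = dosage >= 0
    w = _simplex_lstsq(A[valid], dosage[valid] / 2.0)
    return dict(zip(pop_labels, (float(x) for x in w)))


def global_ancestry_panel(panel: HaplotypePanel, reference_freqs: np.ndarray,
                          pop_labels: list[str]) -> pd.DataFrame:
    """Vectorized global ancestry for every individual of a panel."""
    H = panel.haplotypes
    miss = H == MISSING
    dos = np.where(miss, 0, H).astype(np.float64)
    dosage = dos[0::2] + dos[1::2]
    n_missing = (miss[0::2] | miss[1::2]).sum(axis=1)
    rows = []
    for i in range(panel.n_ind):
        d = dosage[i].copy()
        if n_missing[i]:
            d[(miss[2 * i] | miss[2 * i + 1])] = -1.0
        rows.append(global_ancestry(d, reference_freqs, pop_labels))
    out = pd.DataFrame(rows)
    out.insert(0, "participant_id", panel.ids)
    return out


def local_ancestry(hap: np.ndarray, sites: pd.DataFrame,
                   reference_freqs: np.ndarray, pop_labels: list[str],
                   window_cM: float = 1.0, margin: float = 2.0,
                   min_sites: int = 10) -> pd.DataFrame:
    """Window-wise haplotype assignment by allele log-likelihood.

    Windows tile each chromosome in ``window_cM`` steps; a window is
    labelled with the argmax population unless the log-likelihood margin
    over the runner-up is below ``margin`` (then "unassigned"), or the
    window has fewer than ``min_sites`` sites.
    """
    f = np.clip(reference_freqs, _FREQ_EPS, 1 - _FREQ_EPS)
    ll_site = np.where(hap[None, :] == 1, np.log(f), np.log1p(-f))
    rows = []
    chrom_col = sites["chrom"].to_numpy()
    cm_col = sites["cM"].to_numpy()
    for chrom in dict.fromkeys(sites["chrom"]):
        in_chrom = np.flatnonzero(chrom_col == chrom)
        cm = cm_col[in_chrom]
        lo, hi = cm[0], cm[-1]
        edges = np.arange(lo, hi + window_cM, window_cM)
        for a, b in zip(edges[:-1], edges[1:]):
            mask = (cm >= a) & (cm < b)
            idx = in_chrom[mask]
            if len(idx) < min_sites:
                label = "unassigned"
            else:
                ll = ll_site[:, idx].sum(axis=1)
                order = np.argsort(ll)[::-1]
                if ll[order[0]] - ll[order[1]] < margin:
                    label = "unassigned"
                else:
                    label = pop_labels[order[0]]
            rows.append((chrom, float(a), float(min(b, hi)), label))
    return pd.DataFrame(rows, columns=["chrom", "start_cM", "end_cM", "label"])


def windows_to_fractions(windows: pd.DataFrame, pop_labels: list[str]
                         ) -> dict[str, float]:
    """Convert window labels to genome fractions; unassigned windows are
    excluded from the denominator."""
    w = windows[windows["label"] != "unassigned"]
    total = (w["end_cM"] - w["start_cM"]).sum()
    out = {}
    for p in pop_labels:
        part = w.loc[w["label"] == p, "end_cM"].sum() - \
            w.loc[w["label"] == p, "start_cM"].sum()
        out[p] = float(part / total) if total > 0 else 0.0
    return out


def apply_cohort_filters(metadata: pd.DataFrame,
                         profiles: pd.DataFrame,
                         ssa_pop: str = "AFR",
                         eur_pop: str = "EUR") -> pd.DataFrame:
    """Attach boolean cohort flags to participant metadata.

    Cohort definitions: African = >=95% Sub-Saharan African ancestry and
    self or all four grandparents born in Africa; European = >=99%
    European ancestry and self or all four grandparents born in Europe;
    US = all four grandparents born in the US, or born in the US with
    grandparent birth information unavailable or split across countries.
    Participants without an ancestry profile are excluded from the
    ancestry-filtered cohorts (a count is recorded in ``attrs``).
    """
    df = metadata.merge(profiles, on="participant_id", how="left")
    has_prof = df[ssa_pop].notna()
    ssa = df[ssa_pop].fillna(0.0)
    eur = df[eur_pop].fillna(0.0)
    born = df["born_region"].astype(str)
    gp = df["gp_born_region"].astype(str)

    df["us_cohort"] = (gp == "US") | ((born == "US") & gp.isin(["unknown", "multiple"]))
    df["african_cohort"] = has_prof & (ssa >= SSA_AFRICAN_MIN) & \
        ((born == "Africa") | (gp == "Africa"))
    df["european_cohort"] = has_prof & (eur >= EUR_EUROPEAN_MIN) & \
        ((born == "Europe") | (gp == "Europe"))
    df["us_ge5_ssa"] = df["us_cohort"] & has_prof & (ssa >= SSA_US_FILTER_MIN)
    df["us_ge99_eur"] = df["us_cohort"] & has_prof & (eur >= EUR_US_FILTER_MIN)
    df.attrs["n_missing_profile"] = int((~has_prof).sum())
    return df
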