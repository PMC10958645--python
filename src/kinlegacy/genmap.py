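"""Genetic maps: the ordered (chrom, bp, cM) site scaffold all analyses share.

A :class:`GeneticMap` carries one ordered site list per autosome, with both a
physical (bp) and a genetic (cM) coordinate per site.  The synthetic genome
defaults to 22 autosomes whose genetic lengths are scaled human autosome
lengths summing to ``L_hap`` = 3,500 cM, so that the diploid total
``D = 2 * L_hap = 7,000`` cM puts relationship-degree arithmetic on the human
scale (280 cM of sharing is 4% of the diploid autosomal genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default haploid autosomal map length (cM)
DEFAULT_L_HAP = 3500.0

#: synthetic bp scale: 1 cM per 10 kb
BP_PER_CM = 10_000

# approximate human autosome genetic lengths (cM), used as relative weights
_HUMAN_AUTOSOME_CM = np.array(
    [286, 269, 223, 214, 204, 192, 187, 168, 166, 181, 158,
     175, 126, 120, 142, 134, 129, 118, 108, 108, 63, 75],
    dtype=float,
)


class MapError(ValueError):
    """Raised for malformed genetic maps."""


@dataclass
class GeneticMap:
    """Ordered mapped sites for a set of chromosomes.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``bp`` (int, >= 0) and
        ``cM`` (float, >= 0), sorted by (chrom, bp), cM non-decreasing in
        bp within each chromosome.
    """

    sites: pd.DataFrame
    _chrom_order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"chrom", "bp", "cM"}
        if not required.issubset(self.sites.columns):
            raise MapError(f"map needs columns {sorted(required)}")
        self.sites = self.sites.reset_index(drop=True)
        self._chrom_order = list(dict.fromkeys(self.sites["chrom"]))
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            cm = grp["cM"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                raise MapError(f"bp not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise MapError(f"cM decreasing on {chrom}")
            if bp[0] < 0 or cm[0] < 0:
                raise MapError(f"negative coordinates on {chrom}")

    # -- basic accessors -------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_order)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chrom_slices(self) -> dict[str, slice]:
        """Map chromosome id -> slice of row positions in ``sites``."""
        out: dict[str, slice] = {}
        start = 0
        chrom_col = self.sites["chrom"].to_numpy()
        for chrom in self._chrom_order:
            n = int((chrom_col == chrom).sum())
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def chrom_length_cM(self, chrom: str) -> float:
        grp = self.sites.loc[self.sites["chrom"] == chrom, "cM"]
        return float(grp.iloc[-1] - grp.iloc[0])

    @property
    def haploid_total_cM(self) -> float:
        """Sum of per-chromosome genetic lengths (last - first cM)."""
        return float(sum(self.chrom_length_cM(c) for c in self._chrom_order))

    @property
    def diploid_total_cM(self) -> float:
        return 2.0 * self.haploid_total_cM

    # -- construction ----------------------------------------------------

    @classmethod
    def default(cls, n_sites: int = 20_000, L_hap: float = DEFAULT_L_HAP,
                n_chrom: int = 22) -> "GeneticMap":
        """Uniform-recombination synthetic map: 1 cM per 10 kb.

        ``n_sites`` sites are spread over ``n_chrom`` chromosomes in
        proportion to scaled human autosome lengths (total ``L_hap`` cM),
        evenly spaced in cM within each chromosome.
        """
        if n_chrom < 1 or n_sites < 2 * n_chrom:
            raise MapError("need >=2 sites per chromosome")
        weights = _HUMAN_AUTOSOME_CM[:n_chrom]
        if n_chrom > len(_HUMAN_AUTOSOME_CM):
            weights = np.ones(n_chrom)
        lengths = weights / weights.sum() * L_hap
        counts = np.maximum(2, np.round(weights / weights.sum() * n_sites)).astype(int)
        frames = []
        for i in range(n_chrom):
            cm = np.linspace(0.0, lengths[i], counts[i])
            bp = np.round(cm * BP_PER_CM).astype(np.int64)
            if np.any(np.diff(bp) <= 0):
                # degenerate spacing (< 1 bp between sites): keep order
                bp = bp + np.arange(len(bp), dtype=np.int64)
            frames.append(pd.DataFrame({
                "chrom": f"chr{i + 1}", "bp": bp, "cM": cm,
            }))
        # linspace endpoints collide in bp only if spacing < 1/BP_PER_CM cM;
        # enforce strict bp increase defensively
        sites = pd.concat(frames, ignore_index=True)
        return cls(sites)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df[["chrom", "bp", "cM"]])

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    # -- interpolation ---------------------------------------------------

    def interp_cM(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Linearly interpolate genetic position for physical positions."""
        grp = self.sites[self.sites["chrom"] == chrom]
        return np.interp(np.asarray(bp, dtype=float),
                         grp["bp"].to_numpy(dtype=float),
                         grp["cM"].to_numpy())
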