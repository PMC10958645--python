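"""IBD segment records and match parameters."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class IBDSegment:
    """A maximal shared haplotype interval between two individuals.

    ``start_idx``/``end_idx`` are 0-based half-open site row positions in
    the panel the segment was called on; genetic coordinates are the map
    values at the first and last matching site, so
    ``length_cM = end_cM - start_cM``.
    """

    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start_cM: float
    end_cM: float
    length_cM: float
    n_sites: int
    start_idx: int = -1
    end_idx: int = -1
    start_bp: int = -1
    end_bp: int = -1

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise ValueError("self-IBD segment")
        if self.end_cM <= self.start_cM:
            raise ValueError("segment end must exceed start")

    def pair_key(self) -> tuple:
        return (self.id1, self.hap1, self.id2, self.hap2, self.chrom)


@dataclass(frozen=True)
class MatchParams:
    """Detection thresholds.

    ``min_cM`` is the reporting floor; segments are called down to
    ``min_cM / 2`` before error-tolerant stitching so that a single allele
    flip inside a long true segment does not lose it, then re-filtered at
    ``min_cM`` after stitching.  ``stitch_gap_cM`` is the largest genetic
    gap bridged when merging same-pair fragments.
    """

    min_cM: float = 7.0
    stitch_gap_cM: float = 1.0
    min_sites: int = 16

    def __post_init__(self) -> None:
        if self.min_cM <= 0 or self.stitch_gap_cM <= 0 or self.min_sites <= 0:
            raise ValueError("match parameters must be positive")


def segments_to_frame(segments: list[IBDSegment]) -> pd.DataFrame:
    cols = ["id1", "hap1", "id2", "hap2", "chrom", "start_bp", "end_bp",
            "start_cM", "end_cM", "length_cM", "n_sites"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in segments],
                        columns=cols)
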