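"""Geographic aggregation with privacy masking, and randomization tests.

The geographic summaries follow the privacy protocol of large-cohort IBD
maps: coordinates rounded to the nearest integer, participants 80%
downsampled, cells with fewer than 25 retained participants masked
entirely, and any remaining count of 1-4 suppressed so that no reported
individual is distinguishable from fewer than four others.

The enrichment test asks whether a focal subset of a cohort carries more
IBD connections (or close relatives) than identically sized random
subsets: the null redraws |focal| participants without replacement from
the reference cohort, and the Monte-Carlo p-value uses the add-one
estimator (b+1)/(R+1).  The exact hypergeometric tail is returned
alongside as an analytic check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .utils import derive_rng

MIN_CELL = 25
DOWNSAMPLE = 0.8
K_ANON = 5


@dataclass
class GeoCell:
    lat: int
    lon: int
    n_participants: int
    n_after_downsample: int
    n_connected: int | None
    n_close: int | None
    masked: bool

    @property
    def proportion_connected(self) -> float | None:
        if self.masked or self.n_connected is None:
            return None
        return self.n_connected / self.n_after_downsample


def connection_table(metadata: pd.DataFrame, pair_summaries,
                     historical_ids: set, close_cM: float = 30.0
                     ) -> pd.DataFrame:
    """Per-participant connection flags from pair summaries.

    ``connected`` marks sharing >= 1 IBD segment with any historical
    individual; ``close`` marks a total of >= ``close_cM`` with a single
    historical individual; ``total_cM`` is the best single-historical
    total and ``best_match`` that individual's id.
    """
    best: dict[str, tuple[float, str]] = {}
    for s in pair_summaries:
        for me, other in ((s.id1, s.id2), (s.id2, s.id1)):
            if other in historical_ids and me not in historical_ids:
                if me not in best or s.total_cM > best[me][0]:
                    best[me] = (s.total_cM, other)
    df = metadata[["participant_id"]].copy()
    df["connected"] = df["participant_id"].isin(best)
    df["total_cM"] = df["participant_id"].map(
        lambda p: best.get(p, (0.0, ""))[0])
    df["close"] = df["total_cM"] >= close_cM
    df["best_match"] = df["participant_id"].map(
        lambda p: best.get(p, (0.0, ""))[1])
    return df


def geo_aggregate(metadata: pd.DataFrame, connections: pd.DataFrame,
                  downsample: float = DOWNSAMPLE, min_count: int = MIN_CELL,
                  seed: int = 0) -> list[GeoCell]:
    """Privacy-preserving per-cell counts of connected/close participants.

    Retention is an independent Bernoulli(``downsample``) draw per
    participant; cells below ``min_count`` retained participants are
    masked, and any surviving count in 1..K_ANON-1 is suppressed (None).
    """
    rng = derive_rng(seed, "geo-downsample")
    df = metadata.merge(connections, on="participant_id")
    df = df.dropna(subset=["lat", "lon"])
    df["cell_lat"] = np.round(df["lat"]).astype(int)
    df["cell_lon"] = np.round(df["lon"]).astype(int)
    df["retained"] = rng.random(len(df)) < downsample
    cells = []
    for (lat, lon), grp in df.groupby(["cell_lat", "cell_lon"]):
        kept = grp[grp["retained"]]
        n_keep = len(kept)
        masked = n_keep < min_count
        if masked:
            n_conn = n_close = None
        else:
            n_conn = int(kept["connected"].sum())
            n_close = int(kept["close"].sum())
            if 1 <= n_conn < K_ANON:
                n_conn = None
            if n_close is not None and 1 <= n_close < K_ANON:
                n_close = None
        cells.append(GeoCell(int(lat), int(lon), len(grp), n_keep,
                             n_conn, n_close, masked))
    return cells


def geo_cells_frame(cells: list[GeoCell]) -> pd.DataFrame:
    rows = [{"lat": c.lat, "lon": c.lon, "n_participants": c.n_participants,
             "n_after_downsample": c.n_after_downsample,
             "n_connected": c.n_connected, "n_close": c.n_close,
             "masked": c.masked} for c in cells]
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    observed: int
    n_focal: int
    n_reference: int
    n_flagged_reference: int
    p_mc: float
    p_exact: float
    null_mean: float
    null_sd: float
    n_reps: int
    seed: int
    statistic: str


def randomization_enrichment(focal_ids, reference_ids,
                             connections: pd.DataFrame,
                             n_reps: int = 1000, seed: int = 0,
                             statistic: str = "connected") -> EnrichmentResult:
    """Is the focal subset enriched for the chosen flag vs random subsets?

    ``focal_ids`` must be a subset of ``reference_ids``.  The null draws
    ``n_reps`` samples of size |focal| without replacement from the
    reference; p_mc = (1 + #{null >= observed}) / (n_reps + 1).  The exact
    hypergeometric upper tail P(X >= observed) is computed alongside.
    """
    if statistic not in ("connected", "close"):
        raise ValueError("statistic must be 'connected' or 'close'")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    focal = set(focal_ids)
    reference = list(dict.fromkeys(reference_ids))
    if not focal <= set(reference):
        raise ValueError("focal ids must be a subset of the reference")
    if len(focal) > len(reference):
        raise ValueError("focal larger than reference")
    flag = connections.set_index("participant_id")[statistic]
    flags = flag.reindex(reference).fillna(False).to_numpy(dtype=bool)
    observed = int(flag.reindex(sorted(focal)).fillna(False).sum())
    n, N, K = len(focal), len(reference), int(flags.sum())
    rng = derive_rng(seed, "enrichment", statistic)
    null = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        draw = rng.choice(N, size=n, replace=False)
        null[r] = flags[draw].sum()
    p_mc = (1 + int((null >= observed).sum())) / (n_reps + 1)
    p_exact = float(hypergeom.sf(observed - 1, N, K, n))
    return EnrichmentResult(observed, n, N, K, p_mc, p_exact,
                            float(null.mean()), float(null.std(ddof=1)) if n_reps > 1 else 0.0,
                            n_reps, seed, statistic)
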