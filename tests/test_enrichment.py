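"""Randomization-test calibration and geographic privacy masking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from kinlegacy.enrichment import (geo_aggregate, geo_cells_frame,
                                  randomization_enrichment)


def conn_frame(ids, connected, close=None):
    close = close if close is not None else [False] * len(ids)
    return pd.DataFrame({"participant_id": ids, "connected": connected,
                         "close": close,
                         "total_cM": [30.0 if c else 0.0 for c in close]})


class TestRandomization:
    def test_zero_observed_gives_p_one(self):
        ids = [f"p{i}" for i in range(20)]
        conn = conn_frame(ids, [i >= 10 for i in range(20)])
        res = randomization_enrichment(ids[:5], ids, conn, n_reps=200, seed=1)
        assert res.observed == 0
        assert res.p_mc == 1.0

    def test_exact_tail_small_enumeration(self):
        """Focal = 5 all flagged out of 10 with 5 flagged: the exact tail is
        C(5,5)/C(10,5) = 1/252."""
        ids = [f"p{i}" for i in range(10)]
        conn = conn_frame(ids, [i < 5 for i in range(10)])
        res = randomization_enrichment(ids[:5], ids, conn, n_reps=4000, seed=2)
        assert res.observed == 5
        assert res.p_exact == pytest.approx(1 / 252, rel=1e-9)
        se = math.sqrt(res.p_exact * (1 - res.p_exact) / res.n_reps)
        assert abs(res.p_mc - res.p_exact) < 3 * se + 2 / res.n_reps

    def test_enriched_focal_is_significant(self):
        """Focal connection rate 3x the reference rate -> tiny p."""
        rng = np.random.default_rng(3)
        n_ref, n_focal = 2000, 150
        ids = [f"p{i}" for i in range(n_ref)]
        flags = rng.random(n_ref) < 0.05
        flags[:n_focal] = rng.random(n_focal) < 0.15
        conn = conn_frame(ids, list(flags), list(flags))
        res = randomization_enrichment(ids[:n_focal], ids, conn,
                                       n_reps=10_000, seed=3,
                                       statistic="close")
        assert res.p_mc <= 0.001

    def test_focal_not_subset_rejected(self):
        ids = [f"p{i}" for i in range(10)]
        conn = conn_frame(ids, [True] * 10)
        with pytest.raises(ValueError):
            randomization_enrichment(["zz"], ids, conn, n_reps=10)

    def test_mc_matches_hypergeometric_many_configs(self):
        """Monte-Carlo p agrees with the exact tail within 3 MC standard
        errors across random configurations."""
        rng = np.random.default_rng(11)
        for trial in range(25):
            N = int(rng.integers(40, 300))
            K = int(rng.integers(1, N))
            n = int(rng.integers(5, N))
            ids = [f"p{i}" for i in range(N)]
            flags = np.zeros(N, dtype=bool)
            flags[rng.choice(N, K, replace=False)] = True
            focal = [ids[i] for i in rng.choice(N, n, replace=False)]
            conn = conn_frame(ids, list(flags))
            res = randomization_enrichment(focal, ids, conn, n_reps=400,
                                           seed=trial)
            se = math.sqrt(max(res.p_exact * (1 - res.p_exact), 1e-12)
                           / res.n_reps)
            assert abs(res.p_mc - res.p_exact) <= 3 * se + 2 / res.n_reps

    def test_type_one_error_calibrated(self):
        """With focal drawn at random, rejection at alpha = 0.05 stays in
        the 95% binomial interval over repeated null draws."""
        rng = np.random.default_rng(21)
        N, K, n = 800, 240, 80
        ids = [f"p{i}" for i in range(N)]
        flags = np.zeros(N, dtype=bool)
        flags[:K] = True
        conn = conn_frame(ids, list(flags))
        reps = 400
        rejections = 0
        for t in range(reps):
            focal = [ids[i] for i in rng.choice(N, n, replace=False)]
            obs = sum(flags[ids.index(f)] for f in focal)
            # exact tail of the correctly specified null
            p = float(hypergeom.sf(obs - 1, N, K, n))
            rejections += p <= 0.05
        half = 1.96 * math.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) <= half + 0.01

    def test_p_monotone_in_observed(self):
        ids = [f"p{i}" for i in range(100)]
        flags = [i < 40 for i in range(100)]
        conn = conn_frame(ids, flags)
        focal_low = [ids[i] for i in range(40, 60)]      # 0 flagged
        focal_high = ids[:20]                            # all flagged
        lo = randomization_enrichment(focal_low, ids, conn, 500, 5)
        hi = randomization_enrichment(focal_high, ids, conn, 500, 5)
        assert hi.observed > lo.observed
        assert hi.p_mc < lo.p_mc
        for r in (lo, hi):
            assert 0 < r.p_mc <= 1


class TestGeoAggregate:
    @staticmethod
    def _meta(counts):
        rows = []
        k = 0
        for (lat, lon), n in counts.items():
            for _ in range(n):
                rows.append({"participant_id": f"p{k}", "lat": lat + 0.2,
                             "lon": lon - 0.3})
                k += 1
        return pd.DataFrame(rows)

    def test_small_cells_masked(self):
        meta = self._meta({(39, -77): 30, (45, -110): 10})
        conn = conn_frame(list(meta["participant_id"]),
                          [False] * len(meta))
        cells = geo_aggregate(meta, conn, downsample=1.0, min_count=25, seed=0)
        by = {(c.lat, c.lon): c for c in cells}
        assert not by[(39, -77)].masked
        assert by[(45, -110)].masked
        assert by[(45, -110)].n_connected is None

    def test_boundary_24_retained_masked(self):
        meta = self._meta({(10, 10): 24})
        conn = conn_frame(list(meta["participant_id"]), [False] * 24)
        cells = geo_aggregate(meta, conn, downsample=1.0, min_count=25, seed=0)
        assert cells[0].masked

    def test_zero_connected_proportion_zero(self):
        meta = self._meta({(0, 0): 100})
        conn = conn_frame(list(meta["participant_id"]), [False] * 100)
        cells = geo_aggregate(meta, conn, downsample=1.0, seed=0)
        assert cells[0].proportion_connected == 0.0

    def test_downsample_within_binomial_bounds(self):
        meta = self._meta({(5, 5): 1000})
        conn = conn_frame(list(meta["participant_id"]), [False] * 1000)
        cells = geo_aggregate(meta, conn, downsample=0.8, seed=4)
        sd = math.sqrt(1000 * 0.8 * 0.2)
        assert abs(cells[0].n_after_downsample - 800) < 3 * sd

    def test_small_counts_suppressed_k_anonymity(self):
        meta = self._meta({(1, 1): 60})
        ids = list(meta["participant_id"])
        connected = [i < 3 for i in range(60)]          # 1-4 connected
        conn = conn_frame(ids, connected)
        cells = geo_aggregate(meta, conn, downsample=1.0, seed=0)
        assert cells[0].n_connected is None             # suppressed
        assert not cells[0].masked

    def test_no_emitted_cell_violates_privacy_rules(self):
        rng = np.random.default_rng(9)
        rows = []
        for k in range(2000):
            rows.append({"participant_id": f"p{k}",
                         "lat": float(rng.integers(30, 34)) + rng.uniform(-.4, .4),
                         "lon": float(rng.integers(-90, -86)) + rng.uniform(-.4, .4)})
        meta = pd.DataFrame(rows)
        conn = conn_frame(list(meta["participant_id"]),
                          list(rng.random(2000) < 0.03),
                          list(rng.random(2000) < 0.01))
        cells = geo_aggregate(meta, conn, seed=2)
        frame = geo_cells_frame(cells)
        visible = frame[~frame["masked"]]
        assert (visible["n_after_downsample"] >= 25).all()
        for col in ("n_connected", "n_close"):
            vals = visible[col].dropna()
            assert not ((vals >= 1) & (vals <= 4)).any()
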