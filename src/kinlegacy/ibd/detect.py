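"""Error-tolerant IBD detection: PBWT calls plus gap stitching.

Degraded panels break long true segments into exact-match fragments.
Detection therefore calls fragments down to half the reporting floor,
merges same-pair fragments separated by small genetic gaps (the gap is
included in the merged length), and re-applies the full floor afterwards.
"""

from __future__ import annotations

from collections import defaultdict

from ..panel import MISSING, HaplotypePanel
from .pbwt import DetectionError, pbwt_long_matches
from .segments import IBDSegment, MatchParams


def stitch_segments(segments: list[IBDSegment],
                    params: MatchParams) -> list[IBDSegment]:
    """Merge same-pair, same-chromosome segments with gaps <= stitch_gap_cM;
    drop post-merge segments below ``min_cM``."""
    by_pair: dict[tuple, list[IBDSegment]] = defaultdict(list)
    for s in segments:
        by_pair[s.pair_key()].append(s)
    out: list[IBDSegment] = []
    for group in by_pair.values():
        group.sort(key=lambda s: s.start_cM)
        cur = group[0]
        merged = [cur]
        for s in group[1:]:
            if s.start_cM - cur.end_cM <= params.stitch_gap_cM:
                cur = IBDSegment(
                    id1=cur.id1, hap1=cur.hap1, id2=cur.id2, hap2=cur.hap2,
                    chrom=cur.chrom, start_cM=cur.start_cM,
                    end_cM=max(cur.end_cM, s.end_cM),
                    length_cM=max(cur.end_cM, s.end_cM) - cur.start_cM,
                    n_sites=max(cur.end_idx, s.end_idx) - cur.start_idx,
                    start_idx=cur.start_idx,
                    end_idx=max(cur.end_idx, s.end_idx),
                    start_bp=cur.start_bp, end_bp=max(cur.end_bp, s.end_bp))
                merged[-1] = cur
            else:
                cur = s
                merged.append(cur)
        out.extend(m for m in merged if m.length_cM >= params.min_cM - 1e-12)
    out.sort(key=lambda s: (s.id1, s.id2, s.chrom, s.start_cM, s.hap1, s.hap2))
    return out


def detect_ibd(historical: HaplotypePanel, cohort: HaplotypePanel,
               params: MatchParams | None = None) -> list[IBDSegment]:
    """IBD segments between historical individuals and cohort members.

    Both panels must share an identical site index.  Missing alleles are
    filled with the per-site major allele (the matching-on-imputed-genomes
    convention) before the PBWT sweep; only pairs involving at least one
    historical individual are returned, stitched and filtered at
    ``params.min_cM``.
    """
    params = params or MatchParams()
    merged = HaplotypePanel.concat([historical, cohort])
    if (merged.haplotypes == MISSING).any():
        merged = merged.fill_missing_major()
    hist = set(historical.ids)
    raw = pbwt_long_matches(merged, params.min_cM / 2.0,
                            min_sites=params.min_sites,
                            include_ids=hist)
    raw = [s for s in raw if (s.id1 in hist) != (s.id2 in hist)]
    return stitch_segments(raw, params)


def detect_ibd_within(panel: HaplotypePanel, params: MatchParams | None = None,
                      include_ids: set[str] | None = None) -> list[IBDSegment]:
    """IBD among members of one panel (optionally only pairs touching
    ``include_ids``), with the same stitch-and-filter protocol."""
    params = params or MatchParams()
    if (panel.haplotypes == MISSING).any():
        panel = panel.fill_missing_major()
    raw = pbwt_long_matches(panel, params.min_cM / 2.0,
                            min_sites=params.min_sites,
                            include_ids=include_ids)
    return stitch_segments(raw, params)


__all__ = ["detect_ibd", "stitch_segments", "pbwt_long_matches",
           "DetectionError", "MatchParams", "IBDSegment"]
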