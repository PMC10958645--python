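"""End-to-end pipeline: simulate -> detect -> relate -> ancestry -> enrich
-> network -> link, with a cohort summary table using magnitude-dependent
display rounding.

Every tunable threshold lives in :class:`RunConfig` (JSON round-trip), and
all randomness derives from its single seed, so a rerun with the same
config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import enrichment as enr
from . import network as net
from . import pedigree_link as plink
from . import relatedness as rel
from .ibd import MatchParams, detect_ibd, detect_ibd_within, segments_to_frame
from .synthetic.scenario import StudyConfig, StudyData, simulate_study
from .synthetic.fixtures import write_fixture


@dataclass
class RunConfig:
    seed: int = 0
    n_sites: int = 20_000
    min_cM: float = 7.0
    stitch_gap_cM: float = 1.0
    min_sites: int = 16
    close_cM: float = 30.0
    expand_cM: float = 100.0
    prune_cM: float = 700.0
    ssa_african_min: float = 0.95
    eur_european_min: float = 0.99
    ssa_us_filter_min: float = 0.05
    eur_us_filter_min: float = 0.99
    geo_downsample: float = 0.8
    geo_min_count: int = 25
    n_reps: int = 1000
    coverage_min: float = 0.5
    max_g: int = 8
    banker_rounding: bool = False
    outdir: str = "kinlegacy_run"

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        return cls(**json.loads(text))

    def match_params(self) -> MatchParams:
        return MatchParams(self.min_cM, self.stitch_gap_cM, self.min_sites)


def round_ibd(value_cM: float, banker: bool = False) -> float:
    """Magnitude-dependent display rounding for IBD amounts.

    >100 cM -> nearest ten; 30-100 -> nearest five; 10-30 -> nearest
    integer; <10 -> one decimal place.  Halves round away from zero
    unless ``banker`` is set.
    """
    if value_cM < 0:
        raise ValueError("IBD amounts are non-negative")
    from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
    mode = ROUND_HALF_EVEN if banker else ROUND_HALF_UP
    # Decimal on the printed value so that e.g. 0.95 is a true half case
    d = Decimal(repr(float(value_cM)))
    if value_cM > 100:
        out = (d / 10).quantize(Decimal(1), mode) * 10
    elif value_cM >= 30:
        out = (d / 5).quantize(Decimal(1), mode) * 5
    elif value_cM >= 10:
        out = d.quantize(Decimal(1), mode)
    else:
        out = d.quantize(Decimal("0.1"), mode)
    return float(out)


@dataclass
class CohortSummaryRow:
    cohort: str
    n_participants: int
    prop_connected_pct: float
    n_segments: int
    median_segment_cM: float
    max_segment_cM: float
    median_total_cM: float
    max_total_cM: float
    display: dict[str, str] = field(default_factory=dict)


_COHORT_COLS = [("all", None), ("african", "african_cohort"),
                ("european", "european_cohort"), ("us", "us_cohort"),
                ("us_ge5_ssa", "us_ge5_ssa"), ("us_ge99_eur", "us_ge99_eur")]


def summarize_cohorts(connections: pd.DataFrame, flags: pd.DataFrame,
                      seg_frame: pd.DataFrame, historical_ids: set,
                      banker: bool = False) -> list[CohortSummaryRow]:
    """Table-1-style per-cohort IBD summary (raw values plus display
    strings rounded by :func:`round_ibd`)."""
    conn = connections.merge(
        flags[["participant_id"] + [c for _, c in _COHORT_COLS if c]],
        on="participant_id")
    seg = seg_frame.copy()
    seg["cohort_member"] = np.where(seg["id1"].isin(historical_ids),
                                    seg["id2"], seg["id1"])
    seg = seg[~seg["cohort_member"].isin(historical_ids)]
    rows = []
    for name, col in _COHORT_COLS:
        sub = conn if col is None else conn[conn[col]]
        members = set(sub["participant_id"])
        s = seg[seg["cohort_member"].isin(members)]
        connected = sub[sub["connected"]]
        totals = connected["total_cM"]
        n = len(sub)
        row = CohortSummaryRow(
            cohort=name, n_participants=n,
            prop_connected_pct=100.0 * len(connected) / n if n else 0.0,
            n_segments=len(s),
            median_segment_cM=float(s["length_cM"].median()) if len(s) else 0.0,
            max_segment_cM=float(s["length_cM"].max()) if len(s) else 0.0,
            median_total_cM=float(totals.median()) if len(totals) else 0.0,
            max_total_cM=float(totals.max()) if len(totals) else 0.0)
        row.display = {
            k: f"{round_ibd(getattr(row, k), banker):g}"
            for k in ("median_segment_cM", "max_segment_cM",
                      "median_total_cM", "max_total_cM")}
        rows.append(row)
    return rows


def run_pipeline(config: RunConfig, study: StudyData | None = None,
                 write: bool = True) -> dict:
    """Execute every stage and return the report bundle.

    ``study`` may be passed to reuse an already simulated cohort (the
    stages re-derive everything else from it deterministically).
    """
    out = Path(config.outdir)
    log: dict[str, dict] = {}
    seed = config.seed

    # ---- simulate
    if study is None:
        study = simulate_study(StudyConfig(n_sites=config.n_sites), seed=seed)
    covered = [i for i in study.historical.ids
               if study.coverage[i] > config.coverage_min]
    log["simulate"] = {"n_historical": study.historical.n_ind,
                       "n_covered": len(covered),
                       "n_cohort": study.cohort.n_ind,
                       "n_sites": study.gmap.n_sites}
    if write:
        write_fixture(out / "fixture", study.historical, study.cohort,
                      study.metadata, study.gmap, true_ibd=study.true_ibd)

    # ---- detect
    params = config.match_params()
    segments = detect_ibd(study.historical, study.cohort, params)
    hist_segments = detect_ibd_within(study.historical, params)
    seg_frame = segments_to_frame(segments)
    hist_ids = set(study.historical.ids)
    covered_set = set(covered)
    seg_cov = [s for s in segments
               if (s.id1 not in hist_ids or s.id1 in covered_set)
               and (s.id2 not in hist_ids or s.id2 in covered_set)]
    log["detect"] = {"n_segments": len(segments),
                     "n_historical_segments": len(hist_segments)}

    # ---- relate
    summaries = rel.summarize_pairs(seg_cov)
    hist_pairs = [s for s in rel.summarize_pairs(hist_segments)
                  if s.id1 in covered_set and s.id2 in covered_set]
    cohort_pairs = [s for s in summaries
                    if (s.id1 in hist_ids) != (s.id2 in hist_ids)]
    families = rel.build_families(hist_pairs,
                                  D=2 * study.gmap.haploid_total_cM,
                                  all_ids=covered)
    log["relate"] = {"n_pairs": len(summaries),
                     "n_families": len(families["families"])}

    # ---- ancestry
    profiles = anc.global_ancestry_panel(study.cohort, study.model.freqs,
                                         study.model.pop_labels)
    flags = anc.apply_cohort_filters(study.metadata, profiles)
    connections = enr.connection_table(study.metadata, cohort_pairs,
                                       covered_set, config.close_cM)
    log["ancestry"] = {"n_profiles": len(profiles)}

    # ---- enrich
    def ids_where(col):
        return list(flags.loc[flags[col], "participant_id"])

    region = flags.set_index("participant_id")["region"]
    focal_africa = [i for i in ids_where("african_cohort")
                    if region[i] in ("africa_senegal", "africa_congo")]
    focal_europe = [i for i in ids_where("european_cohort")
                    if region[i] in ("europe_gb", "europe_ireland")]
    focal_md = [i for i in ids_where("us_cohort") if region[i] == "maryland"]
    tests = {
        "africa_connected": (focal_africa, ids_where("african_cohort"),
                             "connected"),
        "europe_connected": (focal_europe, ids_where("european_cohort"),
                             "connected"),
        "us_ge5ssa_connected": (ids_where("us_ge5_ssa"), ids_where("us_cohort"),
                                "connected"),
        "maryland_close": (focal_md, ids_where("us_cohort"), "close"),
    }
    enrich = {}
    for name, (focal, ref, stat) in tests.items():
        res = enr.randomization_enrichment(
            focal, ref, connections, n_reps=config.n_reps,
            seed=seed + 1, statistic=stat)
        enrich[name] = dataclasses.asdict(res)
    geo = {}
    for name, col in [("african", "african_cohort"),
                      ("european", "european_cohort"), ("us", "us_cohort")]:
        sub = flags[flags[col]]
        cells = enr.geo_aggregate(sub, connections, config.geo_downsample,
                                  config.geo_min_count, seed=seed + 2)
        geo[name] = enr.geo_cells_frame(cells)
    log["enrich"] = {k: v["p_mc"] for k, v in enrich.items()}

    # ---- network
    afr_ids = ids_where("african_cohort")
    conn_afr = set(connections.loc[connections["connected"],
                                   "participant_id"]) & set(afr_ids)
    afr_members = sorted(conn_afr)
    afr_cc = rel.summarize_pairs(detect_ibd_within(
        study.cohort.subset(afr_members), params)) if len(afr_members) > 1 else []
    graph = net.build_graph(afr_cc, config.prune_cM, node_ids=afr_members)
    clusters = net.cluster_graph(graph, seed=seed)
    # close relatives' own relatives need cohort-cohort IBD: a second sweep
    # restricted to pairs touching a close relative, then a third over the
    # resulting familial node set for its internal edges
    us_conn = connections[
        connections["participant_id"].isin(ids_where("us_cohort"))]
    close_set = set(us_conn.loc[us_conn["close"], "participant_id"])
    if close_set:
        cc_close = rel.summarize_pairs(detect_ibd_within(
            study.cohort, params, include_ids=close_set))
        node_set = set(close_set)
        for s in cc_close:
            if s.total_cM >= config.expand_cM:
                node_set.update((s.id1, s.id2))
        cc_all = rel.summarize_pairs(detect_ibd_within(
            study.cohort.subset(sorted(node_set)), params))
    else:
        cc_all = []
    groups = net.familial_groups(us_conn, cc_all, config.close_cM,
                                 config.expand_cM, seed=seed)
    log["network"] = {"n_clusters": len(clusters.clusters),
                      "n_familial_groups": len(groups.clusters)}

    # ---- link (attachments onto Family A)
    fam_a = plink.HistoricalPedigree(study.family_peds["A"])
    members_a = set(study.families["A"])
    by_ext: dict[str, dict[str, list[float]]] = {}
    for s in seg_cov:
        h, c = (s.id1, s.id2) if s.id1 in hist_ids else (s.id2, s.id1)
        if h in members_a and c not in hist_ids:
            by_ext.setdefault(c, {m: [] for m in members_a})
            by_ext[c][h].append(s.length_cM)
    posteriors, ext_ids = [], []
    for ext in sorted(by_ext):
        if sum(len(v) for v in by_ext[ext].values()) == 0:
            continue
        posteriors.append(plink.infer_attachment(
            by_ext[ext], fam_a, max_g=config.max_g, min_cM=config.min_cM,
            L_hap=study.gmap.haploid_total_cM,
            n_chrom=len(study.gmap.chroms)))
        ext_ids.append(ext)
    agg = plink.aggregate_attachments(posteriors)
    prof_idx = profiles.set_index("participant_id")
    map_nodes, rules = [], []
    for ext, post in zip(ext_ids, posteriors):
        c = post.map_candidate
        map_nodes.append(c.node)
        row = prof_idx.loc[ext]
        rules.append(bool(row["NAM"] >= 2 * row["AFR"]))
    assoc = plink.ancestry_association_test(
        map_nodes, rules, {"A_father", "A_fgm", "A_fgf"},
        n_reps=max(config.n_reps, 1000), seed=seed + 3)
    upward = sum(1 for p in posteriors
                 if p.map_candidate.direction == "upward")
    log["link"] = {"n_externals": len(posteriors),
                   "upward_share": upward / len(posteriors) if posteriors else 0.0,
                   "association_p": assoc.p_value}

    # ---- summarize
    table = summarize_cohorts(connections, flags, seg_frame[
        seg_frame.apply(lambda r: (r["id1"] in covered_set)
                        or (r["id2"] in covered_set), axis=1)],
        hist_ids, banker=config.banker_rounding)
    report = {
        "config": dataclasses.asdict(config),
        "log": log,
        "families": {"families": families["families"],
                     "singletons": families["singletons"],
                     "edge_labels": {f"{a}|{b}": v for (a, b), v
                                     in families["edge_labels"].items()}},
        "enrichment": enrich,
        "cohort_table": [dataclasses.asdict(r) for r in table],
        "association": dataclasses.asdict(assoc),
        "attachment_summary": agg.to_dict(orient="records"),
        "upward_share": log["link"]["upward_share"],
    }
    if write:
        out.mkdir(parents=True, exist_ok=True)
        seg_frame.to_csv(out / "ibd_segments.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            out / "pair_summaries.tsv", sep="\t", index=False)
        profiles.to_csv(out / "ancestry.tsv", sep="\t", index=False)
        for name, frame in geo.items():
            frame.to_csv(out / f"geo_{name}.tsv", sep="\t", index=False)
        net.to_graphml(graph, out / "ibd_network_african.graphml",
                       flags, ["region"])
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_jsonable))
    report["_objects"] = {
        "study": study, "segments": segments, "summaries": summaries,
        "connections": connections, "flags": flags, "geo": geo,
        "clusters": clusters, "groups": groups, "posteriors": posteriors,
        "ext_ids": ext_ids, "graph": graph, "profiles": profiles,
    }
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
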