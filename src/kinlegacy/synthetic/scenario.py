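"""The synthetic study: a historical cemetery cohort linked to a living one.

:func:`simulate_study` generates, from one seed, everything the pipeline
consumes:

* 27 "historical" individuals — five genetic families (a mother with two
  sons and a 2nd–3rd-degree relative, plus four smaller mother/child
  groups, 15 individuals in all) and 12 unrelated singletons — genotyped
  through labelled gene dropping and then degraded to emulate imputed
  low-coverage historical genomes;
* a present-day cohort of ~2,000 members across US, African and European
  regions, most unrelated to the families, plus planted relatives whose
  lineages descend from un-genotyped ancestors of the families (so their
  true IBD with the historical individuals is known exactly);
* per-participant metadata (coordinates, birth/grandparent regions) and
  true ancestry fractions.

The planted structure mirrors the study design the pipeline is meant to
detect: close relatives concentrated in one US region, distant connections
concentrated in two African and two European regions, and one family whose
un-sampled father carries Indigenous-American-like ancestry that his
collateral descendants inherit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genmap import GeneticMap
from ..panel import HaplotypePanel
from ..utils import derive_rng
from .admixture import AncestryTract, simulate_admixed_fresh, tract_fraction
from .degrade import DegradationParams, degrade
from .pedigree import (GeneDropResult, PedigreeNode, PedigreeSpec,
                       drop_through_pedigree)
from .popmodel import PopulationModel

POPS = ["AFR", "EUR", "NAM"]

AFR_HEAVY = (0.80, 0.18, 0.02)
US_MIXED = (0.75, 0.23, 0.02)
US_EURO = (0.003, 0.995, 0.002)
AFRICAN = (0.990, 0.0075, 0.0025)
EUROPEAN = (0.001, 0.998, 0.001)
NAM_RICH = (0.02, 0.68, 0.30)


@dataclass(frozen=True)
class RegionSpec:
    name: str
    lat: int
    lon: int
    n: int
    region_class: str          # 'US' | 'Africa' | 'Europe'
    weights: tuple
    g: float = 8.0


DEFAULT_REGIONS = [
    RegionSpec("maryland", 39, -77, 230, "US", US_MIXED),
    RegionSpec("us_south", 33, -84, 380, "US", AFR_HEAVY),
    RegionSpec("us_other", 41, -93, 300, "US", (0.02, 0.96, 0.02)),
    RegionSpec("us_eur", 40, -75, 300, "US", US_EURO),
    RegionSpec("us_tiny", 45, -110, 18, "US", (0.5, 0.48, 0.02)),
    RegionSpec("africa_senegal", 15, -17, 80, "Africa", AFRICAN),
    RegionSpec("africa_congo", -4, 15, 80, "Africa", AFRICAN),
    RegionSpec("africa_other", 9, 8, 200, "Africa", AFRICAN),
    RegionSpec("europe_gb", 52, -1, 120, "Europe", EUROPEAN),
    RegionSpec("europe_ireland", 53, -8, 60, "Europe", EUROPEAN),
    RegionSpec("europe_other", 48, 2, 260, "Europe", EUROPEAN),
]

# planted externals: (group, count, anchor kind, lineage meioses from the
# anchor couple to the external, region pool, chain-spouse ancestry,
# family rotation)
_PLANT_PLAN = [
    ("close_md", 30, "family", (4, 5, 6), ["maryland"], US_MIXED,
     "AABCDE"),  # family rotation, A twice
    ("close_us", 20, "family", (5, 6), ["us_south", "us_other"], US_MIXED,
     "ABCDE"),
    ("f_side", 25, "father_A", (4, 5, 6), ["maryland", "us_south", "us_other"],
     NAM_RICH, "A"),
    ("africa", 12, "family", (7, 8), ["africa_senegal", "africa_congo"],
     AFRICAN, "ABCDE"),
    ("europe", 22, "euro_side", (5, 6), ["europe_gb", "europe_ireland"],
     EUROPEAN, "CCABDE"),
]


@dataclass
class StudyConfig:
    n_sites: int = 20_000
    n_chrom: int = 22
    L_hap: float = 3500.0
    F: float = 0.1
    founder_g: float = 6.0
    degradation: DegradationParams = field(
        default_factory=lambda: DegradationParams(0.001, 0.02))
    regions: list = field(default_factory=lambda: list(DEFAULT_REGIONS))
    plant_plan: list = field(default_factory=lambda: list(_PLANT_PLAN))


@dataclass
class StudyData:
    config: StudyConfig
    gmap: GeneticMap
    model: PopulationModel
    historical: HaplotypePanel            # degraded
    historical_clean: HaplotypePanel
    cohort: HaplotypePanel
    metadata: pd.DataFrame
    families: dict[str, list[str]]        # family label -> genotyped ids
    family_peds: dict[str, PedigreeSpec]  # family-only pedigrees
    drops: dict[str, GeneDropResult]
    true_ibd: pd.DataFrame
    coverage: dict[str, float]
    external_info: pd.DataFrame           # id, family, anchor, degree, group

    @property
    def historical_ids(self) -> list[str]:
        return list(self.historical.ids)


# -- pedigree builders ---------------------------------------------------


def _family_trunk(ped: PedigreeSpec, fw: dict, label: str) -> None:
    """Shared upper structure of every family: the genotyped mother's
    maternal grandmother line is African, while her father descends from a
    fully European great-grandparent couple — giving the historical
    individuals the mostly-African, partly-European ancestry profile the
    cohort's European connections trace back through."""
    for fid, w in [(f"{label}_eggm", EUROPEAN), (f"{label}_eggf", EUROPEAN),
                   (f"{label}_egf", AFR_HEAVY), (f"{label}_gm", AFR_HEAVY)]:
        ped.add(PedigreeNode(fid, founder=True, generation=0))
        fw[fid] = w
    ped.add(PedigreeNode(f"{label}_egm", generation=1,
                         mother=f"{label}_eggm", father=f"{label}_eggf"))
    ped.add(PedigreeNode(f"{label}_gf", generation=2,
                         mother=f"{label}_egm", father=f"{label}_egf"))
    ped.add(PedigreeNode(f"{label}_mother", sex="F", generation=3,
                         genotyped=True, mother=f"{label}_gm",
                         father=f"{label}_gf"))


def _family_A(ped: PedigreeSpec, fw: dict) -> list[str]:
    """Mother + two sons (died in childhood) + a niece-of-mother relative,
    with the sons' father un-genotyped but given parents (one carrying
    Indigenous-American-like ancestry) so that lineages through his
    ancestors can be enumerated and planted."""
    _family_trunk(ped, fw, "A")
    for fid, w in [("A_fgm", (0.30, 0.20, 0.50)), ("A_fgf", (0.60, 0.35, 0.05)),
                   ("A_sibsp", AFR_HEAVY)]:
        ped.add(PedigreeNode(fid, founder=True, generation=0))
        fw[fid] = w
    ped.add(PedigreeNode("A_father", generation=3, mother="A_fgm", father="A_fgf"))
    ped.add(PedigreeNode("A_sib", generation=3, mother="A_gm", father="A_gf"))
    ped.add(PedigreeNode("A_son1", sex="M", generation=4, genotyped=True,
                         mother="A_mother", father="A_father", died_child=True))
    ped.add(PedigreeNode("A_son2", sex="M", generation=4, genotyped=True,
                         mother="A_mother", father="A_father", died_child=True))
    ped.add(PedigreeNode("A_rel24", generation=4, genotyped=True,
                         mother="A_sibsp", father="A_sib"))
    return ["A_mother", "A_son1", "A_son2", "A_rel24"]


def _family_generic(ped: PedigreeSpec, fw: dict, label: str,
                    n_children: int) -> list[str]:
    """Mother and children genotyped; father and grandparents not."""
    _family_trunk(ped, fw, label)
    ped.add(PedigreeNode(f"{label}_fa", founder=True, generation=0))
    fw[f"{label}_fa"] = AFR_HEAVY
    out = [f"{label}_mother"]
    for c in range(1, n_children + 1):
        ped.add(PedigreeNode(f"{label}_c{c}", generation=4, genotyped=True,
                             mother=f"{label}_mother", father=f"{label}_fa"))
        out.append(f"{label}_c{c}")
    return out


def _add_chain(ped: PedigreeSpec, fw: dict, anchor_m: str, anchor_f: str,
               g_down: int, ext_id: str, spouse_w: tuple) -> None:
    """A lineage of ``g_down`` meioses from the anchor couple down to an
    external (genotyped) present-day individual."""
    base_gen = max(ped.nodes[anchor_m].generation,
                   ped.nodes[anchor_f].generation)
    prev_m, prev_f = anchor_m, anchor_f
    for i in range(1, g_down + 1):
        nid = ext_id if i == g_down else f"{ext_id}~{i}"
        ped.add(PedigreeNode(nid, generation=base_gen + i,
                             genotyped=(i == g_down),
                             mother=prev_m, father=prev_f))
        if i < g_down:
            sp = f"{ext_id}~sp{i}"
            ped.add(PedigreeNode(sp, founder=True, generation=base_gen + i - 1))
            fw[sp] = spouse_w
            prev_m, prev_f = nid, sp


# -- ancestry truth ------------------------------------------------------


def _index_tracts(tracts: list[AncestryTract]) -> dict[str, list[AncestryTract]]:
    out: dict[str, list[AncestryTract]] = {}
    for t in tracts:
        out.setdefault(t.chrom, []).append(t)
    return out


def _composed_ancestry(drop: GeneDropResult, ind: str,
                       founder_tracts: dict[str, dict]) -> dict[str, float]:
    """True ancestry of a gene-dropped individual: intersect its founder-
    labelled segments with each founder haplotype's recorded tracts."""
    lengths = dict.fromkeys(POPS, 0.0)
    for h in (0, 1):
        for chrom, segs in drop.haps[ind][h].items():
            for s, e, lab in segs:
                for t in founder_tracts[lab].get(chrom, []):
                    lo, hi = max(s, t.start_cM), min(e, t.end_cM)
                    if hi > lo:
                        lengths[t.pop] += hi - lo
    total = sum(lengths.values())
    return {p: v / total for p, v in lengths.items()}


def _fraction_dict(tracts0, tracts1) -> dict[str, float]:
    return {p: 0.5 * (tract_fraction(tracts0, p) + tract_fraction(tracts1, p))
            for p in POPS}


# -- study generator -----------------------------------------------------


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    config = config or StudyConfig()
    gmap = GeneticMap.default(config.n_sites, config.L_hap, config.n_chrom)
    model = PopulationModel.simulate(POPS, gmap.n_sites, F=config.F, seed=seed)

    # ---- pedigrees: five families plus planted external chains
    fam_sizes = {"B": 2, "C": 2, "D": 2, "E": 1}   # children per mother
    peds: dict[str, PedigreeSpec] = {}
    fam_weights: dict[str, dict] = {}
    families: dict[str, list[str]] = {}
    for lab in "ABCDE":
        ped = PedigreeSpec()
        fw: dict = {}
        if lab == "A":
            families[lab] = _family_A(ped, fw)
        else:
            families[lab] = _family_generic(ped, fw, lab, fam_sizes[lab])
        peds[lab], fam_weights[lab] = ped, fw
    family_only = {lab: PedigreeSpec(dict(peds[lab].nodes)) for lab in peds}

    ext_rows = []
    rng_plan = derive_rng(seed, "plant-plan")
    available = [r.name for r in config.regions]
    for group, count, anchor_kind, g_opts, region_pool, spouse_w, fam_cycle \
            in config.plant_plan:
        region_pool = [p for p in region_pool if p in available] or \
            available[:1]
        for j in range(count):
            fam = fam_cycle[j % len(fam_cycle)]
            if anchor_kind == "father_A":
                fam, anc_m, anc_f = "A", "A_fgm", "A_fgf"
            elif anchor_kind == "euro_side":
                anc_m, anc_f = f"{fam}_eggm", f"{fam}_eggf"
            else:
                anc_m, anc_f = f"{fam}_gm", f"{fam}_gf"
            g_down = int(g_opts[j % len(g_opts)])
            ext_id = f"X_{group}_{j:03d}"
            _add_chain(peds[fam], fam_weights[fam], anc_m, anc_f,
                       g_down, ext_id, spouse_w)
            region = region_pool[int(rng_plan.integers(len(region_pool)))]
            # path degree to the anchor couple's pedigree children is
            # g_down + their own distance below the couple
            ext_rows.append((ext_id, fam, anc_m, g_down, group, region))
    external_info = pd.DataFrame(
        ext_rows, columns=["participant_id", "family", "anchor",
                           "lineage_g", "group", "region"])

    # ---- founder haplotypes and gene drops
    drops: dict[str, GeneDropResult] = {}
    founder_tracts: dict[str, dict] = {}
    for lab, ped in peds.items():
        rng_f = derive_rng(seed, "founders", lab)
        fhaps = {}
        for fid in ped.founders():
            w = fam_weights[lab][fid]
            h0, t0 = simulate_admixed_fresh(model, w, config.founder_g, gmap, rng_f)
            h1, t1 = simulate_admixed_fresh(model, w, config.founder_g, gmap, rng_f)
            fhaps[fid] = (h0, h1)
            founder_tracts[f"{fid}|0"] = _index_tracts(t0)
            founder_tracts[f"{fid}|1"] = _index_tracts(t1)
        drops[lab] = drop_through_pedigree(ped, fhaps, gmap,
                                           seed=derive_rng(seed, "drop", lab)
                                           .integers(2**31))

    # ---- historical panel: family members + 12 unrelated singletons
    hist_ids: list[str] = [m for lab in "ABCDE" for m in families[lab]]
    panels = [drops[lab].materialize(families[lab]) for lab in "ABCDE"]
    rng_s = derive_rng(seed, "singletons")
    singles_H = np.empty((24, gmap.n_sites), dtype=np.uint8)
    ancestry_rows: dict[str, dict] = {}
    for i in range(12):
        sid = f"S{i + 1:02d}"
        h0, t0 = simulate_admixed_fresh(model, AFR_HEAVY, config.founder_g,
                                        gmap, rng_s)
        h1, t1 = simulate_admixed_fresh(model, AFR_HEAVY, config.founder_g,
                                        gmap, rng_s)
        singles_H[2 * i], singles_H[2 * i + 1] = h0, h1
        hist_ids.append(sid)
        ancestry_rows[sid] = _fraction_dict(t0, t1)
    sites = panels[0].sites
    H_hist = np.vstack([p.haplotypes for p in panels] + [singles_H])
    historical_clean = HaplotypePanel(sites, H_hist, hist_ids)
    historical = degrade(historical_clean, config.degradation,
                         seed=derive_rng(seed, "degrade-hist").integers(2**31))
    coverage = {i: (1.2 if not i.startswith("S") or int(i[1:]) <= 7 else 0.3)
                for i in hist_ids}
    for lab in "ABCDE":
        for m in families[lab]:
            ancestry_rows[m] = _composed_ancestry(drops[lab], m, founder_tracts)

    # ---- cohort: unrelated per-region members + planted externals
    meta_rows = []
    rng_meta = derive_rng(seed, "metadata")
    cohort_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for reg in config.regions:
        rng_r = derive_rng(seed, "region", reg.name)
        block = np.empty((2 * reg.n, gmap.n_sites), dtype=np.uint8)
        for i in range(reg.n):
            pid = f"P_{reg.name}_{i:04d}"
            h0, t0 = simulate_admixed_fresh(model, reg.weights, reg.g, gmap, rng_r)
            h1, t1 = simulate_admixed_fresh(model, reg.weights, reg.g, gmap, rng_r)
            block[2 * i], block[2 * i + 1] = h0, h1
            cohort_ids.append(pid)
            ancestry_rows[pid] = _fraction_dict(t0, t1)
            meta_rows.append(_meta_row(pid, reg.name, reg.lat, reg.lon,
                                       reg.region_class, rng_meta))
        blocks.append(block)
    region_by_name = {r.name: r for r in config.regions}
    for lab in "ABCDE":
        fam_ext = external_info[external_info["family"] == lab]
        if len(fam_ext) == 0:
            continue
        ids = list(fam_ext["participant_id"])
        panel = drops[lab].materialize(ids)
        blocks.append(panel.haplotypes)
        cohort_ids.extend(ids)
        for pid, region in zip(ids, fam_ext["region"]):
            reg = region_by_name[region]
            ancestry_rows[pid] = _composed_ancestry(drops[lab], pid,
                                                    founder_tracts)
            meta_rows.append(_meta_row(pid, reg.name, reg.lat, reg.lon,
                                       reg.region_class, rng_meta))
    cohort = HaplotypePanel(sites, np.vstack(blocks), cohort_ids)
    metadata = pd.DataFrame(meta_rows)
    metadata = metadata.set_index("participant_id").loc[cohort_ids].reset_index()
    frac = pd.DataFrame.from_dict(ancestry_rows, orient="index")
    frac.index.name = "participant_id"
    frac = frac.rename(columns={p: f"true_frac_{p}" for p in POPS}).reset_index()
    metadata = metadata.merge(frac, on="participant_id", how="left")

    # ---- truth: IBD between historical individuals and everyone dropped
    ibd_rows = []
    for lab in "ABCDE":
        fam_ext = external_info[external_info["family"] == lab]
        members = families[lab]
        others = [m for m in members] + list(fam_ext["participant_id"])
        for i, a in enumerate(others):
            for b in others[i + 1:]:
                if a not in members and b not in members:
                    continue
                for chrom, s, e, ha, hb in drops[lab].true_ibd(a, b):
                    ibd_rows.append((a, b, chrom, s, e))
    true_ibd = pd.DataFrame(ibd_rows, columns=["id1", "id2", "chrom",
                                               "start_cM", "end_cM"])

    hist_ancestry = {i: ancestry_rows[i] for i in hist_ids}
    metadata.attrs["historical_ancestry"] = hist_ancestry
    return StudyData(config, gmap, model, historical, historical_clean,
                     cohort, metadata, families, family_only, drops,
                     true_ibd, coverage, external_info)


def _meta_row(pid: str, region: str, lat: int, lon: int,
              region_class: str, rng: np.random.Generator) -> dict:
    jit = rng.uniform(-0.4, 0.4, size=2)
    u = rng.random()
    if region_class == "US":
        if u < 0.70:
            born, gp = "US", "US"
        elif u < 0.90:
            born, gp = "US", "unknown"
        elif u < 0.97:
            born, gp = "US", "multiple"
        else:
            born, gp = "US", "Europe"   # all four grandparents abroad
    else:
        born, gp = region_class, region_class
    return {"participant_id": pid, "region": region,
            "lat": lat + jit[0], "lon": lon + jit[1],
            "born_region": born, "gp_born_region": gp}


# -- small simulation fixtures used by validation ------------------------


def simulate_lineal_pair(d: int, gmap: GeneticMap, seed: int = 0) -> float:
    """True total IBD (cM) between an ancestor and a degree-``d`` lineal
    descendant, from a fresh gene drop (alleles never materialized)."""
    ped = PedigreeSpec()
    fw: dict = {}
    ped.add(PedigreeNode("anc", founder=True, generation=0))
    ped.add(PedigreeNode("anc_sp", founder=True, generation=0))
    prev_m, prev_f = "anc", "anc_sp"
    for i in range(1, d + 1):
        nid = f"n{i}"
        ped.add(PedigreeNode(nid, generation=i, mother=prev_m, father=prev_f))
        if i < d:
            sp = f"sp{i}"
            ped.add(PedigreeNode(sp, founder=True, generation=i - 1))
            prev_m, prev_f = nid, sp
    zeros = np.zeros(gmap.n_sites, dtype=np.uint8)
    fhaps = {f: (zeros, zeros) for f in ped.founders()}
    drop = drop_through_pedigree(ped, fhaps, gmap, seed=seed)
    return drop.true_ibd_total("anc", f"n{d}")


def simulate_sib_pedigree_with_grandchild(gmap: GeneticMap, seed: int = 0
                                          ) -> tuple[PedigreeSpec, GeneDropResult]:
    """Two genotyped siblings with un-genotyped parents, plus one external
    grandchild of sibling X — the attachment-recovery fixture."""
    ped = PedigreeSpec()
    for fid in ("P1", "P2", "SPX", "SPC"):
        ped.add(PedigreeNode(fid, founder=True, generation=0))
    ped.add(PedigreeNode("X", generation=1, genotyped=True,
                         mother="P1", father="P2"))
    ped.add(PedigreeNode("Y", generation=1, genotyped=True,
                         mother="P1", father="P2"))
    ped.add(PedigreeNode("C1", generation=2, mother="X", father="SPX"))
    ped.add(PedigreeNode("EXT", generation=3, mother="C1", father="SPC"))
    zeros = np.zeros(gmap.n_sites, dtype=np.uint8)
    fhaps = {f: (zeros, zeros) for f in ped.founders()}
    drop = drop_through_pedigree(ped, fhaps, gmap, seed=seed)
    return ped, drop
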