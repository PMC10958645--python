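import numpy as np
import pytest

from kinlegacy.genmap import GeneticMap
from kinlegacy.panel import HaplotypePanel
from kinlegacy.synthetic import PopulationModel


@pytest.fixture(scope="session")
def dense_map() -> GeneticMap:
    """4 chromosomes, 350 cM, ~5.7 sites/cM — dense enough that chance
    haplotype matches above a 7 cM floor are vanishingly rare."""
    return GeneticMap.default(n_sites=2000, L_hap=350.0, n_chrom=4)


@pytest.fixture(scope="session")
def one_chrom_map() -> GeneticMap:
    """Single 50 cM chromosome with 300 sites."""
    return GeneticMap.default(n_sites=300, L_hap=50.0, n_chrom=1)


@pytest.fixture(scope="session")
def truth_map() -> GeneticMap:
    """Human-scale 22-chromosome map with minimal sites: used when only
    segment bookkeeping (not alleles) matters."""
    return GeneticMap.default(n_sites=44, L_hap=3500.0, n_chrom=22)


@pytest.fixture(scope="session")
def model3(dense_map) -> PopulationModel:
    return PopulationModel.simulate(["AFR", "EUR", "NAM"], dense_map.n_sites,
                                    F=0.1, seed=11)


def make_panel(gmap: GeneticMap, H: np.ndarray, ids=None) -> HaplotypePanel:
    sites = gmap.sites.copy()
    sites["ref"] = "A"
    sites["alt"] = "G"
    if ids is None:
        ids = [f"i{k}" for k in range(H.shape[0] // 2)]
    return HaplotypePanel(sites, H.astype(np.uint8), ids)


@pytest.fixture(scope="session")
def mini_study():
    """Scaled-down synthetic study: same structure as the full demo
    (families, planted relatives, regions) on an 8-chromosome 700 cM
    genome at full site density."""
    from kinlegacy.synthetic import StudyConfig, simulate_study
    from kinlegacy.synthetic.scenario import DEFAULT_REGIONS, RegionSpec
    cfg = StudyConfig(n_sites=4000, n_chrom=8, L_hap=700.0)
    cfg.regions = [RegionSpec(r.name, r.lat, r.lon,
                              18 if r.name == "us_tiny" else max(12, r.n // 8),
                              r.region_class, r.weights, r.g)
                   for r in DEFAULT_REGIONS]
    return simulate_study(cfg, seed=5)


def random_panel_with_sharing(gmap, n_ind, seed, n_plant=12,
                              plant_len=(60, 300)):
    """Random haplotypes plus planted shared stretches between pairs."""
    rng = np.random.default_rng(seed)
    n_haps = 2 * n_ind
    f = rng.uniform(0.1, 0.9, gmap.n_sites)
    H = (rng.random((n_haps, gmap.n_sites)) < f).astype(np.uint8)
    for _ in range(n_plant):
        i, j = rng.choice(n_haps, 2, replace=False)
        L = int(rng.integers(*plant_len))
        s = int(rng.integers(0, gmap.n_sites - L))
        H[j, s:s + L] = H[i, s:s + L]
    return make_panel(gmap, H)


def small_study_config():
    """Integration-scale study: full site density and map length (the
    conditions chance-match rates depend on), but a reduced cohort."""
    from kinlegacy.synthetic.scenario import (AFR_HEAVY, AFRICAN, EUROPEAN,
                                              US_EURO, US_MIXED, RegionSpec,
                                              StudyConfig)
    regions = [
        RegionSpec("maryland", 39, -77, 40, "US", US_MIXED),
        RegionSpec("us_south", 33, -84, 45, "US", AFR_HEAVY),
        RegionSpec("us_other", 41, -93, 45, "US", (0.02, 0.96, 0.02)),
        RegionSpec("us_eur", 40, -75, 35, "US", US_EURO),
        RegionSpec("us_tiny", 45, -110, 12, "US", (0.5, 0.48, 0.02)),
        RegionSpec("africa_senegal", 15, -17, 15, "Africa", AFRICAN),
        RegionSpec("africa_congo", -4, 15, 15, "Africa", AFRICAN),
        RegionSpec("africa_other", 9, 8, 30, "Africa", AFRICAN),
        RegionSpec("europe_gb", 52, -1, 20, "Europe", EUROPEAN),
        RegionSpec("europe_ireland", 53, -8, 12, "Europe", EUROPEAN),
        RegionSpec("europe_other", 48, 2, 30, "Europe", EUROPEAN),
    ]
    return StudyConfig(n_sites=20_000, regions=regions)


@pytest.fixture(scope="session")
def study_small():
    from kinlegacy.synthetic import simulate_study
    return simulate_study(small_study_config(), seed=11)


@pytest.fixture(scope="session")
def pipeline_report(study_small, tmp_path_factory):
    from kinlegacy.pipeline import RunConfig, run_pipeline
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig(seed=11, n_sites=20_000, n_reps=300, outdir=str(out))
    return run_pipeline(cfg, study=study_small)
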