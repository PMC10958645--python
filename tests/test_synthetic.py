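"""Generator checks: drift calibration, admixture tracts, meiosis
conservation, degradation channels and fixture round-trips."""

import numpy as np
import pytest

from kinlegacy.genmap import GeneticMap
from kinlegacy.panel import MISSING, HaplotypePanel, PanelError
from kinlegacy.synthetic import (DegradationParams, ModelError, PedigreeNode,
                                 PedigreeSpec, PopulationModel, degrade,
                                 drop_through_pedigree, read_fixture,
                                 simulate_admixed, simulate_founders,
                                 write_fixture)
from kinlegacy.synthetic.admixture import tract_fraction
from kinlegacy.synthetic.pedigree import PedigreeError

from conftest import make_panel


def hudson_fst(H1: np.ndarray, H2: np.ndarray) -> float:
    """Moment estimator of Fst from two haplotype blocks (test oracle)."""
    p1, p2 = H1.mean(axis=0), H2.mean(axis=0)
    n1, n2 = H1.shape[0], H2.shape[0]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


class TestFounders:
    def test_f_zero_collapses_to_shared_frequencies(self):
        m = PopulationModel.simulate(["a", "b"], 500, F=0.0, seed=1)
        assert np.array_equal(m.freqs[0], m.freqs[1])

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ModelError):
            PopulationModel(["a", "b"], np.array([1.0, 0.5]),
                            np.array([0.1, 0.1]))
        with pytest.raises(ModelError):
            PopulationModel(["a"], np.array([0.5]), np.array([1.0]))

    def test_fst_calibration(self):
        gmap = GeneticMap.default(n_sites=10_000, L_hap=350.0, n_chrom=4)
        m = PopulationModel.simulate(["a", "b"], 10_000, F=0.15, seed=5,
                                     p_range=(0.05, 0.95))
        panel = simulate_founders(m, gmap, n_per_pop=50, seed=5)
        H = panel.haplotypes
        fst = hudson_fst(H[:100], H[100:])
        assert abs(fst - 0.15) < 0.03

    def test_differentiation_monotone_in_F(self):
        gmap = GeneticMap.default(n_sites=5_000, L_hap=350.0, n_chrom=4)
        ests = []
        for F in (0.01, 0.05, 0.15):
            m = PopulationModel.simulate(["a", "b"], gmap.n_sites, F=F, seed=2)
            panel = simulate_founders(m, gmap, n_per_pop=40, seed=2)
            H = panel.haplotypes
            ests.append(hudson_fst(H[:80], H[80:]))
        assert ests[0] < ests[1] < ests[2]

    def test_deterministic_under_seed(self, dense_map, model3):
        a = simulate_founders(model3, dense_map, 5, seed=9)
        b = simulate_founders(model3, dense_map, 5, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestAdmixture:
    def test_pure_weights_give_single_population(self, dense_map, model3):
        donors = simulate_founders(model3, dense_map, 4, seed=3)
        hap, tracts = simulate_admixed(donors, (1.0, 0.0, 0.0), g=5,
                                       gmap=dense_map, seed=3)
        assert {t.pop for t in tracts} == {"AFR"}
        assert tract_fraction(tracts, "AFR") == pytest.approx(1.0)

    def test_tract_fraction_matches_weights(self, model3):
        gmap = GeneticMap.default(n_sites=2000, L_hap=3500.0, n_chrom=22)
        m = PopulationModel.simulate(["a", "b"], gmap.n_sites, F=0.1, seed=4)
        donors = simulate_founders(m, gmap, 3, seed=4)
        fracs = [tract_fraction(
            simulate_admixed(donors, (0.8, 0.2), g=10, gmap=gmap, seed=s)[1],
            "a") for s in range(20)]
        assert abs(np.mean(fracs) - 0.8) < 0.05 * 0.8 + 0.02

    def test_bad_weights_rejected(self, dense_map, model3):
        donors = simulate_founders(model3, dense_map, 2, seed=1)
        with pytest.raises(ValueError):
            simulate_admixed(donors, (0.5, 0.2, 0.1), g=5, gmap=dense_map)


class TestGeneDrop:
    @staticmethod
    def trio(gmap, seed=0):
        ped = PedigreeSpec()
        ped.add(PedigreeNode("m", founder=True))
        ped.add(PedigreeNode("f", founder=True))
        ped.add(PedigreeNode("c", generation=1, mother="m", father="f"))
        rng = np.random.default_rng(seed)
        fh = {i: ((rng.random(gmap.n_sites) < 0.5).astype(np.uint8),
                  (rng.random(gmap.n_sites) < 0.5).astype(np.uint8))
              for i in ("m", "f")}
        return ped, fh

    def test_parent_child_total_is_full_haploid_length(self, truth_map):
        ped, fh = self.trio(truth_map)
        drop = drop_through_pedigree(ped, fh, truth_map, seed=2)
        assert drop.true_ibd_total("m", "c") == pytest.approx(3500.0, abs=1e-6)
        assert drop.true_ibd_total("f", "c") == pytest.approx(3500.0, abs=1e-6)

    def test_sibling_mean_total_near_half_diploid(self, truth_map):
        ped, fh = self.trio(truth_map)
        ped.add(PedigreeNode("c2", generation=1, mother="m", father="f"))
        totals = [drop_through_pedigree(ped, fh, truth_map, seed=s)
                  .true_ibd_total("c", "c2") for s in range(20)]
        assert abs(np.mean(totals) - 3500.0) < 0.10 * 3500.0

    def test_true_ibd_symmetric(self, truth_map):
        ped, fh = self.trio(truth_map)
        ped.add(PedigreeNode("c2", generation=1, mother="m", father="f"))
        drop = drop_through_pedigree(ped, fh, truth_map, seed=7)
        ab = {(c, s, e) for c, s, e, _, _ in drop.true_ibd("c", "c2")}
        ba = {(c, s, e) for c, s, e, _, _ in drop.true_ibd("c2", "c")}
        assert ab == ba

    def test_tiny_chromosome_transmits_unrecombined(self):
        gmap = GeneticMap.default(n_sites=4, L_hap=0.0001, n_chrom=2)
        ped, fh = self.trio(gmap)
        drop = drop_through_pedigree(ped, fh, gmap, seed=1)
        for chrom in gmap.chroms:
            segs = drop.haps["c"][0][chrom]
            assert len(segs) == 1    # no crossover on a ~0 cM chromosome

    def test_missing_founder_haplotypes_error(self, truth_map):
        ped, fh = self.trio(truth_map)
        del fh["f"]
        with pytest.raises(PedigreeError):
            drop_through_pedigree(ped, fh, truth_map)

    def test_cycle_rejected(self, truth_map):
        ped = PedigreeSpec()
        ped.add(PedigreeNode("a", generation=0, mother="b", father="b"))
        ped.add(PedigreeNode("b", generation=1, mother="a", father="a"))
        with pytest.raises(PedigreeError):
            ped.validate()


class TestDegrade:
    def test_zero_rates_identity(self, dense_map, model3):
        panel = simulate_founders(model3, dense_map, 3, seed=6)
        out = degrade(panel, DegradationParams(0.0, 0.0), seed=1)
        assert np.array_equal(out.haplotypes, panel.haplotypes)

    def test_rate_one_flips_everything(self, dense_map, model3):
        panel = simulate_founders(model3, dense_map, 3, seed=6)
        out = degrade(panel, DegradationParams(1.0, 0.0), seed=1)
        assert np.array_equal(out.haplotypes, panel.haplotypes ^ 1)

    def test_flip_rate_within_binomial_bounds(self, model3):
        gmap = GeneticMap.default(n_sites=2000, L_hap=350.0, n_chrom=4)
        m = PopulationModel.simulate(["a", "b", "c"], 2000, F=0.1, seed=11)
        panel = simulate_founders(m, gmap, 50, seed=6)
        rate = 0.001
        out = degrade(panel, DegradationParams(rate, 0.0), seed=2)
        n = panel.haplotypes.size
        flipped = int((out.haplotypes != panel.haplotypes).sum())
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(flipped - n * rate) < 3 * sd

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            DegradationParams(1.5, 0.0)

    def test_missing_masks_both_haplotypes(self, dense_map, model3):
        panel = simulate_founders(model3, dense_map, 3, seed=6)
        out = degrade(panel, DegradationParams(0.0, 0.3), seed=3)
        miss = out.haplotypes == MISSING
        assert miss.any()
        assert np.array_equal(miss[0::2], miss[1::2])


class TestFixtures:
    def test_round_trip(self, tmp_path, dense_map, model3):
        import pandas as pd
        hist = simulate_founders(model3, dense_map, 2, seed=8)
        cohort = HaplotypePanel(hist.sites, hist.haplotypes.copy(),
                                [f"P{i}" for i in range(hist.n_ind)])
        meta = pd.DataFrame({"participant_id": cohort.ids,
                             "lat": 39.0, "lon": -77.0,
                             "born_region": "US", "gp_born_region": "US"})
        write_fixture(tmp_path, hist, cohort, meta, dense_map)
        back = read_fixture(tmp_path)
        assert np.array_equal(back["historical"].haplotypes, hist.haplotypes)
        assert back["historical"].ids == hist.ids
        assert len(back["metadata"]) == len(meta)

    def test_unphased_vcf_rejected(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(PanelError):
            HaplotypePanel.from_vcf(vcf)

    def test_duplicate_ids_rejected(self, tmp_path, dense_map, model3):
        import pandas as pd
        hist = simulate_founders(model3, dense_map, 2, seed=8)
        meta = pd.DataFrame({"participant_id": ["x", "x"],
                             "lat": [0.0, 0.0], "lon": [0.0, 0.0]})
        with pytest.raises(PanelError):
            write_fixture(tmp_path, hist, hist, meta, dense_map)

    def test_missing_alleles_round_trip_as_missing(self, tmp_path, dense_map,
                                                   model3):
        panel = simulate_founders(model3, dense_map, 2, seed=8)
        H = panel.haplotypes.copy()
        H[0, :5] = MISSING
        panel = make_panel(dense_map, H, list(panel.ids))
        panel.to_vcf(tmp_path / "m.vcf")
        back = HaplotypePanel.from_vcf(tmp_path / "m.vcf", dense_map)
        assert (back.haplotypes[0, :5] == MISSING).all()
        assert np.array_equal(back.haplotypes, H)
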