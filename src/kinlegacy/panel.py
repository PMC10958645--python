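"""Phased haplotype panels and their VCF round-trip.

The :class:`HaplotypePanel` is the matching substrate: a (2 * n_individuals)
x n_sites matrix of 0/1 alleles over a shared mapped site index, with row
2*i / 2*i+1 holding individual i's two phased haplotypes.  Missing alleles
are stored as :data:`MISSING` and must be filled (per-site major allele,
mirroring matching on imputed genomes) before PBWT matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import GeneticMap

MISSING = np.uint8(255)


class PanelError(ValueError):
    """Raised for malformed or inconsistent panels."""


@dataclass
class HaplotypePanel:
    sites: pd.DataFrame          # chrom, bp, cM, ref, alt
    haplotypes: np.ndarray       # uint8 (2*n_ind, n_sites), 0/1/MISSING
    ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.ids), len(self.sites)):
            raise PanelError("haplotype matrix shape does not match ids/sites")
        if len(set(self.ids)) != len(self.ids):
            raise PanelError("duplicate individual ids")
        ok = (self.haplotypes <= 1) | (self.haplotypes == MISSING)
        if not ok.all():
            raise PanelError("alleles must be 0, 1 or missing")

    # -- accessors -------------------------------------------------------

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def individual_of(self, hap_row: int) -> str:
        return self.ids[hap_row // 2]

    def hap_rows(self, ind_id: str) -> tuple[int, int]:
        i = self.ids.index(ind_id)
        return 2 * i, 2 * i + 1

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        chrom_col = self.sites["chrom"].to_numpy()
        start = 0
        for chrom in dict.fromkeys(self.sites["chrom"]):
            n = int((chrom_col == chrom).sum())
            out[chrom] = slice(start, start + n)
            start += n
        return out

    def genetic_map(self) -> GeneticMap:
        return GeneticMap(self.sites[["chrom", "bp", "cM"]].copy())

    # -- manipulation ----------------------------------------------------

    def fill_missing_major(self) -> "HaplotypePanel":
        """Replace missing alleles by the per-site major allele.

        Emulates matching on complete imputed genomes: the PBWT needs a
        concrete allele at every site, and the flip-error channel of the
        degradation model stands in for imputation error.
        """
        H = self.haplotypes.copy()
        miss = H == MISSING
        if miss.any():
            obs = np.where(miss, 0, H).astype(np.int64)
            n_obs = (~miss).sum(axis=0)
            n_one = obs.sum(axis=0)
            major = (n_one * 2 > n_obs).astype(np.uint8)  # ties -> 0 (ref)
            H[miss] = np.broadcast_to(major, H.shape)[miss]
        return HaplotypePanel(self.sites, H, list(self.ids))

    def subset(self, ind_ids: list[str]) -> "HaplotypePanel":
        rows = []
        for i in ind_ids:
            a, b = self.hap_rows(i)
            rows.extend([a, b])
        return HaplotypePanel(self.sites, self.haplotypes[rows], list(ind_ids))

    @staticmethod
    def concat(panels: list["HaplotypePanel"]) -> "HaplotypePanel":
        """Stack individuals from panels sharing an identical site index."""
        first = panels[0]
        for p in panels[1:]:
            if not _same_sites(first.sites, p.sites):
                raise PanelError("site index mismatch between panels")
        ids: list[str] = []
        for p in panels:
            ids.extend(p.ids)
        H = np.vstack([p.haplotypes for p in panels])
        return HaplotypePanel(first.sites, H, ids)

    # -- VCF round-trip --------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write a phased VCF 4.2 with '|' separated GT fields."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(self.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.ids) + "\n")
            ref = self.sites.get("ref", pd.Series(["A"] * self.n_sites))
            alt = self.sites.get("alt", pd.Series(["G"] * self.n_sites))
            H = self.haplotypes
            code = {0: "0", 1: "1", int(MISSING): "."}
            for j in range(self.n_sites):
                row = self.sites.iloc[j]
                gts = "\t".join(
                    f"{code[int(H[2 * i, j])]}|{code[int(H[2 * i + 1, j])]}"
                    for i in range(self.n_ind))
                fh.write(f"{row['chrom']}\t{int(row['bp'])}\t.\t{ref.iloc[j]}\t"
                         f"{alt.iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path, gmap: GeneticMap | None = None) -> "HaplotypePanel":
        """Read a phased biallelic VCF; multi-allelic sites are excluded.

        Unphased genotypes ('/' separated with two called alleles) raise
        :class:`PanelError`.  Genetic positions come from ``gmap`` when
        given (interpolated at each bp), else from uniform 1 cM / 10 kb.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        chroms, bps, refs, alts = [], [], [], []
        cols = []
        for var in vcf:
            if len(var.ALT) != 1:
                continue  # biallelic PBWT: drop multi-allelic sites
            g = np.array(var.genotypes)  # (n, 3): a0, a1, phased flag
            called = (g[:, 0] >= 0) & (g[:, 1] >= 0)
            if np.any(called & (g[:, 2] == 0)):
                raise PanelError(
                    f"unphased genotype at {var.CHROM}:{var.POS}; phased GT required")
            col = np.empty(2 * len(ids), dtype=np.uint8)
            a0 = np.where(g[:, 0] < 0, int(MISSING), g[:, 0])
            a1 = np.where(g[:, 1] < 0, int(MISSING), g[:, 1])
            col[0::2] = a0
            col[1::2] = a1
            cols.append(col)
            chroms.append(var.CHROM)
            bps.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
        H = np.column_stack(cols) if cols else np.empty((2 * len(ids), 0), np.uint8)
        sites = pd.DataFrame({"chrom": chroms, "bp": bps, "ref": refs, "alt": alts})
        if gmap is not None:
            cm = np.empty(len(sites))
            for chrom, grp in sites.groupby("chrom", sort=False):
                cm[grp.index] = gmap.interp_cM(chrom, grp["bp"].to_numpy())
            sites["cM"] = cm
        else:
            sites["cM"] = sites["bp"] / 10_000.0
        sites = sites[["chrom", "bp", "cM", "ref", "alt"]]
        return cls(sites, H, ids)


def _same_sites(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if len(a) != len(b):
        return False
    return (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all() and \
        (a["bp"].to_numpy() == b["bp"].to_numpy()).all()
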