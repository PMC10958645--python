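"""On-disk study fixtures: phased VCFs plus metadata/truth TSVs.

Everything round-trips losslessly through the package's readers, so a
written fixture is a complete, self-describing input for the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ..genmap import GeneticMap
from ..panel import HaplotypePanel, PanelError


def write_fixture(outdir, historical: HaplotypePanel, cohort: HaplotypePanel,
                  metadata: pd.DataFrame, gmap: GeneticMap,
                  true_ibd: pd.DataFrame | None = None,
                  true_ancestry: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write VCFs (phased GT), the map and the metadata/truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if set(historical.ids) & set(cohort.ids):
        raise PanelError("historical and cohort ids overlap")
    if metadata["participant_id"].duplicated().any():
        raise PanelError("duplicate participant ids in metadata")
    paths = {
        "historical_vcf": out / "historical.vcf",
        "cohort_vcf": out / "cohort.vcf",
        "map": out / "genetic_map.tsv",
        "metadata": out / "metadata.tsv",
    }
    historical.to_vcf(paths["historical_vcf"])
    cohort.to_vcf(paths["cohort_vcf"])
    gmap.to_tsv(paths["map"])
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    if true_ibd is not None:
        paths["true_ibd"] = out / "true_ibd.tsv"
        true_ibd.to_csv(paths["true_ibd"], sep="\t", index=False)
    if true_ancestry is not None:
        paths["true_ancestry"] = out / "true_ancestry.tsv"
        true_ancestry.to_csv(paths["true_ancestry"], sep="\t", index=False)
    return paths


def read_fixture(outdir) -> dict:
    out = Path(outdir)
    gmap = GeneticMap.from_tsv(out / "genetic_map.tsv")
    bundle = {
        "map": gmap,
        "historical": HaplotypePanel.from_vcf(out / "historical.vcf", gmap),
        "cohort": HaplotypePanel.from_vcf(out / "cohort.vcf", gmap),
        "metadata": pd.read_csv(out / "metadata.tsv", sep="\t"),
    }
    for name in ("true_ibd", "true_ancestry"):
        p = out / f"{name}.tsv"
        if p.exists():
            bundle[name] = pd.read_csv(p, sep="\t")
    return bundle
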