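# kinlegacy

Identity-by-descent (IBD) analysis connecting historical genomes to a
large living cohort: segment detection, relationship-degree estimation,
genetic family reconstruction, geographic enrichment testing with privacy
masking, IBD-network clustering, and pedigree attachment-point inference.

The package addresses a problem from historical population genetics: a
small set of genotyped historical individuals (for example, imputed
low-coverage genomes from a historical cemetery) is compared against a
large cohort of present-day genotyped participants to find their living
relatives, localize those relatives geographically, and infer *where on
the historical family tree* each present-day lineage connects.  Because
real cohorts of this kind are private, the package ships a first-class
synthetic-data generator that reproduces the statistical structure of
such a study — admixed populations, multi-generation pedigrees, planted
relatives, and a degradation channel emulating imputed low-coverage
genomes — so every stage is testable end to end from a single seed.

## The models at the core

**IBD detection.** Haplotype matching uses the positional Burrows–Wheeler
transform (PBWT): one left-to-right sweep over the phased panel maintains
the positional prefix and divergence arrays and reports every maximal
allele-identical interval of at least *L* sites in O(sites × haplotypes).
The cM floor (default 7 cM) is translated per chromosome into the minimal
site count a qualifying window can contain.  Because degraded genomes
break long true segments, fragments are called down to half the floor,
same-pair fragments separated by ≤ 1 cM are stitched (gap included), and
the full floor is re-applied.  An independent brute-force maximal-run
scanner serves as the testing oracle: on error-free panels the two agree
exactly.

**Relatedness.** With diploid map length *D* (default 2 × 3,500 = 7,000
cM), degree-*d* relatives share an expected *D*·2⁻ᵈ, so the degree
estimate from a pairwise total *T* is round(log₂(*D*/*T*)), clamped to
[1, 12], with no degree assigned below 10 cM.  A total of 280 cM is 4% of
the genome and degree 5; 30 cM maps to degree 8 ("9th or closer").
Genetic families are connected components over pairs of degree ≤ 3.

**Enrichment.** Whether a focal subset (a region, an ancestry-filtered
cohort) carries more IBD connections than chance is tested by drawing
identically sized random subsets from the reference cohort without
replacement; p = (b+1)/(R+1), with the exact hypergeometric tail computed
alongside as a cross-check.  Geographic summaries round coordinates to
integers, downsample participants to 80%, mask cells with < 25 retained
participants and suppress any count of 1–4 (k ≥ 5 anonymity).

**Attachment inference.** For each external relative, every candidate
attachment point (node *v*, lineage degree *g*) of the historical
pedigree is scored by a composite likelihood: path degree *d* to each
genotyped member gives an expected segment count *a*(*rd*+*c*)·2¹⁻ᵈ
(*r* = map length in Morgans, *c* = chromosomes, *a* = common ancestors)
with Poisson counts and truncated-exponential segment lengths (mean
100/*d* cM).  The posterior is a softmax over candidates under a flat
prior.

## Worked example

```python
from kinlegacy import estimate_degree, genome_fraction
from kinlegacy.pipeline import RunConfig, run_pipeline

print(genome_fraction(280.0, 7000.0))   # 4.0  (% of diploid genome)
print(estimate_degree(280.0).degree)    # 5    (5th-degree relationship)
print(estimate_degree(30.0).degree)     # 8    (i.e. "9th-degree or closer")

report = run_pipeline(RunConfig(seed=1, outdir="demo_run"))
print(report["log"])
```

On the default synthetic study (27 historical individuals — five planted
families plus 12 singletons — and a ~2,100-member cohort over 22
chromosomes / 20,000 sites) the run prints, among other things:

```
"relate":  {"n_pairs": 276, "n_families": 5}
"enrich":  {"africa_connected": 0.002, "europe_connected": 0.001,
            "us_ge5ssa_connected": 0.001, "maryland_close": 0.001}
"link":    {"n_externals": 45, "upward_share": 0.89, "association_p": 0.001}
```

meaning: the five planted genetic families are reconstructed exactly; the
regions where relatives were planted are significantly enriched for IBD
connections under the randomization test; most external pedigrees attach
on the ancestor side of the historical family (collateral relatives); and
externals carrying the planted ancestry signature attach preferentially
through the un-genotyped father's lineage (permutation p ≈ 10⁻³).
`demo_run/` receives the full fixture (phased VCFs, genetic map, metadata)
plus segment, pair-summary, ancestry, geographic and network outputs.

A command-line entry point wraps the same stages:

```bash
kinlegacy simulate --seed 1 --outdir fixture/
kinlegacy detect-ibd --vcf-historical fixture/historical.vcf \
    --vcf-cohort fixture/cohort.vcf --map fixture/genetic_map.tsv \
    --min-cm 7 --out segments.tsv
kinlegacy run --seed 1 --outdir demo_run
```

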