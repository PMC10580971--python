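# peatmethane

Community-assembly and methane-kinetics analysis for peatland
methanogen/methanotroph marker-gene studies.

In *Sphagnum* peatlands, net methane emission is set by the balance between
methanogens (tracked by the *mcrA* gene) and methanotrophs (tracked by
*pmoA*), and the water table level is a dominant control on both. Studies of
this system combine marker-gene OTU tables with chamber flux measurements,
closed-bottle incubations and qPCR gene quantification, and ask whether the
microbial communities are assembled by stochastic (neutral) or deterministic
(niche) processes. This package implements that analysis chain as a tested,
reusable library with a synthetic-data module that provides known ground
truth for every estimator, so each statistic carries a recovery test.

It is aimed at microbial ecologists and biogeochemists who want these
standard analyses reproducible and verifiable rather than re-scripted per
study.

## What it computes

**Sloan neutral community model (NCM).** Under neutral assembly with local
community size *N* (reads per rarefied sample) and migration rate *m*, a
taxon with mean relative abundance p̄ has local relative abundance
q ~ Beta(*Nm*p̄, *Nm*(1−p̄)). Its occurrence frequency across samples is the
probability of detection at depth *N*; `fit_ncm` estimates *Nm* by least
squares on the occurrence–abundance curve, reports *R*², and partitions taxa
into above/within/below a 95% Wilson band around the prediction
(`partition_taxa`).

**Modified stochasticity ratio (MST).** For each within-group sample pair,
the observed Jaccard dissimilarity *D* is compared with the expectation *E*
under a null model that keeps each sample's richness and draws taxa with
probability proportional to their occurrence frequency:
MST = *D*/*E* if *D* ≤ *E*, else (1−*D*)/(1−*E*). 100% means the observation
matches the null (pure stochasticity); 50% is the conventional boundary
between more deterministic (<50%) and more stochastic (>50%) assembly.

**Levins niche breadth.** B<sub>j</sub> = 1/Σ<sub>i</sub>P<sub>ij</sub>²
over taxon *j*'s distribution of reads across samples: 1 for a strict
specialist, the number of samples for a perfect generalist.

**Co-occurrence networks.** Spearman correlations on relative abundances of
taxa above an overall relative-abundance floor (default 0.1%); edges at
|r| > 0.7 and p < 0.01; eight topology descriptors (nodes, edges, average
degree, average path length, clustering coefficient, diameter, density,
Newman modularity).

**Diversity and ordination.** Rarefaction (exact without-replacement
subsampling), Shannon/Gini-Simpson/Pielou indices, Bray-Curtis and Jaccard
dissimilarity, classical-scaling PCoA, and a seeded one-way PERMANOVA.

**Gas kinetics.** Static-chamber flux
F = (dc/dt)·(M/V₀)·(P/P₀)·(T₀/T)·H in mg CH₄ m⁻² h⁻¹; closed-bottle
potential methane production/oxidation with cumulative N₂-dilution
correction, in µg CH₄ g⁻¹ dry weight d⁻¹; qPCR standard curves with
amplification efficiency 10^(−1/slope) − 1 and the 90–110% / R² > 0.99
quality gate, and absolute abundances in copies per g fresh peat.

## Worked example

Generate a synthetic 48-sample study (4 sites × 4 depths × 3 replicates,
one niche-filtered marker, one neutral marker) and run the full pipeline:

```bash
python analysis/01_simulate_study.py
python analysis/02_run_pipeline.py
```

which prints:

```
24 outputs, 2 warnings
mcrA: NCM m=0.027 R2=-2.638 | MST=24.4% | niche breadth B=16.20 | PERMANOVA site p=0.0050
pmoA: NCM m=0.500 R2=0.991 | MST=68.0% | niche breadth B=20.74 | PERMANOVA site p=0.6000
```

The niche-leaning marker (generated under strong Gaussian water-table
filtering) fits the neutral model poorly (negative *R*²) and sits well below
the 50% MST boundary — deterministic assembly — while the neutral marker
(generated at *m* = 0.5) returns its true migration rate, a high *R*², and
an MST above 50%. Site structure is significant only where the environment
filters (PERMANOVA p = 0.005 vs 0.6).

The same stages are available as a CLI (`peatmethane simulate | diversity |
permanova | ncm | mst | niche | network | flux | incubation | qpcr | all`),
e.g.

```bash
peatmethane ncm --table results/demo/inputs/pmoA_otu_table.tsv --outdir out/
```

Drivers `analysis/03–05` run the ground-truth recovery experiments
(neutral-model parameter recovery, MST regime discrimination, PERMANOVA
calibration, gas/qPCR round-trips) and write their tables under
`results/benchmarks/`.

## Layout

```
src/peatmethane/   library (community, assembly, network, gas, synthetic,
                   pipeline, benchmarks, cli)
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. brute-force oracles
scripts/           acceptance.py
docs/methods.md    models, parameter choices, numerical decisions, limits
```
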