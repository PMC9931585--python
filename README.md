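# imctme

Spatial single-cell analysis of imaging mass cytometry (IMC) tissue
cores, for studies that relate the tumour immune microenvironment to
clinical outcome. The package covers the full analysis chain used in
tissue-microarray IMC cohorts — one ~1 mm² core per patient, ~35
antibody channels at ~1 µm/pixel — together with a synthetic cohort
generator so every stage can be developed and validated without any
patient data.

## What it computes

**Marker masks and phenotyping.** Each lineage channel is turned into a
curated binary mask (3×3 median filter → exact 1-D k-means quantization
into six intensity groups → selection of the brightest groups →
8-connected blob removal → optional adaptive refinement). For a cell
c with pixels j = 1..N_c, each pixel carries a presence vector over the
n lineage masks, E(p_j) = (p_{M_1}, …, p_{M_n}), p_{M_k} ∈ {0, 1}; the
cell's majority vector sums them, M_c = (Σ_j p_{M_1}, …, Σ_j p_{M_n}),
and argmax M_c assigns the lineage, with ties broken by the panel's
rank priority and marker-combination rules (e.g. CD68 ± CD163) resolved
by secondary-marker pixel majority. Expression is the raw per-channel
mean pixel value; display summaries are 95th-percentile normalized and
z-scored.

**Cell–cell interactions.** Cells within 6 px (minimum mask-to-mask
distance) interact. For each ordered type pair (A, B) the statistic is
the mean B-neighbour count over A cells; shuffling type labels over
fixed positions gives the null, and the add-one estimator
p = (1 + #{perm ≥ obs}) / (1 + n_perm) with 1,000 permutations calls
interaction or avoidance at p < 0.01, aggregated per histological
pattern as mean signed calls.

**Cellular neighbourhoods (CNs).** Every cell's window is the
type-frequency vector of its n = 10 nearest neighbours; windows pooled
over all cores are clustered by mini-batch k-means into tCN
neighbourhoods, each core's CN prevalence normalized to 100%.

**Survival.** Any per-patient quantity is z-scored over the cohort and
split at z = 0 into high (z ≥ 0) and low (z < 0) strata, compared with
the Kaplan–Meier estimator and the log-rank (Mantel–Cox) test
(χ² = (O − E)²/V with the standard tied-time hypergeometric variance).

**Outcome prediction.** Each channel image is embedded into a 2,048-d
vector (a pluggable backbone: the reference is an ImageNet-pretrained
ResNet-50; a deterministic download-free hash-projection backbone ships
for testing), embeddings are concatenated per core, reduced by
mini-batch sparse PCA to 9 components, and classified by an RBF-kernel
SVM with random oversampling under patient-grouped stratified 5-fold
cross-validation. Scores are compared to the baseline prediction score
(the modal-class fraction). Per-marker rankings and marker-subset
evaluations identify minimal predictive panels.

**Synthetic cohorts.** A marked point process places typed cells
(uniform baseline, Gaussian niches, displacement-induced pairwise
attraction/repulsion), renders them as discs, draws channels as
on/off-target means under multiplicative log-normal noise, and links
progression (logistic model) and survival (exponential proportional
hazards with independent censoring) to the realized spatial features.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/03_phenotyping.py` generates a 524-cell core at
realistic noise and phenotypes it:

```
524 cells phenotyped; accuracy vs planted labels: 100.0%

called composition (fraction of total cells):
core_id                  core
freq_total_B cell       0.097
freq_total_NK           0.105
...
```

and `python examples/06_survival.py` plants a protective lymphoid niche
in a 60-patient cohort and recovers it:

```
stratified 60 patients: 35 high / 25 low
log-rank chi-square = 8.817, p = 0.0030
events (high, low): (25, 20), expected: (33.4, 11.6)

Kaplan-Meier survival at 24 months: high = 0.76, low = 0.46
```

The high-prevalence stratum has fewer events than expected under the
null and better survival — the planted effect, read back by the
analysis chain.

A thin CLI mirrors the pipeline stages
(`imctme synth|masks|phenotype|interactions|neighborhoods|survival|predict|run`,
each with `--config`, `--seed`, `--out`, `--log-level`); real cohorts
can be read from multipage TIFFs or per-marker TIFF directories plus a
clinical CSV.

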