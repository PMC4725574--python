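# Methods

## Signal model

A marker with population B-allele frequency q (drawn once per marker map
from Uniform(0.05, 0.95)) carries b B alleles out of c chromosomal copies,
drawn binomially under Hardy–Weinberg. Its BAF mean is b/c (uniform noise
when c = 0, e.g. Y probes in a female sample) and its LRR mean is μ(c),
the copy-number response, linearly interpolated between
μ = {0: −3.5, 1: −0.66, 2: 0.0, 3: 0.40, 4: 0.68} (log2 units). These are
canonical Illumina-array expectations; they are configurable and nothing
downstream assumes their exact values, only that μ is increasing with
μ(2) = 0.

Mosaicism mixes two cell populations linearly in intensity space: with
anomalous fraction f, effective copy number is (1−f)c₁ + fc₂ and BAF mean
is ((1−f)b₁ + fb₂)/((1−f)c₁ + fc₂). The lost or gained copy is a uniformly
chosen existing allele, so heterozygous sites split symmetrically into two
bands displaced by d = f/(2(2−f)) (monosomy mosaic) or d = f/(2(2+f))
(trisomy/triploid mosaic) from 0.5. UPD chromosomes are diploid in LRR and
fully homozygous in BAF except an optional distal fraction p_r of markers
that revert to population heterozygosity (meiotic recombination before
monosomy rescue).

Noise defaults: LRR SD 0.20 per marker, BAF SD 0.03 at heterozygous bands,
halved and reflected inward at the 0/1 boundary for homozygous clusters
(so clean samples show no spurious heterozygosity). These emulate
blood-derived DNA on a ~550k-marker panel; the default map carries 22,000
autosomal, 1,000 X and 200 Y markers (~1,000 per autosome), a
reduced-density emulation chosen so whole-cohort simulation stays fast
while every chromosome-scale statistic remains well resolved (e.g. a 20%
distal UPD-recovery segment on chromosome 21 still spans ~200 markers).

What the generator does **not** model: probe-level X/Y channel intensity,
GC waves, plate/batch effects, cell-line artifacts, and segmental
(sub-chromosomal) mosaicism. Passing tests therefore demonstrate that the
detector correctly inverts this band model at realistic noise, not that it
is robust to every artifact of real arrays.

## Anomaly detection

Each chromosome is summarized by its mean LRR and its BAF heterozygosity
rate (fraction of observed BAF in [0.25, 0.75]). Both statistics are
z-scored against the sample's other autosomes, leave-one-out, so a large
anomaly cannot inflate its own reference SD. X is scored against all
autosomes; Y is judged only on absolute LRR.

Sex is predicted twice — single vs double X from the X het rate
(threshold 0.05) and Y presence from mean Y LRR (threshold −1.0) — and
combined; an XX call with X-dosage z above 5 becomes an XXX candidate.
Discordance with a reported sex is flagged, never auto-corrected.

The decision table requires corroboration from both channels:

* **UPD**: |z_LRR| ≤ 3 (diploid dosage) and z_het ≤ −3. A terminal
  heterozygous run is located by a changepoint objective (suffix het count
  minus 0.15 × suffix length, maximized); runs covering > 60% of the
  chromosome are ordinary heterozygosity and veto the call. The residual
  core must have het rate < 0.02; a terminal run of ≥ 25 markers makes the
  call `upd_partial_recovery`, otherwise `upd_complete`. The core-first
  ordering matters: with a recovered distal segment the whole-chromosome
  het rate exceeds any sensible LOH threshold, so the threshold is applied
  after stripping the detected run.
* **Gain/loss**: z_LRR beyond ±3 with a band-informative BAF pattern. Band
  deviation d̂ is the median |BAF − 0.5| over markers in (0.08, 0.92) — a
  window wide enough to hold the split bands up to f ≈ 0.85 while
  excluding homozygous clusters. d̂ ≥ 0.035 counts as a split; f̂ ≥ 0.9
  reports the constitutional (non-mosaic) class. An LRR excursion with
  fully normal BAF is reported as `normal` with a warning — this
  conjunction is what drives the false-call rate on clean diploid cohorts
  to zero while the raw 3 SD rule alone would flag a few chromosomes per
  hundred samples.
* **Diploid/triploid mosaicism** is genome-wide by construction and
  invisible to within-sample z-scores; it is called when ≥ 10 autosomes
  show a band split at near-normal z_LRR, with f̂ from the trisomy
  inversion of the median deviation.

The UPD dosage gate uses the same 3 SD bound as aneuploidy flagging. A
tighter gate (1.5 SD) was tried first and rejected ~13% of true UPD
chromosomes on LRR noise alone, because the leave-one-out z has t-like
tails with ~20 reference degrees of freedom.

X is run through the autosomal decision table only for samples whose
combined sex call is XX (a diploid-X baseline), which is how 45,X/46,XX
mosaics are detected; the hemizygous X of males is never classified there.

## CNV consensus

Same-sample, same-state calls from different algorithms overlapping by
≥ 1 bp are grouped transitively; the consensus interval is the group
intersection (conservative against boundary over-call; union available).
A chained group whose common intersection is empty falls back to the
union. Marker counts are recomputed from the map over the consensus
interval. The `large` tier (> 1 Mb, > 100 markers, strict inequalities)
accepts any algorithm support; the `phenotype` tier (> 100 kb, ≥ 10
markers) demands all three algorithms. Rarity clusters events by ≥ 0.5
reciprocal overlap, same state, transitively (union–find): cluster of one
event ⇒ singleton, carrier frequency > 1% ⇒ common, else rare.
Transitive clustering can chain distinct events bridged by one long call;
this is accepted for its order-invariance.

## Statistics

Exact 2×2 tests fix both margins; the two-sided p sums hypergeometric
probabilities of tables no more probable than the observed one (with a
1e−7 relative tie tolerance), matching the convention of standard exact
test implementations. Both the cross-product odds ratio (a·d)/(b·c) and
the conditional-MLE odds ratio (noncentral hypergeometric likelihood, with
exact tail-inversion 95% CI) are always reported, because published tables
mix the two conventions.

The burden layer computes 7 per-sample statistics (carrier indicator, CNV
count, total kb, mean length, genes covered, mean genes per CNV, genic-CNV
count) per CNV class {all, deletions, duplications} and contrast
{cases vs all controls, vs screened, vs population}, i.e. 63 tests, each a
one-sided (case > control) label permutation of the difference in arm
means with add-one empirical p = (1 + #{perm ≥ obs})/(n_perm + 1).
Zero-CNV samples contribute zeros to counts and are excluded from per-CNV
means. "Genes covered" sums per-CNV gene counts (a gene hit by two CNVs
counts twice), since consensus records carry counts, not gene identities.
Bonferroni control uses 0.05/63 = .00079.

Phenotype association is unconditional OLS with listwise deletion
(covariate hooks exist; none are default). The effective number of tests
among the five phenotypes is computed from the correlation-matrix
eigenvalues by both Nyholt (1 + (M−1)(1 − Var λ/M), variance with ddof 1)
and Li–Ji (Σ 1{λ≥1} + frac(λ)); the Nyholt Bonferroni correction is the
downstream default, with the Šidák variant reported alongside. Power uses
the noncentral F distribution with ncp = f²·n for the linear design, and
the two-proportion z formula or exact simulation through the Fisher test
for carrier-frequency designs.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere in memory; BED's 0-based
  half-open convention is converted only at the I/O boundary.
* Missing LRR/BAF are NaN and excluded from all summaries; readers reject
  malformed input with file/line/field in the message rather than coerce.
* Every stochastic operation takes an explicit seed; cohorts derive
  per-sample child seeds from (seed, sample index), so single samples are
  reproducible in isolation and whole runs are byte-identical under a
  fixed config.
* The pipeline's per-algorithm call sets are generated from the CNV truth
  table (emission probability 1−fn per algorithm, Gaussian boundary
  jitter, Poisson false positives anchored at a random marker with
  log-uniform 20–500 kb size) rather than re-segmented from the intensity
  signal; segmentation HMMs are out of scope and a truth-driven caller
  model is what makes consensus behaviour testable against known ground
  truth.
* Pipeline-planted CNVs are log-uniform 200 kb – 5 Mb so that the filter
  tiers stay populated at reduced marker density; case deletions are
  biased toward gene intervals (rejection sampling) to plant the
  genes-per-deletion enrichment the burden grid is designed to detect.
* Problem sizes used by the test suite and acceptance script — 400-sample
  classification cohort, 25 replicates per mosaic fraction, 500–1,000
  permutation/regression cohorts — were chosen to make Monte-Carlo noise
  small relative to the asserted margins.

## Known limitations

* Thresholds are calibrated against this generator's noise model; real
  arrays with GC waves or higher BAF drift would need the exposed
  thresholds retuned.
* The mosaic-fraction estimator assumes a single anomalous clone per
  chromosome; multi-clone mixtures bias f̂ toward an average.
* Segmental UPD, mosaic segmental CNVs, and X-inactivation-related BAF
  skew are not modelled or detected.
* The published corrected α of .0073 for the phenotype layer cannot be
  reconstructed without the original trait correlation matrix (no
  v_eff ≤ 5 method yields α/v_eff = .0073 from five traits); the package
  computes its corrections from the data at hand and displays published
  values only for comparison. Likewise the published power figures for
  the two-proportion designs depend on unrecoverable calculator settings;
  only the linear-model figure (88%) is reproduced exactly.
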