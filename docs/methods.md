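# Methods

## Model and assumptions

The pipeline treats a patient's inherited variant landscape as a noisy
read-out of a latent "recurrence-prone" network state. Its stages and the
assumptions behind them:

**Germline zygosity from paired VAFs.** In a diploid normal sample, reads
supporting a heterozygous variant should arrive at ~50% frequency and a
homozygous one near 100%; binomial read sampling spreads these around their
expectation. The filter reads the printed thresholds literally on the
percent scale with inclusive endpoints: homozygous at normal VAF ≥ 90%,
heterozygous in [45%, 65%]. Everything else — including tumor reads
contaminating the normal at low VAF — is treated as not germline. Variants
lacking a normal VAF cannot be classified and are dropped with a warning
count. Multi-allelic records are split per alternate allele before
classification. The functional gate is a pure consumer of annotation
scores; the default rule is a permissive OR (any annotator calls the
variant damaging: CADD phred ≥ 15, MutationTaster "disease_causing",
CRAVAT p < 0.05), with an AND variant selectable. A variant with no
annotation evidence is never retained.

**Propagation.** The update is the random-walk-with-restart form with
symmetric degree normalization (the standard reading of seed-based "heat
diffusion"); the source text of this method family does not write the
equation, so the rule, α, the tolerance and the seed weighting are design
choices of this package and are all exposed in `PropagationConfig`:

* `alpha = 0.7` — retention; heat keeps walking with probability α and
  restarts at the seeds with 1 − α. Values in (0, 1) guarantee a unique
  fixed point; the iteration contracts by factor α per step, so the L1
  tolerance `1e-8` is reached in ≲ 55 iterations at the default.
* Seeds are weighted uniformly (1/|seeds|) rather than unit-weighted so
  that heavily mutated samples do not dominate the aggregated matrix, and
  each final column is renormalized to sum exactly to one. Column sums of
  the raw fixed point are not conserved under symmetric normalization;
  renormalization is what makes columns comparable.
* Samples whose seeds all miss the network are excluded and reported, not
  imputed.

A consequence worth knowing: because each column's mass is fixed at one, a
sample with more seeds spreads its heat more widely, so *any* systematic
group difference in seed counts leaks a small opposite-signed shift into
every non-seeded gene. This "burden anti-signal" is real, not an artifact
of the generator — screening therefore sees both the localized planted
signal (positive) and the diffuse burden signal (negative), and the
two-sided round test can hit on either. The defaults below were chosen so
that gene-level ranking still isolates the localized signal.

**MSS screening.** Per hallmark and per round: 30 genes drawn uniformly
from the hallmark pool (restricted to network genes), a class-stratified
80% sample subset, and a two-sided rank-sum test on the per-sample mean
heat of the drawn genes. Rounds with p < `hit_alpha` are hits; genes are
ranked by their hit-round frequency (ties broken lexicographically). The
rank-sum statistic was preferred to a t-test because heating scores are
strongly right-skewed; the t-test remains selectable. The round test is
computed as a batched normal-approximation Mann–Whitney (continuity
corrected), identical to scipy's asymptotic two-sided p on these sample
sizes — this is what makes 10⁴ rounds per hallmark cheap. Defaults:
`n_rounds = 10000`, `hit_alpha = 0.05`, `min_hits = 600`. The hit floor
must sit well above the binomial null expectation `hit_alpha · n_rounds`
(= 500): a floor at the null mean would let ~half of all uninformative
hallmarks emit signatures by chance. 600 is ≈ +4.6 SD above the null.
Frequency ranking needs many rounds because the presence of one gene among
30 shifts a round's statistic by only a few percent; the per-gene rate
differences are small and concentrate like √n_rounds.

**CSS voting.** Pearson correlation of a sample's profile (restricted to
signature genes) against the two centroids; the larger r wins, an exact
tie goes to low risk (an arbitrary but fixed and documented choice). A
signature abstains when over half its genes are missing, fewer than two
are available, or either correlation is undefined. Abstentions shrink the
effective vote count and the cutoffs are rescaled by
`S_effective / S` (rounded half down), so missingness cannot force a low
call. Cutoffs are grid-searched over all `0 ≤ K_low < K_high ≤ S` on the
testing split only, maximizing low-risk accuracy + high-risk accuracy
subject to ≥ 50% of testing samples receiving a call; ties prefer the
widest unpredicted band, then the smallest `K_low`. Expression-based
classification reuses the gene lists and cutoffs unchanged; centroids are
recomputed from per-gene z-scored expression using training-split mean/SD
(no leakage), with leave-one-out centroids for samples inside the training
split.

**Evaluation.** The four table metrics follow the clinical footnote
definitions (accuracy = purity of a predicted group, recall = coverage of
a true group), computed over called samples only; empty denominators are
NA, never 0. The KM-curve "two-sided χ² test" is implemented as the
log-rank test, whose statistic is χ²(1); a from-first-principles
`logrank_statistic` is kept alongside the lifelines-backed test for
cross-checks and permutation use. Cox models (lifelines partial
likelihood) encode stage ordinally I–IV and nodal status 0–3, dropping
X/NA; non-convergence is reported per model. Group contrasts use Welch's
two-sided t-test with raw p-values by default (Benjamini–Hochberg behind a
flag).

**Oncotype DX.** The published Paik et al. 21-gene formula is the
referent: reference centering on ACTB/GAPDH/GUSB/RPLP0/TFRC, group scores
HER2 = 0.9·GRB7 + 0.1·ERBB2 (floor 8), ER = (0.8·ESR1 + 1.2·PGR + BCL2 +
SCUBE2)/4, proliferation = mean of MKI67/AURKA/BIRC5/CCNB1/MYBL2 (floor
6.5), invasion = mean of CTSV/MMP11; RSu = 0.47·HER2 − 0.34·ER +
1.04·prolif + 0.10·invasion + 0.05·CD68 − 0.08·GSTM1 − 0.07·BAG1; RS =
20·(RSu − 6.7) clamped to [0, 100]; bins low < 18 ≤ intermediate < 31 ≤
high. Every coefficient, floor and threshold lives in `OncotypeModel` so a
variant of the formula can be dropped in from YAML. For FPKM-style input
the matrix is log2(x+1)-transformed before reference centering. In paired
comparisons with the CSS, intermediate-risk samples are excluded by
default (merging them into high risk is a flag), since two-bin tables do
not say how three bins were collapsed.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the
conditions under which the pipeline's properties are asserted.

* **Network**: preferential attachment (Barabási–Albert), 600 genes, 3
  edges per newcomer — scale-free like real interaction networks, with
  hubs for propagation to concentrate on.
* **Planted signal**: 8 driver genes chosen uniformly; the *informative*
  set is the drivers plus their first neighbors (typically 40–80 genes).
  Recurred samples draw functional germline genes at 3× the base rate on
  the informative set only. Because the signal lives in a network
  neighborhood rather than a fixed list, propagation — not raw mutation
  counting — is what recovers it.
* **Seed rate**: 60 expected functional germline genes per non-recurred
  sample. A high base rate keeps the group difference in *total* seed
  counts small relative to the per-gene informative contrast; with sparse
  seeding the burden anti-signal described above dominates and
  frequency ranking degrades (measured during design: recovery plateaus
  near 50% at low base rates).
* **Hallmarks**: 10 sets of 150 genes; the first two carry the signal with
  informative genes as a ~25% minority diluted in background, the rest are
  pure background. The minority design is what makes screening
  non-trivial: only informative-rich draws separate the classes strongly.
* **Variants**: per seeded gene 1–2 functional records (CADD 15–40), het
  with probability 0.8 else hom; normal VAF is binomial(coverage, p)/
  coverage with p = 0.5/1.0/0.25 for het/hom/somatic contaminant and
  Poisson(80) coverage. Benign germline background (CADD < 15) and ~20%
  somatic contaminants make both filter gates non-trivial.
* **Cohort design**: 200 training / 60 testing / 200 validation samples,
  15% recurrence. Disease-free survival is exponential with rates
  0.02/month (recurred) vs 0.005/month (non-recurred) — medians ln2/λ ≈
  34.7 vs 138.6 months — censored by an independent U(0, 120 months)
  draw. Age, stage and nodal status are generated independent of the
  planted signal, so clinical covariates should not out-predict the
  signatures.
* **Expression / metagenes**: standard normal per gene; informative genes
  shifted by `expr_shift` (default 0.8 SD) in recurred samples. Twelve
  leukocyte metagene profiles (MDSC, E-Memory CD8, DC+, CD8+, Tfh, Monos,
  memory B, B cell+, NK−, MC−, γδ T, neutrophils) with signed group
  shifts — memory B and resting mast cells up in the recurred group, most
  others down.
* **Null mode**: `seed_enrichment = 1` and `expr_shift = 0` make the
  generator label-permutation-invariant; nothing downstream can beat
  chance, which is what the calibration tests assert.

What the generator does **not** emulate: linkage between variants, tumor
subclonal structure, read-level artifacts, realistic gene-length/coverage
variation, correlated expression modules, or the true size of exome
cohorts (a real network has ~6000 genes and ~60k interactions; tests run
at a few hundred genes). Passing tests therefore demonstrate the
machinery's correctness and calibration under the stated statistical
structure, not clinical performance.

## Numerical choices and degenerate inputs

* Propagation cannot diverge for α < 1; the 1000-iteration cap is a guard.
  Gene symbols are matched case-insensitively (upper-cased); unmatched
  seeds are logged and dropped.
* Hallmark pools smaller than the signature size are skipped with a
  warning; identical class centroids are flagged as degenerate.
* Exact Pearson ties → low; undefined correlations → abstention; a sample
  with all signatures abstaining is unpredicted.
* Per-hallmark RNG streams are spawned from one seed keyed by hallmark
  order, so adding or removing a hallmark leaves the others' draws
  unchanged; all generators are `numpy` `default_rng` and every public
  entry point is deterministic given its seed/config.
* Problem sizes in the test suite are scaled to run in minutes: the
  calibration suite uses 300-gene cohorts with 500-round screens, the
  recovery suite the full 600-gene defaults over 10 generator seeds.

## Known limitations

* The MSS reconstruction is faithful in spirit — randomized gene/sample
  screening with frequency ranking and a fixed 30-gene output — but the
  original's round-level statistic and hit criterion are not public;
  conclusions about the original algorithm's exact gene lists cannot be
  drawn.
* Grid-searched vote cutoffs on a 60-sample testing split are
  high-variance; the fit report retains the full grid so the flatness of
  the objective can be inspected.
* The Oncotype comparison applies an RT-PCR-calibrated formula to other
  expression scales; with reference-centered RNA-seq data the published
  group floors frequently bind, which compresses low-end scores. On
  synthetic cohorts the comparison direction is data-dependent and is
  reported without claim.
* High-risk calls are much less accurate than low-risk calls at a 15%
  recurrence rate; the method is a rule-out more than a rule-in, and the
  unpredicted band absorbs genuinely ambiguous samples.
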