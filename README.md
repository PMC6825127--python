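# germline-nog

Recurrence-risk prediction for cancer patients from their **germline**
(inherited) genome. Most prognostic genomic tests read the tumor; this
package implements a pipeline that instead asks whether the constitutional
variants a patient was born with — observed in the healthy tissue of a
tumor/normal exome pair — predict whether an ER+ breast tumor will recur.
It is aimed at computational biologists who want to run, stress-test or
extend this class of network-based germline prognostic models, and it ships
a synthetic-cohort generator so every stage is testable without any
protected data.

## The method

1. **Germline calling from paired VAFs.** A variant is germline homozygous
   when its variant allele frequency (VAF) in the *normal* sample is
   ≥ 90%, heterozygous when it lies in the closed window 45–65%, and is
   discarded otherwise (somatic leakage, noise). Only variants flagged
   damaging by functional annotators (CADD phred ≥ 15, MutationTaster
   "disease causing", CRAVAT p < 0.05 — scores are inputs, never computed)
   are kept. The genes with ≥ 1 retained variant are a sample's **seeds**.

2. **Network propagation.** Seeds act as heat sources on a gene–gene
   recurrence network. With the symmetric-normalized adjacency
   `W = D^-1/2 A D^-1/2`, the update

   `F_{t+1} = α · W F_t + (1 − α) · F_0`,   `F_0` uniform over seeds,

   is iterated to its fixed point `(1−α)(I−αW)^-1 F_0` (α = 0.7), turning a
   binary mutation profile into a continuous per-gene **heating score**;
   each sample's scores are normalized to sum to one.

3. **MSS signature discovery.** For each cancer-hallmark gene set, Multiple
   Survival Screening draws thousands of random 30-gene subsets and
   stratified sample subsets, marks a round a *hit* when the drawn genes'
   mean heat separates recurred from non-recurred samples (two-sided
   rank-sum, p < 0.05), and ranks genes by hit frequency. Hallmarks whose
   hit count clears a floor emit a 30-gene **NOG signature** with low/high
   risk centroids (per-gene class means).

4. **NOG_CSS ensemble.** Each signature votes per sample by Pearson
   correlation against its two centroids. Vote cutoffs `K_low < K_high`
   are grid-searched on a held-aside testing split: ≤ `K_low` high votes
   calls a sample **low risk**, ≥ `K_high` calls it **high risk**, the band
   between stays **unpredicted**. The same signatures and cutoffs can also
   classify expression profiles (leave-one-out centroids, training-split
   z-scoring).

5. **Evaluation.** Accuracy/recall per predicted group, Kaplan–Meier
   curves with the log-rank χ² test, Cox proportional-hazards covariate
   comparison, germline burden contrasts, leukocyte metagene / TIL-fraction
   Welch t-tests, and a head-to-head with the Oncotype DX 21-gene
   recurrence score (Paik formula, RS = 20·(RSu − 6.7) clamped to 0–100).

## Worked example

```python
import germline_nog as gn

cohort = gn.generate_cohort(gn.SyntheticConfig(rng_seed=7))
result = gn.run_pipeline(cohort, mss_config=gn.MSSConfig(rng_seed=7))

print(f"signatures emitted : {len(result.signatures)}")
print(f"CSS cutoffs        : K_low={result.css.K_low}, K_high={result.css.K_high}")
m = result.metrics["valid"]
print(f"validation metrics : low acc {m.low_accuracy:.1f}%  high acc {m.high_accuracy:.1f}%")
chi2, p = result.validation_logrank
print(f"validation log-rank: chi2={chi2:.2f}, p={p:.3g}")
```

prints

```
signatures emitted : 9
CSS cutoffs        : K_low=3, K_high=6
validation metrics : low acc 95.6%  high acc 25.0%
validation log-rank: chi2=3.20, p=0.0735
```

Nine hallmarks emitted a 30-gene signature; a sample with ≤ 3 of 9 high
votes is called low risk and with ≥ 6 high risk. On the held-out validation
split 95.6% of predicted-low samples did not recur, while only 25% of
predicted-high samples recurred — the germline pipeline is a reliable
rule-out and a weak rule-in, the asymmetry this class of method shows on
real cohorts too. The log-rank test compares disease-free survival between
the two predicted groups.

The same estimators are exposed scikit-learn style
(`NetworkPropagator`, `MSSScreener`, `CSSClassifier`, `OncotypeRS` with
`fit`/`transform`/`predict` and `get_params`), and a thin CLI covers the
file-based workflow:

```bash
germline-nog simulate --config sim.yaml --out data/
germline-nog call --vcf-dir data/vcf --out seeds.tsv
germline-nog propagate --network data/network.tsv --seeds seeds.tsv --out heat.tsv
germline-nog mss --heat heat.tsv --clinical data/clinical.tsv --gmt data/hallmarks.gmt --out sigs/
germline-nog css-fit --signatures sigs/signatures.tsv --heat heat.tsv --clinical data/clinical.tsv --out model.json
germline-nog predict --model model.json --heat heat.tsv --out calls.tsv
germline-nog evaluate --calls calls.tsv --clinical data/clinical.tsv --out report/
```

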