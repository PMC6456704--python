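# episcan

Two-stage exhaustive SNP–SNP epistasis analysis for case-control cohorts,
with a synthetic-cohort generator providing ground truth for every stage.

The protocol:

1. **Marker QC** — Hardy–Weinberg exact test (P ≥ 10⁻⁶) and minor-allele
   frequency (≥ 10⁻⁵) filters.
2. **Additive scan** — per-marker logistic regression of status on additive
   dosage plus covariates (principal components, batch indicators), Wald P.
3. **Independence screen** — pool markers with scan P < 5×10⁻⁸, drop
   perfect duplicates, refit one joint model, keep markers with joint
   P < 0.05. These form the *additive background*.
4. **Pair screen** — exhaustive covariate-free approximate interaction test
   over all marker pairs using bit-plane popcount contingency tables and a
   Kirkwood-superposition statistic that upper-bounds the exact 4-df LRT;
   retain pairs with approximate P < 10⁻¹⁰ and dosage r² < 0.2.
5. **Exact tests** — covariate-adjusted 4-df interaction likelihood-ratio
   test (genotype-factor coding, four product terms), unconditional and
   conditional on the additive background; significance at 10⁻¹³
   (genome-wide) and 1.1×10⁻⁸ (chip-wide) on the conditional P.
6. **Replication** — rerun the conditional test in a disjoint replication
   cohort; a pair replicates at P < 0.05.
7. **Effects** — NOIA-style orthogonal decomposition (A1, A2, D1, D2 and
   four epistatic products) and observed-scale variance accounting across
   nested models.

## CLI

```sh
# full protocol from a flat YAML config
episcan run --config run.yaml

# individual stages
episcan additive --bfile disc --covar disc.covar --out out/
episcan screen   --bfile disc --covar disc.covar --p 1e-10 --r2 0.2 --out candidates.tsv
episcan exact    --bfile disc --covar disc.covar --candidates candidates.tsv \
                 --background out/background.tsv --out results.tsv
episcan effects  --bfile disc --covar disc.covar --pairs results.tsv \
                 --background out/background.tsv --out out/
```

Inputs are PLINK bed/bim/fam triplets (SNP-major) plus a whitespace- or
tab-delimited covariate file keyed by FID/IID. A run config looks like:

```yaml
bfile: disc
covar: disc.covar
replication_bfile: rep
replication_covar: rep.covar
out_dir: out
screen_p: 1.0e-10
screen_r2: 0.2
```

Synthetic cohorts (LD blocks, planted additive and epistatic effects,
batches, subpopulations) are generated with
`episcan.synthetic_data.simulate_cohort` and written to disk with
`write_cohort`; `split_cohort` produces stratified discovery/replication
halves.

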