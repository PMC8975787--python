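# chickadmix

Hybrid ancestry and body-condition analysis for a two-species songbird
contact zone.

Black-capped and mountain chickadees overlap across much of western North
America and occasionally hybridize. A recurring question in such systems
is whether co-occurrence carries a fitness cost: are birds in sympatry in
worse body condition than conspecifics in allopatry, and is cryptic hybrid
ancestry part of the pattern? `chickadmix` implements the full analysis
chain for that question so it can be run, tested, and audited end to end:

1. **Genotype I/O and site filters** — minimal VCF (GT-only) in/out, site
   QUAL ≥ 30, minor-allele-frequency and missingness filters, optional
   depth bounds.
2. **Diagnostic loci** — per-SNP Weir–Cockerham F_ST between two parental
   reference panels; loci with F_ST > 0.65 are retained as
   ancestry-informative.
3. **Hybrid index** — for each bird, the proportion h ∈ [0, 1] of alleles
   from parental population B under the Buerkle binomial-mixture
   likelihood (genotype at locus l ~ Binomial(2, (1−h)p_Al + h·p_Bl)),
   sampled by MCMC (uniform prior, 6000 iterations, burn-in 3000) with a
   grid-ML cross-check; folded to g(h) = 0.5 − |h − 0.5| and called hybrid
   when g(h) ≥ 0.20.
4. **Scaled mass index** — body condition as SMI_i = M_i·(L0/L_i)^b_SMA,
   with b_SMA from standardized major axis regression of ln-mass on
   ln-tarsus per species; sympatry vs allopatry compared by Welch's t.
5. **Model selection** — all-subsets Gaussian models of SMI (sex, age,
   sympatry, elevation × latitude, optional hybrid index, optional random
   intercept for year), ranked by AICc, full model averaging over the
   ΔAICc ≤ 4 set with Buckland unconditional standard errors.

A synthetic-data module generates cohorts with exactly the structure the
chain assumes — two drifted parental populations with a near-fixed locus
tail, F1/backcross classes, mass–tarsus allometry with configurable
condition deficits — so every stage is testable without any field data.
See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Run the bundled demo (synthetic cohort of 220 birds, 2000 loci, ~20 s):

```sh
chickadmix run examples/demo_config.yaml
```

The run directory gets per-stage tables (`fst_table.tsv`,
`hybrid_indices.tsv`, `smi.tsv`, `model_set_A.tsv`,
`averaged_coefficients_A.tsv`, ...) plus `report.json`, which for this
config contains (abridged):

```json
{
  "n_loci_after_filter": 1989,
  "n_diagnostic_loci": 67,
  "hybrid_summary": {
    "n_hybrids": 20,
    "n_sympatric": 170,
    "percent_hybrid": 11.8
  },
  "condition_comparisons": {
    "A": {
      "mean_sympatric": 10.71,
      "mean_allopatric": 11.3,
      "percent_lower": 5.5,
      "t": -4.436,
      "df": 36.41,
      "p": 8.1e-05
    }
  }
}
```

Reading it: 67 of 1989 post-filter loci are diagnostic (F_ST > 0.65
between the parental panels); 20 of the 170 sympatric birds (11.8%) carry
a folded hybrid index ≥ 0.20; and sympatric species-A birds average 5.5%
lower SMI than allopatric ones (10.71 g vs 11.30 g at the standard tarsus
length), a difference the Welch test puts far beyond chance — the
generator had planted a 5% sympatric mass deficit, which the chain
recovers. The same quantities appear as a strongly supported sympatry
term in `averaged_coefficients_A.tsv`.

The library surface mirrors the stages (`read_vcf`, `filter_sites`,
`fst_scan`, `select_diagnostic_loci`, `estimate_h_mcmc`,
`rescale_hybrid_index`, `fit_sma`, `compute_smi`, `compare_groups`,
`enumerate_models`, `model_average`, ...), and each CLI subcommand
(`simulate`, `filter`, `fst`, `hindex`, `smi`, `compare`, `average`)
consumes and produces the documented plain-text formats, so any stage can
be run or replaced on its own.

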