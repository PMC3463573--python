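# mitopop

Mitochondrial phylogeography toolkit: haplotype diversity statistics,
neutrality tests, mismatch-distribution expansion dating, and
median-joining haplotype networks for aligned haploid (mtDNA) sequence
samples — with a built-in neutral coalescent simulator so the whole
pipeline runs and calibrates itself without any external data.

It is aimed at population geneticists analysing intraspecific mtDNA
surveys (the motivating case is the *Daphnia pulex* species complex:
ND5/COX1 fragments, lineages sampled across many collection sites) who
want the classical demographic-history toolkit as tested, scriptable
Python instead of a chain of GUI programs.

## What it computes

Given an alignment of n sequences, after collapsing identical sequences
into haplotypes (complete deletion of gap/ambiguous columns):

* **Diversity** — segregating sites S; haplotype count K; haplotype
  diversity H = n/(n−1)(1 − Σp²); nucleotide diversity π (mean pairwise
  per-site distance, Jukes–Cantor corrected per pair), partitioned into
  synonymous π_s and nonsynonymous π_n by Nei–Gojobori counting under
  the invertebrate mitochondrial code.
* **Neutrality** — Tajima's D = (θ_π − S/a₁)/√(e₁S + e₂S(S−1)) and
  Fu's Fs = ln(S′/(1−S′)) with S′ = Pr(K ≥ k_obs) under the Ewens
  sampling formula; p-values from constant-size coalescent replicates
  conditioned on the observed S. Both go strongly negative under recent
  expansion.
* **Mismatch / expansion** — the pairwise-difference histogram is fitted
  by least squares with the sudden-expansion model
  F_i(τ, θ₀) = Σ_j e^(−τ) τ^j/j! · θ₀^(i−j)/(θ₀+1)^(i−j+1);
  goodness of fit (SSD), Harpending's raggedness and a 95% percentile
  CI for τ come from a parametric bootstrap.
* **Dating** — τ = 2µt with µ the whole-haplotype per-generation rate,
  so t = τ/(2 µ_site L) generations, converted to years with a
  generations-per-year range.
* **Networks** — median-joining haplotype networks (ε-relaxed minimum
  spanning network plus majority-consensus median vectors) with MP
  post-processing that keeps only nodes/links on shortest spanning
  (Steiner) trees.
* **Simulation** — a neutral coalescent generator (constant size or
  sudden expansion, finite- or infinite-sites mutation) used for null
  distributions, bootstraps and synthetic datasets.

## Worked example

Simulate an expanded population and analyse it end to end:

```bash
mitopop simulate --n 60 --length 500 --theta0 1.0 --theta1 1000 \
    --tau 3 --seed 5 --sites 20 --out-prefix syn
mitopop neutrality syn.fasta --reps 2000 --seed 2
mitopop mismatch  syn.fasta --reps 1000 --seed 2
mitopop date --tau 2.88 --length 496
```

The neutrality call on this fixture prints (abridged):

```json
{"d": -2.7271, "fs": -91.11, "p_d": 0.0, "p_fs": 0.0,
 "n": 60, "s": 95, "k": 56, "theta_pi": 4.366, "tail": "lower"}
```

— D and Fs far below zero with p < 1/reps: the excess of rare variants
and of haplotypes that recent expansion produces. The mismatch call fits
τ̂ = 4.31 (95% CI 2.71–5.01 on this draw; the truth τ = 3 sits inside)
with a smooth unimodal histogram (raggedness 0.022, P = 0.34; SSD
P = 0.50, so the expansion model is not rejected).
The `date` call converts a mutational-time estimate using the direct
mitochondrial rate estimate µ = 6.6×10⁻⁸/site/generation:

```json
{"generations_rounded": 44000, "years_rounded": [8800, 22000]}
```

i.e. τ = 2.88 on a 496-nt fragment dates an expansion to ~44,000
generations, or 8,800–22,000 years ago for an organism with 2–5
generations per year.

The same analyses are available as a one-shot pipeline
(`mitopop run-all config.yaml`) that writes per-stage TSV/JSON/GraphML
artifacts and a manifest with seeds and input checksums, and as plain
library calls (`mitopop.diversity_stats`, `mitopop.fit_expansion`,
`mitopop.median_joining`, ...).

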