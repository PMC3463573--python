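# Methods

`mitopop` implements the statistical core of a mitochondrial
phylogeography study: given an alignment of haploid (mtDNA) sequences it
summarises polymorphism, tests the neutral constant-size null, fits a
sudden-expansion model to the mismatch distribution, dates the expansion
in mutational time, and draws a median-joining haplotype network. This
note records the models, the conventions chosen where the literature
leaves them open, and what the simulation-based tests do and do not
establish.

## Site handling

All alignment-wide statistics (segregating sites, nucleotide diversity,
haplotype identity, distance matrices, mismatch histograms) are computed
over *retained* columns: any column containing a gap, `N` or IUPAC
ambiguity code in any sequence is removed first (complete deletion). A
single consistent site set keeps S, pi and pairwise distances mutually
coherent; the cost is that one unresolved individual removes a column for
everyone, so heavily incomplete sequences should be excluded before
analysis. Sequences that differ only inside deleted columns collapse to
the same haplotype. The synonymous/nonsynonymous machinery is the one
exception: it works codon-by-codon in the supplied reading frame and
skips, per sequence pair, codons in which either copy carries a non-ACGT
symbol or a stop (pairwise codon deletion), because complete deletion
would destroy the frame.

## Diversity statistics

* Haplotype diversity `H = n/(n-1) * (1 - sum p_i^2)` — the probability
  that two randomly drawn sequences represent different haplotypes, with
  the small-sample correction.
* Nucleotide diversity pi is the mean pairwise per-site p-distance;
  with `jc_correct=True` (default for reported values) each pairwise
  distance is first corrected for multiple hits with Jukes–Cantor,
  `d = -(3/4) ln(1 - (4/3) p)`. Correction is applied **per pair**, then
  averaged; a flag exists to report the uncorrected mean as well. Pairs
  reaching `p >= 0.75` raise a domain error rather than being silently
  clamped — at that divergence the model is inapplicable and the user
  should know.
* pi_s and pi_n partition sites and differences by unweighted
  Nei–Gojobori (1986) counting: each codon position contributes the
  fraction of its three possible single-base changes that are synonymous
  (so synonymous + nonsynonymous sites sum to exactly 3 per codon), and
  differences between codons are averaged over all orderings of the
  changed positions, excluding pathways through stop codons whenever a
  stop-free pathway exists. Changes *to* stop codons count as
  nonsynonymous. The genetic code defaults to NCBI translation table 5
  (invertebrate mitochondrial) and is configurable; the reading frame
  must be supplied explicitly — pi_s/pi_n are refused without it, since
  a wrong frame silently produces nonsense.

## Neutrality tests

Tajima's D uses the standard constants (a1, a2, b1, b2, c1, c2, e1, e2)
with theta_pi counted per sequence pair, not per site. For n = 2 the
variance constants vanish together with the numerator and D is defined
as 0. S = 0 raises an error instead of returning 0 — "no information" and
"perfectly neutral" are different statements.

Fu's Fs is the log-odds of the Ewens-sampling probability of observing
at least the sampled number of haplotypes given theta = theta_pi:
`Fs = ln(S'/(1-S'))`, `S' = Pr(K >= k_obs)`. The Ewens probabilities use
unsigned Stirling numbers of the first kind computed by the recurrence
`|s(n+1,k)| = n|s(n,k)| + |s(n,k-1)|` entirely in log space, which is
exact to ~1e-15 against rational arithmetic for small n and stable to
n in the hundreds. `S'` equal to 1 (k_obs = 1) or numerical underflow
raise explicit overflow errors.

P-values come from neutral constant-size coalescent replicates
**conditioned on the observed S**: exactly S mutations are dropped
uniformly on each simulated genealogy (infinite sites), and D, Fs are
recomputed from the branch-defined allele counts — no sequences are
built, which keeps 10^5 replicates cheap. A theta-conditioned null
(Poisson mutations at rate theta_pi/2, monomorphic replicates redrawn
and counted) is available behind `conditioning="theta"`. `p_Fs` is
`Pr(Fs_sim <= Fs_obs)`. For D the default (`tail="auto"`) takes the tail
on the side of the observed value; note that this sign-switching rule is
*not* a uniformly distributed p-value (rejecting at 0.05 under the null
happens ~10% of the time, as with any two-sided-by-selection rule), so
the calibration tests use the fixed lower tail, which is the direction
relevant to expansion detection. Both fixed tails are available.

## Mismatch distribution and expansion model

The observed mismatch distribution is the histogram of pairwise
differences, enumerated over individuals by default (`weight_by_count`)
so that common haplotypes carry their sampling weight.

Under a sudden expansion tau mutational units ago from equilibrium
diversity theta0 into a population large enough that post-expansion
coalescence is negligible (theta1 = infinity), the pairwise difference
count is Poisson(tau) plus a geometric equilibrium term:

    Fhat_i(theta) = theta^i / (theta+1)^(i+1)
    F_i(tau, theta0) = sum_{j<=i} e^-tau tau^j/j! * Fhat_{i-j}(theta0)

The finite-theta1 transient
`F = Fhat(theta1) + e^(-tau/theta1) * conv(Pois(tau), Fhat(theta0) - Fhat(theta1))`
is available behind a flag and is validated against the coalescent pair
simulator; it reduces to the convolution form as theta1 -> infinity and
to Fhat(theta0) at tau = 0. Frequencies beyond the last modelled class
are pooled into it so every vector sums to 1; the unpooled model mean is
exactly tau + theta0. The reference analysis program fits a *spatial*
expansion whose likelihood is not published in closed form, so a tau
fitted here to the same data need not match its output exactly; the
model choice is recorded in every manifest.

Fitting minimises the sum of squared deviations between observed and
model class frequencies with L-BFGS-B from a fixed start grid
(tau in {0.5, 1, 2, 4, 8, observed mean}; theta0 in {0.1, 1, 5}); the
grid is ranked by objective value and the three best starts are polished
(polishing all eighteen gave identical optima on every instance checked,
at several times the cost). The result is a deterministic function of the
input. Optimiser tolerances are tightened (`ftol=1e-14`) so that
zero-residual self-consistency recovers parameters to ~1e-8.

Goodness of fit and uncertainty use a parametric bootstrap: coalescent
samples of the observed size are simulated under the fitted model
(theta1 = 1000 stands in for infinity; finite-sites sequences of the
observed length), each replicate is refitted, and

* `p_ssd` = share of replicates with SSD >= the observed SSD,
* `p_raggedness` = share with Harpending's raggedness >= observed, where
  `r = sum_{i=1..d+1} (x_i - x_{i-1})^2` with the explicit boundary
  convention `x_{d+1} = 0` (conventions differ between sources; this one
  is covered by a regression test),
* the tau confidence interval is the (2.5%, 97.5%) percentile interval
  of the refitted tau values.

Replicates with no polymorphism are redrawn and counted.

## Dating

tau = 2 * mu_hap * t with mu_hap = mu_site * L, so
`t = tau / (2 * mu_site * L)` generations; a generations-per-year range
(low, high) maps t to the year interval (t/high, t/low). The default
mutation rate is the direct mitochondrial estimate 6.6e-8 per site per
generation, and the default life-cycle range is 2–5 generations per
year. Reported values are rounded to the nearest 1,000 generations (the
year range is derived from the rounded generation count, matching the
headline arithmetic 44,000 -> 8,800–22,000); raw values are kept in the
JSON output.

## Median-joining networks

The epsilon-relaxed minimum spanning network admits an edge of weight w
iff its endpoints are not connected by admitted edges of weight
<= w - epsilon - 1; at the default epsilon = 0 this is exactly the union
of all minimum spanning trees. Median vectors are proposed from mutually
linked triplets as per-column majority consensus — a three-way tie takes
the state of the first node in ID order, a deterministic resolution of a
choice the original algorithm leaves open — and those within epsilon of
the iteration's minimal connection cost are added until the node set
stabilises. A final cleanup removes median vectors of degree <= 2 whose
removal does not lengthen the network. Because medians arise only from
triplets that are mutually linked, the algorithm does not manufacture
interior nodes for chain-like genealogies; on star-like (expansion)
data, where ties are pervasive, the reconstructed network reproduces the
true genealogy's path metric exactly in our simulations.

MP post-processing keeps exactly the nodes and links present in at least
one minimum-total-length tree spanning all observed haplotypes,
computed by exhaustive search over median-vector subsets with the
cycle-rule characterisation of MST membership inside each optimal
subgraph. This is exact but exponential in the number of medians, so it
is guarded at 25 nodes (ample for per-lineage networks after haplotype
collapsing); beyond the guard the pipeline keeps the unpruned network
and says so in the manifest. Equally optimal reticulations can exist;
ID-order tie-breaking makes the reported one reproducible.

## Coalescent simulator

Time is scaled in units of N_e generations of the current (haploid)
population, so each lineage pair coalesces at rate 1 and theta = 2 N_e
mu_hap gives mutations at rate theta/2 per unit branch length
(E[pairwise differences] = theta at equilibrium). Demographies: constant
size, and sudden expansion with the event at scaled time tau/theta1.
Mutations are finite-sites by default — uniform site, uniform different
base — so simulated data can contain homoplasy and exercise network
reticulations; `infinite_sites=True` assigns each mutation a fresh site
and guarantees tree-like data for the network ground-truth tests.
`fixed_S` conditioning places exactly S mutations uniformly on the tree
(the neutrality-test null); site collisions are counted and reported.
All randomness flows from one numpy Generator; replicate streams are
spawned from the root seed, and every artifact records its seed.

What the generator emulates: neutral genealogies, finite- or
infinite-site mutation, the two demographies above. What it does not:
recombination (absent from mtDNA anyway), migration structure,
selection, rate heterogeneity across sites, and sequencing error — so
green simulation tests certify the statistics and the inference
machinery, not robustness to those real-data complications.

## Test problem sizes

Statistical tests are seeded and sized to give comfortable margins at
desk runtimes: type-I calibration of the neutrality tests uses 500
trials of n=25, S=15 with 200 null replicates each; tau recovery uses
500 datasets at tau=3, n=100, L=500 (observed median relative error
~0.20 against the 0.25 bound); bootstrap CI coverage uses 100 datasets
at n=50, L=300 with 100 bootstrap replicates each (observed coverage
~0.90 against the 0.88 bound); SSD calibration uses 80 trials. The
model-vs-simulation comparisons use 1e5 pairs and check classes with at
least 5 expected counts (where the 3-standard-error normal band is
meaningful); the theta1=infinity oracle is simulated at theta1=1e6.

## Known limitations

* The spatial-expansion likelihood of the reference program is not
  implemented; tau estimates on real data may differ for that reason
  alone.
* pi_s/pi_n require a user-supplied reading frame and refuse frames with
  internal stops in the consensus; there is no frame auto-detection.
* MP pruning is exact but exponential; large epsilon values or very
  diverse samples can exceed the node guard.
* Monte-Carlo p-values are plain proportions; at small replicate counts
  they can be 0 and should be read as "< 1/reps".
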