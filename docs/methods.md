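# Methods

`plastburst` reimplements, as a tested library, the comparative-genomics
workflow used to characterise a burst of plastid-to-nucleus DNA transfer in
a plant genome: maximum-likelihood gain–death modelling of gene-family
sizes on a dated species tree, pairwise synonymous-substitution (Ks)
estimation under a codon model, redundancy-corrected Ks age distributions
with Gaussian-mixture peak detection, quantification of nuclear plastid
DNA (NUPT) from local-alignment hits, and GO-term enrichment. A
synthetic-data module generates inputs with the statistical structure each
stage assumes, together with machine-readable ground truth, so the whole
pipeline is exercised without downloading genomes.

## Gene-family turnover

Family size evolves along each branch as an immigration–death process:
new copies arrive at a per-family gain rate γ (per Myr, independent of the
current count) and each existing copy is lost at a per-copy death rate δ
(per Myr). Over a branch of duration t the transition has the closed form

    X(t) | X(0)=i  =  Binomial(i, e^{−δt}) + Poisson((γ/δ)(1 − e^{−δt})),

i.e. binomial thinning of the starting copies plus independently
accumulated gains. This closed form is used everywhere in the likelihood;
a truncated-generator matrix exponential is kept in the test suite as an
independent oracle (they agree to 1e-10 on a grid of rates and times).

Likelihoods are computed by Felsenstein pruning over a truncated state
space 0..N with N = max(10, 2 × largest observed count), raised
automatically when leaf counts demand it; doubling N beyond sufficiency
changes log-likelihoods by less than 1e-8. The root state is marginalised
under a prior — stationary Poisson(γ/δ) by default, with uniform and
fixed-count priors available — since the data cannot identify the root
distribution.

Three branch-rate hypotheses are fitted: `global` (one rate pair,
2 parameters), `free` (a pair per branch) and `branch` (a designated
foreground terminal branch vs all remaining branches, 4 parameters).
Fitting is bounded multi-start ML in log-rate space (L-BFGS-B, bounds
1e-8–10 per Myr, 5 restarts by default, deterministic given a seed).
Restart draws come from a log-uniform window 1e-5–1 per Myr — narrower
than the box, because starts at the box corners produce degenerate Poisson
means under small state caps and waste restarts. Models are compared by
the Akaike evidence ratio exp(ΔAIC/2) with a significance cutoff of 2.7
(ΔAIC ≈ 2); ties go to the model with fewer parameters. For a significant
branch model, the family is called expanded or contracted by comparing the
foreground leaf count with the posterior-mode ancestral count at the
foreground branch's parent (marginal reconstruction via an
upward/downward pass), with a `lost_all` flag when the foreground count is
zero but the reconstructed ancestor was not.

Families with zero genes in every species are rejected as untestable
input: such families are unobservable in real data. Simulation studies,
where the zero rows are genuinely observed, may keep them
(`allow_absent_families=True`); dropping them while using the
unconditional likelihood biases gain-rate recovery upward by tens of
percent.

## Pairwise Ks estimation

`gy94_fit` maximises the likelihood of a gap-aligned codon pair under a
Goldman–Yang-type model: the generator over the 61 sense codons has
entries proportional to π_j, κπ_j, ωπ_j or κωπ_j according to whether the
single-nucleotide change is a transition and/or nonsynonymous;
multi-nucleotide changes have rate zero. Stationary frequencies are F3×4
(position-specific nucleotide frequencies multiplied per codon, stops
removed, renormalised; zero-frequency codons receive a 0.5/61 pseudocount
to keep the generator irreducible). The generator is scaled to unit
substitution flux so t is in expected substitutions per codon, and P(t) is
computed by eigendecomposition of the symmetrised matrix D^{1/2}QD^{−1/2}.
Optimisation is bounded L-BFGS-B on (log t, log κ, log ω) with t ∈
[1e-4, 30], κ ∈ [0.1, 20], ω ∈ [1e-3, 5], best of 5 log-uniform restarts;
a fit with t at its upper bound is flagged saturated.

dS follows the Goldman–Yang site convention: dS = t·ρ_S / (3·f_S), where
ρ_S is the synonymous fraction of substitution flux under the fitted model
and f_S the synonymous site fraction of the same model with ω fixed to 1
(mutational site counting); dN analogously. External codon-model programs
may normalise sites differently, so exact numeric agreement with any
particular implementation is not claimed — correctness is established by
simulation recovery (median dS within ±10% of planted truth on 500-codon
pairs at dS = 0.5) and by the model's internal consistency checks
(reversibility, stationarity, unit flux).

`ng86_ks` is the Nei–Gojobori (1986) counting estimator with Jukes–Cantor
correction, used as a fast cross-check. Stop-codon handling: at each codon
position the three possible changes are classified and changes to stops
are excluded, the position contributing the synonymous fraction of the
remaining viable changes; multi-step pathways passing through a stop are
dropped and the remainder averaged (if no stop-free pathway exists the
position changes are classified directly against the end codon). dS is
flagged undefined when pS ≥ 3/4. Codon columns containing a gap or
ambiguity in either sequence are excluded throughout, mirroring
insertion-skipping alignments upstream.

## Node-weighted Ks distributions

A family of n genes yields n(n−1)/2 pairwise Ks values for only n−1
duplication events. Following a Vanneste-style correction, each
midpoint-rooted family tree is split recursively from the root until every
retained subclade has all internal pairwise Ks ≤ 5 (saturation threshold,
inclusive); then each duplication node with a and b leaves in its two
child subtrees contributes its m = a·b cross-pair Ks values at weight 1/m.
The weighting description in the source workflow defines m as "the number
of duplication events", which contradicts its own requirement that the
weights of one duplication event sum to one; the cross-pair reading is the
only one satisfying that constraint and is used here. Missing or
saturation-flagged Ks values count as "> threshold" during splitting and
are skipped during weighting with the node's weights renormalised over its
remaining pairs — conservative against saturated estimates. Polytomies are
resolved deterministically (left-to-right, zero-length branches) and the
resulting nodes treated as ordinary duplication nodes. Per node the
weights sum to one exactly (within 1e-12 in floating point), so the grand
total weight equals the number of contributing duplication nodes.

## Gaussian-mixture peak detection

Ks values are restricted to the window 0.05–5, inclusive at both ends,
to exclude near-identical pairs and saturated estimates. Univariate
unequal-variance Gaussian mixtures are fitted by weighted EM: sample
weights multiply the responsibilities and the effective sample size
n_eff = Σw replaces n in the BIC. With unit weights the weighted fit
reproduces the unweighted fit exactly.

The component count k is chosen two ways, mirroring the mclust/mixtools
pair of routes:

* **BIC** (mclust convention, BIC = 2lnL − (3k−1)ln n_eff, maximised)
  over k = 1..9, three EM initialisations per k;
* **sequential parametric bootstrap** of the likelihood-ratio statistic:
  from k = 1, simulate B = 1000 datasets from the fitted k-model, refit k
  and k+1 on each, p = fraction of bootstrap LRTs ≥ observed; stop at the
  first p > α = 0.01. The replicate loop stops early once the exceedance
  count already guarantees p > α — the count can only grow, so the
  decision is exactly the full-B decision.

EM control parameters: convergence when the lnL gain drops below 1e-10,
at most 1000 iterations (the mixtools default; the printed control values
in the source workflow — maxit = 1e-30, maxrestarts = 1e-3 — are not
usable as counts and were normalised to these), and component collapse
(σ → 0 or an emptied component) triggers up to 20 restarts from perturbed
initialisations before the fit is flagged. Initialisation is
quantile-spaced means, pooled SD, equal proportions. Inside the bootstrap
loop EM is capped at 500 iterations, applied identically to observed and
replicate statistics.

95% confidence intervals around peak means are percentile intervals from a
parametric bootstrap (B = 500) with components matched across replicates
by sorted means; replicates whose refit collapses are discarded and
counted. Whether the original analysis fitted the weighted or unweighted
node-corrected distribution is not recorded; both are supported and
weighted is the default for node-weighted input.

## NUPT quantification

From a BLAST tabular (outfmt 6) hit set of a plastid genome scanned
against a nuclear assembly, `summarize_nupt` reports hit counts, the total
aligned length, the genome fraction, and the size distribution (min, max,
mean, median). By default each hit counts separately and the total is the
plain sum of alignment lengths — the convention under which a reported
total, hit count and mean are mutually consistent (mean = total/n) — while
`merge=True` unions overlapping subject intervals per scaffold first,
bounding the fraction by one. "Insertion length" is the hit's
alignment-length column, gap columns included, matching the consumed
format. The recommended external scan is BLASTN with `-max_target_seqs
1000 -dust no -evalue 1e-5 -penalty -2 -word_size 9` (wrapper provided);
the package never requires BLAST.

For circular plots, scaffolds are selected when at least as long as the
plastid genome and carrying a hit with ≥ 90% identity over ≥ 2000 bp,
ordered by total aligned length; link colours follow min–max identity
ratio bins (blue ≤ 0.25 < green ≤ 0.50 < orange ≤ 0.75 < red), with a
degenerate all-equal hit set coloured red.

`toy_local_align` is a deliberately small ungapped seed-and-extend
aligner (exact 9-mer seeds on both strands, two-sided x-drop 20 extension
with match +1 / mismatch −2, minimum score 30, per-diagonal merging) used
so synthetic fixtures need no external aligner. It handles the
substitution-only divergence of the simulator; it is not a BLASTN
replacement and computes no e-values.

## GO enrichment

Each term annotating at least one universe gene is tested with the
two-sided Fisher exact test on the (subset with term / without, rest with
/ without) table; p-values are Bonferroni-corrected by the number of terms
tested and called significant below 0.05. The universe defaults to
annotated genes only, matching the usual annotation-pipeline denominator,
and is configurable. Direction (over/under) is reported from the
Haldane-corrected sample odds ratio. Annotations are used as given — no
GO-graph ancestor propagation, since upstream annotation pipelines already
expand terms. All universe terms are tested, including terms absent from
the subset (needed to report under-representation), and all enter the
Bonferroni m.

## Synthetic data and what passing tests show

All generators are pure functions of (parameters, seed); a master seed is
split into per-stage substreams by hashing `"{master}:{stage}"` (sha256
mod 2^31). Defaults are the study conditions used throughout the tests:

* **Family counts**: 2,000 families on the bundled 11-species ultrametric
  angiosperm tree at γ = 0.001, δ = 0.002 per Myr, root drawn from the
  stationary prior, branches evolved under exactly the transition law the
  likelihood assumes. The tree topology places Amborella sister to all
  other angiosperms and the magnoliid avocado sister to the
  monocot+eudicot supergroup; node ages are TimeTree-style median
  estimates (root 179 Myr) fixed once in `synthetic.ANGIOSPERM_11_NEWICK`.
* **Codon pairs**: ancestor from π, two descendants evolved t/2 each via
  P(t/2) under the same GY generator as the estimator; true dS from the
  generator's own flux decomposition. Study condition: 500 codons,
  κ = 2, ω = 0.2, dS = 0.5.
* **Ks mixtures**: three components (λ 0.15/0.55/0.30, μ 0.17/1.62/2.53,
  σ 0.05/0.30/0.30) at n = 2,000, window-rejected to 0.05–5. The means
  serve as planted synthetic truth for the mixture machinery, not as a
  real-data reproduction.
* **Duplication trees**: random coalescent-style joins at increasing node
  ages; pairwise Ks = 2 × spanning-node age + Gaussian noise, floored at
  zero.
* **NUPT genomes**: uniform-random plastid and nuclear sequence with
  non-overlapping planted fragments; lognormal sizes (μ = ln 200,
  σ = 1.2, a right-skewed unimodal shape, not a claim about the real
  process), per-insertion divergence uniform in 0–10%, half the fragments
  reverse-complemented. Study condition: 2 Mb genome, 160 kb plastid,
  4.7% planted fraction.

These generators reproduce the statistical structure each stage assumes —
not real genomes. They contain no repeats, GC skew, indels, assembly
artefacts or annotation noise, so passing tests demonstrate correctness of
the algorithms under their own model assumptions, not performance on real
assemblies.

## Problem sizes used in the standard checks

The bundled end-to-end checks run at sizes chosen to keep a full suite
execution on one CPU comfortably short while leaving Monte-Carlo error
well inside each tolerance: the per-family branch-model false-positive
rate is measured on a 500-family subsample of the 2,000 simulated families
(binomial SE ≈ 1 pp against the 8% bound; the acceptance script uses 300),
GY recovery uses 100 pairs (60 in the script), the Fisher-vs-enumeration
check covers all tables with row sums ≤ 8 plus 300 random tables with
margins ≤ 30, and bootstrap component selection runs at B = 200 with
size control checked over 20 seeds.

## Known limitations

* The gain–death law has no per-copy birth component; lineage-specific
  amplification dynamics beyond immigration–death are out of scope, and
  equivalence with any external implementation's stochastic law is not
  claimed.
* Pairwise (two-sequence) codon likelihood only; no rate heterogeneity
  across sites.
* All internal nodes of within-species family trees are treated as
  duplication nodes (no reconciliation against the species tree).
* Mixtures are Gaussian on the raw Ks scale; no log-scale modelling and
  no WGD dating in absolute time.
* The toy aligner is ungapped and substitution-only; real NUPT scans
  should use the documented BLASTN wrapper.
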