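# Methods

`phenolink` implements a pipeline for relating longitudinal gut-microbiome
composition to host metabolic phenotypes in a two-arm perturbation design
(low-dose antibiotic vs. control, with an all-animals switch from normal chow
to high-fat diet), together with a synthetic cohort generator that encodes
the statistical assumptions of every stage and carries planted ground truth
for recovery testing.

## Compositional preprocessing

Sequencing counts carry only relative information. OTUs present in fewer
than 10 % of samples are discarded (the boundary is inclusive: exactly-10 %
OTUs survive, since the rule removes only strictly rarer taxa). A single
pseudocount is added to the raw counts and each sample is mapped by the
centered log-ratio transform, clr_ij = ln(c_ij + 1) − mean_j ln(c_ij + 1).
Because clr subtracts the per-sample mean log, applying it to pseudocounted
counts or to closed relative abundances differs only by a row constant that
the transform removes; the counts reading is implemented. Rarefaction (used
only by the disease classifier) draws exactly `depth` observations per
sample without replacement (multivariate hypergeometric), dropping and
logging samples below depth.

## Multilevel decomposition

Repeated measures are decomposed before regression: each subject's series is
split at the diet switch into (subject × diet-period) cells, and

    within_i  = x_i − mean(cell of i),
    between_i = mean(cell of i) − grand mean.

The centered data reconstruct exactly as within + between and the column
variances add. Cage, sex, and subject baselines never vary within a cell, so
they are absorbed by the between component; the within component carries the
perturbation signal the sPLS stage regresses on. The between-subject factor
(treatment) cannot appear in the within part by construction. Singleton
cells contribute zero within-rows and are flagged. An alternative
subject-only centering is available by passing `diet=None`.

## Sparse PLS with stability selection

The association model is a K = 7-component sparse PLS regression of
within-subject phenotypes (centered, unit-scaled) on within-subject clr
features. Per component, the X-direction is the dominant left singular
vector of the current cross-covariance X′Y, soft-thresholded at η·max|entry|
and renormalised; X and Y are deflated by the resulting score. η = 0
reproduces dense PLS (and approaches the least-squares fit as K approaches
the rank of X); η → 1 keeps only entries within (1−η) of the per-component
maximum. Support is the set of OTUs with a nonzero weight row. When the
cross-covariance rank is exhausted K is reduced with a warning.

η is chosen by the stability approach to regularisation selection: the model
is refit over `n_subsets` = 50 random subject subsets (all repeated measures
of a subject move together), the per-OTU selection frequency θ gives the
instability ξ = 2θ(1−θ), and D(η) = mean_OTU ξ. D is monotonised by a
running maximum from the sparse end and the least-sparse η with D ≤ β is
selected (ties prefer the sparser model). Two deliberate departures from a
literal reading of the source description, both forced by implementation
experience:

- **Instability threshold β.** The quoted "0.1 %" reads as β = 0.001, but
  with seven components the union support always contains a few
  subset-dependent OTUs contributed by the late, noise-dominated components,
  so D never falls to 0.001 at any η and the selector degenerates to its
  densest-model fallback. The default is therefore the stability-selection
  convention β = 0.05 (the same %-vs-proportion ambiguity arises for the
  network stage, where both readings are accepted); the stricter reading
  remains available through the `threshold` argument.
- **Subset size.** A fraction of 10·√n/n exceeds 1 for n ≤ 100 subjects,
  which would make every subset the full data and all instabilities zero.
  The implementation follows the convention of the reference StARS software:
  b = ⌊10·√n⌋ for n > 144, otherwise b = ⌊0.8·n⌋.

Significance of the selected associations is assessed empirically on the
StARS support: 2000 bootstrap refits (subjects resampled with replacement)
give the reported coefficient as the bootstrap median, and 2000 null refits
(subject-to-response assignment permuted in whole-subject blocks) give the
two-sided p-value (1 + #{|null| ≥ |observed|})/(1 + B_null), never zero.
The observed statistic compared against the null is the original-fit
coefficient by default: pooled null-cohort p-values are then
indistinguishable from U(0,1) by a KS test, whereas the bootstrap-median
statistic is visibly conservative (its pooled null p-values average ≈ 0.6).
The median statistic remains available via `p_statistic="median"`.
Associations are flagged at α = 10⁻² per (OTU, phenotype) pair without
further multiplicity correction.

## Clustering of latent scores

Samples are clustered on their sPLS score rows with finite Gaussian
mixtures, EM-fitted from a Ward agglomerative initialisation over
k = 1…9 and four covariance families (spherical, diagonal, tied, full);
the (family, k) pair maximising BIC = 2·loglik − params·ln(n) wins. The
shared-orientation ellipsoidal family of the reference clustering software
is not among scikit-learn's families; full covariance is the closest
implemented superset. Hard argmax assignments feed the downstream stages.
Per-subject trajectories between successive sampled weeks give a transition
diagram; directed cluster-change edges with fewer than six events are
pruned, while self-loops (no change) are reported separately and never
pruned.

## Association networks

Within each cluster's sample set the clr transform is recomputed (the
composition is cluster-local) and a signed microbial association network is
estimated by neighborhood selection: an L1-penalised regression of each
standardised clr column on all others, an edge when either direction keeps
the partner (OR rule; AND available), the sign taken from the
larger-magnitude coefficient. The penalty path has 30 log-spaced values from
λ_max (the largest absolute off-diagonal correlation) down to λ_max/100, and
λ is picked by StARS over 50 row subsets at β = 0.05, with the per-edge
selection frequencies retained on the result. The selected graph is refit on
the full cluster data.

## Network topology

Per-node signatures count the 15 automorphism orbits of connected graphlets
on up to four nodes by exact enumeration (Wernicke's ESU); orbit 0 is plain
degree. Graphlet correlation matrices are Spearman correlations across nodes
of the 11 non-redundant orbits {0,1,2,4,5,6,7,8,9,10,11}; an all-ones dummy
row keeps constant orbit columns well-defined. The redundancy of the four
excluded orbits (and irreducibility of the retained eleven) is verified
programmatically by exact polynomial regression over a random-graph
ensemble. The graphlet correlation distance is the Frobenius norm of the
upper-triangle difference of two such matrices — a pseudometric, embedded in
2-D by classical (Torgerson) MDS with a sign convention for orientation.

Robustness is scored by natural connectivity, ln((1/N)·Σ exp(λ_i)) over
adjacency eigenvalues (0 for an edgeless graph; strictly increasing in
edges), under three attack strategies — uniformly random removal (averaged
over 50 repetitions), highest degree, and highest betweenness — with
targeted rankings recomputed adaptively after each removal (a static mode is
available). Edge signs are ignored for all topology metrics, which require
simple graphs. Keystone taxa are ranked by the sum of degree and betweenness
ranks (hub + bottleneck), ties broken by betweenness then node id.

## Microbiota maturity and disease classification

A random-forest regression (1000 trees, ⌈d/3⌉ features per split) trained on
control samples predicts microbiota age. Microbial maturity is
MM = predicted age − median predicted age of same-bin controls, and
MAZ = MM / SD of same-bin control predictions, with "similar age" realised
as the identical sampled week. Control predictions entering the bin
statistics are out-of-bag, so a control never scores against trees that saw
it; bins with fewer than two controls (or zero SD) are flagged invalid
rather than scored.

Disease outcome (NAFLD or elevated HOMA-IR development) is classified per
sampled week by random forests on counts rarefied to 1000 reads/sample, in
ten independent rarefaction trials, with leave-one-out error. OTU importance
is the mean increase in LOO error (%) when that OTU's held-out values are
permuted — permutation importance evaluated on the LOO predictions
themselves.

## Host phenotype scoring

HOMA-IR = glucose [mg/dL] × insulin [mU/L] / 405, elevated when strictly
above 13.2. Insulin resistance requires at least two of {elevated HOMA-IR,
impaired IPGTT, impaired IPITT}; the two tolerance-test impairments are
clinical inputs, not recomputed (no numeric rule exists for them), though the
censoring conventions for raw curves (clamp at 500 mg/dL; rescue value
20 mg/dL) are provided. NAFLD is diagnostic when the activity score strictly
exceeds 5 with fibrosis present. The Weight+1 response is each subject's
weight at the next later measurement, by order rather than spacing; terminal
measurements are missing and excluded from response matrices.

## Synthetic cohorts

Counts follow a logistic-normal multinomial, matching the log-ratio Gaussian
structure clr-based inference assumes and keeping recovery tests well-posed.
Latent log-abundances are baseline (N(0, 2²) across OTUs) + subject effect
(sd 1) + treatment effect on the antibiotic arm (sd 0.3) + diet effect after
the switch week for all animals (sd 0.5) + signed age trends (0.1
log-units/week on 20 taxa) + correlated noise with covariance inverse to a
planted sparse precision matrix (chain/hub/Erdős–Rényi topologies; chain
partial correlation 0.4). Library sizes are lognormal (median ≈ 15 000
reads); counts are multinomial draws from the softmax composition.
Phenotypes (the seven-response panel) are linear in the latent abundances of
the planted associated OTUs (default 10 OTUs, effect 1.0, each loading on
1–3 responses) plus a subject effect and unit noise; sex is simulated but
given no effect. Planted associated and age-graded taxa are disjoint and
drawn from the upper half of baseline abundance: taxa at ~1 expected
read/sample are unobservable after count quantisation, so planting on them
would make recovery measure sequencing depth rather than the estimator —
the same logic behind the 10 % prevalence filter. Defaults (20 subjects/arm,
weeks 4/11/16/30, switch at week 13, 200 OTUs) keep the full pipeline within
a few minutes on one CPU.

What the generator does *not* emulate: taxonomic block structure, real
phylogenetic correlation, time-varying library-size artefacts, batch/cage
effects beyond the subject intercept, and zero-inflation beyond what the
multinomial induces. Passing recovery tests therefore demonstrates
correctness of the estimators under their own assumptions, not performance
on real amplicon data.

## Numerical conventions

Every stochastic routine takes an explicit seed; the pipeline derives stage
seeds from a master seed as (master·10007 + stage index) mod 2³¹. Mixture
EM uses a 10⁻⁶ covariance regulariser and logs collapses. Empirical
p-values use the add-one correction. The GMM BIC is reported on the
2·loglik − params·ln(n) scale (larger is better). Attack curves record
connectivity after each single-node removal on the fraction grid
[0, (N−1)/N]. Acceptance-scale problem sizes (5–10 simulation seeds, 25–50
StARS subsets, 200–400 trees) are the package's default desk-scale study
conditions; all are configurable upward.
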