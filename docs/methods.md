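# Methods

`atacstrat` re-implements, as a tested library, a chromatin-accessibility
analysis for stratifying glioblastoma stem-cell (GSC) cultures and for
mapping a mouse epigenome signature onto a human cohort.  This note
records the models, the parameters that matter, the synthetic-data
design, and the numerical choices, in enough detail that every result
the test suite and `scripts/acceptance.py` compute can be traced to a
decision made here.

## Peak universe, normalisation and annotation

Peaks are genomic intervals in BED convention (0-based, half-open),
merged across samples with bedtools semantics: intervals sharing at
least one base pair, or bookended, fuse into one region.  Counts are
normalised to counts per million (each sample column scaled to sum to
10^6) with a log2(CPM+1) layer used by all downstream correlation and
factorisation steps; a column with zero total stays zero and is flagged.

Peak-to-gene distance runs from the peak midpoint (floor of the
interval midpoint) to the gene's TSS, signed in the transcriptional
orientation (downstream positive).  The midpoint anchor is a choice —
the convention of standard annotation tools — since either interval
edge would introduce a strand asymmetry.  Region classes follow fixed
windows:

* promoter: signed distance in [-1000, +100] bp (strand-mirrored on the
  minus strand);
* distal regulatory element (DRE): 3 kb < |distance| <= 500 kb;
* other: everything else, including peaks on gene-free chromosomes.

The seven-feature classifier (TSS, TTS, 5'UTR, 3'UTR, exon, intron,
intergenic) resolves overlaps by that priority order, with the TSS
window equal to the promoter window and a +/-100 bp TTS window; both
windows are configurable.

## Saturation model

Random subsampling of samples gives the mean cumulative count of
distinct peaks versus sample number.  The fitted model is

    P(x) = a + b * exp(c*x + d),

in which only the product B = b*exp(d) is identifiable; the model is
therefore fitted as (a, B, c) by Levenberg-Marquardt least squares with
self-starting values (a0 slightly above the curve maximum, c0 and B0
from a log-linear fit of a0 - P), and d is reported as 0.  Tests assert
that refitting with d fixed at an arbitrary value leaves the predictions
unchanged.  A saturating fit requires c < 0; the "saturation sample
size" is the smallest integer n with P(n) >= f*a, default f = 0.99
because the asymptote itself is never attained and no sharper criterion
for "all regions detected" is defined; f is a parameter.  A constant
input curve short-circuits to a degenerate fit (B = 0) rather than an
optimiser failure.

## Non-smooth NMF consensus clustering

Samples are clustered on the log2(CPM+1) matrix of the top-variance
peaks (default: top 20%, ties broken by peak id).  The factorisation is
non-smooth NMF, V ~ W S H with S = (1-theta) I + (theta/k) 11^T,
KL-divergence multiplicative updates in which the W update sees S H and
the H update sees W S.  theta defaults to 0.5 (the common choice for
this family; 0 recovers plain KL-NMF); initialisation is uniform (0, 1];
every recorded objective value is non-increasing and convergence is a
relative objective change below `tol` between evaluations (every
`eval_every` iterations).  Zero entries are guarded by a 1e-12 floor.
Sparsity induced by theta is measured with Hoyer sparseness, the
standard statistic for this model family; strict near-zero counting is
misleading at finite iteration counts because multiplicative updates
approach zeros only asymptotically.

Consensus clustering repeats the factorisation from `n_runs` random
initialisations per k; two samples co-cluster in a run when they share
the argmax factor of H, the consensus matrix is the run average, and
the cophenetic correlation rho_k compares consensus distances
(1 - consensus) with the cophenetic distances of their average-linkage
dendrogram.

**Choice of k.**  k maximises rho_k over the range (default 2..8).
Exact ties at the maximum resolve to the end of the contiguous plateau
that starts at the smallest tied k.  The reason is structural: on
cleanly separable data the consensus is exactly binary — hence rho
exactly 1 — for every k up to the true cluster number (merging two true
clusters is perfectly stable when every run merges the same pair),
while at the true k the consensus is both binary and maximal, and above
it the surplus factor splits differently across initialisations.  The
informative point is therefore where the perfect plateau *ends*.  A
smallest-k tie rule would systematically return k=2 on well-separated
cohorts; an unrestricted largest-k rule would be hijacked by a chance
tie at high k, which the plateau rule ignores unless the tie is
contiguous with the plateau.  Model-selection validity rests on run
diversity: runs must be deep enough that the factorisation at wrong k
actually reaches its init-dependent basin.  Empirically (12 default
cohorts, 16 deep restarts each) the most frequent k=2 partition carries
only ~40-55% of runs, while all k=3 restarts agree.

Final labels at the chosen k are the argmax-of-H labels of the run
whose connectivity matrix correlates best with the consensus matrix — a
deterministic representative run, more robust than one extra
factorisation.  Cluster agreement between two labelings is reported
both as the adjusted Rand index and as matched agreement (Hungarian
assignment on the contingency table, trace/n).

**Desk-scale protocol.**  Tests and the acceptance script run consensus
with 5 restarts per k, a 300-iteration cap (tol 1e-7 checked every 20
iterations) and float32 arithmetic.  These sizes were validated
directly: at this depth the k=3 partition is stable across restarts in
12/12 default cohorts while k=2 and k>=4 partitions are diverse, which
is exactly the regime the cophenetic criterion needs.  More restarts
(the conventional 30) sharpen the consensus estimate but do not change
the selection on these cohorts.

## Differential accessibility

Counts are modelled as negative binomial.  Size factors are
median-of-ratios (computed on peaks observed in every sample, falling
back to library-size ratios); per-peak dispersion is a pooled
within-group method-of-moments estimate floored at 1e-8 and then
moderated towards the matrix-wide median with a prior weight of 8
residual df.  The test is a Wald test on the log2 fold change of
normalised group means with pseudocount 1, referred to a t distribution
with the moderated (residual + prior) df.  Both the moderation and the
t reference are calibration choices verified by simulation: with a
plain normal reference and raw moment dispersions the null p-value
distribution is visibly anti-conservative at 10 samples per group
(fraction p<0.05 of 0.068), while the moderated-t version sits at
0.050 with sensitivity ~1.0 for 4-fold planted peaks; at 3 samples per
group the moderation is what gives the test any power at all.  This is
a deliberately simple approximation of the DESeq2 machinery — the
analysis contribution here is the selection rule, not the test
internals — and the selection thresholds are carried verbatim:

* human cluster-unique peaks: p < 0.01 and FDR < 0.01 and log2FC > 1
  and mean CPM > 30 and CV < 0.2 (all strict);
* mouse group-unique peaks: log2FC > 1 and FDR < 0.05 in *both*
  pairwise comparisons against the other groups (intersection rule;
  union available).

The human CV filter is computed on CPM across all samples.  Note that
for strongly differential peaks a cohort-wide CV below 0.2 and a
fold change above 2 are nearly mutually exclusive; the rule is applied
as printed and exercised on toy tables.  FDR is Benjamini-Hochberg
throughout (statsmodels), tested against the textbook step-up procedure
exhaustively for m <= 12.

## Peak-to-gene linkage

Candidate pairs are peak/gene combinations with 3 kb < |midpoint-TSS|
<= 500 kb (a peak may pair with several genes and vice versa).  For
each pair the Pearson correlation r between log2(CPM+1) accessibility
and expression is computed across id-matched samples; the mean and SD
of r over *all* candidate pairs define the empirical null ("nonspecific
correlation"), giving z-scores, two-sided normal p-values, BH FDR, and
significance at FDR < 0.05.  Links of either sign are retained with the
sign reported.  The global empirical null is a blunt but honest
instrument: it assumes genuinely linked pairs are a small minority.  At
real-link fractions above roughly 6-8% of candidates the null SD
inflates to the point where no pair reaches significance — a property
worth knowing when interpreting dense regulatory regions, and one the
synthetic cohorts respect by keeping planted links sparse.

## Motif deviations

For motif m and sample j the raw deviation is
Y = (observed - expected)/expected with expected counts
E[m, j] = (sum_i M[i, m] f_i) T_j, where T_j is the sample total and
f_i the peak's expected library fraction.  f is defined as the mean
over samples of the per-sample count fraction (composition mean), not
the grand-total fraction: this makes two properties exact rather than
approximate — a motif covering every peak deviates exactly zero, and
deviations are exactly invariant to rescaling any sample's counts.
Z-scores standardise Y against `n_background` (default 50) background
peak sets, built by resampling each member peak from its
mean-accessibility bin (default deciles); background matching uses
accessibility only, since synthetic peaks carry no sequence and hence
no GC dimension.  A motif's variability is the SD of its z-scores
across samples (ddof 1) — a simplified form of the chromVAR-style
variability statistic, flagged as such wherever reported.

Selection rules: cluster-enriched motifs require positive Pearson
correlation with the one-vs-rest cluster indicator, BH q < 0.05 across
motifs and variability > 1.5 (both thresholds configurable; an earlier
deviation cut-off of 1 appears as a separate configurable filter at its
call-site).  TF-expression support requires positive correlation with
the motif's TF gene expression at p < 0.05.  Rank comparisons between
peak sets use the top-k overlap of enrichment rankings, where
enrichment within a peak set is a one-sided hypergeometric test of
motif membership against the peak universe, ranked by p with motif-id
tie-break — a surrogate for sequence-based motif enrichment that
preserves the structure of the comparison without PWM scanning.

## Cross-species mapping

Mouse group-unique peaks convert to human peaks through nearest-gene
annotation, a one-to-one homolog map, and the significant peak-to-gene
links (gene -> union of linked peaks), with the retention count recorded
at every step; an empty intermediate yields an empty result with
diagnostics, not an exception.  Guided clustering re-runs consensus
nsNMF at fixed k on the mapped peaks and scores matched agreement and
ARI against a reference labelling.  The random-peak control repeats the
guided clustering on size-matched draws (without replacement) from the
peaks-to-genes universe and reports the null mean, SD and the observed
value's empirical percentile; reduced iteration counts carry a reported
standard error.  The motif-overlap control compares top-10 enrichment
rankings between a mouse peak set and its mapped human set, against
nulls built by pushing size-matched random mouse sets through the same
chain.

## Synthetic cohorts

The generator plants every structure the pipeline is meant to recover.
A cohort lives on one linear chromosome with genes on a 1.2 Mb grid
(TSS at +600 kb, alternating strand, a 20 kb two-exon gene model), so
promoter/DRE windows and nearest genes are unambiguous by construction.
Peaks are 500 bp.  Each cluster owns `frac_cluster_specific` of the
peaks (default 2% per cluster), open (negative-binomial mean
`open_mean`, default 40) exactly in that cluster's samples and closed
(`closed_mean`, default 5) elsewhere; 90% of them sit at DRE
coordinates of a private host gene, the rest at promoters.  Defaults
mirror the study design the package targets: 60 samples in 3 clusters
(20/20/20), 20,000 peaks, ~70% DRE, NB dispersion 0.1, library sizes
uniform in [150k, 450k] (scaling all means), and a motif universe of
414 with 10-motif per-cluster programs over a 5% background membership
rate.

Two features give the background realistic texture rather than pure
noise.  Background peaks wobble log-normally per sample
(`bg_sample_jitter_sd`, default 0.5 natural-log units): biological
sample-to-sample variation that is unrelated to the planted clusters,
which is what makes "random peak sets do not reproduce the clusters" a
meaningful statement.  And a fraction of free genes
(`frac_background_linked`, default 0.3) get one genuinely linked distal
peak — real peak-gene links that carry no subtype information — so the
significant-link universe is dominated by cluster-uninformative links,
as in real cohorts.  Expression of a linked gene is the linked peak's
log2(CPM+1) plus Gaussian noise; with `link_target_r` set, the noise SD
is derived per peak to give that population correlation (used where a
stated correlation, e.g. r = 0.8, is the study condition), and with
`link_noise_sd = 0` the correlation is exactly 1.  All randomness flows
from a single seeded generator: equal configs and seeds give bitwise
identical cohorts.

Paired cohorts share part of their cluster programs through the homolog
map: for `shared_program_frac` of each mouse cluster's defining genes
(capped by the human capacity) the homolog is a defining gene of the
corresponding human cluster; every other mouse gene maps to a uniformly
random unused human gene, so non-shared homology carries cluster signal
only at the chance rate.  Motif programs use a shared namespace and are
identical across species for corresponding clusters.  The power-law
presence generator draws each peak's sample count m with
P(m) proportional to m^-gamma and places the samples uniformly.

What the generator does **not** emulate: read-level artefacts (GC,
fragment length, Tn5 bias), genuine genome annotation, correlated peak
modules beyond the planted programs, many-to-many homology (supported
but off by default), and overlapping cluster programs.  Passing tests
therefore demonstrate the pipeline's contracts — recovery of planted
structure under NB noise and honest behaviour of its null controls —
not performance on any real cohort.

## Problem sizes used by tests and the acceptance script

Saturation: 100 noisy curves (60 points, 0.5% noise).  Clustering: the
full default cohort per seed (50 seeds in the test suite; 10 in the
acceptance script) with the desk-scale consensus protocol above.
Differential: 10,000 peaks, 500 planted 4-fold, 10 vs 10.  Linkage:
100 null simulations of 5,000 pairs x 40 samples; planted recall on a
cohort with ~270 planted links at r = 0.8 (kept sparse so the empirical
null stays valid).  Motifs: 50 seeds (25 in the script) of 4,000-peak,
30-sample cohorts with a single planted 10-motif program over 414
motifs.  Cross-species: 25 paired cohorts per sharing level (5 in the
script) with a 200-draw agreement null (100 in the script).  The
paired human cohort uses 32,000 peaks and 3,200 genes with ~12
defining genes per cluster and ~1,300 background links, so the
significant-link universe is only ~2.5% cluster-informative — large
enough that size-matched random draws rarely carry the handful of
informative peaks needed to reconstruct the clusters, which is what
makes the random-peak control discriminating.  Mouse cohorts use 3
samples per group with reduced background jitter (0.15): clonal mouse
cultures are far more homogeneous than patient-derived ones, and
3-per-group moment tests have no power otherwise.

## Known limitations

The NB Wald test is an approximation: no dispersion trend, no outlier
handling; its calibration was tuned (moderation weight, t reference) at
the group sizes used here and should be re-examined for very small or
very unbalanced designs.  The empirical linkage null breaks down when
real links are dense (see above).  The cophenetic plateau rule assumes
the consensus at the true k is at least as stable as at smaller k,
which planted-cluster cohorts guarantee but heavily nested real data
may not.  Guided clustering at fixed k inherits all nsNMF local-optima
caveats; with very few mapped peaks (< ~3 per cluster) its agreement is
essentially noise, and the random-peak control is the honest yardstick.
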