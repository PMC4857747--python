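# Methods

This note documents the models, conventions and parameter choices behind
`xenomir`, in the order data flows through the package.

## The Crt data model

A qPCR array produces one relative threshold cycle (Crt) per feature per
sample; lower values mean more template, one cycle ≈ a two-fold change.
`CrtMatrix` stores a features × samples table with NaN for wells that did
not amplify ("Undetermined"), plus per-sample metadata parsed from the
`<P|C>_<donor>_<hour>` naming convention (P = plasma, C = cellular/PBMC).
Present values must be finite and in (0, 45) cycles — a 40-cycle run with
headroom; derived matrices that are no longer on the cycle scale (e.g.
mean-centred data) relax the range check but keep all other validation.

Replicate QC follows the standard rule that technical triplicates with a
Cq standard deviation above 0.4 are unreliable: late, near-stochastic
amplification produces exactly this scatter, and such measurements sit in
the same Cq range as non-specific signal.

## Normalizations

Four strategies, chosen because circulating-miRNA arrays have no agreed
reference:

* **raw** — no adjustment;
* **geomean** — per-sample correction `c_s = GM_s − mean_s(GM_s)` where
  `GM_s` is the geometric mean of the Crt values of the k most invariant
  fully-observed features (default k = 22, the GM22 convention;
  selection is by smallest across-sample SD with lexicographic
  tie-break); every value becomes `Crt − c_s`;
* **single_ref** — the same correction from one reference assay (miR-16
  style; default: the single most invariant feature);
* **quantile** — classical quantile normalization onto the across-sample
  mean order statistics.

Corrections are centred on the across-sample mean so normalization
preserves the overall cycle scale and paired fold changes are independent
of the anchor.

Two numerical caveats are deliberate. First, the geometric mean is taken
on the Crt cycle values themselves (not on linearized 2^−Crt
quantities), matching the field's stated practice. Because subtracting a
constant does not shift a geometric mean by that constant, the
post-normalization equality of reference geomeans — and the idempotence
of re-normalizing — hold only to second order; at realistic spreads the
residual is ~10⁻³ cycles, and tests assert these properties at a 10⁻²
tolerance. A singleton reference set is exact. Second, quantile
normalization with missing cells builds the reference distribution from
the fully-observed features, ranks each sample over its observed values
only, and maps by linear interpolation of quantile position; missing
cells stay missing. With no missing data this reduces exactly to the
classical algorithm (sorted per-sample vectors become identical to
machine precision).

## The paired screen and concordance

For each feature, per-donor ΔCrt = Crt(peak) − Crt(baseline) over donors
with both sides observed. Inclusion requires detection in ≥ 90% of
samples (≥ 9 of 10 in the five-donor design, guaranteeing ≥ 4 complete
pairs) and ≥ 4 pairs; excluded features are reported with status "na"
rather than dropped. The test is a two-tailed one-sample t-test of the
differences (t = mean/ (sd/√n), df = n − 1); zero-variance differences
raise a degenerate status instead of a meaningless p. Fold change is the
arithmetic mean of per-donor 2^(−ΔCrt) (the "avg FC" convention; a
geometric option exists). No multiple-testing correction is applied by
default — the robustness device is the **concordance criterion** (the
intersection of hit sets across all normalizations); an optional
Benjamini–Hochberg adjustment is available but off by default.

## Clustering

Samples are compared after mean-centring each feature; distance is
d = 1 − r (Pearson, pairwise-complete over mutually observed features,
≥ 3 shared; an |r| variant is exposed). Note that Pearson correlation is
invariant to adding a constant to a sample, so a uniform per-sample shift
is invisible to this distance — only feature-wise structure can cluster
samples. Agglomeration is UPGMA: inter-cluster distance is the unweighted
mean of all cross-pair *leaf* distances (recomputed from the original
matrix, so heights are history-independent), ties broken by lowest
cluster-id pair. Newick export is ultrametric (leaf depth = root
height / 2), children ordered by smallest leaf name.

## Catalogs and the read mapper

Mature miRNA catalogs are stored DNA-alphabet (U→T), 16–28 nt, names
unique per species. The host/donor partition calls a donor miRNA
"shared" iff a host sequence lies within `max_distance` edits (edlib
global edit distance; default 0 = byte-identical). The default is
deliberately strict: database homology annotations are name/family-based
and looser, so the 0-distance criterion gives the most conservative
donor-unique set — the set whose reads cannot be endogenous.

The mapper is exact and fully specified rather than heuristic:
5′-anchored ungapped comparison, ≤ `trim_3p` (default 2) nt of length
difference at the 3′ end (mature-miRNA reads differ mostly by 3′
trimming/templated extension), ≤ `max_mismatch` (default 1)
substitutions over the shared prefix. Reads outside 16–28 nt are
unmapped. Ambiguous reads (several equally good hits) are split
fractionally when the hits share a species class, otherwise assigned to
the lexicographically first name with an ambiguity counter. Gaps,
genomes, precursors, adapters and isomiR nomenclature are out of scope;
`mapped + unmapped = total` always holds, and mapping percentage is
reported to one decimal.

## Evidence rules and stoichiometry

Donor-unique counts pass through a cascade: ≥ `min_count` (default 10)
raw reads in at least one sample; a nonzero count at every time point;
and intake consistency — the maximum must fall in the post-intake window
AND the baseline count must be below `peak_ratio` (default 0.5) × peak.
The published qualitative judgment ("most abundant at baseline, hence
not from the meal") is thereby parameterized; 0.5 requires the peak to
at least double the baseline, comfortably outside Poisson noise at the
count threshold. All-zero profiles are "insufficient".

Stoichiometry treats blood as a well-mixed compartment (default 5 L) and
a meal as `milk_volume` (default 1 L) at `milk_concentration` (fmol/L;
pmol/L inputs are converted at the boundary, ×1000):

    required_milk_volume   = target × blood_volume / (conc × efficiency)
    required_uptake_fraction = target × blood_volume / (conc × milk_volume)

Both defaults are configurable; with them, a 300 fmol/L rise needs 75 L
of 20 fmol/L milk at perfect uptake, or 1% systemic uptake from 1 L at
150 pmol/L. A required fraction > 1 is flagged infeasible.

## The synthetic-data generator

`simulate_crt_matrix` draws
`Crt[f,(d,t)] = baseline_f + donor_(f,d) + effect_(f,t) + outlier_(d,t) + ε`,
with ε ~ N(0, noise_sd) on the cycle scale (Cq-type quantities are
log-domain, with approximately normal replicate error). Values above the
limit of detection are censored to missing — deterministic thresholding,
matching "did not amplify" semantics, with no separate dropout process.
The donor effect is a **feature-wise profile** (i.i.d. N(0,
donor_effect_sd) per feature, shared by that donor's samples): donors
differ in which miRNAs run high, not by a uniform shift. This matters
twice — the paired design cancels it exactly in ΔCrt, and
correlation-based clustering can see it, which is how samples come to
cluster by donor rather than by time point (a uniform scalar shift would
be invisible to Pearson distance). Outliers are whole-sample scalar
shifts, emulating compromised specimens that amplify cycles late.

Defaults describe the emulated design: 223 features, 5 donors, T0 vs T3,
baseline 27 ± 4 cycles across features, donor effect 0.5, replicate
noise 0.5, LOD 35. The variance components are not published for the
real samples; these values produce realistic detection behaviour (most
features fully observed, high-baseline features censored) and are meant
to be examined with `null_screen_calibration` rather than trusted.

Catalog simulation plants an exact shared core
(`round(shared_fraction × n_donor)` byte-identical sequences) with all
sequences unique per catalog; read simulation draws multinomial counts
from a weight vector (optionally with one dominant miRNA at a fixed
fraction, and donor-unique spike-ins scaled by a per-timepoint dose
kernel), then emits full-length copies with substitution-only errors
(no indels — the dominant short-read error mode — which keeps the
ungapped mapper a valid inverse). Truth counts are exact by
construction. One integer seed drives a CRC-named RNG stream per
generator, so components are independently reproducible.

What the generator does *not* emulate: adapter sequence, UMIs, ligation
bias, isomiR 3′ heterogeneity, PCR duplicates, probabilistic dropout,
or feature–feature correlation beyond the donor profile. Passing
recovery tests therefore demonstrate correctness of the pipeline's
logic under its stated assumptions, not robustness to those real-data
phenomena.

## Calibration behaviour and test sizes

Under the null, the per-feature paired t-test is exactly calibrated for
raw data; the screening suite checks that every normalization's
empirical p < 0.01 rate stays within 3 binomial SDs of 1% over ~5,500
feature-tests (25 simulated 223-feature experiments — enough tests for a
tight check while keeping the default suite under a minute for this
item). One honest caveat: normalizations that subtract a data-derived
per-sample correction (single_ref most of all) share that correction's
noise across all features of an experiment, correlating the tests; the
aggregate rate is then slightly overdispersed relative to the binomial
SD, so occasional seeds can land just outside the naive band even though
per-feature marginal calibration is essentially exact. The recovery
check plants a −2-cycle peak effect at 0.2-cycle noise (t ≈ 16 at five
pairs) and requires concordance across all four normalizations in ≥ 95
of 100 experiments.

Other verification routes are deliberately independent of the code they
check: UPGMA against a brute-force oracle that recomputes cluster
distances from raw leaf pairs (and against scipy's linkage), the t-test
against scipy's `ttest_1samp`, catalog distances against a hand-written
Levenshtein DP, and the mapper against simulation truth counts.

## Known limitations

* The mapper's ambiguity handling is a convention, not an inference;
  paralog families collapsed by fractional assignment should be
  interpreted at the family level.
* Quantile normalization with heavy missingness leans on the
  fully-observed reference set; with few complete features the reference
  becomes noisy (a minimum of 2 is enforced, but more is better).
* The evidence cascade judges pooled counts; with pooled libraries no
  donor-level statistics are possible, which is why the verdicts are
  categorical rather than probabilistic.
* Edit-distance homology at threshold 0 is conservative by design;
  raising `max_distance` grows the shared set monotonically and shrinks
  the donor-unique evidence base.
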