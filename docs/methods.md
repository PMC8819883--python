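# Methods

`fetometab` implements the full post-alignment analysis of a non-targeted
LC-MS metabolomics comparison of germ-free (GF) and specific-pathogen-free
(SPF) mouse dams: placenta, fetal intestine and fetal brain sampled from two
fetuses in each of six dams per group (12 fetuses per group, 7 male /
5 female), each sample measured in four analytical modes (RP+, RP−, HILIC+,
HILIC−), with a pooled QC sample injected repeatedly through the run. The
package starts from aligned feature tables (features × injections); peak
picking and alignment are upstream of its scope.

## Data model

A `FeatureTable` couples the intensity matrix with per-feature metadata
(mode, m/z in Da within the 50–1500 collection window, retention time in
minutes) and per-injection metadata (injection order, sample type, group,
organ, dam, fetus sex). Missingness is a single sentinel (NaN); zero-filled
exports can be converted at read time via a dialect flag, because detection
rates must count true missingness. When no feature identifier is present,
`mode_mz@rt` is constructed so joins across stages are reproducible.

## Quality-control filtering

Per mode, each feature's QC and biological dispersions are summarized on
detected values only:

* classic RSD = sd(QC)/mean(QC);
* RSD\* = 1.4826·MAD(QC)/median(QC), the non-parametric analogue;
* D-ratio = sd(QC)/sd(biological);
* D-ratio\* = MAD(QC)/MAD(biological) — the 1.4826 consistency constant
  cancels in this ratio and is therefore not applied.

A feature is kept iff it is present in **more than 70 %** of QC injections,
in **at least 60 %** of samples of at least one study group, in at least
50 % of all injections (an explicit, configurable reading of the separate
"low number of missing values" clause, which is otherwise unquantified),
and its dispersion passes either the primary rule (RSD\* < 20 % **and**
D-ratio\* < 10 %) or the rescue clause (classic RSD, RSD\* and basic
D-ratio all < 10 %). Flagged features are withheld from statistics but kept
for raw-signal presence lookups. Detection rates pool biological injections
across organs by default (configurable to per-organ); cleanup runs per mode
before merging.

## Drift correction

Intensity drift along the injection order is estimated per feature from the
pooled-QC injections: a cubic smoothing spline (GCV-chosen smoothing
parameter, `scipy.interpolate.make_smoothing_spline`) on log QC intensity
versus injection order, anchored at the first QC injection; every injection
is divided by `exp(g(order) − g(order_ref))`. With fewer than five detected
QC points the fit falls back to a least-squares line (the GCV spline is
degenerate below five points), and below two points the feature passes
through. A correction is applied only if it strictly reduces the feature's
QC classic RSD (gate configurable off); runaway spline extrapolations are
clipped and rejected by the same gate. The correction is scale-equivariant
and leaves missing cells missing.

In the pipeline, drift correction runs per mode (QC curves are
mode-specific) and **before** the QC metrics are computed: uncorrected
drift inflates QC dispersion and would flag otherwise reproducible
features. The opposite ordering is available (`drift_before_qc=False`).

## Imputation

After the four cleaned mode tables are merged, remaining missing values are
filled with a missForest-style iterative random forest: QC injections are
removed first (enforced — pooled replicates would bias the fill), features
are initialized at their observed mean, visited in order of increasing
missingness, regressed each on all other features (forests of 50 trees,
`max_features="sqrt"` — the standard RF heuristic; full-p regression per
feature would be quadratic in feature count), and the sweep repeats until
the sum of squared changes in imputed cells stops decreasing (cap 10
sweeps). Imputation runs on the log scale by default. Observed cells are
restored bit-for-bit afterwards. The reported OOB error is the mean over
imputed features of OOB MSE divided by the variance of the observed values;
it is a data-dependent diagnostic, not a target.

## Differential abundance and exclusivity

Per organ, each feature is tested with a two-sample pooled-variance
Student's t-test — the two-group "simple linear model" — on log
intensities (Welch and raw-scale variants behind flags). P-values are
Benjamini–Hochberg adjusted **within each organ** (each organ is its own
family; a global family is available behind a flag). Effect size is
Cohen's d with pooled SD and no small-sample correction, signed
**GF − SPF**: d < 0 means more abundant in SPF. A feature is significant at
q < 0.05 and |d| > 0.8. Features with zero pooled variance get a missing p
and are excluded from the BH family size so undefined tests do not dilute
the adjustment.

Note on the sign convention: the source material for this rule states the
SPF-higher direction once as d > 0.8 and once as d < −0.8 under a GF-vs-SPF
labelling; the package fixes GF − SPF throughout and documents it rather
than reconciling the two statements silently.

Presence ("exclusivity") calls use the raw, pre-imputation table: a
feature's group SNR in an organ is the mean of its detected intensities
divided by an explicit per-mode noise floor (user-supplied; estimated as
the 1st percentile of detected intensities when not given — upstream
software's per-peak S/N is not carried through exported feature tables, so
the noise term must be made explicit; the choice is recorded in the run
manifest). A feature is `spf_only` in an organ when SNR(SPF) > 5,
SNR(GF) < 5, q < 0.05 and d < −0.8 (mirrored for `gf_only`); `both` when
both SNRs clear 5, otherwise `neither`.

Venn partitioning records, per feature and direction, the **exact** set of
organs with a significant call, so the seven cell counts of each diagram
sum to that direction's "at least one organ" margin.

## Clustering and embedding

t-SNE (exact gradients — sample counts are tens; PCA initialization; fixed
seed) embeds z-scored log intensities; perplexity defaults to 10 and is
clamped to the feasible `(n − 1)/3` per scope, since a 24-sample organ
scope cannot support perplexity 10. k-means with k = 10 (multiple restarts,
fixed seed) orders heatmap rows per organ independently: cluster blocks,
then within-cluster by correlation with the cluster mean profile.
Annotated-metabolite heatmaps are ordered by average-linkage hierarchical
clustering on correlation distance (1 − Pearson r); constant features have
undefined correlation and are placed last with a warning.

## Annotation

Features are matched against a reference library (MSP or constructed) under
primary adducts — [M+H]+/[M+Na]+ in positive modes, [M−H]−/[M+Cl]− in
negative — at 10 ppm, RT window 0.1 min, MS2 greedy square-root-intensity
cosine with 0.02 Da fragment tolerance and 0.7 threshold (all
configurable). MSI levels: 1 = in-house standard with RT + m/z + MS2
agreement; 2 = m/z + MS2 against any source, or RT + formula against an
in-house standard when no MS2 exists; 3 = compound class only, and only via
a user-supplied class rule table (in-silico fragmentation is out of scope);
4 = unknown. Ties prefer higher MS2 score, then smaller ppm error. One
compound can yield several features; all matches are reported and the
best-evidence feature per compound is flagged representative.

## Pathway enrichment

A deliberately simplified mummichog-style analysis: significant m/z values
are mapped to all candidate compounds under the adduct rules at 10 ppm
(isobars retained), the compound universe defaults to everything reachable
from the observed m/z list, and each pathway is scored two ways — a
one-sided Fisher exact test (hypergeometric tail, computed by direct
enumeration with exact integer binomials) and an empirical permutation
null that redraws the observed number of significant m/z from the full
feature list (add-one-smoothed p, `enriched` at perm p < 0.05). No
network/module currency handling or compound-activity weighting; the GSEA
branch is out of scope. The MetaboAnalyst-style normalization (per-sample
median normalization, cube-root transform, per-feature autoscaling) is
provided for upstream significance calls and requires positive values in
that order.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream guarantee is verified.

* **Layout**: the full study design above; biological injection order is
  randomized (samples were randomized to batches); `n_qc = 8` pooled-QC
  injections per mode are interleaved evenly (roughly one per ten
  injections — QC cadence is conventional and configurable).
* **Intensities**: log-normal around a per-feature baseline drawn log-uniform
  between 2·10⁴ and 2·10⁶ counts, with biological CV 0.5 and three
  structural components: per-feature organ offsets (a random permutation of
  graded levels spanning ±0.8 log-units plus jitter — organs have distinct
  metabolomes, and this between-organ spread is what dominates the pooled
  biological dispersion in the D-ratio denominators), a shared dam intercept
  (fetuses are nested in dams; small SD 0.05, so plain t-tests remain
  appropriate downstream), and i.i.d. noise.
* **QCs**: per feature, the mean of the biological log intensities plus
  technical noise with CV 0.05.
* **Drift**: a smooth multiplicative curve of injection order per feature
  (degree-2 polynomial or sinusoid, normalized to ±amplitude, default 0.1).
* **Missingness**: each cell is detected with probability logistic in log
  intensity (midpoint = the 2000-count noise floor, matching a
  minimum-peak-height-style threshold; steepness 2), so low-abundance
  features are missing more often — the intensity-dependent mechanism seen
  in real peak tables.
* **Effect classes**: `null`, `spf_up`/`gf_up` (a log2 shift in a random
  non-empty organ subset, default 1.5; SPF-higher is modelled as a decrease
  in GF, matching the GF − SPF sign convention), and
  `spf_exclusive`/`gf_exclusive`. Default class proportions (18 % / 12.5 % /
  0.8 % / 0.1 %) mirror the fractions such a study reports. Exclusive
  features place the absent group's underlying level in a narrow band just
  below the noise floor (0.4–0.7×), so it is occasionally detected at low
  intensity — as a genuinely below-SNR-5 metabolite is in real data — while
  the present group sits the planted effect (default log2 = 6) above it;
  generation fails fast if the requested effect cannot clear the SNR
  threshold with a 2× safety margin. Exclusive features also share a latent
  per-sample factor (correlation 0.8): co-varying microbial metabolites are
  real, and that correlation is what allows a random-forest imputer to
  infer low values for the absent group from a feature's detected
  companions — without it, forests trained on rows where the feature is
  observed could only predict present-group-level values. Ordinary up/down
  features keep baselines high enough that the depleted group stays above
  SNR 5 under unfavourable organ offsets, so planted differential features
  never masquerade as exclusive ones. Exclusive features get no organ
  offsets, keeping their SNR guarantees exact.

What the generator does **not** emulate: adducts/isotopes/fragments of one
metabolite (effects are planted at the feature level), batch structure
beyond one run per mode, retention-time drift, heteroscedastic
per-feature CVs, or missing-not-at-random mechanisms other than intensity
censoring. Guarantees verified on this generator therefore speak to the
correctness of the algorithms under the stated design, not to instrument
physics.

## Numerical and design choices

* All delimited output is TSV, UTF-8, `.` decimal, 12 significant digits —
  reruns are byte-identical and round-trips preserve doubles to better than
  1e-9 relative.
* Every stochastic step (generation, imputation, k-means, t-SNE,
  permutations) takes an explicit seed; the run manifest stores the config
  and seed, and `run_from_manifest` reproduces all tables exactly.
* Effect-class assignment iterates classes in a canonical order so the
  truth is invariant to configuration key order.
* BH handles NaN p-values by exclusion from the family size; ties are
  stable.
* The t-SNE duplicate-sample and determinism guarantees hold for the exact
  method; Barnes-Hut is unnecessary at these sample counts.
* Scaled problem sizes used by the verification scripts (e.g. 200
  features/mode for end-to-end runs, 6000 features for null-FDR checks,
  ~1500/mode by default) are the package's desk-scale defaults; a real
  four-mode study is an order of magnitude larger and runs the same code.

## Known limitations

* The drift model is QC-anchored and smooth; step changes (e.g. a source
  cleaning mid-run) are not modelled, though the RSD gate prevents harm.
* The missForest imputer's accuracy on features detected in only one group
  depends on correlated companions being present; on data without such
  structure, imputed values shrink toward the observed mean and exclusivity
  significance is conservative.
* Level-3 annotation requires a user-supplied class rule table; no
  in-silico fragmentation is performed.
* Pathway results depend entirely on the supplied GMT content and adduct
  set; no pathway database is bundled.
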