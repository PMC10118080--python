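# Methods

`oilmark` re-implements, as a tested pipeline over synthetic data, an
untargeted LC-QTOF-MS workflow for authenticating cold-pressed seed oils:
species-specific marker ions are discovered from aligned metabolomic
profiles of sunflower, rapeseed, sesame and flaxseed oils, verified against
a negative panel of other oil species, and then used for targeted screening
of unknowns and of low-level (1 % and 5 % v/v) adulteration mixtures.  The
package also carries the accompanying bioactivity endpoints (ABTS/TEAC,
total phenolics, total carotenoids) and their post-hoc statistics.

## The synthetic study

No public instrument data accompany this workflow at desk scale, so the
`synthetic_data` module generates feature tables with the statistical
structure the analysis assumes.  The default study is 4 target oil species
x 4 producers (a–d) x 2 bottles = 32 runs, plus 5 marker-free panel species
from the same producers (40 runs) and 4 solvent blanks — 76 runs in all.
For each target oil the negative panel is therefore the 3 other target
species plus the 5 panel species: 8 species, 64 runs.

Each species expresses three ion families:

* its **markers** (the packaged 29-marker library: precursor m/z, RT ± spread,
  five MS/MS fragments, collision energy, 1 %/5 % mixture detectability);
* a share (default 0.8) of a **common background** metabolome of 500 ions
  (m/z uniform on 100–900 Th, RT on 0.5–29 min, lognormal base heights,
  median 30 000 counts) — the cross-species overlap typical of seed oils;
* a fixed **solvent contaminant** set of 40 ions present in every run and
  in the blanks.  Their mass defect is confined to 0.70–0.95, disjoint from
  the library's defects, which keeps blanks and markers resolvable.

A feature's height in a run is a variance-component product

```
height = base × exp(producer_shared) × exp(producer) × exp(batch) × exp(run)
```

with independent Gaussian log-effects: a producer-level factor shared by all
of that producer's features (sd 0.3; pressing yield / seed-lot concentration
— this is the correlated, class-orthogonal systematic variation that makes
X-orthogonal model components meaningful), a per-feature producer effect
(sd 0.5), a per-feature bottle effect (sd 0.2) and a per-run global
injection/extraction factor (sd 0.15).  These defaults were set so that the
max–min spread of a marker's signal across its 8 runs falls in the ~50–90 %
range reported for commercial oils; the default study yields spreads of
roughly 42–94 % with a median near 78 %.  Observed m/z gets ppm-scaled
Gaussian noise (sd 1.5 ppm) and RT an absolute jitter (sd 0.05 min), chosen
so aligned RT spreads match the per-marker ± tolerances of the library while
staying inside the alignment windows.  Features below the 600-count
detection floor are censored.  All draws come from `numpy` generators
seeded from the design seed, so a design reproduces bit-identical datasets.

**Marker base intensities** are calibrated against the 1 %-mixture flags:
with a 600-count floor, a marker survives 1 % dilution iff its base height
is ≥ 60 000 counts.  Markers flagged detectable at 1 % get 150 000 counts
(300 000 for the ions reported as most intense per oil); the faint ones get
40 000.  Absolute intensities are otherwise free parameters — the source
tables report only relative spreads — and the `abundance` column (a
peak-integral proxy, 100 × height) carries the vendor's 50 000-count
minimum compound abundance, which therefore never bites on apex heights.

What the generator deliberately does **not** emulate: chromatographic peak
shapes, isotope patterns and adducts, correlated RT drift within a batch,
ion suppression in mixtures, and real compound identities.  Passing tests
show the pipeline's statistics and decision rules are correct under the
assumed variance structure; they do not certify performance on real
instrument data.

## Alignment and filtering

Features are aligned across runs with combined relative + absolute
tolerances (0.1 % + 0.15 min on RT, 5 ppm + 2.0 mDa on m/z).  Two features
co-align when their tolerance windows overlap (|Δ| ≤ hw₁ + hw₂ on both
axes).  The algorithm is greedy seeded clustering — features pre-sorted by
descending height, each unassigned feature seeds a consensus and absorbs at
most one feature per run (ties: smallest |Δm/z|, then |ΔRT|, then input
order) — followed by one recentring pass that re-assigns features to
windows around the intensity-weighted consensus references, strongest
consensus first.  The second pass heals the boundary splits a single
seed-centred pass produces when one run's RT jitter straddles the window
edge; orphaned features re-seed.  The pre-sort makes the partition
invariant to sample order; on instances whose clusters are well separated
the result equals exhaustive single-linkage clustering with the same
windows (property-tested).

Filtering follows the vendor semantics: cells below 600 counts or quality
80 are zeroed (inclusive thresholds) and empty consensus rows dropped; any
consensus detected in a blank — or lying within the windows of one — is
removed; finally only compounds found in at least `min_fraction` (default
1.0, i.e. all) of the samples of some oil class enter modelling.  Missing
values are 0 (not detected), matching the floor semantics of the simulator.

## Chemometrics

Columns are mean-centred and Pareto-scaled (x' = (x − mean)/√sd; constant
columns dropped with a warning).  PCA uses NIPALS with deflation and is
tested against an SVD oracle to 1e-6.

OPLS-DA is orthogonal signal correction inside NIPALS PLS2 on a 1/0 class
dummy matrix ("A+O+0" = A predictive, O X-orthogonal, 0 Y-orthogonal;
default 3+2+0 for the four-class problem).  Each orthogonal weight is a PLS
loading projected out of the span of X'Y, so orthogonal scores are *exactly*
uncorrelated with every class column; when the orthogonal residual is
numerically empty (the zero-noise limit, where all X variation is
predictive) extraction stops early with a warning rather than failing.
Predictive weights are computed directly as the dominant right singular
vector of Y'X — the NIPALS fixed point — so components are deterministic
and exact.  Class assignment is by largest predicted Ŷ.

Statistics: R2X per component and cumulative (predictive + orthogonal);
R2Y = 1 − RSS/TSS on the fitted dummies; S2Y = RSS/((N−1)·k); SEE =
√(RSS/(N−A−1)) with A the total component count (the root-mean-square error
of estimates with a df correction — a design choice, since only the loose
definition is standard); Q2 = 1 − PRESS/SS from k-fold cross-validation
with deterministic venetian-blind folds (sample i → fold i mod k, default
k = 7) and centring/scaling re-estimated inside each training fold.
Permutation testing refits on shuffled labels, p = (1 + #{Q2π ≥ Q2})/(nπ+1)
(default nπ = 200, a conventional count).  VIP is the usual
√(p · Σ SSYₐ wₐⱼ² / Σ SSYₐ) over predictive components; per-class
contributions back-project the class displacement in predictive score space
through the loadings.

On the default synthetic study the 3+2+0 model sits in the
strong-discrimination regime — R2X ≈ 0.59–0.73, R2Y ≈ 0.95–0.99,
Q2 ≈ 0.82–0.93 across seeds, permutation p at its floor — which is the
qualitative regime expected of well-separated oil classes; the exact values
depend on the noise realisation and on how much unstructured per-feature
producer variance the generator injects.

## Marker discovery, screening, mixtures

A candidate marker for a target oil must be (i) detected in **every**
sample of that oil, (ii) detected in **zero** of the 64 negative-panel
runs, and (iii) above the VIP threshold.  Exclusivity is the binding rule;
the VIP threshold defaults to 0 and is used for ranking, because with a
fully filtered matrix the VIP distribution concentrates near 1 and any
fixed cut-off would discard genuine low-intensity markers (the threshold
remains configurable for stricter selections).  With zero noise, discovery
returns exactly the planted marker sets with no false positives; at the
default noise it recovers ≈ 100 % over 20 seeds in the packaged tests.

Targeted screening matches each library marker to the nearest feature
within the precursor's m/z window and within `rt_tol × multiplier` of the
library RT (default multiplier 3, covering producer/batch drift beyond the
± spread).  MS/MS confirmation is optional (`min_fragments` of the 5
library fragments within the m/z window); screening is MS1-only by
default, as extracted-ion-chromatogram verification implies.  A declared
species is "authentic-consistent" when all of its markers are present.

Mixtures scale the minor parent's heights by the volume fraction f and the
major's by 1 − f, sum co-eluting features within the alignment windows,
then re-apply the detection floor; detection in a mixture is presence of
the screened feature (height ≥ floor).  Mixing is linear before censoring
and detection is monotone in f (property-tested).  The per-marker
abundance-variability statistic is 100 × (max − min)/max over the runs where
the marker was detected (0 for a single detection, undefined when never
detected) — the reading of "percent difference between the highest and
lowest signal" as a percentage of the highest.

## Bioassays

%Reduction = (Ac − As)/Ac × 100 (scale-invariant; negative pro-oxidant
readings allowed with a warning).  EC50 is where the fitted dose–response
crosses 50 %: a four-parameter logistic (scipy `curve_fit`, Hill slope
bounded to [0.05, 20]) with fall-back to log-linear interpolation between
the bracketing points when the fit fails or leaves > 5 % of the response
range as RMS residual; responses must bracket 50 %.  TEAC = EC50(Trolox,
mg/l) / EC50(oil, kg/l), landing directly in mg Trolox per kg oil.  TPC and
TCC invert OLS calibration lines (gallic acid 25–200 µg/ml; β-carotene
5–500 µg/ml), blank-subtract absorbances first, convert replicates to
concentration individually and average; readings outside the calibrated
range are flagged as extrapolation.

One-way ANOVA and Tukey HSD run from summary statistics (mean, SD, n per
group): pooled MSE = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1), studentized-range tests at the
pooled df, compact letters by insert-and-absorb ordered so "a" marks the
highest mean.  The letter display is validated on every run: two groups
share a letter iff their Tukey p ≥ α (= 0.05).  Because the packaged
bioactivity table stores only means and SDs, re-tested letters can differ
in borderline pairs from letters computed on raw readings; the headline
structure (sole top phenolics group, the not-detected sunflower sample in
the lowest group) reproduces.  The not-detected TPC entry is encoded as
mean 0, SD 0, which contributes no error variance to the pooled MSE.

The assay simulator generates plates from known true values (linear
calibration + multiplicative absorbance noise for TPC/TCC; a Hill
dose–response around the implied EC50 for ABTS, with a matching Trolox
standard plate): analysis recovers truth exactly at zero noise and with
< 1 % bias at 2 % noise over 500 Monte-Carlo runs.

## Problem sizes and numerical choices

The packaged tests and the acceptance script run the full 76-run study
(≈ 32 000 features, ≈ 530 consensus compounds): 20 seeds for the recovery
check, 5 seeds for the reported recovery average, 199–200 label
permutations, and 500 Monte-Carlo plates per assay — sizes chosen so the
whole suite re-derives every headline quantity in well under a minute each
while keeping Monte-Carlo standard errors far below the tested tolerances.
NIPALS tolerance is 1e-12 with a 1000-iteration cap; PLS weights are exact
SVD solutions; tie-breaks everywhere are deterministic (height, then m/z,
then RT, then input order), so identical configurations yield identical
reports.

## Known limitations

Alignment is greedy, not globally optimal; pathological chained clusters
can differ from single linkage.  The OPLS-DA cross-validation scheme
(venetian blinds, scaling refit per fold) is one of several conventions, so
third-party software will give slightly different Q2 on the same matrix.
Marker structures are not identified (out of scope), quantitative
adulteration-level estimation is deliberately absent — the per-producer
signal spread of 40–90 % makes single-marker quantitation unreliable — and
all performance statements are conditional on the synthetic variance model
described above.
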