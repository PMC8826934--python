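# Methods

This note documents the statistical procedures implemented in `tempomics`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

A cohort is a dense array x_{j,k,t}: subject j, molecule k, time t (integer
minutes since glucose ingestion), in each molecule's original measurement
units, with NaN for missing draws. The reference design samples at
0, 10, 20, 30, 45, 60, 75, 90, 120, 150, 180, 210, 240 min, with the
fasting draw optionally duplicated at −10 min; any strictly increasing grid
containing 0 is accepted. When both pre-ingestion draws are present the
fasting value becomes their mean and the grid is collapsed to start at 0.
The interchange format is a tidy long CSV (one measurement per row), which
makes missingness unambiguous; floats are written at 17 significant digits
and parsed in round-trip mode so read→write→read is bit-exact.

## Missing-data exclusion

A molecule is dropped when its missing-cell count strictly exceeds
floor(N_subjects × N_times_raw × 0.05), evaluated on the raw draw schedule
(so a 20-subject, 14-draw design tolerates 14 missing cells; a molecule at
exactly the threshold is retained). The filter runs before the fasting
collapse so the cell budget counts every scheduled draw. No imputation is
performed anywhere; each downstream statistic declares its own
missing-data policy.

## Normalization

Per molecule k: S_{k,t} is the cross-subject standard deviation at time t
with the **population** denominator N; S̄_k is the mean of S_{k,t} over time
points with at least two available subjects; Y_{j,k,t} = (x_{j,k,t} −
x_{j,k,0}) / S̄_k; Ȳ_{k,t} is the subject mean of Y. The TVRI z-scores (below)
instead use the **sample** denominator N − 1. The two denominators are part
of the respective definitions and are deliberately not unified; each module
implements its own form exactly and the tests pin both against naive loop
oracles. Ȳ_{k,0} = 0 holds exactly for every retained molecule, and Y is
invariant under a common positive rescaling of a molecule's measurements
(numerator and S̄ scale together). A molecule whose S̄ is zero (constant
across subjects and times) is excluded as "zero dispersion".

## Responder calling

For every molecule and post-ingestion time point: the log2 fold change is
the mean over subjects of log2(x_t / x_0) (the per-subject form matches the
paired design; ratio-of-means is available by option), and a two-tailed
paired t-test compares x_t with x_0, dropping incomplete pairs pairwise and
requiring at least 3 pairs. Degenerate zero-variance differences are
reported as p = 1 when all differences are zero and as p = 0 with a flag
when all differences are equal and nonzero. Storey q-values are computed
over the pooled family of all molecule × time tests (per-molecule families
by option) with π̂₀ = #{p > λ}/((1 − λ) m) at fixed λ = 0.5 by default — the
fixed-λ estimator keeps the procedure deterministic; the cubic-spline
smoother over λ ∈ [0.05, 0.90] is available by flag. The q-values equal
π̂₀ × (Benjamini–Hochberg step-up), an identity the tests exploit as an
independent oracle. A molecule is a responder iff some time point has
|log2 FC| > 0.585 (strictly; 2^0.585 = 1.5) **and** q < 0.1; its direction
is the sign of the change at the earliest such time point, so curves that
cross zero later keep the direction of their first significant excursion.

## Clustering and labelling

Mean normalized trajectories Ȳ (molecules × times) are clustered with
Euclidean distance and Ward's method in the ward.D2 convention (pairwise
distances not pre-squared) and the tree is cut to a requested K (defaults:
13 for the molecule panel, 4 for the fasting-correlation matrix; the
originating analysis published cluster counts rather than cut heights, so K
is the configuration parameter). Cluster ids follow dendrogram leaf order.
Labels are computed on the cluster mean trajectory: amplitude large when
max |Ȳ| > 2.5 normalized units, small in (1.5, 2.5], otherwise not_clear;
kinetics transient when |Ȳ| after the global extremum falls to ≤ 50% of it,
else sustained (not_clear amplitude implies not_clear kinetics); direction
is the extremum's sign.

## PCA

Columns (time points) of Ȳ are mean-centred across molecules — no variance
scaling — and decomposed by SVD. Column-centring (rather than row-centring)
keeps flat molecules near the score origin, which is what makes PC1
interpretable as amplitude-and-direction. Scores are row projections;
the factor loading of a component at a time point is the Pearson
correlation between the component scores and that column, so loadings live
in [−1, 1]. Signs are fixed deterministically: PC1 is flipped if needed so
its loading at the time point nearest 90 min is positive (amplitude
component positive for increases), PC2 so its loading at the earliest
post-ingestion time is positive (rate component positive for early
excursions).

## Similarity indices

* **TVRI**: requires complete data for the molecule (any missing cell skips
  it, mirroring the exclusion of molecules not measured at every draw) and
  nonzero cross-subject variance at every time point. z across subjects per
  time (ddof 1), per-subject sd of z over time (ddof 1), TVRI = 1 − mean.
* **TPSI**: the t = 0 entries of x′ (identically zero) are part of the
  concatenation by definition; they deflate the correlation slightly and
  are kept. Pairs contribute only positions where both subjects are
  present. The correlation value is invariant to the ordering of the
  pair blocks, to per-subject additive constants (differencing removes
  them) and to a common positive rescaling.
* **TPSM**: subjects are concatenated in fixed dataset order; only
  positions where both molecules are present contribute. TPSM_Abs = |TPSM|.
* **Fasting-correlation profile**: Pearson r across subjects between the
  fasting values and each time point's values, per molecule (≥ 3 complete
  subjects per cell); the resulting responder × time matrix is clustered
  with the same Ward procedure at K = 4.

Pearson correlation is used throughout; zero-variance inputs yield NaN with
a recorded reason rather than an arbitrary value.

## Network analysis

Nodes are molecules; an edge joins k and l iff |TPSM_{kl}| > 0.6 (strict),
with the signed value kept as metadata. Shortest paths are unweighted.
Components are computed over nodes with at least one edge; isolated nodes
are reported separately. Betweenness uses Brandes' algorithm, normalized by
2/((n − 1)(n − 2)) with n the number of connected nodes in the whole graph;
per-component normalization is available by flag. deg_Normalized divides a
node's degree by the size of its own metabolic group in the analysed panel
— the verbal definition of the group-normalized degree; the printed
summation form of that index is ill-posed as written and is not
implemented.

## AUC and T_AUC1/2

Per subject and molecule, AUC is the signed trapezoidal area of x′ over
0–240 min (concentration × min); interior missing points are bridged by
linear interpolation, and fewer than two points leave the feature
undefined. T_AUC1/2 is the earliest time at which the cumulative signed
area reaches AUC/2, located by linear interpolation of the cumulative curve
within the bracketing interval; trajectories whose cumulative area crosses
the half level more than once are flagged non-monotone. Computing on x′
(not the raw curve; raw available by flag) makes AUC zero-baselined and
signed, so decreasing molecules get negative amplitudes. The correlation
screen relates each target's per-subject features to each reference
molecule's (configurable; by default the two responders with the largest
positive PC1 scores, the glucose/insulin-like pair of a glucose-challenge
panel), with Storey q over the pooled screen family and significance at
q < 0.1. Screen targets default to responders assigned to the first six
panel clusters — the clearly responsive branches of the dendrogram.

## Synthetic cohorts

The generator emulates the *structure* of an OGTT panel, not its
physiology: deterministic temporal archetypes (transient increase peaking
20–60 min, sustained decrease, transient decrease, flat, late rebound)
shared within metabolic groups; lognormal subject baselines (concentrations
are positive and their spread differs per molecule); concentrations built
as baseline × (1 + template + shape perturbation) and floored at 1% of
baseline. The shape perturbation is one process with a group-shared and a
molecule-private component (marginal sd `shape_noise_sd`, within-group
correlation `within_group_corr`); each draw persists across time points
with probability `rank_stability` and is redrawn otherwise. Persistent
draws cancel in the difference from fasting and keep the cross-subject
ordering fixed, so `shape_noise_sd` → 0 or `rank_stability` → 1 drives
TPSI → 1, while `rank_stability` → 0 with appreciable noise drives TVRI
down — giving monotone dials for both indices, which the tests verify over
≥ 20 seed replicates. Missing cells are deleted uniformly at random at
`missing_rate`; `missing_molecule_fraction` < 1 confines them to a random
molecule subset, emulating panels where dropouts concentrate in a few
assays.

Presets: `study-like` (20 subjects × 83 molecules; 6 large transient
increases, 3 lipid-like transient decreases, 8 amino-acid-like sustained
decreases, 2 rebounding hormones, flat filler in every group, and one
bridge molecule mixing the amino-acid and lipid templates — the
citrulline-like intermediary), `water` (every archetype flat, 83
molecules), and single-group `amino-acid-like` (stable ranks) and
`glucose-like` (reshuffling ranks) regimes for the TPSI/TVRI quadrant
recovery tests. Preset amplitudes keep decreasing templates above −1 so
concentrations stay positive without distorting the floor.

What passing tests on synthetic data do **not** show: assay-specific error
structure (heteroscedastic, occasionally non-lognormal), physiological
coupling beyond shared templates (no glucose–insulin feedback), non-random
missingness mechanisms, and demographic covariate effects. Results on real
panels depend on those properties; the synthetic suite validates the
statistics' implementation and their response to known ground truth, not
biological conclusions.

## Numerical notes and limitations

* Strict inequalities at every published threshold (fold change, q, TPSM,
  amplitude bands, missing-cell budget); values exactly at a threshold do
  not pass, except the missing-cell budget where exactly-at-threshold
  molecules are retained.
* Problem sizes in the test-suite simulations (12–20 subjects, 8–83
  molecules, 5–25 seed replicates) were chosen to make the checked
  contrasts decisive at desk scale; all statistics are O(subjects² ×
  times) or cheaper and run on much larger panels.
* Cluster-count defaults (13 / 4) are conventions of the reference design,
  not data-driven choices; no gap statistic or silhouette selection is
  provided.
* The pooled Storey family across molecules × times is the conservative
  reading when a family is unstated; per-molecule families change q-values
  and are available by option.
* TPSI on subjects sharing one shape up to multiplicative baseline scaling
  is slightly below 1 (the pooled pair correlation mixes slopes); it equals
  1 exactly only when the trajectories coincide.
* Growth-hormone-like "late rebound" curves have no single amplitude/rate
  description; they are generated (as the `late_rebound` archetype) and
  clustered, but their PCA projection mixes both components.
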