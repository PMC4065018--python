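# Methods

## The analysis

`amynet` quantifies, within single subjects, how the spatial pattern of
amyloid-β plaque load relates to the spatial pattern of intrinsic functional
connectivity, at two scales.

**Inputs.** Per subject, on one common voxel grid: one connectivity z-score
map per intrinsic network (the kind produced by back-projecting group-ICA
components), one PiB-PET standardized-uptake-ratio (SUVR) map, one
grey-matter density map; plus age, gender, group label and a neocortical
composite SUVR. Subjects with composite SUVR ≥ 1.15 are classified
PiB-positive (the conventional cut-off; the boundary value itself is
positive).

**Network voxel sets.** For each subject and network, the network is the set
of voxels whose connectivity z-score exceeds 1 (strict inequality; ties have
measure zero on continuous maps and the threshold is configurable). Sets
smaller than 200 voxels are rejected as degenerate — searchlight statistics
are meaningless below that; realistic networks here have ~10,000 voxels.
Connectivity values are natural-log-transformed to reduce the skew induced
by one-sided thresholding (configurable; the raw scale is also supported).

**Global correlation.** r_GLOBAL is the Pearson correlation between
log-connectivity and PiB uptake over all network voxels, Fisher-transformed
(atanh) for averaging and t-tests. Correlations are clipped at
±(1 − 1e−7) before atanh so degenerate perfect correlations stay finite.

**Local correlation.** To ask whether plaques depress connectivity *locally*,
over and above the network-scale coupling, the network-scale coupling is
first removed exactly: Gram-Schmidt orthogonalization demeans both vectors
and subtracts from one its projection onto the other, forcing the
whole-network correlation to zero (the module's defining contract, enforced
to |r| < 1e−10). A sphere of radius 6 mm then visits every network voxel;
within the sphere, only in-network voxels count as neighbors. Centers with
fewer than 25 in-network neighbors are skipped (boundary estimates are
unreliable); a neighborhood of exactly 25 is kept. The Pearson correlation
of the orthogonalized pair over the neighborhood, Fisher-transformed, is
recorded at the center (r_LOCAL). Because orthogonalization is asymmetric,
the whole procedure runs in both directions (PiB decorrelated w.r.t.
connectivity, and vice versa) and the two maps are averaged voxel-wise on
the Fisher-z scale (the scale on which values are recorded), keeping only
voxels recorded in both. Per subject and network, the summary statistic is
the median r_LOCAL over recorded voxels.

On a 2-mm isotropic lattice the 6-mm sphere holds 123 voxels (closed ball,
center included) — the order of magnitude ("~100 voxels") this kind of
searchlight is designed around. The implementation accumulates neighborhood
sums by shifting whole arrays once per sphere offset, and is verified
voxel-for-voxel against a brute-force KD-tree + direct-Pearson oracle.
Neighborhoods whose variance falls below 1e−12·n (flat PiB patches occur in
synthetic nulls) are skipped and tallied, not raised.

**Covariate residualization.** Median network grey-matter density, age and
gender (F = 1, M = 0) are regressed out of each scalar metric (median PiB,
Fisher-z r_GLOBAL, median r_LOCAL) by OLS, separately per network. Two
scopes exist:

* `pooled` — one fit across all subjects, single intercept; residuals are
  globally demeaned.
* `per_group` (default) — covariate slopes fitted within each group, and
  only the covariate contributions subtracted; the group mean is kept.

The default matters. Patients are ~5.5 years older than controls by design,
and grey-matter density tracks age, so in a pooled fit the age/grey-matter
slopes absorb a sizeable part of any true group effect (measured on the
default cohort: per-network group t on Fisher-z r_GLOBAL drops from 4.8–7.9
to 2.0–3.7). A per-group fit avoids that leakage; but a per-group fit whose
intercept were also subtracted would zero each group's mean and annihilate
exactly the group effects tested downstream. Keeping the group mean while
removing within-group covariate structure is the only variant under which
"group tests on residualized data" is a coherent procedure, so that is what
`per_group` does. Residuals are uncorrelated (|r| < 1e−10) with every
covariate within each fitted scope, and residualization is idempotent.
Constant covariates are absorbed by the intercept rather than raising.
No degrees-of-freedom correction is applied to downstream tests for the
fitted covariates; with very small groups (≲ 6 subjects) this visibly
shrinks the error stratum and inflates F — group sizes in the bundled
calibration experiments are kept at 10–23 per group where the effect is
negligible.

**Cohort statistics.** Group differences use a classical split-plot
(mixed-design) ANOVA: subjects-within-groups mean square tests the group
effect on df (g−1, N−g); the subject×network-within-groups stratum tests
network and group×network on df (m−1, (N−g)(m−1)); no sphericity
correction. The implementation is plain sums of squares and is checked
against an independent oracle and against `pingouin.mixed_anova`. Post-hoc
tests are Student (pooled-variance) two-sample t by default (Welch is a
switch), with explicit Bonferroni families (default 7 for per-network group
tests, 21 for pairwise network contrasts). Voxel-wise group t-maps use a
two-sided height threshold (default p < 1e−4), 26-connected cluster
labelling, a minimum extent (default k = 100), and — instead of
random-field theory — a permutation max-cluster-extent null for family-wise
corrected cluster p-values. A subsampling control repeatedly draws patient
subsets matched in size to the control group and reports the fraction of
draws in which the group test stays significant.

## The synthetic cohort generator

No imaging data ship with the package; the generator produces cohorts that
carry the structure the analysis is built to detect, with known effect
sizes.

* **Templates.** Each network is a sum of Gaussian blobs (default: six
  coupled two-node networks, sd 12 mm, amplitude 3.5, plus one single-node
  control network, sd 14 mm, amplitude 4.0, placed far from the coupled
  group) on a 56×72×56 grid of 2-mm voxels. Values are clipped at the blob
  amplitude; templates with fewer than 500 supra-1.0 voxels are rejected.
  With the default connectivity noise (sd 0.4, FWHM 6 mm), selected networks
  hold ~10,000 voxels.
* **Connectivity maps.** z_kj = template_j + smooth noise.
* **PiB maps.** P_k = baseline_ref + (baseline_group − baseline_ref)·u_k
  + b_global·u_k·W − c_local·u_k·L_k + smooth noise (sd 0.15).
  * W is the mean coupled template smoothed at FWHM 16 mm, centered — a
    wide-scale field that makes PiB track network topography (cores over
    periphery), driving a positive r_GLOBAL.
  * L_k is the subject's own fine-scale connectivity fluctuation,
    Σ_j w_j·(z_kj − S₆[z_kj]) over coupled networks, template-weighted
    (w_j ∈ [0,1]) so the negative coupling concentrates in network cores,
    and normalized to unit SD over network cores so c_local is the SD (in
    SUVR units) of the injected local component.
  * u_k is a mean-one lognormal per-subject burden factor (CV 0.3 in
    patients, 0 in controls) scaling baseline elevation, both couplings and
    the composite SUVR — heavier-burden patients couple more strongly, which
    is what the across-subject PiB vs r_GLOBAL correlation measures.
* **Defaults** mirror a realistic study: 23 patients / 12 controls; patient
  PiB baseline 1.4 vs 1.0; b_global 0.35 and c_local 0.02 in patients, both
  zero in controls and in the control network; ages 69.3 (7.4) vs 63.8
  (5.15); patient composite SUVR reflected above the 1.15 cut-off, control
  SUVR reflected below it (group separation is exact by construction);
  grey matter declines linearly with age plus noise; gender carries no
  injected effect and exists to exercise residualization. At these values
  the patient group shows mean r_GLOBAL ≈ +0.10…0.14 and mean median
  r_LOCAL ≈ −0.15 in coupled networks and ≈ 0 in the control network —
  the magnitude regime such studies report. Everything is bit-reproducible
  from one integer seed (per-subject generators spawned from a single
  `SeedSequence`).

**Two interactions worth knowing about.** First, injecting the global
coupling through a wide-scale field has a mechanical consequence: the
orthogonalization removes β·x voxel-wise, but a wide field cannot track x's
local fluctuations, so the residual carries −β times those fluctuations and
r_LOCAL turns negative in patients *even with c_local = 0*. The injected
effects are therefore only approximately independent: patient-negative
r_LOCAL on the default design is produced jointly by b_global and c_local.
Second, because L_k is a component of z, the −c_local·L_k term also drags
r_GLOBAL down, and at large c_local (≳ 0.1) the induced negative global
correlation is itself removed by orthogonalization and overcompensates
locally — median r_LOCAL is U-shaped in c_local. Dose-response is cleanly
monotone in the small-c operating regime (c ≤ 0.05), which is where the
defaults and the monotonicity checks live.

**What the generator does not emulate.** No PET counts, tracer kinetics,
partial-volume effects, BOLD time series, head motion, registration error,
or anatomical cortex geometry; maps are generated directly at the
statistical level the pipeline consumes, on a box grid. Passing tests
demonstrate that the pipeline recovers known structure of this statistical
form — not that the method is robust to acquisition artifacts or anatomy.

## Problem sizes used by the test suite

Unit tests run on small hand-built lattices (12³–20³). Null calibration
simulates 50 single-network cohorts of 20 subjects on a 24³ grid (~1,700
network voxels each) and checks that mean Fisher-z r_GLOBAL and mean median
r_LOCAL sit within 2·SE of zero and that one-sample tests reject at the
nominal 5% rate (binomial band). Pattern reproduction runs the full default
design (23 + 12 subjects, 7 networks, ~10,000 voxels each) once at a fixed
seed. The analysis scripts under `analysis/` re-run the same default design
end to end.

## Known limitations

* Neighborhood restriction to in-network voxels means r_LOCAL maps of
  overlapping networks are computed independently per network.
* The permutation t-map exchanges whole subjects; it assumes exchangeability
  under the null and does not model covariates.
* The mixed ANOVA is the classical decomposition — no sphericity correction
  and no REML mixed-effects model; with m = 1 network the within-subject
  strata are undefined and reported as missing.
* `pooled` residualization remains available but attenuates group effects
  whenever covariates differ between groups; see above.
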