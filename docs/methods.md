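# Methods

This note documents the models, conventions and numerical choices behind
`trabarch`, and what the synthetic-data validation does and does not show
about real µCT data.

## Volumes and VOI extraction

Volumes are 3-D arrays with a fixed anatomical convention: axis 0 runs
proximal→distal (slice order), axis 1 is the image vertical, axis 2 the
image horizontal with anterior at low index.  Left bones are mirrored
along axis 2 exactly once (enforced by a side flag), so medial–lateral
eigenvector components are comparable across specimens.

Landmarks are supplied as JSON files rather than interactive clicks; each
articular structure (humeral head, humeral trochlea, femoral head,
femoral lateral condyle) has a required landmark name-set.  The VOI centre
is the midpoint of the proximal-most/distal-most landmark slices and the
midpoint of the bounding box of the in-slice edge landmarks; midpoints at
.5 round down (a fixed, documented tie-break).  Cubes have odd edges so
"centred" is exact, specified as centre ± half-edge in 0-based voxel
indices.

The "no cortical bone" criterion is operationalised as cube ⊆ trabecular
compartment mask: the cube grows symmetrically one voxel layer at a time
and stops at the first face protruding from the mask.  The mask is an
explicit input (hand segmentation or erosion of a bone mask); the package
does not attempt cortical/trabecular segmentation.  Cubes below 16 voxels
edge are rejected as unusable — they would contain only a few trabeculae,
and parameters measured on them are dominated by sampling noise.

## Binary morphometry

**Thresholding.** Default is Otsu's between-class-variance maximiser; the
strategy is pluggable (`fixed:N`) and recorded in the output, because the
threshold routine used by any given scanning workflow is rarely published
and results can be sensitive to it.

**Purify.** Largest 26-connected foreground component kept; enclosed
cavities (background components other than the largest 6-connected one)
are filled.  The (26, 6) foreground/background connectivity pair is the
standard dual choice.  The result has exactly one component of each
phase, a precondition of the Euler-based connectivity estimate.

**BV/TV** is voxel counting.  **TV** = (edge · spacing)³ exactly.

**BS** triangulates the 0.5-level marching-cubes isosurface of the
zero-padded indicator, pre-smoothed with a Gaussian of σ = 0.8 voxel.
The smoothing is load-bearing: on raw binary data marching cubes
overestimates a sphere's area by ≈ 9% (staircase bias); with σ = 0.8 a
digitised ball of radius 40 voxels is reproduced to +0.5% and a large box
to −1.4%.  Larger σ would round corners of plate-like structures too
aggressively.

**Tb.Th / Tb.Sp** follow the Hildebrand–Rüegsegger model-independent
definition: a voxel's local thickness is the diameter of the largest
sphere containing it that fits in the phase; the parameter is the
volume-weighted mean.  Implementation: Euclidean distance transform, then
sphere-painting in descending radius bins of 0.5 voxel (bounding the
quantisation error at half a bin, well inside the ±1 voxel accuracy the
method itself has on digitised structures).  The volume border counts as
a phase boundary — trabeculae cut by the VOI face are not credited with
unbounded thickness.  Separation is computed on the background of the
purified volume (cavities already filled).

**Connectivity** is 1 − χ with χ the Euler characteristic of the bone
phase (26-connectivity, computed on the padded volume).  On a purified
VOI this equals the first Betti number — the number of redundant
connections, roughly the number of trabeculae.  The implementation is
validated against a brute-force oracle that builds the polyhedral
continuous analog (every subset of foreground voxels within a 2×2×2 cell
spans a simplex) and counts simplices.

**MIL fabric.** Directions are a quasi-uniform Fibonacci set on the upper
hemisphere (default 2000; tests and the acceptance script use 96–128,
which is ample for the strongly patterned phantoms).  Each direction gets
a parallel line grid at 1-voxel spacing with one seeded random sub-voxel
offset, sampled at 0.5-voxel steps with nearest-voxel lookup (numba
kernel; a plain-numpy caster serves as the test oracle).
MIL(ω) = total in-volume line length / bone–void boundary crossings;
directions with zero crossings are capped at the cast length and flagged.
The tensor is fitted by linear least squares on MIL⁻², and the ellipsoid
semi-axes (eigenvalues, normalised to mean 1) are reported descending.

**DA** = 1 − λ_min/λ_max, bounded in [0, 1].  The older unbounded
λ_max/λ_min convention is deliberately not used; published values for
this parameter suite lie in [0, 1].

**Eigenvector conventions.** Components are reported in anatomical
(x, y, z) = (anterior, vertical, proximodistal) order.  Each eigenvector
is normalised to the upper hemisphere (z ≥ 0; ties broken toward positive
x).  MDT is the first eigenvector as (θ, φ): inclination from the
proximodistal axis and azimuth from the anterior axis.  Both the angles
and the direction cosines are emitted, since either convention is found
in the literature.

## Phylogenetic machinery

The Brownian covariance C has entries equal to shared root-to-MRCA path
lengths.  Pagel's λ multiplies the off-diagonal entries (equivalent to
internal-branch rescaling on ultrametric trees).  λ is estimated by
bounded scalar search of the GLS likelihood on [−0.5, 1.5] (tolerance
1e-6), then clamped to [0, 1]: negative optima become 0, optima above 1
become 1.  Both ML and REML criteria are implemented.  The generic
`fit_lambda_gls` defaults to ML; the comparative chain (BMsp regression
and AN(C)OVA routing) uses REML, for two reasons: the reference tooling
for this kind of analysis (gls with a Pagel correlation structure)
defaults to REML, and at n = 29 species with a five-parameter design the
ML estimate of λ is biased low by the unpenalised estimation of fixed
effects (observed bias ≈ −0.3 under the study conditions, halved by
REML).  The AN(C)OVA λ is estimated under the model actually tested
(type + optional covariate) rather than the size regression alone —
otherwise a clustered group effect masquerades as phylogenetic signal and
the subsequent whitening absorbs part of the effect being tested.

**RRPP.**  Data and designs are whitened by C_λ^(−1/2) (eigendecomposition
square root; eigenvalues below 1e-10·max raise rather than being
pseudo-inverted).  The observed F compares full and reduced OLS fits of
the whitened data; the null distribution permutes reduced-model residuals
(999 permutations by default, seeded), and p counts the observed case, so
p ≥ 1/(n_perm+1).  R² is the effect sum of squares over the reduced-model
sum of squares.  Pairwise contrasts are distances between least-squares
group means (covariate at its mean), re-estimated under the omnibus
permutation schedule.  At C = I the observed F equals the classical
ANOVA F to machine precision; on null phylogenetic data the empirical
type-I rate is ≈ 0.05 (calibration experiment).

**Conspecific specimens** are averaged to species values before every
phylogenetic fit (the tree has one tip per species); specimen-level
values remain in descriptive tables and ratios.  No multiple-testing
correction is applied across parameters/VOIs, matching the single-test
reporting convention of this analysis family; a Benjamini–Hochberg pass
is available to users of the library.

## Comparative chain

**BMsp** is ln–ln: ln(species mass) ~ ln(species-mean TV), λ-optimised,
then each specimen is predicted from its own TV.  Mass and volume are
expected to scale isometrically on the log scale (slope ≈ 1), which the
recovery test confirms.  TV is the size proxy because the VOI is defined
as the largest cube fitting the articular structure, so TV tracks the
structure's size directly.

**Size screen / routing.**  A parameter is size-correlated when the RRPP
regression on BMsp has p < α (α = 0.05, configurable); it is then
analysed by ANCOVA (type effect over a BMsp-only reduced model),
otherwise by ANOVA.  Size-regression residuals are exported for the
"sc" visualisation convention.

**Phylogenetic PCA** removes the GLS mean a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹X and
eigen-decomposes the evolutionary covariance R = XcᵀC⁻¹Xc/(n−1),
converted to a correlation matrix by default because the variables mix
units (ln g, mm⁻³, mm, mm²).  BMsp is included as a variable.  Scores are
the centred (scaled) data on the eigenvectors; on a star tree the result
equals ordinary PCA.  Signs are fixed by making each component's
largest-magnitude loading positive.

**Two-block PLS.**  With two trait blocks, both are GLS-centred and
whitened by C^(−1/2) and rPLS is the correlation of the first
singular-score pair of the cross-covariance (permutation p by row
shuffling of one block).  For the "types vs phylogeny" question the
second block is the phylogeny itself; a full-rank tree representation
would let the SVD correlate any first block perfectly (rPLS ≡ 1), so the
default block is the leading principal-coordinate axes of the
double-centred Brownian covariance truncated at 95% of trace, used
without whitening — whitening a block derived from C would reinject the
tree into both blocks and void the permutation null.  Under this
construction clustered type assignments score rPLS ≈ 0.9 with small p,
and random assignments give approximately uniform p.

## Character history

Parsimony uses uniform-cost dynamic programming (down-pass cost vectors,
up-pass marginalisation), which yields the exact minimum step count —
identical to Fitch's algorithm for an unordered character — and the exact
MPR state set per node, verified against exhaustive enumeration on small
trees.  The single reported reconstruction resolves ties toward the
parent's state, then lexicographically; a transition is a branch whose
parent and child chosen states differ.  Ambiguity is reported, never
silently resolved.  RI = (g − s)/(g − m) with m = (observed states − 1)
and g = n_tips − max state frequency; undefined for invariant characters.

The Mk equal-rates likelihood uses Felsenstein pruning with per-node
rescaling and a uniform root prior; the ML rate is a bounded search over
log-rate (tolerance 1e-10 on the log scale, tighter than the 1e-8 the
rate needs).  Stochastic maps draw node states root-down from conditional
distributions, then rejection-sample branch trajectories conditioned on
endpoints (forced-first-event proposal for unequal endpoints, 1000
attempts per branch before the map's node states are redrawn).  Node
posteriors are frequencies over maps; mean change counts are bounded
below by the parsimony steps, as required.

## Synthetic data: what it emulates, and what it does not

Phantoms digitise continuous solids by the voxel-centre-inside rule, so
closed forms are exact up to edge effects: plate stacks (BV/TV = t/p,
Tb.Th = t·s, Tb.Sp = (p−t)·s), three-axis rod lattices
(BV/TV = 3f² − 2f³), aligned square rods (known main direction), balls
(BS, thickness = diameter), a wireframe cube (connectivity exactly 5),
and Gaussian random fields thresholded at a quantile to hit a target bone
fraction, with anisotropy induced by axis-wise smoothing lengths.  GRF
anisotropy has no closed-form MIL, so DA is validated ordinally — it
must increase with the smoothing aspect ratio — rather than against a
number.

The synthetic study mirrors the real design: a unit-height Yule tree with
29 tips (tip edges extended by one exponential waiting time so the
youngest sister pairs are not coincident), locomotor types assigned in
contiguous blocks of the ladderised tip order with frequencies
7/9/6/7 — clustered on the tree, as in the real clade; 35 specimens (six
species sampled twice); four VOI types.  Parameter baselines and
between-species standard deviations use the pooled humeral-head values of
the parameter suite (e.g. BV/TV 0.38 ± 0.05, Tb.Th 0.17 ± 0.02 mm);
mean humeral-head TV is ≈ 71 mm³ and femoral-head TV ≈ 111 mm³ on the
log scale.  Traits evolve with λ = 0.8; the configured effects are a
+2 sd natatorial shift on BV/TV and size couplings (1.0 and 0.8 sd per sd
of ln mass) on BS and Tb.Sp; ln mass = 3.3 + 1.0·ln TV + BM noise
(σ² = 0.5 for mass, 0.04 for TV about the allometry); specimen-level
measurement noise is 2.2% CV, matching reported intra-observer
repeatability.

What passing tests show: the morphometry reproduces known geometry within
stated tolerances; the permutation tests are calibrated; configured
effects of realistic size are recovered with the expected power.  What
they do not show: robustness to scan artefacts (beam hardening, ring
artefacts, partial-volume effects), to threshold misspecification on real
grayscale histograms, or to segmentation errors at the cortical boundary
— phantoms have clean two-phase histograms and exact masks.  The fabric
tensor is validated on idealised anisotropy; biological trabecular fabric
is less regular, and 5° direction accuracy on rods does not bound the
error on low-DA structures.

## Calibration experiment sizes

The experiments report: RRPP type-I rate (500 null datasets × 999
permutations; expected 0.05 ± 0.02), λ separation on a 128-tip tree
(50 replicates each of BM and iid data; λ ≥ 0.9 resp. ≤ 0.1 in ≥ 90%),
and end-to-end study recovery over 500 replicate studies — natatorial
effect detected (majority of its three pairwise contrasts significant)
with power ≥ 0.8, correct ANOVA/ANCOVA routing (BV/TV → ANOVA,
BS → ANCOVA) in ≥ 90%, and mean λ̂ within ±0.25 of the simulated 0.8.
Five hundred replicates keep the Monte-Carlo standard error of these
rates below 0.02; the detection rule (pairwise majority) is fixed in
`trabarch.calibration` and documented there.  Phantom tests run at
128–130 voxel edges, where closed forms hold within 2%; fabric estimation
in tests uses 96–128 directions, a deliberate economy over the 2000-
direction default that is inconsequential for phantoms with a single
dominant orientation.

## Known limitations

- No grayscale fabric methods, star volume, or structure-model index.
- No automatic articular-surface detection or cortical segmentation;
  landmark placement and the trabecular mask are user inputs.
- The Mk machinery is equal-rates only; no ordered or all-rates-different
  models, no Bayesian rate integration.
- The two-block PLS "phylogeny block" is one defensible construction
  among several; the truncation rank (95% of trace) trades sensitivity
  against the degenerate full-rank limit and is recorded in the output.
- Trait evolution other than Brownian-with-λ (e.g. Ornstein–Uhlenbeck)
  is out of scope.
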