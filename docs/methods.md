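# Methods

`wingmorph` implements a complete comparison of traditional and geometric
morphometric species discrimination on 2D wing landmarks, driven by a
synthetic-data generator that emulates a five-species horseshoe-bat
(*Rhinolophus*) study design. This note documents the statistical model,
the generator, the numerical choices, and what the test suite does and
does not establish.

## Geometric pipeline

**Superimposition.** Centroid size is CS = sqrt(Σᵢ ‖xᵢ − x̄‖²). Ordinary
Procrustes alignment centers both configurations, scales them to unit
centroid size and rotates the moving one by the 2D Kabsch (SVD) solution;
reflections are disallowed by default because all configurations are
right-wing halves. The reported distance is the partial Procrustes
distance — the root of the minimized sum of squares at unit size.
Generalized Procrustes analysis (GPA) uses full Procrustes scaling:
every shape stays at unit centroid size and the consensus is re-centered
and re-scaled each iteration; iteration stops when the consensus RMS
change falls below 1e-10 (max 100 iterations — machine-precision
convergence is cheap at this problem size). The consensus orientation is
inherited from the first input configuration and is therefore arbitrary;
all reported statistics are invariant to it, and any comparison of an
estimated tangent vector against a template-frame quantity must first
rotate frames (the helper used by the tests superimposes the consensus on
the template and applies that rotation landmark-wise).

**Tangent projection.** Aligned shapes are projected, at the consensus,
onto the orthogonal complement of the four similarity nuisance directions
(two translations, infinitesimal rotation, scale). Shape vectors have
length 2k = 34 and rank at most 2k − 4 = 30. The linear tangent space is
an approximation: with species means up to ≈0.25 Procrustes units from
the consensus, curvature introduces relative distortions of order the
squared distance (a few percent). This is a property of shape space, not
of any estimator; it is why the parameter-recovery tests at vanishing
noise are run without the interspecific offset.

**Measurement-error audit (Procrustes ANOVA).** Shape variation is
decomposed by sequential nested sums of squares over species,
individual-within-species, fixation-within-individual and photo residual,
summed over all tangent coordinates. Degrees of freedom are the
conventional nested df times 2k − 4; F compares each mean square with the
level below; p-values permute units one level below the tested effect,
with the (count+1)/(N+1) estimator (999 permutations by default, so no
p-value is ever zero). The audit verdict compares the *between-individual
variance component* — (MS_individual − MS_below)/photos-per-individual —
with the photo residual MS. The raw individual MS itself always contains
the photo-error component in a nested design, so comparing raw mean
squares could never flag inflated digitizing error; the component
comparison is the quantity that expresses "measurement error small
relative to variation among individuals". The fixation level is included
when photo replication exists below it, and merged into the residual
otherwise (with a logged note).

**Replicate averaging.** Per individual, tangent vectors and photo
centroid sizes are averaged arithmetically (three photos: two from the
better fixation, one from the other), reducing digitizing-error variance
by about the replicate count.

**Allometric correction.** Static (within-species) allometry is removed
by a pooled within-group regression of shape on centroid size: shape and
size are centered within species, one common slope vector b is fitted by
least squares on the pooled centered data, and the corrected shapes are
yᵢ − b·(xᵢ − x̄_species(i)) — residuals that retain the species mean
differences, which is what downstream ordination and classification
require. The percent of variance explained is 100·SS_pred/SS_total on
the pooled centered data (the two components add exactly). Raw centroid
size is the default size variable (log size is a flag); over the
simulated size ranges the two are nearly collinear within species.
Homogeneity of slopes is tested by permutation (the reduction in residual
SS from separate slopes, scaled by the common-slope residual SS; common-
slope residuals permuted across specimens), because a parametric MANCOVA
interaction test is ill-posed when a species has fewer individuals than
shape dimensions (6 < 30 here).

**Classification.** Leave-one-out cross-validation throughout: for each
held-out specimen the discriminant is refitted on the remainder. Pairwise
LDA assigns to the nearer group mean in the Mahalanobis metric of the
pooled within-group covariance; the multi-group analysis (canonical
variate analysis) whitens by the pooled within-group covariance and
classifies to the nearest group centroid in canonical space. The
covariance inverse is a Moore–Penrose pseudo-inverse at relative
tolerance 1e-10, so folds with more variables than specimens (30 tangent
dimensions vs 13 specimens in the smallest species pair) are handled
without ad-hoc regularization. Priors are equal (species-identification
context), zero-variance variables are dropped per fold with a logged
note, and nearest-centroid ties break by group label order for
determinism. The apparent (resubstitution) rate is also available: at
p = 30, n = 13 it inflates far above chance for pure noise (≈75% vs 50%)
while LOOCV stays approximately unbiased (slightly pessimistic, and
overdispersed across replicate datasets relative to a naive binomial
because folds share training data). This asymmetry is the methodological
argument for cross-validation plus PC reduction, and it is what the
acceptance checks demonstrate; claims that *cross-validated* null rates
exceed chance are not supported by this implementation.

**Dimensionality reduction.** Covariance PCA with axis signs fixed by the
largest loading; discriminant analyses are repeated on the first
{2, 3, 10, 17, 25} components. The retained-dimension suggestion uses
Anderson's chi-square test of equality of trailing eigenvalues with the
(n−1) multiplier: −(n−1)[Σ log λᵢ − q·log λ̄] against χ² with
(q+2)(q−1)/2 df, returning the smallest k whose trailing test is
non-significant at α = 0.05.

**Between-group PCA.** Axes are eigenvectors of the covariance of the
k *unweighted* species mean shapes (each species counts once despite
n from 6 to 22; a weighted variant sits behind a flag); all specimens are
projected after centering at the unweighted grand mean; per-axis variance
is reported as a share of the *total* specimen variance, so the k − 1
axes need not sum to 100%. Evolutionary allometry is quantified by OLS of
first-axis scores on centroid size with a permutation p-value.

**Mean-shape tests.** The pairwise statistic is the Euclidean
tangent-space distance between species mean shapes (equal to the
Procrustes distance in the small-variation regime); the null reshuffles
the two species' specimen labels (10,000 permutations in the full
profile, 999 in the quick profile). A flag re-superimposes the permuted
group mean configurations so the statistic is the actual partial
Procrustes distance; at these effect sizes it is indistinguishable from
the tangent statistic.

**Display.** Shape results are mirrored about the body midline axis
(total-least-squares line through the three declared midline landmarks)
into 31-landmark symmetric "bat-like" configurations and exported as SVG
wireframes with a CSV of coordinates.

## Synthetic-data generator

The generator emulates the study design the analysis assumes: five
species with 6, 7, 22, 20 and 21 individuals (76 total), 17 landmarks on
the right wing half, two fixations per individual and three photos kept
(2 + 1), with raw coordinates emitted y-up at random orientation (±15°),
position and ±0.5% scale jitter, in mm.

**Template.** A hand-drawn, centered, unit-size half wing with 17 named
anatomical roles (digit-3 tip/joints, digit-4 tip and phalanx joints,
wrist, elbow, digit-5 tip, shoulder, cranial and caudal midline points,
armwing trailing edge, tail tip, propatagium and handwing membrane
points). Lengths are landmark distances (hand wing: wrist→digit-3 tip;
arm wing: shoulder→wrist; digit distances 1–7, 7–9, 5–6, 4–5); areas are
shoelace areas of declared simple loops (handwing, armwing, tail, total
wing); wing span is twice the wingtip's distance from the midline axis.

**Shape model.** Each photo configuration is, in the tangent space at the
template:

    template + species offset + gain·a·(logCS_sp − logCS̄)
             + a·(logCS_ind − logCS_sp) + ε_ind + ε_fix + ε_photo

with isotropic Gaussian landmark noise at each hierarchy level
(σ_ind = 0.006, σ_fix = 0.0015, σ_photo = 0.002 shape units — the
simplest structure consistent with the Procrustes ANOVA assumptions),
then scaled to the individual's centroid size. Species mean log sizes
correspond to centroid sizes 150, 192, 200, 210 and 240 mm (smallest to
largest), with within-species sd(log CS) = 0.06; body mass is isometric,
mass = 1.6·10⁻⁶·CS³ g with 20% lognormal noise (wild bats' mass varies
strongly with feeding state), and forearm length is 0.25·CS with 1%
noise.

**Allometric direction.** The static and evolutionary allometric shape
change share one direction *a*: the wing reaching less far craniad with
increasing size (digit-3 region pulled caudally/inward, hand wing
relatively shorter, armwing trailing edge contracted). The drafted field
is projected onto the orthogonal complement of (i) the similarity
nuisance directions and (ii) the gradients, at the template, of the five
scale-free classical ratios (tip length ratio, tip area ratio, wingtip
shape index, aspect ratio, tail-to-wing area ratio). The projection makes
the dominant interspecific trend invisible *to first order* to
ratio-based variable sets while fully visible to the landmark
configuration — the localized, relational shape change that motivates
landmark methods. Without it, five ratios see the single dominant axis
nearly as well as thirty tangent coordinates do, and no ordering between
the method families can emerge; with it, ratio methods still pick up
second-order signal for the size-extreme species, which is exactly the
pattern the comparison should show. The magnitude ‖a‖ is solved
analytically from the target static-allometry fraction f = 0.16: after
3-photo averaging the non-allometric within-species tangent variance is
≈ d(σ_ind² + w_fix σ_fix² + σ_photo²/3) with d = 2k − 4 and w_fix = 5/9
for the 2+1 split, and ‖a‖²·sd(logCS)² = f/(1−f) times that residual.
The evolutionary gain (3.2, i.e. an interspecific slope 3.2 times the
static one) places the species along the same axis strongly enough that
the first between-group PC carries most of the total variance and its
scores track centroid size.

**Species contrasts.** Each species additionally has a fixed,
size-independent tangent offset orthogonal to *a*, with deliberate
regional structure: tail-tip components (visible to the tail-to-wing
area ratio and hence to the second traditional variable set),
phalanx-proportion components on the digit-4 joints — landmarks that lie
on no area loop, so they are visible to the digit-length residuals
(the classical identification characters for these species) but not to
any ratio — and elbow components visible only to the full landmark
configuration. The two hardest species (the intermediate sister pair)
get small, nearly opposite digit patterns and differ otherwise mainly
along the size axis, which is what makes the allometric correction
matter for them. Contrast norms (0.009–0.032 shape units) and the noise
levels were fixed by a pre-freeze calibration against the generator's
stated targets (static allometry fraction, first-axis variance share,
score–size R², method ordering) and are not tuned thereafter.

**What the generator does not emulate.** Within-species covariance is
isotropic, whereas real landmark data have strongly anisotropic,
correlated variation; real traditional measures are digitized manually
(tracing error the landmark-derived bridge here cannot have); there is
no digitizer drift, no left–right asymmetry, no phylogenetic structure,
no image distortion. Consequently the *absolute* classification rates
(the landmark method saturates near 100% here) are not comparable to
rates on real material; the qualitative structure — the ordering of the
variable sets, the cost of skipping allometric correction, the dominance
and size-association of the first between-group axis, the magnitude of
the closest interspecific Procrustes distance (≈0.04) — is the designed,
tested surface.

## Reproducibility and problem sizes

Everything is driven by a single integer seed; per-stage generators are
derived as named substreams (SHA-256 of the stage name mixed into the
seed sequence), so any stage is reproducible in isolation and a re-run
is bit-identical. The test suite exercises the full study size (76
individuals, 228 photos) and aggregates stochastic checks over fixed
seed panels — 20 simulated studies for the calibration and ordering
properties, 200–400 replicates for chance-level and permutation
calibration at small problem sizes — sizes chosen to keep the whole
suite around half a minute on one core while leaving the binomial bands
meaningful. Permutation counts default to 999 (10,000 in the CLI
"full" profile).

## Known limitations

- 2D landmarks only; no semilandmark sliding, no bilateral-symmetry
  decomposition, no 3D.
- The tangent-space linearization degrades quietly as group separations
  approach ≈0.3 Procrustes units; the permutation statistic does not
  re-superimpose per permutation by default.
- The pseudo-inverse LDA handles p ≥ n folds deterministically but is not
  a shrinkage estimator; rates in that regime depend on the tolerance
  convention (declared: relative 1e-10).
- Anderson's test assumes multivariate normality and n well above p; it
  is a convention for choosing a PC count, not an inference of true rank.
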