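# Methods

## The problem

Spin-crossover complexes switch between electronic spin states, and the
partial-charge distribution of the complex differs both between spin
states and between conformations. Classical force fields with fixed
point charges cannot express either dependence. `spincharge` implements
a conformation-adaptive charge model for a minimal heme–oxygen binding
site, Fe(C3N2)2(NH3)·O2: given only the Cartesian geometry of a frame,
it predicts the partial charge of each of the 14 heavy atoms in each of
the three low-lying spin states (singlet, triplet, quintuplet), together
with an ensemble-spread uncertainty.

## Model

### Descriptors

Each atom *i* is encoded by atom-centered symmetry functions: one radial
component per element *J*,

    G_i,J = Σ_{j≠i, j∈J} exp(−η (R_ij − R_s)²) f_c(R_ij),

and one angular component per unordered element pair {J, K},

    G_i,JK = 2^(1−ζ) Σ_{{j,k}} (1 + λ cos θ_jik)^ζ
             · exp(−η (R_ij² + R_ik² + R_jk²)) f_c(R_ij) f_c(R_ik) f_c(R_jk),

with the cosine cutoff f_c(r) = ½(cos(πr/R_c) + 1) for r ≤ R_c, 0 beyond.
Defaults are a single function per component with η = 1 Å⁻², R_s = 1 Å,
λ = +1, ζ = 1 and R_c = 99 Å, so every atom of the complex lies inside
the cutoff and descriptors are smooth if atoms ever approach it. The
angular sum runs over **unordered** neighbor pairs, each counted once;
this keeps G symmetric in (J, K) and avoids double counting (an ordered
sum would merely scale same-element components by 2, which trees absorb,
but the unordered form is the cleaner contract). cos θ is clamped to
[−1, 1] before exponentiation to guard floating-point overshoot.

For the heme model *including hydrogens* the element set is
{H, C, N, O, Fe}: 5 radial + 15 pair components, minus the Fe–Fe angular
component, which is identically zero by composition because a single Fe
cannot supply a neighbor pair — 19 components per atom. Components that
no atom can ever make non-zero are detected from the composition alone
and recorded as `dropped_components`; the layout is a pure function of
composition, never of coordinates.

The alternative scheme is a hand-picked internal-coordinate vector:
eight distances (Fe–N1…N4, Fe–N11, Fe–O12, Fe–O13, O12–O13), the
Fe–O12–O13 angle, and the two ring dihedrals N2-Fe-N1-C10 and
N1-Fe-N2-C5 — 11 numbers describing the whole conformation, shared by
every atom's regressor. Angles are reported in degrees; dihedrals are
signed, in (−180°, 180°], right-hand convention about the central bond.

### Regressors

One random forest per (atom, spin state) — 42 forests for the 14-atom
model. Each forest holds B = 200 trees grown on bootstrap resamples with
m = 5 features drawn at random at every node (m resolves from an
integer, a fraction of p, or a keyword: log2/sqrt/third/all), variance
splitting, grown until pure (`min_samples_split = 2`). The predicted
charge is the tree mean, q̄ = Σ_j T_j(x)/B, and the reported uncertainty
is the population spread σ = √(Σ_j (T_j(x) − q̄)²/B) — denominator B,
not B − 1, matching the ensemble definition used here. The ensembles
are scikit-learn `RandomForestRegressor`s; individual tree outputs stay
accessible so the aggregation can always be recomputed externally.

The train/test split is **frame-wise**: all atoms and all three spin
responses of a conformation stay on the same side, so no conformation
leaks across the split. Per-model seeds fan out deterministically from
one master seed via `SeedSequence(master, spawn_key=(atom, spin))`, so
training order is irrelevant and runs are exactly reproducible.

### Numerical note: feature compression for tree fitting

Symmetry-function values span tens of orders of magnitude — the Gaussian
factor of a far pair is ~e^(−R²). Decision-tree split finding resolves
candidate thresholds on an absolute scale, so components smaller than
the splitter's resolution are effectively invisible even though they
carry real signal (the angular components encoding the O2 orientation
range over 1e−20…1e−5 here). Trees are therefore fit on
log-transformed symmetry-function values (`FeaturizerSpec.log_compress`,
on by default; floored at 1e−300 so exact zeros stay finite). A strictly
monotone per-feature transform leaves an ideal tree's split choices
unchanged — this is a numerical-resolution fix, not a model change.
Internal coordinates are O(1)-scaled and used raw. The raw descriptor
values (the published functional form) are what `featurize` returns and
what the CLI `featurize` command writes.

## Synthetic data generator

Reference data for this system comes from non-adiabatic dynamics
trajectories with DFT ESP charges — expensive and not publicly
available. The generator is a statistical stand-in that reproduces the
reported structure of that data, not its quantum-chemical values.

**Geometry.** An idealized template (Fe at the origin, square-planar N4
at 2.0 Å, two planar C3N2 chelate rings, axial NH3 at 2.1 Å, O2 axial)
with 9 hydrogens for featurization parity (p = 19). Per frame the
binding coordinate is drawn uniformly: Fe–O12 distance d ∈ [1.8, 4.0] Å
and Fe–O12–O13 angle θ ∈ [100°, 180°]; O2 is placed accordingly and
every Cartesian coordinate receives N(0, 0.05² Å²) jitter. The ligand
sphere additionally relaxes smoothly along the binding coordinate
(equatorial dilation 0.15 Å and axial shift −0.20 Å over the full range
of the binding sigmoid, referenced to d = 2.0 Å). This co-variation
emulates how trajectory frames relax as O2 binds or leaves, and it is
what makes the binding state visible in the *local* environment of
ligand atoms far from O2; with pure i.i.d. jitter those atoms would
face an errors-in-variables floor no amount of data overcomes.

**Charges.** The true charge of atom a in spin state s is

    q_a = μ[a,s] + α[a,s]·(g(d) − ½) + β[a,s]·(cos θ − c̄) + ε,

where g is a logistic sigmoid of the Fe–O12 distance (center 2.9 Å,
width 0.35 Å) min-max normalized to [0, 1] over the default distance
range, c̄ is the mean of cos θ over the default angle range, and
ε ~ N(0, 0.01² e²). Centering g and cos θ makes μ the population-mean
charge, so baselines are directly interpretable: Fe carries μ = 1.2,
1.3, 1.5 e in the singlet/triplet/quintuplet — i.e. a +0.1 e
triplet−singlet and +0.2 e quintuplet−triplet offset, the systematic
spin signature. Couplings are spin-uniform by default (spin dependence
lives in μ) and sized so each ligand atom's total variation over the
geometry ranges lands in the 0.5–0.7 e band while Fe spans ~1.7 e, with
the O2 orientation (β) loaded mainly on Fe, O12 and O13. The μ columns
and both coupling tables are shifted to sum exactly to zero (μ over the
13 non-Fe atoms, preserving the Fe baselines; α and β over all 14), so
the final step — a uniform shift forcing every frame's charges to sum
exactly to the molecular charge (default 0) — is noise-only in
expectation and preserves the constructed offsets and spreads.

**What the generator does not emulate.** Real ESP charges respond to
every internal coordinate, not just two; real trajectories sample
Boltzmann-weighted, autocorrelated conformations rather than a uniform
binding coordinate; and real spin surfaces reorder geometries. Passing
tests therefore demonstrate that the pipeline recovers a smooth
two-coordinate charge model under realistic noise — they do not certify
accuracy on quantum-chemical data.

## Reference experiment and observed behavior

The canonical validation (`spincharge.experiments.run_reference_experiment`)
generates 4000 frames, splits half/half frame-wise, trains the 42
forests (B = 200, m = 5) on symmetry functions and evaluates on the
held-out half: per-spin average MAE below 0.02 e with every per-atom
Pearson r above 0.96. Fe is consistently the hardest atom (MAE ≈
0.04–0.05 e): its charge swings ~1.7 e along a steep sigmoid, and the
O2-orientation signal reaches the trees only through strongly entangled
descriptor channels. That residual is a forest-inversion limitation,
not noise — it persists on noise-free data and shrinks only slowly with
sample size. The 11 internal coordinates, which contain the binding
coordinate explicitly, resolve Fe markedly better at moderate-to-large
sample sizes (≳400 frames); below that the comparison is dominated by
small-sample variance.

Problem sizes used in the shipped validation: 4000 frames for the
reference experiment, 2000 for the noise-free recovery study, 1000–1500
for distributional checks, a few hundred for behavioral tests. These
are desk-scale choices that keep the full validation in the
few-minutes range while leaving every measured margin wide.

## Degenerate inputs and tie-breaks

* Coincident atoms (distance < 1e−8 Å) raise a degenerate-geometry
  error naming the pair; descriptors never silently return infinities.
* Collinear points in a dihedral raise rather than returning an
  arbitrary angle; the planar-trans dihedral is +180°, never −180°.
* Pearson correlation on zero-variance input raises an
  undefined-correlation error rather than returning a sentinel.
* Error standard deviation uses the sample (n−1) convention.
* Spin-difference histograms use bins centered on integer multiples of
  the bin width (default 0.02 e), so a difference concentrated at
  0.1 e falls inside one bin instead of straddling an edge.
* Model archives embed a format-version tag; unknown versions and
  truncated archives fail loudly at load time.

## Known limitations

* The charge model is specific to the 14-atom heme-O2 labeling; other
  molecules can be trained per-atom but the internal-coordinate
  defaults and the generator are heme-specific.
* Forests extrapolate poorly outside the sampled binding range; the
  tree spread σ under-reports error there (it measures ensemble
  disagreement, not distance from the training manifold).
* No out-of-bag machinery and no hyperparameter search beyond the
  m-sweep utility.
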