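# Methods

This note records the modelling and numerical choices behind `kedge`:
what is computed, under which conventions, which defaults were genuine
design decisions, and what the synthetic benchmark does and does not
demonstrate.

## Clusters and units

The unit of analysis is a finite, absorber-centred atomic cluster:
element (nuclear charge Z) plus Cartesian position for each site, with
one designated absorbing atom. Coordinates are Angstrom everywhere
internally; configuration values supplied in picometres must be
converted on entry. Energies are eV on a relative scale (0 at the
nominal edge unless stated otherwise).

Real applications start from periodic crystals; a helper
(`cluster_from_cell`) expands a cell into a finite cluster of a chosen
radius, but the package itself only ever operates on finite clusters,
and the synthetic generator produces finite clusters directly.

Two conventions are fixed and load-bearing:

- **Distance ties** (equidistant neighbours) are broken by original
  site order, via stable sorts, so nearest-N selection and feature
  vectors are deterministic for symmetric geometries.
- Clusters with two sites closer than **0.1 Å** are rejected at
  construction as corrupt geometry; this also keeps the Coulomb matrix
  away from its 1/r singularity.

## Coulomb matrix

`M_II = ½ Z^2.4`, `M_IJ = Z_I Z_J / r_IJ`, built from the N atoms
nearest the absorber (absorber included — it carries the dominant
on-diagonal term; a cluster with fewer than N sites leaves trailing
rows/columns zero). Rows and columns are permuted together into
descending row-norm order; zero-padding rows have norm 0 and therefore
sort to the end without special-casing. Equal row norms keep their
pre-sort relative order (stable sort). The feature vector is the
row-wise upper triangle including the diagonal, length ½(N²+N).

The distance unit inside the matrix is Angstrom by default, matching
every radius quoted elsewhere in the package; a Bohr switch is
provided because much of the Coulomb-matrix literature works in atomic
units. The switch only rescales off-diagonal entries by a constant.

## Radial distribution curve

`f(R) = Σ_{I<J} w_I w_J exp(−α (r_IJ − R)²)` over all pairs of atoms
inside the cutoff sphere around the absorber (the pair sum is not
restricted to absorber-involving pairs). Weights default to nuclear
charge; any per-element scalar map may be substituted
(property-weighted curves).

Defaults: cutoff 4.0 Å; grid 0 → 8.0 Å (twice the cutoff — the longest
pair distance two in-sphere atoms can realise) with 800 evenly spaced
points; α = 10 Å⁻². The point count was chosen so that the default
network carries roughly three million weights; α is interpreted in
Å⁻² because on a pm⁻² scale the kernel would be numerically zero for
every realistic pair distance, and the useful 0.5–200 range of α is
only sensible in Å⁻². All three are configurable.

`max_encoded_radius` (distance from absorber to the N-th nearest atom)
and `required_cm_dimension` (site count within a radius, absorber
included) quantify the complementary blind spots of the two
descriptors: a fixed-N CM sees a system-dependent radius, while a
fixed-radius RDC needs a system-dependent CM dimension to match.

## Spectra and broadening

Spectra are cross-sections on strictly increasing energy grids.
Broadening uses the energy-dependent width

    Γ(E) = Γ_i + Γ_f (½ + (1/π) arctan[(π/3)(Γ_f/E_w)(e/E_c − E_c²/e²)]),
    e = E − E_f,

with Γ = Γ_i for e ≤ 0 (the limiting value of the arctangent as its
argument → −∞), which also sidesteps the e → 0 singularity of the
E_c²/e² term.

The width model defines only a width; the kernel shape is a choice.
The default is a unit-area **Lorentzian** (core-hole lifetime
broadening convention); a Gaussian is switchable. The convolution
treats the input as piecewise-constant over its grid cells and
integrates the kernel over each cell in closed form (arctan/erf),
per output point, with the width evaluated at the *output* energy.
Consequences: the Γ → 0 limit is exactly the identity, total intensity
is conserved up to kernel tails that leave the grid, and the O(n²)
cost is irrelevant at a few hundred grid points. An FFT convolution
would not admit the energy-varying width.

Broadening is strictly post-processing: models are trained and scored
on unconvoluted cross-sections; refusing double convolution is
enforced via a flag on the spectrum.

Default width parameters (Γ_i = 1.25 eV, Γ_f = 15 eV, E_c = 30 eV,
E_w = 30 eV, E_f = 0) are plausible placeholders for a
transition-metal K edge on a relative grid and are expected to be set
per dataset. Intensity normalisation before MSE computation is a free
choice that changes the MSE scale; the package offers `max1` and
`none`, records the mode in metadata, and defaults to raw intensities.

## Network

Dense feed-forward stack: input → 1200 → 840 → 588 → 411 → output.
Hidden sizes follow "30% smaller than the previous layer" with
**floor** rounding (588 × 0.7 = 411.6 → 411; the rounding rule is a
package choice). Hidden activations are tanh; the **output layer is
linear** because cross-sections are unbounded above and a tanh output
would clip them. Cost is the MSE averaged over samples and grid
points. Optimisation is ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e−8 —
standard defaults) at η = 3·10⁻⁴ over shuffled minibatches of 100.
Dropout of 15% applies to hidden activations only (not input or
output), only during training, implemented as inverted dropout so
inference needs no rescaling. Default epoch budget 500, no early
stopping unless a patience is configured.

Weights initialise from a symmetric uniform fan-in scheme
(±√(1/fan_in)) drawn from one seeded generator that also drives
minibatch shuffling and dropout masks, so a (seed, data) pair
reproduces the training history bit for bit.

Features are standardised inside `train` (per-feature z-score from the
training set, stored with the model, reapplied at prediction): raw
charge-weighted features reach values of several hundred and would
saturate the first tanh layer immediately. Targets are left on their
natural scale.

Backpropagation is verified against central finite differences on
small networks (relative tolerance 1e−5) rather than trusted.

## Evaluation protocol

Cross-validation: K = 5 folds, 5 repetitions, a fresh seeded partition
per repetition; fold sizes differ by at most one; every sample is
tested exactly once per repetition. Per-fold model seeds are spawned
deterministically from the CV seed. The reported spread is the sample
standard deviation (ddof = 1) over the K × repetitions fold MSEs.
Learning curves subsample without replacement, seeded, then run the
same protocol per size.

Peak analysis operates on broadened spectra. Peaks are
prominence-filtered local maxima (default prominence 5% of the global
maximum). Parity matches each target peak greedily, in energy order,
to the nearest unused estimated peak within a window (default 5 eV);
unmatched peaks are counted, not silently dropped. R² is the squared
Pearson correlation of the pooled pairs by default (an identity-line
1 − SS_res/SS_tot variant is available); with fewer than two pairs R²
is reported as unavailable rather than fabricated. All of these
thresholds are recorded in the result object.

Centile ranking sorts per-sample MSEs ascending and assigns centile
⌈100·rank/n⌉ with minimum-rank ties, so centile 1 is the
best-predicted 1% and centile 100 the worst.

## Synthetic data generator

The generator emulates the *shape* of the real problem — Fe-centred
local environments paired with discretised spectra, where the spectrum
is a smooth function of invariant geometry — so the full pipeline is
trainable and testable offline.

Geometry: Fe at the origin; 8–30 neighbours per cluster drawn from
{O, F, S, Fe}; three shell radii per cluster drawn from 1.8–4.5 Å
(bracketing one to two coordination spheres); Gaussian radial jitter
(σ = 0.15 Å); uniform random directions; 1 Å minimum separation by
rejection. Shell-based placement, rather than uniform filling, puts
the information precisely where CM and RDC look: in the distribution
of interatomic distances.

Toy forward model: one Gaussian line per neighbour, centre
`5 + 15·d` eV for absorber distance d (Å), height `Z/d²`, shared width
2.5 eV, summed on a 0–100 eV grid (300 points by default). This map is
exactly invariant to rotation/translation/reindexing, Lipschitz in the
coordinates, and analytically transparent: scaling all bonds by s
moves every line centre by 15·(s−1)·d exactly, which the tests
exploit. It makes no claim of XANES physics — no multiple scattering,
no edge step, no charge-state shifts — so passing tests demonstrate
that the pipeline can extract geometric signal through these
descriptors, not that it reproduces real Fe K-edge spectra.

## Problem sizes used in the checks

The end-to-end learnability check trains on 2000 synthetic clusters
with the default optimiser, dropout and layer-shrink rule but a
width-reduced first hidden layer (300 neurons), a size at which the
500-epoch budget completes in about a minute on one CPU while still
beating the predict-the-mean baseline more than five-fold
out-of-sample. The learning-curve trend (2000 vs 100 samples, median
over three seeds) runs at further reduced resolution (200-point RDC,
64-wide net, 60 epochs, 3 folds). The acceptance script uses 1500
clusters, a 120-point spectrum grid, 300-point RDC features, and
networks of first-hidden width 128 (cross-validation) and 300
(held-out fit). These sizes are the package's benchmark conditions;
wider networks and more data only improve the margins, at
proportionally higher cost.

## Known limitations

- The toy forward model is geometric, not spectroscopic; conclusions
  about representation quality on real XANES data require real
  ab initio training spectra.
- Peak matching is greedy and orientation-dependent in principle;
  symmetric inputs give symmetric results, but pathological peak sets
  could pair differently when targets and estimates are swapped.
- The MLP is plain numpy on one CPU; it is sized for hundreds of
  thousands to a few million weights, not for GPU-scale experiments.
- `normalise` offers only max-normalisation; MSE values are therefore
  comparable only within a fixed normalisation mode.
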