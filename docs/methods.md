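# Methods

## Scope and model

`co2screen` predicts the thermodynamic stability of carboxylate adducts
formed when a carbanion R⁻ attacks CO2. The response is the CO2
affinity, CO2A = −ΔG° of the carboxylation step in kcal mol⁻¹
(positive ⇒ stable adduct). The predictive model is ordinary least
squares on three z-scored descriptors: the HOMO energy ε_HOMO, the
magnitude of the Hirshfeld atomic dipole at the carbanionic site CA,
and the buried Sterimol B1 at CA. The package covers everything from
SMILES to prediction; it does **not** implement the electronic
structure itself (SCF, dispersion, implicit solvation, RRHO
thermochemistry are engine territory, consumed through the backend
interface).

Two level-of-theory presets mirror the two-round screening economy: a
cheap level for geometries and the ε_HOMO pre-screen, and a refined
level for the affinity energies. Both are opaque strings handed to the
engine; the package never interprets method names.

## Structure handling

Input carbanions must carry an explicit −1 formal charge; an optional
helper deprotonates a user-chosen atom of the neutral C–H acid. Pattern
detection is structural (the unique carbon with formal charge −1 and
exactly two carbon neighbors) and therefore invariant to the atom
ordering of the input SMILES; ambiguous cases (several candidate sites)
are rejected, never auto-picked.

Conformer ensembles come from RDKit ETKDGv3 distance-geometry embedding
with MMFF94 ranking (UFF fallback), a desk-scale stand-in for a
metadynamics conformer search. The ensemble contract is independent of
the generator: conformers sorted ascending by energy, deduplicated at
0.25 Å heavy-atom RMSD (optimal superposition), retained within
6 kcal mol⁻¹ of the minimum, at most 50 embeddings per molecule,
seed 42 — all configurable. The retention settings are conventional
desk-scale values; the pruning pass is idempotent by construction
(greedy keep-first over the energy-sorted list). Units are Å and
Hartree throughout, with 1 Hartree = 627.509474 kcal mol⁻¹ defined at a
single site.

## Descriptors

**Sterimol.** L, B1 and B5 are computed from scratch. With attachment
atom *a*, axis unit vector **u** (from *a* toward the axis atom), and
van der Waals spheres (Bondi radii by default, configurable table):
L = max_i(proj_u(x_i − x_a) + r_i); for a direction **d** ⊥ **u**,
width(d) = max_i(proj_d(x_i − x_a) + r_i); B1/B5 are the min/max of
width over the perpendicular circle. The attachment atom itself does
not contribute. The direction search scans a 1° coarse grid, then
refines *every* local optimum by golden section (tolerance 1e-10 rad),
which keeps the result rigid-motion invariant to below 1e-9 Å even when
the optimum sits on a kink of the width profile. The test oracle is an
independent brute-force 0.01° scan; agreement is ~2e-4 Å, dominated by
the oracle's own grid resolution. L is reported without the historical
+0.40 Å CPK correction (a flag restores it).

**Buried Sterimol.** Atoms whose center lies farther than 5.5 Å (a
common buried-descriptor sphere; configurable) from the attachment atom
are excluded whole; the axis direction always comes from the original
axis atom. When the sphere holds every atom the value equals the plain
Sterimol exactly. An empty sphere is a typed degenerate-geometry error.

**Site B1.** The nucleophilic pattern offers two equivalent axes
(CA→C1, CA→C2); the site descriptor is the arithmetic mean of the two
buried B1 values, with both per-axis values retained. The mean is a
symmetric, order-free combination rule; for C1/C2-symmetric molecules
it reduces to either value.

**Electronic descriptors.** ε_HOMO is read from the backend's orbital
energies (HOMO located by occupancy). The site dipole is the Euclidean
norm of the Hirshfeld atomic dipole vector at CA — the magnitude is the
only rotation-invariant scalar of that vector — in atomic units.

**Aggregation.** Per-conformer values are aggregated as min, max,
Boltzmann-weighted average (weights exp(−ΔE/kT), energies shifted by
the minimum for stability; Gibbs energies when all conformers carry
one, electronic energies otherwise) and the lowest-energy-conformer
value (ties → lowest index). Default temperature 298.15 K; a 293.15 K
preset covers adduct stability at 20 °C.

## Regression and validation

OLS is fit on features z-scored with training-split statistics only;
standardized and raw-space coefficients are both reported.
Rank-deficient designs raise a collinearity error naming the features
linearly explained by the rest. Validation: R²/MAE on a seeded 75/25
train/test split (an explicit assignment can be supplied to reproduce
an external split exactly), leave-one-out Q² (n refits; the internal
solver works on the raw design with an intercept column, which yields
predictions identical to the z-scored fit), and seeded 5-fold CV with
fold sizes differing by at most one, aggregated as pooled-prediction
R². Best-subset search enumerates all subsets of the requested size
(guarded by a candidate cap that points to a staged/greedy fallback),
skips collinear subsets with a reason, and ranks by Q²_LOO with
test-MAE tiebreak — Q²_LOO is the natural primary criterion because it
is computed without a held-out set and penalizes overfit subsets.

The HOMO pre-screen passes candidates with ε_HOMO ≥ −0.140 E_h. The
comparison is inclusive: the threshold marks approximately zero
affinity, so a boundary candidate is worth the refined-level look. The
screen consumes the lowest-energy-conformer ε_HOMO by default (round 1
then costs a single calculation per molecule); a Boltzmann-averaged
variant is configurable. The benchmark correlation against Mayr
nucleophilicity N is a simple linear regression of CO2A on N, reported
as R² with slope; N is a kinetic parameter available only for
characterized nucleophiles, so it serves as an external check, never as
a model feature.

## Synthetic data

The fixture generator emulates the statistical structure of a
descriptor/response table, not its chemistry: true features are iid
standard normal, decoys are correlated 0.3 to true features in
round-robin order (a realistic level of incidental correlation in
descriptor pools), and the response is the planted linear combination
(coefficients 2, −1, 0.5) plus Gaussian noise. The default noise sigma
(0.5257 kcal mol⁻¹) makes the true-model R² ≈ 0.95 at the reference
sample size n = 31, matching the regime the affinity model operates in.
What passing recovery tests shows: at this signal strength and sample
size, the exhaustive search reliably identifies the informative subset.
What it does not show: robustness to non-normal descriptor
distributions, nonlinear structure, or heteroscedastic noise — none of
which the generator produces.

The mock backend computes smooth, bounded functions of interatomic
distances and composition (HOMO energies land in (−0.19, −0.10) E_h so
a −0.140 screen splits realistic batches both ways; Hirshfeld-like
charges sum exactly to the total charge; atomic dipole vectors are
covariant pair sums, so their magnitudes are rotation invariant). It is
explicitly non-physical and exists to exercise caching, filtering,
descriptor extraction and reporting deterministically.

## Numerical and design choices

- Boltzmann weights shift energies by the ensemble minimum before
  exponentiation; weights sum to 1 within 1e-12 even for deep wells.
- The Sterimol B1 golden-section bracket is one coarse-grid cell around
  each local optimum; refining every local optimum (not just the global
  coarse best) protects against minima separated by less than the grid
  resolution.
- QM results are cached content-addressed by (structure hash at 1e-6 Å,
  settings hash); reruns are free and bit-identical.
- Per-stage randomness derives from the single config seed via a stable
  hash, so stages can be re-run independently without reseeding.
- Failures are sandboxed per nucleophile with a typed reject taxonomy
  (pattern / embedding / convergence / parse / missing-feature); the
  report conserves inputs: every id appears exactly once across
  predictions and rejects.
- Degenerate inputs: single-atom systems yield empty pair sums (valid
  mock results); constant responses yield zero coefficients and an
  intercept equal to the mean; constant nucleophilicity input is a
  typed degenerate-input error.

## Problem sizes

The test suite and the acceptance script run at desk scale: 100 random
geometries for the Sterimol oracle comparison, 100 seeds for the
subset-recovery rate at n = 31 with 12 candidate features, conformer
ensembles of ≤ 10 embeddings for the pipeline batches. These sizes give
stable statistics for the properties under test while keeping a full
run in the low tens of seconds.

## Known limitations

- Affinity-level free energies are consumed from the backend, so the
  prediction quality is bounded by the engine's thermochemistry; the
  package adds no corrections.
- The buried-sphere exclusion is whole-atom by center distance; atoms
  straddling the boundary are in or out, never fractional.
- The linear model cannot represent the uncommon structural motifs that
  appear as outliers in this chemistry; such candidates are retained in
  training by default (an exclusion flag exists) and should be judged
  with that caveat.
- The conformer generator is a distance-geometry stand-in; ensembles
  for very flexible or metal-coordinating species should come from a
  dedicated conformer search through the external-adapter path.
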