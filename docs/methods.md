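# Methods

This note documents the models implemented in `dnaintercal`, the
assumptions behind them, the synthetic-data generators that stand in for
instrument and simulation output, and the numerical choices that a user
fitting real data should know about.

## Scientific setting

A planar anthracycline chromophore (doxorubicin, DOX, and its
tetrapeptide conjugate Leu–Ala–Gly–Gly–DOX) binds double-stranded DNA by
intercalation: the aromatic core slides between adjacent base pairs while
the substituents extend into the minor or major groove.  The package
implements the complete downstream analysis chain used to characterise
such binding from four independent experimental windows — absorbance
titration, fluorescence quenching, time-resolved fluorescence, and
isothermal titration calorimetry — plus the two simulation-side analyses
(umbrella-sampling free-energy profiles and conformational clustering)
used to rationalise the binding mode.

## Absorbance titrations (Benesi–Hildebrand)

Model: a 1:1 ligand–DNA complex with extinction coefficients
`eps_f` (free) and `eps_b` (bound) at the observation wavelength, 1 cm
path.  The linearization

    A0/(A − A0) = eps_f/(eps_b − eps_f) · (1 + 1/(K_A [DNA]))

is fitted by unweighted ordinary least squares of `A0/|A − A0|` on
`1/[DNA]`, with `K_A = intercept/slope`.  The absolute change is used so
hypochromic titrations (binding *decreases* absorbance, the situation for
these chromophores) are handled identically to hyperchromic ones; `K_A`
is invariant to the common sign of slope and intercept, and a genuinely
non-binding signal still surfaces as the non-binding-signal error.

Points with `|A − A0|` below a floor (default 1e-4 a.u., configurable)
are excluded and reported: the transform divides by `A − A0`, so points
where binding has produced no measurable change contribute pure noise
with enormous leverage.

The titrant concentration entering the regression is the *total* DNA
concentration, the near-universal convention when the titrant is in
excess.  In the conditions emulated here the ligand (18 µM) actually
exceeds the DNA (≤ 1.9 µM), which strains the excess-titrant assumption;
the generator therefore has two modes.  `excess_titrant_ideal` produces
data for which the linearization is exact (used for recovery tests), and
`exact_mass_balance` solves the full 1:1 equilibrium quadratic with
depletion of both species.  The linearized fit on mass-balance data is
biased; the bias shrinks monotonically as the ligand is diluted, which is
demonstrated by test rather than asserted away.

Free energies use `dG = −R T ln K_A` with `R = 1.986e-3 kcal/(mol K)`
and `T = 298 K` by default — the constant pairing under which the
published binding constants map onto the published free energies.  With
`K_A` in 1/M this is the usual 1 M standard-state convention.

## Fluorescence quenching

Three linearizations of the same 1:1 static-quenching model
(`F0/F = 1 + K_A [Q]`) are implemented:

* **Stern–Volmer**: `F0/F` vs `[Q]`; slope `K_SV`, bimolecular rate
  `k_q = K_SV/tau0` (ns → s conversion, factor 1e9, applied so `k_q`
  is in 1/(M s)).
* **Lineweaver–Burk**: `F0/(F0 − F)` vs `1/[Q]`; slope `K_D`,
  `K_A = 1/K_D`; the intercept is reported as a quality check (≈ 1
  under the model).
* **Double-log**: `log10[(F0 − F)/F]` vs `log10 [Q]`; the slope is the
  binding-site number `n` and the intercept `log10 K_A`.  On data that
  exactly obey the 1:1 static model the slope is exactly 1 — this is an
  algebraic identity, which is why it serves as an end-to-end exactness
  check of the whole chain.

Mechanism classification: quenching is called *static* when the apparent
`k_q` exceeds the diffusion-collision ceiling (2.0e10 1/(M s)) — no
collisional process can quench faster, so the "rate" must reflect
ground-state complexation — and, when lifetime data are available, the
lifetime is flat in `[Q]` (`|tau0/tau − 1|` ≤ 0.05 by default, covering
the ~2% relative uncertainty typical of these lifetime measurements).
*Dynamic* requires a sub-ceiling rate together with monotonically
decreasing lifetimes.  The exact threshold value is deliberately
classified *indeterminate*: the diagnostic is "much larger than", not
"at least".  Points with `F ≥ F0` are excluded with a warning rather
than erroring — instrument noise at low `[Q]` routinely produces them.

## Lifetime fitting

TCSPC decay histograms are fitted with `m(t) = A exp(−t/tau) + B` by
maximum likelihood under Poisson counting statistics.  Poisson MLE is
exact at arbitrarily low counts, where Gaussian least squares is biased;
at high counts the two coincide (tested).  Optimisation runs in log
parameters (Nelder–Mead; the surface is poorly conditioned in natural
units because `A` and `tau` differ by four orders of magnitude), and the
standard error of `tau` comes from the observed information —
a finite-difference Hessian of the negative log-likelihood at the
optimum, which matches the analytic Fisher information to ~1e-7 on these
problems.  A reduced chi-square is reported as a goodness-of-fit
diagnostic.  No instrument response deconvolution and no
multi-exponential models: the emulated data are well inside the regime
where a monoexponential tail fit is standard.

## ITC (Wiseman single-site model)

The overflow-cell concentration bookkeeping after cumulative injected
volume `v` into cell volume `V0` is

    M_t = M0 (1 − v/2V0)/(1 + v/2V0),   L_t = L_syr (v/V0)/(1 + v/2V0),

which tracks the exact continuous-mixing integration to ≤ 0.1% for
`v ≤ 0.1 V0` (tested).  Bound ligand follows the single-set-of-identical-
sites closed form

    L_b = ½ { L_t + n M_t + 1/K − sqrt[(L_t + n M_t + 1/K)² − 4 n M_t L_t] },

cross-checked against brute-force equilibrium bisection to 1e-8 relative
on a thousand random parameter draws.  Injection heats are increments of
`L_b · dH · V0` with the standard displaced-volume correction
`dQ_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`.

Fitting minimises squared residuals over `(n, logK, dH)` — logK for
conditioning — with initial guesses derived from the isotherm itself
(stoichiometry from the half-heat molar ratio, `K` from the inflection
concentration, `dH` from the first usable injection's molar heat).
Standard errors come from the Jacobian at the optimum.  The first
injection is discarded by default: a small priming injection (2 µL here
versus 10 µL for the rest) is the standard signature of syringe-tip
diffusion losses.  A warning is raised when the Wiseman `c = n K M0`
leaves [1, 1000], the window in which the three parameters are jointly
identifiable.  The cell volume is not part of the emulated experiment's
public record; the default 1.400 mL is typical for the instrument class
and must be supplied explicitly for real data.

The decomposition `dG = −RT ln K`, `TdS = dH − dG` is recomputed from
the *unrounded* fitted `K`; reporting both `K` and `logK` avoids the
small inconsistencies that arise when downstream numbers are derived
from rounded logK values.

A raw-thermogram path (per-injection linear baseline between quiescent
segments, trapezoidal integration) is provided for completeness;
integrated-heat tables are the primary input.

## Umbrella sampling and WHAM

The reaction coordinate `r` is the separation between the centres of
mass of the intercalation-site base pairs and the planar chromophore.
Windows carry harmonic biases `U_w(r) = ½ k_w (r − r0_w)²`; the package
default layout is 21 windows at 0.2 nm spacing with
`k = 143.05 kcal/(mol nm²)`, and `kT = 0.5925 kcal/mol` (298.15 K).

`wham_solve` iterates the standard self-consistent WHAM equations on a
uniform grid (default bin width 0.02 nm) until the window offsets change
by less than `tol` (default 1e-6 kcal/mol, cap 1e5 iterations; failure
to converge is flagged, not raised).  Bias factors are evaluated at bin
centres.  Samples outside the grid are counted into per-window edge
diagnostics rather than silently dropped, and non-overlapping adjacent
windows raise a connectivity error naming the gap — a non-overlapping
ladder is the single most common silent failure mode of real umbrella
runs.  The final self-consistency residual is stored on the profile.

Two reference conventions: `min_zero` (default on solve) and
`plateau_zero` via `set_reference`, which subtracts the mean over a
user-declared dissociated plateau and warns if that region has a
residual slope.  `locate_minimum` refines the argmin with a parabola
through the three bracketing bins and flags minima on the search
boundary.  Ties between equal minima break toward smaller `r` (the
bound state) by grid order.

The synthetic sampler draws from each biased density with vectorised
Metropolis Monte Carlo (50 parallel walkers per window by default,
0.05 nm proposals, 500-sweep burn-in, thinning 2), recording acceptance
rates and an autocorrelation-based effective sample size.  It is a 1-D
sampler of the *estimator's* input distribution, not a molecular
simulation: replica exchange between windows only improves mixing, which
the sampler controls directly through chain length, and the one-sided
end-wall restraints used in the emulated simulations act on a different
coordinate and are therefore omitted from the bias bookkeeping (a hook
for extra bias terms exists for users who need them).  Consequences of
these simplifications: passing recovery tests demonstrate the estimator
chain (histogramming, WHAM iteration, referencing, minimum extraction)
is correct, not that any particular molecular system is converged.

Reference profiles are cubic splines (or piecewise-linear interpolants)
through control points, held exactly constant beyond a plateau onset
(which defines the zero) and walled off below the first knot.  The
shipped profiles emulate the published shapes: a deep intercalated well
near 0.2 nm, a surface-bound shoulder, and a dissociated plateau.

An *absolute* binding free energy is deliberately not computed by
default: it requires a standard-state/volume correction whose recipe is
not part of the emulated study.  `binding_free_energy_1d` computes the
1-D ratio `−kT ln[∫_bound e^{−F/kT} / ∫_ref e^{−F/kT}]` over
user-declared regions and is documented as convention-dependent.

## Conformer clustering and structural descriptors

Frames are superposed by minimising the heavy-atom RMSD of the
intercalation-site base pairs (Kabsch/Wahba, proper rotations only,
degenerate selections rejected), after which all RMSDs are plain
coordinate RMSDs without refitting.  Input ensembles are assumed whole
and centred; no periodic-boundary imaging is applied.

Clustering is hybrid k-centers/k-medoids under an RMSD cutoff (default
0.3 nm): k-centers seeding starts from frame 0 (deterministic by
default — reproducibility was preferred over seeding variance; a
seeded-random option exists) and adds the farthest frame until every
frame is within the cutoff of a centre, which bounds the covering radius
by construction and fixes the number of clusters.  K-medoids refinement
(default 10 sweeps, convergence typically ≤ 3) replaces each centre with
the member minimising the summed within-cluster RMSD; ties break toward
the lower frame index.

The chromophore rotation angle between two poses is defined as the acute
angle between the first principal axes of the ring atoms, projected onto
the least-squares plane of the site base pairs (pooled over both
frames).  This is an explicit convention — the quantity is only defined
up to a choice of projection plane — and is validated on constructed
in-plane rotations.  Minimum inter-selection distances (e.g. amino
nitrogen to the nearest phosphate) are exact all-pairs scans.

The synthetic ensemble generator produces Gaussian-jittered copies of
blueprint conformers with known population fractions and labels, so
clustering accuracy is measured against ground truth.  Published cluster
populations and contact distances derive from trajectories that are not
reproducible at desk scale; they appear only as fixture presets, never
as assertions about real data.

## Pipeline

The YAML pipeline config carries explicit unit suffixes in every key
(`temperature_K`, `cutoff_nm`, ...) to keep unit errors visible.  Stage
failures are isolated: independent stages still run, the report records
the error, and the CLI exit code aggregates.  The report's consistency
checks verify, for every method, that the reported `dG` equals
`−RT ln K` to machine precision, and that the ligand affinity ordering
agrees across methods.  Re-running with the same config and seed
reproduces the report bit-for-bit.

## Problem sizes used in the shipped tests

Recovery studies use 21 windows × 1e4 Metropolis samples (1e5 exact
Gaussian samples for the analytic cross-check), 50 noisy ITC isotherms,
100-seed lifetime calibration at 1e6 counts, and 1000-frame conformer
ensembles — sizes chosen so the estimators are well inside their
asymptotic regimes while the whole suite remains a desk-scale
computation.

## Known limitations

* All titration fits are unweighted least squares; no heteroscedastic
  weighting scheme is exposed.
* The two titration-derived association constants (absorbance ~1e6 1/M,
  fluorescence ~1e7 1/M) are reported side by side without
  reconciliation; the order-of-magnitude gap between the methods is a
  property of the emulated study and the package does not adjudicate it.
* No multi-site or competitive ITC models, no heat-capacity analysis.
* No 2-D PMFs, no autocorrelation-based decorrelation of window samples
  (the effective sample size is reported as a diagnostic only).
* The PDB reader handles multi-model files only; trajectory formats are
  out of scope.
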