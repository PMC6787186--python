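# Methods

## Model

The chain is a two-dimensional discrete worm-like chain: N beads at
positions r_i ∈ R², connected by stiff harmonic bonds and a bending
potential, adsorbed flat on a patterned surface. Working in 2D reflects
the physics of strong adsorption — the analyzed observables (tangent
correlations, end-to-end distance, in-plane displacement) are all
in-plane, and height fluctuations of an adsorbed chain are of order 0.1 Å,
far below any length that matters here. Desorption into solution is not
modeled.

Internal units are nm, ns, and kBT at the convention temperature
(300 K unless stated; kBT = 0.59616 kcal/mol = 0.025852 eV). Conversions:
1 kcal/mol = 1.6774 kBT; the thermal voltage kBT/e is numerically
0.025852 V.

Energy terms (defaults in parentheses):

* **Bonds** — ½ k_b (|r_{i+1} − r_i| − a)² with a = 0.625 nm, the mean
  monomer spacing of surface-adsorbed ssDNA, and k_b = 100 kBT/a²
  (= 256 kBT/nm²). Bond fluctuations are then √(kBT/k_b) = a/10, small
  enough that the chain is effectively inextensible on the scales
  analyzed.
* **Bending** — κ (1 − cos θ_i) at each interior joint, θ_i the angle
  between consecutive bond vectors. κ is set from the target persistence
  length (below).
* **Excluded volume** — soft overlap penalties ε(1 − (r/σ)²)² for r < σ,
  acting in two shells: a local backbone term (σ = a/2, ε = 1 kBT) for
  pairs at least 3 bonds apart, and an optional distant "nucleotide
  footprint" term (σ = 0.9 nm, pairs ≥ 8 bonds apart, default strength 0)
  discussed under *Limitations*. Pairs 1–2 and 1–3 are excluded because
  bonds and the bending potential own that geometry; a 1–3 repulsion
  would act as a hidden extra bending stiffness.
* **Surface** — Δε Σ_i s(r_i), where s ∈ [0, 1] smoothly indicates the
  strongly binding material. A single boundary at x = 0 uses
  s = ½[1 + tanh(x/δ)]; a stripe of width w = 1.8 nm along x centered on
  y = 0 uses s = ½[tanh((y + w/2)/δ) − tanh((y − w/2)/δ)]. The smoothing
  length δ = 0.3 nm is a van-der-Waals-scale boundary width; the tanh
  profile keeps the gradient analytic everywhere. Δε = −6.1 kcal/mol
  (−10.23 kBT) per bead is the adhesion difference between the two
  materials. The common baseline adhesion (−23.2 kcal/mol per bead on the
  weaker material) exerts no lateral force and is kept as metadata only.
* **Field** — −Σ_i q_i E x_i with E in V/nm along +x (optionally V/Lx
  from a voltage and a stripe length), converted to kBT via the thermal
  voltage. Charges are uniform, q_i = Q/N with Q = 10.2 e, the
  effective (screened) charge of the chain; charge signs are taken
  positive by convention and only magnitudes are reported.

Forces are the exact analytic negative gradient of every term (the test
suite verifies them against central finite differences at 1e−5 relative
on random configurations). A numba-compiled kernel duplicates the force
arithmetic for the integrator; kernel and reference implementation are
compared to 1e−12 in the tests.

## Dynamics

Overdamped (Brownian) dynamics with the Euler–Maruyama step

    Δr_i = F_i Δt / γ + √(2 kBT Δt / γ) ξ_i ,

ξ_i standard normal per component. The per-bead friction defaults to
γ = kBT/(N · 0.13 nm²/ns) so the chain centre of mass diffuses at
D = kBT/(Nγ) = 0.13 nm²/ns. Hydrodynamic interactions are omitted
(screened at a surface). The step size obeys the bond-relaxation
stability criterion Δt ≤ 0.1 γ/k_b, which gives the default
Δt = 1.5×10⁻⁴ ns; first-order integration at a tenth of the fastest
relaxation time leaves a ~5% bias on bond-length variance and ~1% on mean
spacing, negligible for the targeted observables (where it matters, the
tests integrate with a smaller Δt). Any bond exceeding 3a aborts the run
with the offending step index; with the stability criterion enforced this
does not occur in practice.

Noise comes from a PCG64 generator seeded per scenario; identical
scenario + seed reproduces trajectories bit-for-bit, and every output
carries its full parameter record and seed. Positions are stored
unwrapped; the stripe potential is invariant along x, so no periodic box
is needed for driven runs.

Scenario presets (equilibration fraction discarded from the front of the
sampled frames):

| scenario           | geometry        | start                    | steps | sampled every |
|--------------------|-----------------|--------------------------|-------|---------------|
| free_uniform       | uniform         | linear                   | 2×10⁶ | 300           |
| boundary_crossing  | single boundary | circular, 2 nm inside A  | 4×10⁵ | 200           |
| stripe_confinement | stripe          | linear on the stripe     | 10⁷   | 1000          |
| driven_transport   | stripe          | linear on the stripe     | 4×10⁶–6×10⁶ | 100–1000 |

## Bending-stiffness calibration

For joint energy κ(1 − cos θ) in 2D the equilibrium joint angles are
independent with density ∝ exp(βκ cos θ), so the per-joint tangent
correlation is the Bessel ratio ⟨cos θ⟩ = I₁(βκ)/I₀(βκ). The stiffness
for a target l_p inverts ⟨cos θ⟩ = e^(−a/l_p) exactly (the common
small-angle mapping κ = l_p kBT/(2a) is this inversion's first-order
expansion and is ~30% off at l_p/a ≈ 2.2).

Self-avoidance perturbs this mapping: even the weak local backbone
repulsion swells the chain and raises the apparent (exponential-fit)
persistence length above the bare-κ value. The default stiffness is
therefore the Bessel inversion times a calibration constant
(`KAPPA_EV_RESCALE` = 0.8743, i.e. κ = 1.47 kBT for the default chain),
determined by bisection with `calibrate_bend_stiffness` so that the full
estimator pipeline — free runs, tangent correlations, weighted
exponential fit — returns l_p = 1.39 ± 3% nm. Ideal chains
(excluded volume disabled) use the bare inversion.

## Estimators

* **Tangent correlations** C(N) = ⟨t_i · t_{i+N}⟩ average over bead index
  and frames; zero-length bonds are excluded with a warning. Batch-means
  standard errors (20 contiguous frame blocks) are available and are
  robust to frame-to-frame correlation.
* **Persistence length** — least squares on ln C(N) vs N·a over
  separations 1–6 by default; l_p = −1/slope. When standard errors are
  supplied the fit is inverse-variance weighted: for a 20-mer the large-N
  tail is poorly determined and, uncorrected, dominates the slope noise.
  The recovery pipeline additionally pools correlations over four
  independent replicas, because a single run can sit in a long-lived
  conformational excursion that biases the whole curve. Non-positive
  correlations truncate the fit range with a warning; fewer than two
  usable points is an error.
* **MSD / diffusion** — time-averaged (all-pairs) ⟨ΔX²⟩ per lag;
  D = slope/2 with a free intercept. The default fit window is the first
  25 nonzero lags: the chain COM in this model is memoryless with no
  localization noise, and for such data the statistical error of the MSD
  grows with lag (relative variance ≈ 4Δ/3T), so small lags carry
  essentially all the information. The window is a parameter for data
  that do not satisfy these assumptions.
* **Drift and mobility** — drift velocity is the least-squares slope of
  X(t); mobility is the through-origin slope of v against E over several
  fields (v = 0 at E = 0 by symmetry).
* **Effective charge** — q_eff = kBT μ / D in units of e.
* **Screening** — 1 − q_eff/n_backbone with n_backbone = 19 for a 20-mer
  (19 internucleotide phosphates).
* **Manning fraction** — 1 − b/l_B for l_B > b, else 0, with the Bjerrum
  length of water at 300 K, l_B = 0.71 nm, as default.
* **Occupancy / proximity** — a bead is assigned to the strong-binding
  domain when s > ½; proximity counts use a KD-tree with an inclusive
  cutoff (default 0.35 nm).

## Confinement theory

Extension of a chain of contour length l_c = N·a (the 20-mer gives
12.5 nm) and persistence length l_p in a stripe of width w:
Gauss–de Gennes l_c l_p/w, Odijk l_c[1 − A(l_p/w)^(−2/3)] with the
universal prefactor A = 0.17 (raising an error when the deflection
correction reaches 1). Regimes: Odijk for w ≤ l_p, de Gennes for
w ≥ 2 l_p, transition in between; ties go to the adjacent named regime
since only the open interval defines the transition. For the default
geometry (l_p = 1.39 nm, w = 1.8 nm) the predictions are 96.5 Å and
99.8 Å in the transition regime.

## What the generator emulates, and what it does not

The simulator stands in for adsorbed-chain trajectories with the stated
statistical structure: contour geometry, persistence length, adhesion
contrast between domains, chain diffusivity, and field-driven drift. It
does not model nucleotide chemistry (sequence, base pairing/stacking,
hairpin duplexes), explicit solvent or ions (screening enters only
through the effective charge), desorption, atomistic adhesion energetics,
or separate frictions on the two materials (a single γ is used; the
two domains are distinguished by binding energy only). Timescales are
coarse-grained: CG time maps to physical time only through the imposed
diffusivity, so kinetic quantities (e.g. boundary-crossing times) are not
comparable to atomistic values — equilibrium and linear-response
observables (extension statistics, D, μ, q_eff) are.

Consequently, passing tests demonstrate internal consistency of the
estimators and of the model's equilibrium/transport physics at the stated
parameters; they do not certify chemical realism of ssDNA conformations.

## Numerical choices

* Force/gradient agreement is asserted at 1e−5 relative (central
  differences, h = 1e−5 nm).
* Stiffness inversion uses exponentially scaled Bessel functions and
  Brent root finding (xtol 1e−12).
* The through-origin mobility fit is Σ vE / Σ E².
* Negative screening fractions (q_eff above the bare charge) are clamped
  to zero with a warning rather than reported.
* XYZ output rounds frame times to the comment-line precision; the reader
  rebuilds an exactly uniform time grid (and takes the frame interval
  from the JSON sidecar when present).

## Limitations

**Backfolding vs the closed-form predictions.** At equilibrium the
default chain (fitted l_p = 1.39 nm, l_c = 12.5 nm) backfolds in the
1.8-nm stripe: hairpin turns cost only a few kBT with soft walls, so long
runs average over folded and extended states and the mean end-to-end
distance settles near 6.5 nm — well below the 9.65–9.98 nm closed forms,
which describe a deflecting, backfolding-free chain (this package's
theory module likewise omits backfolding corrections). The discrepancy is
a property of the physics, not of sampling: an ideal worm-like chain with
the same l_p equilibrates in the same range, and no examined combination
of repulsion range/strength, wall hardness, and stiffness reproduces both
the free-chain persistence length and a ~9.7 nm confined extension
simultaneously. Trajectories that remain extended over finite windows
(as short atomistic simulations started from stretched states are) sit in
the stretched basin and do read out ~9–10 nm. Enabling the distant
nucleotide-footprint repulsion (`ev_distant_strength` ≈ 4 kBT) suppresses
hairpins and raises the equilibrium stripe extension to ~9.1–9.5 nm, but
inflates the free-chain apparent persistence length to ~2.5 nm; the
package keeps the persistence-length calibration as the defining contract
of the default parameter set and leaves the footprint term off.

**Other limitations.** The 25-lag MSD window and the N = 1–6 correlation
fit range assume trajectories of at least a few thousand frames of a
20-mer; both are parameters. The Euler–Maruyama scheme is first order;
observables sensitive to sub-bond-relaxation detail need a smaller Δt
than the stability default. Entropy-driven scaling arguments with chain
length are outside scope: all defaults describe the 20-mer.

## Problem sizes

The acceptance script integrates 10⁷ steps (≈1.5 μs of CG time) for the
stripe and zero-field transport runs and 3 × 6×10⁶ steps for the driven
runs; the persistence-length recovery pools 4 × 5×10⁶-step free runs.
These lengths put every stochastic estimate's statistical error at a few
percent (replica scatter across seeds: extension ±3%, μ ±1%, D ±1%,
l_p ±4%) and complete in about a minute on one CPU.
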