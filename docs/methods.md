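# Methods

This note documents the models, estimators and numerical choices behind the
package, what the synthetic-data generators do and do not emulate, and the
design decisions taken where the methodology left room.

## Two-state mixture model and affected-spectrum extraction

Water in solution is partitioned into *bulk* water (molar absorptivity
ε_b(ν), identical to pure water) and *affected* water (ε_a(ν)), with N
moles of affected water per mole of solute. On a per-kg-of-solvent basis
the measured spectrum at molality m is

    ε(ν; m) = (1 − N·M·m)·ε_b(ν) + N·M·m·ε_a(ν),

with M = 0.018015 kg·mol⁻¹ the mean molar mass of water (the small isotope
correction from HDO is ignored; M is configurable). The model is linear in
m, so the pointwise slope at infinite dilution is fitted by least squares
**with the intercept fixed at the measured bulk spectrum** — with only
3–7 series points a free intercept would destabilise the slope — and

    ε_a = ε_b + (∂ε/∂m)₀ / (N·M).

The slope's standard error combines the residual variance of the series
fit (n−1 degrees of freedom) with the noise of the measured bulk spectrum
propagated through the fixed intercept (gain Σwm/Σwm²). Bulk noise is
estimated pointwise by cubic Savitzky–Golay detrending: for a smooth band
on a 1 cm⁻¹ grid the detrended residual is essentially pure noise, and the
residual variance is rescaled by the filter's exact noise-transfer factor
1 − 2c₀ + Σc². A noiseless series therefore yields (numerically) zero
uncertainty, which the exactness tests rely on.

### Determining N

N is fixed by non-negativity: the smallest N for which ε_a(ν) ≥ −δ across
the analysis window. This criterion is a reconstruction of standard
difference-spectroscopy practice; because the underlying literature does
not pin down one canonical rule, the implementation keeps it overridable by
a user-supplied N everywhere (and raises a dedicated "unidentifiable" error
when the slope has no negative region, in which case non-negativity cannot
bound N from below).

Numerically the feasibility condition N·M·ε_b(ν) + slope(ν) + δ(ν) ≥ 0 is
monotone in N, so a bisection on [0.1, 50] at resolution 0.01 finds the
boundary; a brute-force grid scan is kept in the tests as an oracle.

Two refinements make the criterion usable on noisy data:

1. **Pointwise tolerance.** Absorbance noise is proportional to the signal,
   so a single quiet-window δ cannot cover the window. The automatic
   tolerance is 3× the slope standard error, with the pointwise variances
   averaged over ~25 cm⁻¹ (they have few degrees of freedom per point).
   The scalar quiet-region estimate (median stderr over 2750–2800 cm⁻¹)
   remains available for reporting.
2. **Parametric-bootstrap bias correction.** The minimal-feasible-N
   statistic rides on the most negative noise excursion and is therefore
   biased (in either direction, depending on how the tolerance multiplier
   relates to the realised extreme). The procedure is replayed on a
   denoised (Savitzky–Golay, window 25 cm⁻¹, quadratic) slope plus
   synthetic noise at the estimated level — with the replay tolerance
   inflated by √(1+g²), g the filter's noise gain, because the reference
   still carries smoothed noise — and the median overshoot relative to the
   noise-free replay is subtracted. The bootstrap uses a fixed internal
   seed (deterministic for given data) and 40 replicates; for noiseless
   data the estimated noise is zero and the correction vanishes exactly.
   Under the validation conditions (1% multiplicative noise, 5 molalities,
   50 seeds) this brings the bias of N from ≈ −1 (uncorrected, 3σ
   tolerance) to ≈ −0.05 with a spread of ≈ 0.37.

## Ternary analysis: theoretical reference, ΔN, shared/excess water

For osmolyte mole fraction x among the solutes (water is excluded from the
mole fractions), the non-interacting reference is

    N_theor = (1−x)·N_p + x·N_o,
    ε_theor = [(1−x)·N_p·ε_p + x·N_o·ε_o] / N_theor,

normalised **per mole of solute pair**; N_exp from a mixture series is
interpreted on the same basis. ΔN = N_exp − N_theor is labelled *shared*
(negative beyond a tolerance), *excess* (positive) or *none*; the labelling
tolerance defaults to the quadrature sum of the supplied N uncertainties
(zero if none are given) and is overridable.

The decomposition maximises retained pure-solute affected water

    max  w_p·(1−x)·N_p + w_o·x·N_o,  (w_p, w_o) ∈ [0,1]²
    s.t. r(ν) = N_exp·ε_exp − w_p·(1−x)·N_p·ε_p − w_o·x·N_o·ε_o ≥ −δ(ν) ∀ν.

This objective is the package's reconstruction of the observable behaviour
of the published share analysis (pure contributions plus a non-negative
shared/excess remainder; a mixture whose osmolyte water is fully absorbed
into the shared population drives w_o to zero). It is a linear program and
is solved exactly with HiGHS (scipy.optimize.linprog) in a lexicographic
cascade: retained water, then w_p + w_o, then minimal |w_p − w_o| via an
epigraph variable — the last two levels only matter at degenerate optima
(e.g. proportional component spectra). Each level is frozen with a slack
that grows geometrically from 1e-8 to 1e-4 of the objective until the
cascade is feasible, because the solver's reported optimum can overstate
the exactly-achievable value by its feasibility tolerance. An exhaustive
0.01-step grid over (w_p, w_o) is kept in the tests as the optimality
oracle.

The remainder r(ν) is the shared/excess spectrum; its water count is
N_sh = N_exp − w_p(1−x)N_p − w_o·x·N_o (water bookkeeping is exact by
construction) and its integrated-intensity share is
100·∫r dν / ∫N_exp·ε_exp dν.

**Noisy inputs.** A pointwise max-constraint is fragile under white noise,
so the recommended entry point for measured spectra
(`denoised_decomposition`) smooths ε_exp, ε_p and ε_o with the *same*
quadratic Savitzky–Golay filter (25 cm⁻¹ window) — smoothing is linear, so
the mixture weights are unchanged — and sets δ(ν) = 3·g·σ̂(ν)·N_exp with
σ̂ the detrending-based pointwise noise estimate and g the filter's noise
gain. Under the validation conditions (true share 10%, w_o = 0, 1%
multiplicative noise, 50 seeds) the recovered share is within ±1.0
percentage point and w_o stays below 0.005.

## Band parameters and the frequency–distance transform

Band descriptors: position of the maximum ν° (3-point parabolic
refinement), gravity centre νg = ∫ν·ε dν / ∫ε dν (a proxy for the mean
H-bond energy), full width at half height (linear interpolation of the
half-height crossings; if a band crosses more than twice the outermost
crossings are used, with a warning), and the trapezoid integrated
intensity.

The transform to oxygen–oxygen distances uses a strictly monotone knot
table ν(R) interpolated with PCHIP (monotone cubic); the inverse is exact
(bracketed root-finding on the forward interpolant). P(R) =
ε(ν(R))·|dν/dR|/Z is evaluated on a 0.001 Å grid over the calibration
range; wavenumbers outside the spectrum's support contribute zero and set
a `clamped` flag; negative intensities within the tolerance δ are clipped
to zero and the clipped fraction recorded. Because the Jacobian shrinks
toward long distances, the mode of P(R) is not the image of the band
maximum, and mode ordering between two solutes can invert relative to their
band maxima — a regression test constructs exactly such an inversion.

**Calibration provenance.** The packaged `nu_roo_calibration.csv` is a
synthetic stand-in assembled from published ice/clathrate-hydrate
correlation trends (steep near 2.55 Å, saturating toward the free-OD
limit). It is adequate for the package's property-based validation and for
relative comparisons, but quantitative distances require a laboratory
calibration supplied as a CSV (`R_angstrom,nu_cm-1`); every distance
distribution records which calibration produced it.

## Trajectory analyses

Orthorhombic boxes and the minimum-image convention throughout; r_max is
capped at half the smallest box edge. Atom indices are 0-based in the API
and 1-based in configuration files.

* **Geometric centers** are unweighted centroids after minimum-image
  unwrapping relative to the fragment's first atom; fragments spanning more
  than half the box are rejected as ambiguous.
* **RDF**: g(bin) = (V/N)·count/(frames·V_shell) with exact shell volumes
  (4π/3)(r₊³−r₋³); default bin width 0.1 Å. For uniform points g → 1.
* **Orientation angles** between a probe's bond vector and the vector from
  its reference atom to a fragment center, accumulated into caller-supplied
  distance bins (angle bin default 5°); each distance bin's histogram is
  normalised to unit area over degrees, and empty bins are flagged `None`
  rather than NaN-filled.
* **Hydrogen bonds**: geometric criterion, donor-centred — O···O ≤ 3.5 Å
  and H–O(donor)···O(acceptor) angle ≤ 30°. These defaults are standard
  literature choices (the criterion is configurable and echoed in every
  report); a bonded pair counts once even if both members donate. Shell
  membership uses water-oxygen distance to the nearest solute heavy atom
  with a default cutoff of 4.0 Å, closed interval (a molecule exactly at
  the cutoff is in the shell).

## Synthetic data

Spectra are sums of pseudo-Voigt components. Defaults emulate the OD
stretch of HDO at 25 °C: bulk band at 2509 cm⁻¹, fwhh 162 cm⁻¹, peak molar
absorptivity 58.3 (integrated intensity ≈ 10⁴ dm³·mol⁻¹·cm⁻²); the
peptide-like affected band is a red-shifted two-component profile with
N = 6, the osmolyte-like one sits closer to bulk with N = 4. Series use
five molalities 0.2–1.0 mol·kg⁻¹, a 28.4 μm path length and 4.25 mol·dm⁻³
HDO (≈ 4% D2O) when written as absorbance files. Noise is multiplicative
(ε·(1+σz)), reflecting signal-proportional absorbance noise; the validation
level is σ = 1%.

The default Gaussian fraction is 1.0: identification of N by non-negativity
requires the affected band to decay at least as fast as the bulk band in
the far wings, and Lorentzian tails — which fall off only quadratically —
make the minimal feasible N systematically too small. Band asymmetry is
represented by multi-component sums instead. This mirrors a genuine
limitation of the experimental method, not just of the generator.

What the generator does **not** emulate: baseline drift and atmospheric
residuals, solvent-displacement effects at high molality (the mixture model
is exactly linear in m here), band-shape changes of ε_a with concentration,
and correlated (pink) detector noise. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to instrument systematics.

Toy trajectories realise known structure: uniform ideal gas (g→1), shells
at an exact radius, water lattices with an exactly known hydrogen-bond
count (each water donates to its +x and +y neighbours), and rigid 3-atom
probes with isotropic or fixed-angle orientation laws. Coordinates are
wrapped into the box; all randomness flows from one recorded seed.

## Validation problem sizes

The shipped tests and the acceptance script use: 601-point spectra
(2200–2800 cm⁻¹ at 1 cm⁻¹), 5-molality series, 50 noise seeds for recovery
statistics, 10 random instances for decomposition optimality, ideal-gas
trajectories of 1000 atoms × 200 frames, 10⁵ orientation probes, and a
4³ water lattice. These sizes give sampling errors comfortably below the
assertion tolerances while keeping a full run in seconds.

## Known limitations

* The non-negativity criterion cannot determine N when the affected band
  nowhere undershoots bulk (no negative slope region); N must then come
  from elsewhere.
* Per-pair normalisation of N_exp is a documented convention; translating
  to per-mole-of-peptide requires dividing by (1−x).
* The decomposition assumes exactly two pure components; a third
  co-solute, or concentration-dependent ε_a, is out of scope.
* Triclinic boxes, H-bond dynamics (lifetimes, residence times) and any
  electron-density-based interaction analysis are out of scope.
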