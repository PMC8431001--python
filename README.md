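# hydr

Analysis of solute hydration shells from HDO difference FTIR spectra and
molecular trajectories.

## The problem

Water next to a solute — a peptide backbone fragment, an osmolyte like TMAO
or urea — is spectroscopically different from bulk water. In isotopically
diluted water (a little D2O in H2O) the uncoupled OD stretching band of HDO
is a clean probe of the hydrogen bonds that each water molecule donates:
stronger, shorter H-bonds pull the band red. This package implements the
difference-spectroscopy workflow that turns concentration series of such
spectra into quantitative statements about hydration shells, and the
trajectory analyses that complement them:

* **Affected-water extraction.** The two-state model writes the measured
  molar absorptivity of a solution at molality *m* as

  ε(ν; m) = (1 − N·M·m)·ε_b(ν) + N·M·m·ε_a(ν)

  where ε_b is the bulk-water spectrum, ε_a the solute-affected spectrum,
  N the number of affected water molecules per molecule of solute and M
  the molar mass of water (kg·mol⁻¹). The slope (∂ε/∂m)₀ at infinite
  dilution, fitted with the intercept fixed at the measured bulk spectrum,
  gives ε_a = ε_b + (∂ε/∂m)₀/(N·M); N itself is the smallest value keeping
  ε_a non-negative across the analysis window (a user-supplied N always
  overrides the search).

* **Two-solute (ternary) analysis.** For a peptide–osmolyte mixture at
  osmolyte mole fraction *x* among the solutes, the non-interacting
  reference is N_theor = (1−x)·N_p + x·N_o with the correspondingly
  weighted spectrum. ΔN = N_exp − N_theor classifies the interaction:
  negative → *shared* water (overlapping hydration spheres), positive →
  *excess* water (extra molecules perturbed only in the mixture). A
  constrained decomposition then splits the experimental affected spectrum
  into retained pure-solute parts (weights w_p, w_o) and a non-negative
  shared/excess remainder, reporting its intensity share.

* **Distance distributions.** Through a monotone empirical correlation
  ν(R) between OD frequency and O···O distance, any band maps to a
  distance distribution P(R) = ε(ν(R))·|dν/dR|/Z, with mode R° and mean Rg;
  differences ΔP(R) between experimental and theoretical mixtures localise
  where H-bond structure changed.

* **Trajectory statistics.** Fragment-geometric-center radial distribution
  functions g(r) = (V/N)·dN/dV, distance-binned orientation angles of
  osmolyte bond vectors (urea C=O, TMAO N–O) toward a fragment center, and
  geometric hydrogen-bond counts split by solvation-shell membership.

A first-class synthetic-data module generates ground-truthed inputs for
every stage (mixture-model spectra series, toy trajectories with known
radial/orientational/H-bond structure), which is what the test suite and
the acceptance script run on.

## Worked example

```python
from hydr import (default_peptide_truth, make_binary_series,
                  extract_affected_water, band_parameters,
                  default_frequency_distance_map, to_distance_distribution)

truth = default_peptide_truth(N_true=6.0)          # two-component affected band
series = make_binary_series(truth)                 # 5 molalities, 0.2-1.0 mol/kg
result = extract_affected_water(series.series, series.bulk)
print(f"N = {result.N:.2f}")
p = to_distance_distribution(result.epsilon_a, default_frequency_distance_map())
print(f"R_mode = {p.r_mode:.3f} A, R_mean = {p.r_mean:.3f} A")
```

prints

```
N = 5.99
R_mode = 2.688 A, R_mean = 2.735 A
```

The affected number comes out at the generator truth (6.0) to within the
0.01 search resolution; the distance mode below the bulk value reflects the
red-shifted affected band mapping to shorter, stronger hydrogen bonds.
The same run from the shell:

```bash
hydr simulate spectra --config truth.yaml --seed 0 --out series/
hydr extract --manifest series/manifest.yaml --N auto --out affected.csv --report report.json
# N = 5.99 (delta = 0.003285)
hydr transform --in affected.csv --out p_of_r.csv
# r_mode = 2.688 A, r_mean = 2.735 A (hydr-default-ice-hydrate)
```

and a whole peptide + osmolyte + mixtures study runs from one config:

```bash
hydr run --config study.yaml
#   x=0.50: delta_N=+0.00 (excess), share=0.1%
```

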