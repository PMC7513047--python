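# activeblend

Simulation and interface analysis of **scalar active–passive polymer
blends**: melts in which half the chains are coupled to a hot Langevin
thermostat and half to a cold one.  Above a critical temperature asymmetry
such two-temperature ("scalar activity") blends phase-separate into steady
states with genuine heat flux through the interface — a minimal model for
the spatial segregation of transcriptionally active and silent chromatin.
The package targets researchers in coarse-grained polymer simulation and
active matter who want both the dynamics and the full non-equilibrium
interfacial tool chain in one place.

## What it computes

**Model.**  Kremer–Grest bead–spring chains (N = 40) with purely repulsive
WCA pairs, `U = 4ε[(σ/r)¹² − (σ/r)⁶] + ε` for `r < 2^{1/6}σ`, and FENE bonds
(`K = 30 ε/σ²`, `r_max = 1.5 σ`), at density `0.85 σ⁻³` in reduced LJ units.
Grønbech-Jensen–Farago Langevin dynamics at `dt = 0.005 τ` with
species-resolved reservoirs `(Th, Tc)` and shared friction `ζ = 1.5 τ⁻¹`.

**Analysis.**

* z-resolved slab profiles of density, mean square velocity,
  species-resolved effective temperatures `T_eff = ⟨v²⟩/3`, hot number
  fraction, pressure tensor; demixing order parameter `Φ = 2x − 1` from
  inter-chain like-species contacts; gyration radii by phase region.
* The asymmetry parameter `χ = (Th_eff − Tc_eff)/Tc_eff` and the entropy
  production per hot particle `Ṡ/3ζ = Th_eff/Th + Tc_eff/Tc − 2`, with the
  quadratic-to-plateau crossover locating the critical asymmetry χ*.
* Fourth-order (Binder-type) sub-box density cumulants
  `U_n = ⟨m₄⟩/⟨m₂⟩²` and their crossings; binodal plateau extraction and
  power-law fits `Δρ = A(χ − χ*)^β′`.
* Capillary-wave spectra of block-resolved interface heights,
  `L²⟨C²⟩ = 2/(γβ q²)`, mode autocorrelation times, interfacial stiffness
  `γβ` from both the spectrum and the width-scaling route
  `w² = ln(n_B/c)/(2πγβ)`, and χ* from the root of `γβ ∝ √χ − √χ*`.
* Seeded synthetic generators (two-phase slabs, q⁻² height ensembles, AR(1)
  mode series, critical-curve families) that make every estimator testable
  without MD.

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Measure the interfacial stiffness of a synthetic capillary ensemble and
recover the critical asymmetry from a family of stiffness estimates:

```python
import numpy as np
import activeblend as ab

# 400 independent interface snapshots with known stiffness 1.0 sigma^-2
spec = ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=16, n_snapshots=400, seed=7)
fields = ab.make_height_ensemble(spec)

spectrum = ab.spectrum_from_heights(fields)
est = ab.stiffness_from_spectrum(spectrum)
print(f"gamma*beta (spectrum) = {est.gamma_beta:.3f} +/- {est.uncertainty:.3f}")

per_nb = {nb: ab.make_height_ensemble(
    ab.SpectrumSpec(L=40.0, gamma_beta=1.0, nB=nb, n_snapshots=400, seed=20 + nb))
    for nb in (5, 6, 7, 8, 9)}
ws = ab.width_scaling_from_heights(per_nb)
print(f"gamma*beta (width)    = {ws.gamma_beta:.3f}  (c = {ws.c:.2f})")

chi = np.array([0.7, 1.0, 1.5, 2.0])
gb = 1.2 * (np.sqrt(chi) - np.sqrt(0.54))
chi_star, unc = ab.chi_star_from_stiffness(chi, gb)
print(f"chi* from stiffness root = {chi_star:.3f}")
```

Output:

```
gamma*beta (spectrum) = 1.002 +/- 0.005
gamma*beta (width)    = 1.038  (c = 1.24)
chi* from stiffness root = 0.540
```

The spectrum route recovers the generator's stiffness to well under a
percent statistically; the width route agrees within its ~5–10% fit
systematics; the stiffness root locates the asymmetry at which interface
fluctuations become soft.

A short MD run from the shell:

```bash
activeblend simulate --config examples/demo.toml --out demo.h5
activeblend profiles demo.h5 --slabs 60 -o density -o msv
activeblend capillary demo.h5 --nb 8 --nb 16 --out capillary.json
```

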