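# nanochrome

Chromatic digital counting of single plasmonic nanoparticles — a
simulation and analysis toolkit for dual-band dark-field biosensing.

## The problem

A localized surface plasmon resonance (LSPR) biosensor reads out molecular
binding as a tiny red shift of the scattering spectrum of an individual
gold nanoparticle (AuNP).  In the dual-segment chromatic scheme modelled
here, ~80 nm antibody-functionalised AuNPs flow through a microfluidic
channel under dark-field illumination; a multiband filter combination
leaves two nonadjacent detection windows — a narrow **G-band (545–552 nm)**
just blue of the LSPR peak and a wide **R-band (590–622 nm)** on its red
flank — recorded simultaneously in the green and red channels of a color
camera.  Each detected particle yields a spectral chromatic contrast

```
γ = (R_scat − G_scat) / (R_scat + G_scat)
```

Analyte (IL-6) capture thickens the protein shell on the gold core,
red-shifts the LSPR, and increases γ.  Because the single-particle shift is
far smaller than the population spread, the readout is *digital*: fit a
Gaussian to the negative-control (N.C.) γ distribution, place a cutoff at
its one-sided upper 95 % bound (μ + 1.6449 σ), and count the rate of
particles above it.  The signal per condition is

```
ΔNP% = 100 · (NP_sample/n_sample − NP_N.C./n_N.C.)
```

Regressing ΔNP% on log10(concentration) gives the standard curve; the
detection limits follow as `LOD = DF·3.3·σ_int/S` and `LOQ = DF·10·σ_int/S`
(S = slope, σ_int = intercept standard error, DF = dilution factor).

The package covers the full chain for users who want to study or extend
this class of assay without the physical instrument:

* **`nanochrome.optics`** — coated-sphere (gold core + protein shell) Mie
  scattering with embedded Johnson & Christy gold optical constants;
* **`nanochrome.instrument`** — filter-stack model, band integrals, γ,
  surface sensitivity `S_s = Δγ/ΔT`, band-configuration comparison;
* **`nanochrome.simulate`** — ground-truthed synthetic two-channel image
  stacks (Gaussian spots, Poisson/read noise, size dispersion, shell
  heterogeneity, doublet aggregates, Sips binding isotherm);
* **`nanochrome.spots`** — spot detection, annulus-background photometry,
  per-spot γ, pixel-area aggregate exclusion;
* **`nanochrome.counting`** — Gaussian fit, 95 % cutoff, ΔNP%, standard
  curves, LOD/LOQ, quantification and recovery;
* **`nanochrome.cli`** — `nanochrome simulate | analyze | calibrate |
  run-all`.

See `docs/methods.md` for the model assumptions and parameter choices.

## Worked example

```python
import numpy as np
from nanochrome import (
    ParticleModel, scattering_spectrum, peak_wavelength,
    configuration_comparison, NONADJACENT_BANDS, ADJACENT_BANDS,
)
from nanochrome.optics import default_grid

spec = scattering_spectrum(ParticleModel(80.0, 0.0), default_grid())
print(f"LSPR scattering peak: {peak_wavelength(spec):.1f} nm")

cmp = configuration_comparison(
    ParticleModel(80.0), NONADJACENT_BANDS, ADJACENT_BANDS, t1=1.67, t2=1.77
)
print(f"sensitivity ratio (nonadjacent/adjacent): {cmp['sensitivity_ratio']:.2f}")
print(f"signal enhancement: {cmp['enhancement_percent']:.1f} %")
```

prints

```
LSPR scattering peak: 559.0 nm
sensitivity ratio (nonadjacent/adjacent): 1.26
signal enhancement: 27.3 %
```

i.e. the bare 80 nm sphere in water peaks at ≈560 nm, and the nonadjacent
band pair responds ≈1.26× more strongly to growing the protein shell from
1.67 nm (antibody/PEG layer) to 1.77 nm (plus captured IL-6) than a pair of
adjacent 20 nm bands centred on the peak.

A full synthetic assay from the shell:

```bash
nanochrome run-all --seed 1 --out runs/demo \
    --concentrations 0.1,0.631,3.98,25.1,158,1000 --replicates 3
```

simulates a negative control plus six IL-6 concentrations (pg/mL),
analyses every frame, and writes `runs/demo/report.json` containing the
per-condition ΔNP%, the standard-curve fit (slope ≈ 1.5 %/decade,
R² ≈ 0.99 at default settings) and the LOD/LOQ on both the log10 and
concentration scales.

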