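# minwaves

Quantitative analysis tools for cell-free reconstitution assays in which
MinDE surface waves pattern FtsA-anchored FtsZ on lipid membranes. The
package covers the three measurement legs such a study rests on:

1. **Kymograph wave metrics** — wavelength and velocity of traveling
   membrane waves via Sobel edge detection plus a linear Hough transform on
   a kymograph taken parallel to the propagation direction; oscillation
   period of standing waves via per-pixel temporal autocorrelation; and
   two-channel phase relations (Pearson correlation and the spatial
   cross-correlation lag as a fraction of the wavelength) to classify
   antiphase vs in-phase patterns. Rim ("perimeter") kymographs handle the
   circling patterns seen in water-in-oil microdroplets.
2. **Expression kinetics** — per-replicate nonlinear least-squares fits of
   the phenomenological sigmoid

   y(t) = k' + k·tⁿ / (tⁿ + Kⁿ)

   with derived expression lifespan T_plateau = 2K/n + K (when synthesis
   effectively stops) and apparent translation rate v = k·n/(4K) (the slope
   at the half-rise time t = K), replicate aggregation as mean ± SD, and
   two-tailed Welch *t* tests for condition comparisons.
3. **QconCAT absolute quantification** — light/heavy (¹⁴N/¹⁵N) peptide peak
   area ratios referenced to ribosomal core-protein peptides of known
   concentration, averaging technical replicates within biological
   replicates.

A seeded synthetic-data module generates every input with known ground
truth: planar/spiral/standing surface waves with an optional anticorrelated
second channel, droplet rim patterns, sigmoid expression time courses, and
light/heavy peptide tables — so each analysis stage can be validated in a
closed loop.

The analysis stages are scikit-learn-style estimators
(`TravelingWaveEstimator`, `StandingWaveEstimator`, `AntiphaseEstimator`,
`SigmoidExpressionModel`, `QconcatQuantifier`) with plain-function wrappers,
so they compose with sklearn pipelines and model selection.

## Worked example

```python
import numpy as np
from minwaves import TravelingWaveEstimator, StandingWaveEstimator
from minwaves.geometry import StackGeometry
from minwaves.synth import WaveSimParams, simulate_traveling_wave, simulate_standing_wave

geom = StackGeometry(n_frames=60, height=320, width=320,
                     pixel_size_um=1.0, frame_interval_s=2.0)

# a noisy 76-um wave traveling at 0.5 um/s
wave = WaveSimParams(wavelength_um=76.0, velocity_um_s=0.5,
                     amplitude=100.0, noise_sd=10.0, seed=1)
est = TravelingWaveEstimator(direction_deg=0.0).fit(simulate_traveling_wave(wave, geom))
print(f"wavelength {est.wavelength_um_:.1f} um, "
      f"velocity {est.velocity_um_s_:.3f} um/s from {est.n_lines_} wavefronts")

standing = WaveSimParams(pattern="standing", wavelength_um=60.0,
                         period_s=105.0, amplitude=100.0, noise_sd=20.0, seed=3)
sgeom = StackGeometry(128, 96, 96, 1.0, 3.0)
sw = StandingWaveEstimator().fit(simulate_standing_wave(standing, sgeom))
print(f"period {sw.period_s_:.0f} s, oscillating fraction {sw.fraction_oscillating_:.2f}")
```

prints

```
wavelength 75.1 um, velocity 0.499 um/s from 5 wavefronts
period 105 s, oscillating fraction 0.94
```

i.e. the Sobel+Hough pipeline recovers the simulated wavelength and
velocity to ~1%, and the autocorrelation analysis nails the oscillation
period, with 94% of pixels qualifying as oscillating.

Kinetics and quantification work from tidy tables:

```python
from minwaves import fit_kinetics_dataset, quantify_table
from minwaves.synth import (KineticsSimParams, simulate_kinetics,
                            simulate_peptide_table, DEFAULT_CTERM_PEPTIDES)

fits, agg = fit_kinetics_dataset(simulate_kinetics(KineticsSimParams(seed=0)))
a = agg["MinD"].mean
print(f"MinD: rate {a['v_translation']:.3f} uM/min, lifespan {a['t_plateau']:.0f} min")

areas = simulate_peptide_table({"FtsA": 1.5, "MinD": 4.2, "MinE": 3.2},
                               ribo_conc_uM=1.0, noise_cv=0.05, seed=0)
summary, _ = quantify_table(areas, ribo_conc_uM=1.0,
                            cterm_peptides=dict(DEFAULT_CTERM_PEPTIDES))
print(summary[["protein", "concentration_uM", "sd_uM"]].round(2).to_string(index=False))
```

prints

```
MinD: rate 0.042 uM/min, lifespan 145 min
protein  concentration_uM  sd_uM
   FtsA              1.50   0.04
   MinD              4.34   0.05
   MinE              3.22   0.04
```

A CLI mirrors the library (`minwaves simulate|analyze-waves|fit-kinetics|
quantify|compare|run`); every run directory receives a `manifest.yaml` with
the tool version, config snapshot, input digests and per-stage status.

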