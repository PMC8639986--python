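# rtkquant

Quantitative analyses for studies of membrane receptor-tyrosine-kinase
oligomerization and intracellular-region conformation — the kind of
integrative workflow used to dissect how phosphorylation of the EphA2
kinase–SAM linker (the S892/S897/T898/S899/S901 cluster) shifts the
receptor between closed and extended conformations and drives
oligomerization. The package bundles five independent analysis stages,
each exercisable end to end on synthetic data with known ground truth:

| Stage | Module | Core quantity |
|---|---|---|
| FRET dimerization curves | `rtkquant.fret` | K_diss and intrinsic FRET Ẽ from FRET = f_D([T]; K)·x_A·Ẽ |
| Fluctuation brightness | `rtkquant.fif` | molecular brightness ε = σ²/⟨I⟩ − 1 per 15×15-px segment |
| SAXS primary analysis | `rtkquant.saxs` | Guinier Rg/I0, Debye I(q), P(r), D_max by regularized IFT |
| HDX-MS uptake | `rtkquant.hdx` | relative fractional uptake, difference profiles, residue maps |
| Kinase-screen statistics | `rtkquant.screen` | rankings, cumulative shares, site preference, co-phosphorylation |
| Synthetic data | `rtkquant.synthetic` | generators realizing each stage's statistical model |

The science behind each stage — models, assumptions, parameter defaults,
numerical choices, and limitations — is documented in
[docs/methods.md](docs/methods.md).

## Worked example: recovering a dimerization curve

```python
from rtkquant import fret, synthetic as syn

cfg = syn.FretSimConfig(k_diss=200.0, e_tilde=0.55, n_regions=300,
                        noise_sd=0.03, seed=1)
samples = syn.gen_fret_dataset(cfg)
result = fret.fit_dimerization(samples)
print(f"K_diss = {result.k_diss:.1f} (truth 200)")
print(f"E~     = {result.e_tilde:.3f} (truth 0.55)")
print(f"95% CI for K_diss: ({result.k_diss_ci[0]:.0f}, {result.k_diss_ci[1]:.0f})")
```

prints

```
K_diss = 217.3 (truth 200)
E~     = 0.569 (truth 0.55)
95% CI for K_diss: (185, 256)
```

i.e. from 300 noisy membrane regions the fit recovers the dissociation
constant within 9% and the intrinsic FRET within 4%, and the asymptotic
confidence interval covers the generating value. The same round-trip
pattern works for every stage — for example

```python
import numpy as np
from rtkquant import saxs, synthetic as syn

beads = syn.gen_toy_structure("dumbbell", radius=15.0, separation=80.0,
                              n_points=3000, seed=6)
curve = saxs.debye_intensity(beads, np.linspace(0.005, 0.35, 120),
                             method="histogram")
pr = saxs.ift_pr(curve, np.arange(60.0, 161.0, 5.0))
print(f"D_max = {pr.d_max:.1f} A (geometry: 80 + 2*15 = 110)")
```

prints `D_max = 108.8 A (geometry: 80 + 2*15 = 110)` — the indirect
Fourier transform recovers the maximum particle dimension of the
two-lobed fixture from its scattering curve alone.

## Command line

A thin CLI wraps the library for file-based workflows:

```sh
rtkquant simulate fret --out data/            # synthetic region table
rtkquant fret-fit --in data/samples.csv --out fit.json
rtkquant fif --images imgs/ --detector photon_counting --out fifout/
rtkquant saxs guinier --in curve.dat
rtkquant saxs ift --in curve.dat --out pr.txt
rtkquant hdx uptake --in state_table.csv --backexchange 0.25 --out uptake.csv
rtkquant kinase-screen rank --in kinase_table.csv --top 45 --out ranked.csv
```

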