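# mtseam

Desk-scale pseudo-helical cryo-EM reconstruction of kinesin-decorated
microtubules — and the analyses that surround such a structure: density-
steered flexible fitting of atomic models, rigid-body subdomain motion
analysis, and stopped-flow nucleotide-release kinetics fitting.

## Who this is for

Structural biologists and methods developers who want a small, fully
tested, ground-truth-verifiable implementation of the microtubule
processing stack: the lattice geometry with its seam, the forward
imaging model, per-filament seam/polarity determination, wedge-mask
pseudo-helical symmetrization, FSC resolution estimation, and the
protocol logic of ramped density-steered fitting.  Everything runs on
synthetic data in minutes on one CPU.

## The science in brief

A B-lattice microtubule of `N` protofilaments carries a 3-start monomer
helix: crossing all `N` protofilaments accumulates `3 × 40 Å` of axial
rise — one and a half tubulin dimer repeats — so the α/β register must
break at one lateral interface, the **seam**.  True helical averaging is
therefore impossible; instead, all imaged asymmetric units are
transformed onto a single "good" protofilament by the helical operators
(twist `360/N`°, rise `3·40/N` Å), averaged, re-expanded, and combined
through complementary wedge masks that sum to one everywhere
(**pseudo-helical symmetrization**).  Kinesin motor domains decorate one
per tubulin dimer (80 Å repeat), which both marks the dimer lattice —
producing the 80 Å layer line that reports decoration in a filament's
power spectrum — and provides the contrast for per-filament seam and
polarity determination by scoring segments against all `2N` candidate
references.  Resolution is estimated from masked half-map Fourier shell
correlation at the 0.143 threshold.

Down-stream, conformational changes between nucleotide states are
quantified by least-squares superposition and axis–angle (screw)
decomposition of subdomain motions; atomic models are refined into maps
by dynamics under a steering potential `−ξ·Φ(x)` (map low-passed to 6 Å,
backbone atoms only) whose coupling ξ ramps linearly from zero, with the
fitted frame selected just after the initial rapid transition of the
backbone-RMSD convergence curve; and microtubule-stimulated mant-ADP
release is fitted per trace as `F(t) = c + A·e^(−k_obs t)` and across
traces as the saturation hyperbola
`k_obs([MT]) = k_basal + k_max·[MT]/(K_0.5 + [MT])`.

See `docs/methods.md` for models, parameters, numerical choices and
limitations.

## Worked example

Simulate a noisy 14-protofilament data set, determine each filament's
seam and polarity, refine, and estimate resolution:

```python
import copy
from mtseam.pipeline import DEFAULT_CONFIG, run_pipeline

config = copy.deepcopy(DEFAULT_CONFIG)
config["dataset"].update(n_filaments=5, segments_per_filament=6, snr=0.3)
config["refine"].update(ladder=[20.0, 15.0], feedback_cycles=0)
config["seed"] = 3
report = run_pipeline(config)
print(report["resolution_A"], report["phantom_correlation"])
print(report["stages"]["seam"])
```

prints (from an actual run):

```
23.055 0.869
{'t_start_s': 60.77, 'seam_polarity_accuracy': 0.6, 'n_ambiguous': 3}
```

With this deliberately tiny data set (30 noisy repeats) the masked FSC
of the half-maps crosses 0.143 at ~23 Å and the final map correlates
0.87 with the noise-free phantom; at the default desk scale (~200
repeats) the phantom correlation exceeds 0.93 and seam/polarity
recovery per filament is essentially perfect when scored over 12 or
more segments (the acceptance suite measures 52/52 filaments at
SNR 0.3).

The kinetics side in three lines:

```python
import numpy as np
from mtseam.kinetics import KineticTruth, simulate_kinetics, fit_dataset

truth = KineticTruth(k_max=0.26, K_half=21.3)     # 1/s, µM
ds = simulate_kinetics(truth, truth.K_half * np.array([0.25, 0.5, 1, 2, 4]),
                       np.linspace(0, 40, 400), noise_sigma=0.05, n_reps=3, seed=1)
fit = fit_dataset(ds)
print(f"k_max = {fit.k_max:.3f} 1/s, K_0.5 = {fit.K_half:.1f} uM")
```

```
k_max = 0.259 1/s, K_0.5 = 21.5 uM
```

`k_max` is the maximal microtubule-stimulated release rate (the high-
concentration asymptote) and `K_0.5` the apparent half-saturation
constant of the hyperbola.

A `mtseam` command-line tool wraps the stages
(`simulate`, `run`, `fsc`, `domains`, `fit`, `kinetics`); try
`mtseam run --seed 1` or `mtseam --help`.

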