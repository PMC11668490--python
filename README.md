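# flsquant

Quantification of **filopodia-like structures (FLS)** — parallel,
fascin-bundled actin filaments that grow upward from a supported lipid
bilayer in cell-free reconstitutions — from multichannel confocal
z-stacks. The package is aimed at groups running FLS assays (or similar
bilayer-anchored filament reconstitutions) who need reproducible,
scriptable measurements of filament length distributions, actin-probe
displacement, and assembly/disassembly dynamics, plus the accompanying
gel-densitometry and ELISA binding-curve arithmetic.

## What it measures

**Lengths.** FLS are detected by per-slice segmentation and upward
z-linking from the bilayer plane; a structure's length is the path length
through its per-slice centroids,

L = Σᵢ √(Δxᵢ² + Δyᵢ² + Δz²),

measured from the base slice. A candidate is admitted as an FLS when
L ≥ 3 µm, its base area is ≤ 20 µm², and its base circularity 4πA/P²
(crack-length perimeter) is ≥ 0.5. Steady-state length samples are
summarized by the shifted-exponential model
p(L) = λ·exp(−λ(L − L₀)) for L ≥ L₀ = 3 µm, whose maximum-likelihood
rate is λ̂ = 1/(L̄ − L₀) with an exact χ²₂ₙ-pivot confidence interval;
log-frequency histograms expose departures from exponentiality as
curvature.

**Probe displacement.** For two-channel fields (actin + an F-actin probe
such as GFP-UtrCH or LifeAct), per-slice fluorescence areas define the
*actin extent* (first slice with zero actin area), the *probe extent*
(first slice where probe area ≤ ½ × actin area), and their ratio —
~1 for full decoration, < 1 when the probe is displaced from older
actin. Per-field normalized z-profiles and 5×5-pixel intensity profiles
along single structures complete the picture.

**Dynamics.** Time-lapse detections are linked by base-centroid
proximity (bases are membrane-anchored and move least); tracks shorter
than six consecutive frames (2 min at 20 s intervals) are excluded, and
mean length versus time aligned to each track's first detection yields
growth-rate estimates.

**Assays.** Co-sedimentation densitometry
(pellet/(pellet+supernatant)×100 after strip-background subtraction) and
four-parameter logistic ("variable slope") binding curves
R(x) = bottom + (top − bottom)/(1 + (EC50/x)^h) with EC50 fold-changes
and log-scale error propagation.

**Synthetic ground truth.** Because every stage is easiest to trust when
it can be checked against known truth, `flsquant.synthetic` renders
complete two-channel z-stacks and time-lapses — exponential lengths,
tapered-cylinder structures, anisotropic Gaussian PSF, configurable
noise, probe truncation, telegraph growth/shrinkage dynamics and
photobleaching — with an exact per-structure ground-truth table.

## Worked example

```python
import numpy as np
import flsquant as fq

scene = fq.SceneParams(n_fls=50, seed=1)          # one synthetic field
stack, truth = fq.generate_stack(scene)           # 2-channel 60×60×30 µm stack
paths = fq.detect_fls(stack, "actin")             # segment, link, filter

lengths = np.array([p.path_length for p in paths])
fit = fq.fit_shifted_exponential(lengths, location=3.0)
prof = fq.extent_ratio(stack)

print(f"true structures: {truth.n_fls}, detected FLS: {len(paths)}")
print(f"mean length: {lengths.mean():.2f} um")
print(f"exponential rate: {fit.rate:.3f} /um (95% CI {fit.ci_low:.3f}-{fit.ci_high:.3f})")
print(f"extent ratio: {prof.extent_ratio:.2f}")
```

prints

```
true structures: 50, detected FLS: 50
mean length: 6.96 um
exponential rate: 0.252 /um (95% CI 0.187-0.327)
extent ratio: 0.90
```

All 50 rendered structures are recovered; the fitted rate agrees with
the generating rate (0.25 µm⁻¹, i.e. mean length 3 + 1/0.25 = 7 µm),
and the extent ratio is ~1 because the probe channel fully decorates
the actin in this scene.

The same pipeline runs from the shell:

```bash
flsquant simulate --out-dir run1 --n-fields 3 --seed 1
flsquant detect   --out-dir run1 run1/field*.ome.tif
flsquant displace --out-dir run1 run1/field*.ome.tif
flsquant stats    --out-dir run1 run1/fls.csv
```

Each stage writes CSV/JSON outputs plus a `manifest.json` capturing the
resolved configuration and package version, so every number is
re-derivable. A YAML file (`--config`) sets scene, threshold, filter and
tracking parameters; identical configuration and seed give byte-identical
outputs.

## Layout

- `src/flsquant/synthetic.py` — scene/dynamics parameters, ground truth, generators
- `src/flsquant/stack.py` — calibrated stack container, OME-TIFF I/O
- `src/flsquant/segmentation.py` — thresholding, components, z-linking, filters
- `src/flsquant/displacement.py` — extent statistics and intensity profiles
- `src/flsquant/tracking.py` — frame linking, inclusion rule, aligned profiles
- `src/flsquant/length_stats.py` — field means, exponential fits, histograms
- `src/flsquant/assays.py` — densitometry and 4PL binding curves
- `src/flsquant/config.py`, `cli.py` — configuration, manifests, CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
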