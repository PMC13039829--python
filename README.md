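# retquant

Quantification toolkit for studies of photoreceptor degeneration and synaptic
remodeling in the mouse retina. It reimplements, as a tested and reusable
pipeline, the measurement machinery such studies run on four data classes:

- **Confocal immunofluorescence** — maximum-intensity projections, binary
  masks of the outer nuclear layer (ONL), outer plexiform layer (OPL) and
  inner segments (IS), rod-bipolar **dendritic sprouting** length and density
  in the ONL, compartmental mean intensities, TUNEL-positive nucleus counts,
  and ONL thickness at randomized grid positions.
- **Transmission electron microscopy** — per-terminal morphometry of rod
  spherules and cone pedicles: terminal area, mitochondrial areas and counts,
  and mitochondrial occupancy (Σ mitochondrial area / terminal area).
- **Electroretinography (ERG)** — a-wave amplitude (baseline → trough),
  b-wave amplitude (a-trough → subsequent peak), implicit times, the b/a
  ratio, and the reference-latency rule for degenerate traces that lack a
  b-wave peak; per-intensity group summaries with unpaired t-tests.
- **Label-free quantitative proteomics** — Scaffold-style peptide/protein
  identification filters, normalized spectral counts (N-SC), and a
  triple-criterion differential-expression call: signal-to-noise weight
  **W = (μ₁ − μ₂)/(δ₁ + δ₂)** with |W| > 0.8, one-tail unequal-variance
  (Welch) t-test with p < 0.05, and an empirically calibrated fold-change
  window (threshold in [1.5, 2.0], derived from inner-quartile control
  ratios on an ln–ln scale). A protein is a DEP only when **all three** pass.
  Downstream: p-value ranking, Venn-style set comparison, and hypergeometric
  gene-set over-representation from GMT collections.

Because such studies rarely deposit raw images or spectra, `retquant.synthgen`
generates every input class synthetically with exact ground truth — layered
retinal sections with curvilinear sprouts of known length, terminals with
elliptical mitochondria of known analytic area (πab), biphasic ERG waveforms
with exact amplitudes, and overdispersed two-group count matrices with planted
fold changes — so the entire pipeline is testable end to end with no
downloads.

## Worked example

```python
import dataclasses, numpy as np
from retquant.synthgen import RetinaPhantomSpec, make_retina_phantom, random_sprouts
from retquant.imgquant import segment_layers, quantify_sprouting

base = RetinaPhantomSpec(seed=0)                      # 240 x 180 um section, 0.5 um/px
rng = np.random.default_rng(100)
spec = dataclasses.replace(base, sprouts=random_sprouts(8, base, rng))
stack, truth = make_retina_phantom(spec)              # 5 channels + exact truth

masks = segment_layers(stack[0], [stack[2]], is_marker_channel=stack[3],
                       pixel_size_um=spec.pixel_size_um)
res = quantify_sprouting(stack[1], masks)
print(f"truth  {truth.total_sprout_length_um:.1f} um, {truth.sprouted_area_fraction_pct:.2f} %")
print(f"found  {res.total_length_um:.1f} um, {res.density_pct:.2f} %  ({res.n_sprouts} sprouts)")
```

prints

```
truth  354.2 um, 2.11 %
found  315.5 um, 2.07 %  (6 sprouts)
```

i.e. the tracing pipeline recovers total sprout length within ~10% and
sprouting density within a tenth of a percentage point of the planted truth
(two crossing sprouts merge into one traced component here, hence 6 ≥-nucleus
penetrating sprouts from 8 planted polylines).

The same stages are scriptable from the shell:

```bash
retquant synth retina --seed 5 --out out/phantom     # stack.tif + truth.json
retquant imgquant sprouting --images 'out/phantom/*.tif' --out out/sprouting.csv
retquant synth counts --seed 5 --out out/counts
retquant prot deps --config deps.yaml --seed 5 --out out/deps
```

All outputs are deterministic: re-running any command with the same config
and seed reproduces byte-identical CSV/JSON/TIFF files.

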