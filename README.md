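# iirbssfp

Contrast-free brain tissue and glioma lesion segmentation, plus simultaneous
T1 / T2 / macromolecular-proton-fraction (MF) mapping, from the signal
evolutions of an **incomplete-inversion-recovery balanced SSFP** (IIR-bSSFP)
acquisition.

Standard brain-tumor MRI needs four structural sequences and a gadolinium
injection to delineate the contrast-enhancing lesion (CEL) and the
T2-hyperintense non-enhancing lesion (T2L). IIR-bSSFP instead repeats a
nonselective inversion pulse every `T_inv = N·TR` and fills the interval with
N balanced SSFP readouts, reconstructing a series of 20 inversion-time frames
in a single scan. Because recovery between inversions is *incomplete*, the
magnetization settles into a periodic steady state whose evolution mixes T1,
T2 and magnetization-transfer contrast — enough to tell tissues and lesion
compartments apart without contrast agent. This package is for researchers in
quantitative MRI and neuro-oncology imaging who want to simulate, optimize
and validate that processing chain on synthetic data.

## What it computes

**Signal model.** Single-compartment curves follow the Bloch equations
through repeated inversion cycles (no reset to M0 between cycles). The
two-compartment model adds a macromolecular pool of fraction *f* = MF with
Bloch–McConnell exchange (forward rate `k·f`, backward `k·(1−f)`, fundamental
rate k = 19 s⁻¹) and RF saturation of the bound pool through a
super-Lorentzian lineshape (T2b = 10 µs). The on-resonance transient relaxes
with the apparent rate

```
1/T1* = cos²(α/2)/T1 + sin²(α/2)/T2
```

and the echo train converges to the bSSFP steady state
`M0·sin α / ((T1/T2+1) − cos α (T1/T2−1))` — both serve as closed-form
oracles in the test suite.

**Scan-parameter optimization.** Mean signal amplitude and mean pairwise
Euclidean distance between the frame curves of a five-tissue panel
(WM/GM/CSF/glioma/edema) are swept over flip angle (10–60°) and T_inv
(1–5 s); the joint optimum averages the amplitude- and contrast-maximizing
flip angles.

**Segmentation.** Voxel curves are L2-normalized (removing receive-field
shading), the background is thresholded away, and a *spherical k-means*
(assignment by maximal inner product, centers renormalized) is applied
sequentially: 3 segments → split each into 2 → split the four middle
segments again → ten segments, sorted by the time their center reaches
minimum signal. The GM+CSF segments trace the brain contour for skull
stripping; the sorted segments merge positionally into WM, GM, CSF and three
lesion classes (T2L-1, T2L-2, CEL), with an optional necrosis class.

**Mapping.** A dictionary of normalized two-compartment frame curves on a
(T1, T2, MF) grid is matched voxel-wise by maximal inner product,
fingerprinting-style. Note the identifiability caveat in
`docs/methods.md`: normalized fixed-flip-angle curves constrain T1* tightly
but T1 and T2 only jointly.

**Phantom.** A bundled digital head phantom (nested ellipsoids: head, skull
shell, WM, GM ribbon, ventricular CSF, plus a lesion complex of two T2L
shells, a CEL rim and a necrotic core) with class parameters anchored to
in-vivo per-segment means, Rician noise and a smooth multiplicative bias
field makes every stage testable without patient data.

## Worked example

```python
import numpy as np
from iirbssfp import (PhantomSpec, build_phantom, SegmentationModel,
                      DictionaryMapping, ParamGrid, build_dictionary)

spec = PhantomSpec(shape_voxels=(32,)*3, voxel_size_mm=(4.0,)*3, snr=50.0, seed=7)
series, truth = build_phantom(spec)

res = SegmentationModel(series).fit(seed=0)
print(res.summary())

d = build_dictionary(ParamGrid.coarse())
fit = DictionaryMapping(series, d, mask=res.brain_mask).fit()
print(fit.summary())
```

prints

```
Signal-evolution segmentation
  brain voxels: 5200  (threshold otsu, seed 0)
  segments before merging: 10
  class     volume (mL)
  WM              52.10
  GM             234.11
  CSF              5.63
  T2L-1           35.97
  T2L-2            2.69
  CEL              2.30
  NEC              0.00

Dictionary-matching parametric maps
  atoms: 31080   voxels mapped: 5200
  median T1   728.9 ms, T2   72.9 ms, MF  0.060
  match quality: median 0.99943, min 0.99704
```

The ten pre-merge segments and the skull-stripped brain mask come from the
sequential clustering; the per-class volumes are voxel counts times voxel
volume. The median match quality near 1 says the dictionary explains the
measured curves; the per-class label accuracy of the positional merge on
piecewise-constant phantoms is discussed in `docs/methods.md`.

The same pipeline is scriptable from the shell:

```bash
iirbssfp phantom --out ph --size 32 --voxel 4 --seed 0
iirbssfp segment --series ph/series.nii --out-prefix seg
iirbssfp dict-build --out dict.h5 --coarse
iirbssfp map --series ph/series.nii --dictionary dict.h5 --out-prefix maps
iirbssfp evaluate --labels-a seg_labels.nii --labels-b ph/labels.nii
```

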