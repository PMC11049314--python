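# Methods

This note records the models the package implements, the parameter choices
and their rationale, the numerical decisions, and what the synthetic phantom
does and does not establish about behaviour on real data.

## Signal model

### Sequence and state

The acquisition repeats a nonselective inversion every `T_inv` and fills the
interval with `N = floor(T_inv/TR)` balanced SSFP excitations whose flip
angles alternate in sign (the usual π phase cycle). On resonance the
magnetization stays in the y–z plane, so the simulator propagates `(My, Mz)`
for the free pool — plus the longitudinal bound-pool component `Mzb` in the
two-compartment model. Echoes are sampled at `TE` after each pulse and
recorded in the demodulated frame (multiplied by the pulse sign) so signed
evolutions vary smoothly; public curves follow the magnitude convention.

One cycle is: inversion (exact 180° rotation of the free pool about x) →
optional −α/2 catalyzation pulse → TR/2 gap → N readout pulses with TR
spacing → TR/2 gap to the next inversion, totalling exactly `N·TR`.
Catalyzation is on by default: it is standard IR-bSSFP practice and produces
the clean mono-exponential transients the closed-form oracles assume; it can
be disabled. Because `T_inv` is far below full T1 recovery, the magnetization
is **not** reset between cycles; whole cycles repeat from thermal equilibrium
until the start-of-cycle state changes by less than `convergence_tol`
(default 1e-6 relative, maximum 10 cycles for a single curve). Convergence is
detected on the state rather than the echo train — the state determines the
train, and this avoids storing two full trains for the large batches used in
dictionary construction. The sweep and dictionary builders raise the cycle
cap (100 and 40) because short inversion intervals contract slowly for
long-T1* tissues (for CSF at `T_inv` = 1 s the per-cycle contraction is
~0.54, so 1e-6 needs ~25 cycles).

### Two-compartment exchange

The bound (macromolecular) pool holds the fraction `mf` of the equilibrium
magnetization. Between pulses the longitudinal pair `(Mzf, Mzb)` evolves
under coupled relaxation–exchange with forward rate `k·mf` and backward rate
`k·(1−mf)` (detailed balance), propagated with a closed-form 2×2 matrix
exponential; the free transverse component decays with the
exchange-augmented rate `1/T2f + k·mf`. RF pulses rotate the free pool
instantaneously and multiply the bound pool by
`exp(−π α² G(0) / τ)` — the saturation of an equivalent rectangular pulse of
duration τ (default 600 µs) with a super-Lorentzian absorption lineshape.
`G(0)` is evaluated at a 1 kHz offset, the standard workaround for the
on-resonance divergence of the super-Lorentzian. The inversion pulse leaves
the bound pool untouched by default (its ~10 µs T2 destroys any coherent
rotation during a millisecond-scale pulse); this is configurable.

Fixed constants: `T1b = 1000 ms`, `T2b = 10 µs`, fundamental exchange rate
`k = 19 s⁻¹` — literature white-matter-scale values. They are held fixed in
mapping so the dictionary searches only the three reported parameters.

### Oracles

Two independent closed forms validate the engine to better than 1%:
the short-TR bSSFP steady state
`M0 sin α / ((T1/T2+1) − cos α (T1/T2−1))` (the TE = TR/2 echo matches it to
O(TR²); measured max deviation 0.25% over T1 ∈ {600, 1200, 2400} ms ×
T2 ∈ {60, 120, 240} ms), and the transient rate
`1/T1* = cos²(α/2)/T1 + sin²(α/2)/T2` recovered by exponential fits to the
first-cycle envelope (max deviation 0.02%). The two-pool path reduces to the
single-pool curve to ≤1e-6 relative when `mf = 0` and `k = 0`.

## Scan-parameter optimization

The sweep simulates the five-tissue panel — WM (850/70), GM (1400/90), CSF
(4000/1800), glioma (1700/140), edema (1500/110) ms, standard 3 T literature
values — over flip angles 10–60° (step 2°) and `T_inv` 1–5 s (step 250 ms),
always frame-averaged to 20 points so all `T_inv` produce comparable-length
vectors. Amplitude is the mean magnitude over tissues and frames (the SNR
proxy); contrast is the mean pairwise unnormalized Euclidean distance. The
joint optimum averages, per `T_inv` column, the amplitude-argmax and the
distance-argmax flip angles, then means over the chosen `T_inv` window.

Both surfaces are plateaus: amplitude varies by <1% over FA 36–52° and
distance by <1% over 26–44° at `T_inv` = 3 s, so the argmax is not a sharp
quantity. With this panel and recipe the joint optimum over
`T_inv` ∈ [2.5, 4] s evaluates to 40°; readings that normalize the distance,
use first-cycle curves, or shrink the CSF T2 move it anywhere between 33° and
60°. Because of that flatness the package reports the computed optimum rather
than asserting a canonical value; flip angles of roughly 30–45° are all
within a few percent of both objectives.

## Segmentation

Normalization divides each voxel curve by its L2 norm, which cancels any
per-voxel positive gain exactly — receive-field shading, scanner scaling, the
phantom's bias field. Background removal then keeps voxels whose max-over-TI
intensity clears a threshold. Two rules are provided: a fraction of the
robust volume maximum (99th percentile), classically 2%; and a parameter-free
Otsu cut on the max-TI image, which the pipeline entry points use by default.
The fractional rule presumes a reconstruction whose background is darker than
the cut; with honest Rician noise at SNR 50 the Rayleigh background maxima
sit near 5% of peak, above any 2% cut, while Otsu lands cleanly in the gap
between the noise and tissue modes (measured: 100% of head voxels kept, 0% of
air, at SNR 50). No intensity threshold can be invariant to per-voxel gain
fields; the clustering stages downstream of the mask are exactly invariant.

Spherical k-means assigns each normalized curve to the center with maximal
inner product and renormalizes the member mean — monotone ascent of the
summed inner product (property-tested). Initialization is k-means++ on the
sphere with a fixed default seed; an emptied cluster is reseeded from the
worst-fit curve. Clusters are sorted by the frame index at which their center
is minimal (the zero-crossing surrogate, driven by T1*); exact ties are
ordered by a parabolic sub-frame interpolation of the minimum and then by
lineage, keeping the sort deterministic.

The hierarchy is 3 segments → each split in two (6) → the four middle sorted
segments split again (10), each stage re-sorted globally. Brain extraction
closes (3-voxel ball), hole-fills and takes the largest connected component
of the union of the two later-minimum segments of a 3-class run — the grey
matter + CSF contour — which retains enclosed WM and drops the skull shell
(Dice 1.0 against the phantom's true brain at SNR 50). The ten segments merge
positionally: #1 → WM, #2/4/6/8 → GM, #3/5/7 → T2L-1/T2L-2/CEL in min-time
order, #9–10 → CSF. Necrosis is an optional post-step (CSF-labelled voxels
enclosed by the lesion envelope), off by default.

### What the positional merge can and cannot do on phantoms

On in-vivo data the four "GM layers" are partial-volume strata whose signal
minima interleave the lesion classes, which is exactly what the positional
rule encodes. The bundled phantom is piecewise-constant by design (no
partial-volume mixing), so splitting a homogeneous class produces two
statistical twins with identical min-times in adjacent sorted positions, and
the positional rule then assigns twins of normal tissue to lesion classes.
Consequences, measured at 64³/SNR 50: the refinement reliably isolates pure
lesion segments among the ten (CEL and T2L-1 purity ≥ 0.9 across seeds), but
the merged per-class label map does not reach high Dice against truth, and on
a lesion-free WM/GM/CSF phantom the lesion-indexed positions capture ~30–50%
of the brain rather than <1%. This is a structural property of positional
assignment on piecewise-constant data, not a tuning issue; duplicate-collapse
heuristics were examined and rejected because no consistent positional
tie-break exists. Users working with real data should expect the in-vivo
interleaving to restore the rule's intent; users validating on phantoms
should evaluate segment purity, not merged-class Dice.

## Dictionary mapping and identifiability

Atoms are magnitude frame curves of the two-compartment model, L2-normalized,
on a lexicographically ordered (T1, T2, MF) grid with infeasible points
(T2 > T1) removed; matching is exact brute-force nearest neighbour in cosine
distance (first maximum ⇒ smallest parameters on ties), chunked matrix
products, deterministic. The default grid uses ~3% geometric steps over
T1 100–4000 ms and T2 10–400 ms with MF 0–0.40 step 0.01; a coarse variant
(40 × 40 × 21, ~10%/0.02 steps) is used wherever runtime matters, including
the bundled validation scripts.

A fixed-flip-angle, on-resonance IIR-bSSFP evolution has, after
normalization, essentially one shape degree of freedom: the signed periodic
steady state is `m_ss · (1 − (1 + (1−E)/(1+E)) e^{−t/T1*})` with
`E = e^{−T_inv/T1*}`, so the normalized single-pool curve depends on (T1, T2)
only through T1*. Measured on the two-pool model: moving along the iso-T1*
valley from (848, 28.5) ms to (3012, 21.3) ms changes the normalized curve by
6e-4 (L2), versus 3.7e-3 for a half-grid-step T1 move off the valley and
0.02–0.06 of noise on a normalized curve at SNR 50. T1 and T2 are therefore
**not individually identifiable** from a normalized curve at realistic SNR —
only T1* (recovered to ~6–16% per class on the phantom) and, more weakly, MF
(median absolute error 0.01–0.06). Exact-grid-point recovery under SNR-50
noise is accordingly rare (~1%), and per-class median T1/T2 errors span
several grid steps, running along the valley. Class-median T1 still preserves
the WM < GM < CSF ordering. The package exposes T1* through
`apparent_relaxation` as the honest scalar this sequence pins down; mapping
T1 and T2 separately at single-voxel level would need amplitude information
(a calibrated proton-density/receive model) or multi-flip-angle acquisition,
both out of scope.

## Phantom

Geometry: nested ellipsoids on a fixed 128 mm field of view — head
(56/48/44 mm semi-axes), skull shell down to the inner table (50/42/38), WM
core (44/36/32), the GM ribbon between them, two ventricular CSF ellipsoids,
and a spherical lesion complex in the right frontal WM (T2L-1 shell to 15 mm,
T2L-2 to 12 mm, CEL rim to 9 mm, necrotic core to 6 mm). Default matrices:
64³ at 2 mm for tests, 32³ at 4 mm for smoke runs, 128³ at 1 mm for demos —
all the same physical head. Overlapping user geometry raises an error naming
the classes involved.

Class parameters default to the whole-brain per-segment means measured with
this sequence family in patients (T1/T2 in ms, MF in fraction): CSF
2990.4/218.1/0.010, WM 848.0/28.5/0.100, GM 912.4/83.1/0.053, T2L-1
749.5/62.2/0.078, T2L-2 883.8/94.1/0.034, CEL 1300.7/115.8/0.026, NEC
2696.6/190.7/0.022; the skull shell uses a short-T2, macromolecule-rich
stand-in (400/10/0.15). Corruption: a smooth positive polynomial bias field
(order 2, ±20% by default) multiplies the clean signal, then complex Gaussian
noise of σ = peak/SNR is added and the magnitude taken (Rician), default
SNR 50. Everything is deterministic given the seed; geometry and labels never
depend on it (verified: different seeds share labels bit-for-bit).

The phantom emulates the geometry, class contrast, noise statistics and
receive shading of the target data. It does **not** emulate partial-volume
mixing, within-class biological heterogeneity, flow/banding artifacts, or
undersampling/reconstruction residuals — so green phantom tests establish the
correctness and internal consistency of the algorithms, not clinical
segmentation accuracy; and the positional-merge caveat above is a direct
consequence of the first omission.

## Problem sizes and runtimes

The bundled validation uses the coarse dictionary (31 080 atoms), 64³
phantoms at SNR 50 (2–5 noise seeds per check), 200 noisy matching trials,
and the full default optimizer grids; these sizes keep the whole suite in a
few CPU-minutes while leaving every measured quantity stable to well within
the margins quoted above. The default fine dictionary (~640 k feasible
points) builds in a few minutes on one CPU thanks to the vectorized batch
propagator.

## Known limitations

- On-resonance only: no off-resonance profile, banding, or finite-pulse
  effects on the free pool.
- Magnitude-only matching; no proton-density or B1/B0 outputs.
- The exchange constants are fixed literature values, not fitted.
- The positional merge's lesion labels are only meaningful when the data
  contain the partial-volume GM strata seen in vivo (see above).
- T1/T2 separation at voxel level is noise-limited by the T1* degeneracy of
  normalized fixed-flip-angle curves (see above).
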