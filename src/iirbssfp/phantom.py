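"""Synthetic digital head phantom with a glioma lesion complex.

The phantom emulates the geometry this method faces in vivo — a head volume
with white matter, a cortical grey-matter ribbon, ventricular CSF and a skull
shell, plus a lesion complex of two concentric T2-hyperintense shells, a
contrast-enhancing rim and a necrotic core — as nested ellipsoids/spheres on
a 128 mm field of view.  Every class carries a two-pool tissue whose default
T1/T2/MF are the in-vivo class means measured with this sequence family, so
segmentation and mapping can be validated against a known truth.

Corruption model: a smooth positive multiplicative bias field (polynomial in
the coordinates, emulating coil shading) applied to the clean signal, then
Rician noise (magnitude of complex Gaussian) at a prescribed peak-signal-to-
noise-std ratio.  Everything is deterministic given the seed; geometry and
labels never depend on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bloch import simulate_two_pool_batch
from .params import ParameterError, SequenceParams, TwoPoolTissue
from .volume import LabelVolume, TiSeries, load_nifti, save_nifti

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "default_class_tissues",
    "build_phantom",
    "write_fixture",
    "load_fixture",
]

FOV_MM = 128.0

BRAIN_CLASSES = ("WM", "GM", "CSF", "T2L-1", "T2L-2", "CEL", "NEC")
PHANTOM_CLASSES = BRAIN_CLASSES + ("skull",)

LESION_CLASSES = ("T2L-1", "T2L-2", "CEL", "NEC")


def default_class_tissues() -> dict:
    """Per-class two-pool parameters (T1 ms, T2 ms, MF fraction).

    Brain and lesion classes use the whole-brain per-segment means measured
    with this sequence in patients; the skull shell is a short-T2,
    macromolecule-rich stand-in that mimics bone/marrow signal behaviour.
    """
    vals = {
        "CSF": (2990.4, 218.1, 0.010),
        "WM": (848.0, 28.5, 0.100),
        "GM": (912.4, 83.1, 0.053),
        "T2L-1": (749.5, 62.2, 0.078),
        "T2L-2": (883.8, 94.1, 0.034),
        "CEL": (1300.7, 115.8, 0.026),
        "NEC": (2696.6, 190.7, 0.022),
        "skull": (400.0, 10.0, 0.150),
    }
    return {k: TwoPoolTissue(t1, t2, mf) for k, (t1, t2, mf) in vals.items()}


# nested-ellipsoid geometry, mm, centered on the FOV (semi-axes / centers)
DEFAULT_GEOMETRY = {
    "head": (56.0, 48.0, 44.0),
    "brain_outer": (50.0, 42.0, 38.0),  # inner skull table
    "wm_core": (44.0, 36.0, 32.0),
    "ventricle_semi": (8.0, 11.0, 7.0),
    "ventricle_centers": ((11.0, -12.0, 0.0), (-11.0, -12.0, 0.0)),
    "lesion_center": (20.0, 14.0, 0.0),
    "lesion_radii": (15.0, 12.0, 9.0, 6.0),  # T2L-1 | T2L-2 | CEL | NEC edges
}


@dataclass
class PhantomSpec:
    """Everything needed to rebuild one phantom bit-for-bit."""

    shape_voxels: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    snr: float = 50.0
    bias_field_order: int = 2
    bias_amplitude: float = 0.2
    seed: int = 0
    include_lesion: bool = True
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))
    class_params: dict = field(
        default_factory=lambda: {
            k: (t.t1f_ms, t.t2f_ms, t.mf) for k, t in default_class_tissues().items()
        }
    )
    sequence: SequenceParams = field(
        default_factory=lambda: SequenceParams(n_cycles_max=40)
    )

    def __post_init__(self):
        if self.snr <= 0:
            raise ParameterError("snr must be positive (use numpy.inf for noiseless)")
        if self.bias_field_order < 0:
            raise ParameterError("bias_field_order must be >= 0")

    def tissues(self) -> dict:
        return {
            k: TwoPoolTissue(t1, t2, mf) for k, (t1, t2, mf) in self.class_params.items()
        }

    def to_json(self, path) -> None:
        d = asdict(self)
        d["geometry"] = {
            k: (list(map(list, v)) if k == "ventricle_centers" else list(np.atleast_1d(v)))
            for k, v in self.geometry.items()
        }
        d["snr"] = None if np.isinf(self.snr) else self.snr
        Path(path).write_text(json.dumps(d, indent=2, default=float))

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        d = json.loads(Path(path).read_text())
        d["snr"] = np.inf if d["snr"] is None else d["snr"]
        d["shape_voxels"] = tuple(d["shape_voxels"])
        d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        geo = d["geometry"]
        geo["ventricle_centers"] = tuple(tuple(c) for c in geo["ventricle_centers"])
        for k in ("head", "brain_outer", "wm_core", "ventricle_semi", "lesion_center"):
            geo[k] = tuple(geo[k])
        geo["lesion_radii"] = tuple(geo["lesion_radii"])
        d["class_params"] = {k: tuple(v) for k, v in d["class_params"].items()}
        d["sequence"] = SequenceParams(**d["sequence"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Noise-free reference volumes accompanying a phantom."""

    labels: LabelVolume
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    mf: np.ndarray
    clean_signal: np.ndarray  # bias-free 4-D magnitude series


def _grid_mm(shape, voxel):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, voxel)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _inside_ellipsoid(x, y, z, semi, center=(0.0, 0.0, 0.0)):
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _build_labels(spec: PhantomSpec) -> LabelVolume:
    g = spec.geometry
    x, y, z = _grid_mm(spec.shape_voxels, spec.voxel_size_mm)
    head = _inside_ellipsoid(x, y, z, g["head"])
    brain = _inside_ellipsoid(x, y, z, g["brain_outer"])
    wm_core = _inside_ellipsoid(x, y, z, g["wm_core"])
    vent = np.zeros_like(head)
    for c in g["ventricle_centers"]:
        vent |= _inside_ellipsoid(x, y, z, g["ventricle_semi"], c)
    vent &= wm_core

    names = PHANTOM_CLASSES
    code = {n: i + 1 for i, n in enumerate(names)}
    labels = np.zeros(spec.shape_voxels, dtype=np.uint8)
    labels[head & ~brain] = code["skull"]
    labels[brain & ~wm_core] = code["GM"]
    labels[wm_core] = code["WM"]
    labels[vent] = code["CSF"]

    if spec.include_lesion:
        cx, cy, cz = g["lesion_center"]
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        r1, r2, r3, r4 = g["lesion_radii"]
        lesion = r <= r1
        clash = lesion & ~wm_core
        if np.any(clash):
            bad = sorted(
                "background" if c == 0 else names[c - 1]
                for c in np.unique(labels[clash])
            )
            raise ParameterError(f"lesion complex overlaps non-WM classes: {bad}")
        if np.any(lesion & vent):
            raise ParameterError("lesion complex overlaps class CSF (ventricles)")
        labels[(r <= r1) & (r > r2)] = code["T2L-1"]
        labels[(r <= r2) & (r > r3)] = code["T2L-2"]
        labels[(r <= r3) & (r > r4)] = code["CEL"]
        labels[r <= r4] = code["NEC"]

    return LabelVolume(labels, names, spec.voxel_size_mm)


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth strictly positive multiplicative field, mean ~1."""
    if spec.bias_field_order == 0:
        return np.ones(spec.shape_voxels)
    x, y, z = _grid_mm(spec.shape_voxels, spec.voxel_size_mm)
    xs, ys, zs = (c / (FOV_MM / 2.0) for c in (x, y, z))
    f = np.zeros(spec.shape_voxels)
    n_terms = 0
    for i in range(spec.bias_field_order + 1):
        for j in range(spec.bias_field_order + 1 - i):
            for k in range(spec.bias_field_order + 1 - i - j):
                if i == j == k == 0:
                    continue
                f += rng.normal() * xs**i * ys**j * zs**k
                n_terms += 1
    f /= max(np.abs(f).max(), 1e-12)
    field_ = 1.0 + spec.bias_amplitude * f
    return np.clip(field_, 0.05, None)


def class_frame_curves(spec: PhantomSpec) -> dict:
    """Magnitude 20-frame curve of every phantom class (signed average of the
    converged echo train within each TI window, then magnitude)."""
    names = list(spec.class_params)
    t1 = np.array([spec.class_params[n][0] for n in names])
    t2 = np.array([spec.class_params[n][1] for n in names])
    mf = np.array([spec.class_params[n][2] for n in names])
    res = simulate_two_pool_batch(t1, t2, mf, spec.sequence, record="frames")
    if not res.converged.all():
        bad = [n for n, c in zip(names, res.converged) if not c]
        raise ParameterError(f"phantom class simulation did not converge: {bad}")
    return {n: np.abs(res.signal[i]) for i, n in enumerate(names)}, res.ti_ms


def build_phantom(spec: PhantomSpec) -> tuple[TiSeries, GroundTruth]:
    """Generate the 4-D multi-TI series and its ground truth.

    Clean per-voxel curves come from the converged two-pool simulation of the
    voxel's class; the bias field multiplies the clean signal, and complex
    Gaussian noise of std ``peak/snr`` is added before taking the magnitude
    (Rician).  Deterministic given ``spec.seed``.
    """
    label_vol = _build_labels(spec)
    curves, ti_ms = class_frame_curves(spec)
    names = label_vol.class_names
    n_frames = spec.sequence.n_frames

    lut = np.zeros((len(names) + 1, n_frames))
    for i, n in enumerate(names):
        lut[i + 1] = curves[n]
    clean = lut[label_vol.labels]  # (x, y, z, TI)

    t1_map = np.zeros(spec.shape_voxels)
    t2_map = np.zeros(spec.shape_voxels)
    mf_map = np.zeros(spec.shape_voxels)
    for i, n in enumerate(names):
        m = label_vol.labels == i + 1
        p = spec.class_params[n]
        t1_map[m], t2_map[m], mf_map[m] = p

    rng = np.random.default_rng(spec.seed)
    biased = clean * _bias_field(spec, rng)[..., None]
    peak = clean.max()
    if np.isinf(spec.snr):
        noisy = biased
    else:
        sigma = peak / spec.snr
        noisy = np.sqrt(
            (biased + rng.normal(0.0, sigma, biased.shape)) ** 2
            + rng.normal(0.0, sigma, biased.shape) ** 2
        )

    series = TiSeries(noisy, spec.voxel_size_mm, ti_ms)
    truth = GroundTruth(label_vol, t1_map, t2_map, mf_map, clean)
    return series, truth


def write_fixture(series: TiSeries, truth: GroundTruth, directory, spec: PhantomSpec | None = None) -> dict:
    """Write series, labels, truth maps (NIfTI) and the JSON spec; returns paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": d / "series.nii",
        "labels": d / "labels.nii",
        "t1": d / "truth_t1.nii",
        "t2": d / "truth_t2.nii",
        "mf": d / "truth_mf.nii",
        "ti": d / "ti_ms.json",
    }
    save_nifti(series.volume, series.voxel_size_mm, paths["series"])
    save_nifti(truth.labels.labels, series.voxel_size_mm, paths["labels"], dtype=np.uint8)
    save_nifti(truth.t1_ms, series.voxel_size_mm, paths["t1"])
    save_nifti(truth.t2_ms, series.voxel_size_mm, paths["t2"])
    save_nifti(truth.mf, series.voxel_size_mm, paths["mf"])
    meta = {"ti_ms": series.ti_ms.tolist(), "class_names": list(truth.labels.class_names)}
    paths["ti"].write_text(json.dumps(meta))
    if spec is not None:
        paths["spec"] = d / "phantom_spec.json"
        spec.to_json(paths["spec"])
    return paths


def load_fixture(directory) -> tuple[TiSeries, GroundTruth]:
    d = Path(directory)
    meta = json.loads((d / "ti_ms.json").read_text())
    vol, vox = load_nifti(d / "series.nii")
    series = TiSeries(vol, vox, np.array(meta["ti_ms"]))
    labels, _ = load_nifti(d / "labels.nii")
    t1, _ = load_nifti(d / "truth_t1.nii")
    t2, _ = load_nifti(d / "truth_t2.nii")
    mf, _ = load_nifti(d / "truth_mf.nii")
    lv = LabelVolume(labels.astype(np.uint8), tuple(meta["class_names"]), vox)
    clean = np.zeros_like(vol)
    return series, GroundTruth(lv, t1, t2, mf, clean)
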