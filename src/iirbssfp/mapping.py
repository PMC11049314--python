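"""Dictionary-based simultaneous T1/T2/MF mapping.

In the fingerprinting spirit, the forward model (two-compartment
Bloch-McConnell simulation of the inversion-prepared bSSFP frames) is
evaluated once on a (T1, T2, MF) grid; each simulated frame curve is
L2-normalized into a dictionary atom.  A measured voxel curve is then
assigned the parameters of the atom with maximal inner product with its
normalized curve — exact nearest-neighbour search in cosine distance.
Exchange-rate and bound-pool constants are held fixed: only the three
parameters the method maps are searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .bloch import simulate_two_pool_batch
from .params import ParameterError, SequenceParams, SignalCurve
from .volume import TiSeries

__all__ = [
    "ParamGrid",
    "Dictionary",
    "ParametricMaps",
    "build_dictionary",
    "match_curve",
    "map_volume",
    "DictionaryMapping",
    "MappingResults",
]

log = logging.getLogger(__name__)

BACKGROUND = (0.0, 0.0, 0.0, 0.0)  # sentinel for zero-norm voxels


def _geomspace(lo: float, hi: float, step_frac: float) -> np.ndarray:
    n = int(np.ceil(np.log(hi / lo) / np.log1p(step_frac))) + 1
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class ParamGrid:
    """Strictly increasing (T1, T2, MF) axes of the dictionary.

    Defaults: T1 100-4000 ms and T2 10-400 ms geometric with ~3% steps,
    MF 0-0.40 in steps of 0.01.
    """

    t1_values_ms: np.ndarray = field(
        default_factory=lambda: _geomspace(100.0, 4000.0, 0.03)
    )
    t2_values_ms: np.ndarray = field(
        default_factory=lambda: _geomspace(10.0, 400.0, 0.03)
    )
    mf_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.401, 0.01), 4)
    )

    def __post_init__(self):
        for name in ("t1_values_ms", "t2_values_ms", "mf_values"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if len(v) > 1 and not np.all(np.diff(v) > 0):
                raise ParameterError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)
        if self.mf_values.min() < 0 or self.mf_values.max() > 0.5:
            raise ParameterError("mf_values must lie in [0, 0.5]")

    @classmethod
    def coarse(cls) -> "ParamGrid":
        """Runtime-friendly grid: ~10% T1/T2 steps, MF step 0.02."""
        return cls(
            t1_values_ms=np.geomspace(100.0, 4000.0, 40),
            t2_values_ms=np.geomspace(10.0, 400.0, 40),
            mf_values=np.round(np.arange(0.0, 0.401, 0.02), 4),
        )

    def feasible_points(self) -> np.ndarray:
        """Lexicographically ordered (T1, T2, MF) rows with T2 <= T1."""
        t1, t2, mf = np.meshgrid(
            self.t1_values_ms, self.t2_values_ms, self.mf_values, indexing="ij"
        )
        pts = np.column_stack([t1.ravel(), t2.ravel(), mf.ravel()])
        return pts[pts[:, 1] <= pts[:, 0]]


@dataclass
class Dictionary:
    """Unit-norm simulated frame curves with their grid coordinates.

    ``atoms`` is (n_atoms, n_frames); ``params`` the matching (T1, T2, MF)
    rows in lexicographic order, so the *first* maximal inner product is the
    smallest (T1, T2, MF) — the documented tie-break.
    """

    grid: ParamGrid
    seq: SequenceParams
    atoms: np.ndarray
    params: np.ndarray
    constants: dict = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self):
        if self.atoms.shape[0] != self.params.shape[0]:
            raise ParameterError("atoms and params must align")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("atoms", data=self.atoms)
            f.create_dataset("params", data=self.params)
            f.create_dataset("t1_values_ms", data=self.grid.t1_values_ms)
            f.create_dataset("t2_values_ms", data=self.grid.t2_values_ms)
            f.create_dataset("mf_values", data=self.grid.mf_values)
            for k, v in self.constants.items():
                f.attrs[f"const_{k}"] = v
            for k in (
                "flip_angle_deg",
                "tr_ms",
                "te_ms",
                "tinv_ms",
                "n_frames",
                "n_cycles_max",
                "convergence_tol",
                "catalyzation",
                "invert_bound_pool",
                "rf_pulse_duration_us",
            ):
                f.attrs[f"seq_{k}"] = getattr(self.seq, k)
            f.attrs["n_excluded"] = self.n_excluded

    @classmethod
    def load(cls, path) -> "Dictionary":
        with h5py.File(path, "r") as f:
            grid = ParamGrid(
                f["t1_values_ms"][:], f["t2_values_ms"][:], f["mf_values"][:]
            )
            seq_kwargs = {
                k[4:]: v.item() if hasattr(v, "item") else v
                for k, v in f.attrs.items()
                if k.startswith("seq_")
            }
            seq_kwargs["n_frames"] = int(seq_kwargs["n_frames"])
            seq_kwargs["n_cycles_max"] = int(seq_kwargs["n_cycles_max"])
            seq_kwargs["catalyzation"] = bool(seq_kwargs["catalyzation"])
            seq_kwargs["invert_bound_pool"] = bool(seq_kwargs["invert_bound_pool"])
            consts = {
                k[6:]: v.item() if hasattr(v, "item") else v
                for k, v in f.attrs.items()
                if k.startswith("const_")
            }
            return cls(
                grid,
                SequenceParams(**seq_kwargs),
                f["atoms"][:],
                f["params"][:],
                consts,
                int(f.attrs["n_excluded"]),
            )


def build_dictionary(
    grid: ParamGrid,
    seq: SequenceParams | None = None,
    t1b_ms: float = 1000.0,
    t2b_us: float = 10.0,
    k_exchange_per_s: float = 19.0,
) -> Dictionary:
    """Simulate every feasible grid point and normalize the frame curves.

    Non-convergent points are excluded (and logged); the sequence and the
    fixed two-pool constants are stored with the atoms so any map derived
    from the dictionary is reproducible bit for bit.
    """
    seq = seq or SequenceParams(n_cycles_max=40)
    pts = grid.feasible_points()
    if len(pts) == 0:
        raise ParameterError("grid contains no feasible (T2 <= T1) points")
    res = simulate_two_pool_batch(
        pts[:, 0],
        pts[:, 1],
        pts[:, 2],
        seq,
        t1b_ms=t1b_ms,
        t2b_us=t2b_us,
        k_exchange_per_s=k_exchange_per_s,
        record="frames",
    )
    curves = np.abs(res.signal)
    norms = np.linalg.norm(curves, axis=1)
    ok = res.converged & (norms > 0)
    n_excl = int((~ok).sum())
    if n_excl:
        log.warning("excluded %d non-convergent/degenerate grid points", n_excl)
    atoms = curves[ok] / norms[ok, None]
    return Dictionary(
        grid,
        seq,
        atoms,
        pts[ok],
        constants={
            "t1b_ms": t1b_ms,
            "t2b_us": t2b_us,
            "k_exchange_per_s": k_exchange_per_s,
        },
        n_excluded=n_excl,
    )


def match_curve(curve, dictionary: Dictionary) -> tuple[float, float, float, float]:
    """Best-matching (T1, T2, MF, quality) for one curve.

    ``quality`` is the inner product between the normalized curve and the
    winning atom (cosine similarity).  Zero-norm input returns the background
    sentinel (all zeros).  Ties resolve to the smallest (T1, T2, MF).
    """
    v = curve.values if isinstance(curve, SignalCurve) else np.asarray(curve, dtype=float)
    if v.shape != (dictionary.atoms.shape[1],):
        raise ParameterError(
            f"curve length {v.shape} does not match atom length "
            f"{dictionary.atoms.shape[1]}"
        )
    nrm = np.linalg.norm(v)
    if nrm == 0:
        return BACKGROUND
    dots = dictionary.atoms @ (v / nrm)
    i = int(np.argmax(dots))  # first max = smallest (T1, T2, MF)
    t1, t2, mf = dictionary.params[i]
    return float(t1), float(t2), float(mf), float(dots[i])


@dataclass
class ParametricMaps:
    """Voxel-wise parameter maps plus the cosine match quality."""

    t1_map_ms: np.ndarray
    t2_map_ms: np.ndarray
    mf_map: np.ndarray
    match_quality: np.ndarray


def map_volume(
    series: TiSeries, mask: np.ndarray, dictionary: Dictionary, chunk_bytes: float = 2e8
) -> ParametricMaps:
    """Match every in-mask voxel curve against the dictionary.

    Deterministic brute-force nearest neighbour (chunked matrix products);
    out-of-mask voxels are zero in every output map.
    """
    if mask.shape != series.shape:
        raise ParameterError("mask shape does not match series")
    if series.n_frames != dictionary.atoms.shape[1]:
        raise ParameterError("series frame count does not match dictionary atoms")
    curves = series.volume[mask]
    norms = np.linalg.norm(curves, axis=1, keepdims=True)
    nz = norms[:, 0] > 0
    unit = np.zeros_like(curves)
    unit[nz] = curves[nz] / norms[nz]

    n = len(curves)
    best_idx = np.zeros(n, dtype=np.int64)
    best_dot = np.zeros(n)
    step = max(1, int(chunk_bytes / max(dictionary.n_atoms * 8, 1)))
    at = dictionary.atoms.T
    for s in range(0, n, step):
        d = unit[s : s + step] @ at
        best_idx[s : s + step] = np.argmax(d, axis=1)
        best_dot[s : s + step] = d[np.arange(d.shape[0]), best_idx[s : s + step]]

    pars = dictionary.params[best_idx]
    pars[~nz] = 0.0
    best_dot[~nz] = 0.0

    out = [np.zeros(series.shape) for _ in range(4)]
    vals = [pars[:, 0], pars[:, 1], pars[:, 2], best_dot]
    for o, v in zip(out, vals):
        o[mask] = v
    return ParametricMaps(*out)


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------

class DictionaryMapping:
    """Parametric mapping of a multi-TI series, model-object style."""

    def __init__(self, series: TiSeries, dictionary: Dictionary, mask: np.ndarray | None = None):
        self.series = series
        self.dictionary = dictionary
        self.mask = (
            mask if mask is not None else np.linalg.norm(series.volume, axis=3) > 0
        )

    def fit(self) -> "MappingResults":
        maps = map_volume(self.series, self.mask, self.dictionary)
        return MappingResults(self, maps)


@dataclass
class MappingResults:
    model: DictionaryMapping
    maps: ParametricMaps

    def class_medians(self, labels, class_names) -> dict:
        """Median (T1, T2, MF) per labelled class."""
        out = {}
        for i, name in enumerate(class_names):
            m = (labels == i + 1) & self.model.mask
            if np.any(m):
                out[name] = (
                    float(np.median(self.maps.t1_map_ms[m])),
                    float(np.median(self.maps.t2_map_ms[m])),
                    float(np.median(self.maps.mf_map[m])),
                )
        return out

    def summary(self) -> str:
        m = self.model.mask
        q = self.maps.match_quality[m]
        lines = [
            "Dictionary-matching parametric maps",
            f"  atoms: {self.model.dictionary.n_atoms}   voxels mapped: {int(m.sum())}",
            f"  median T1 {np.median(self.maps.t1_map_ms[m]):7.1f} ms, "
            f"T2 {np.median(self.maps.t2_map_ms[m]):6.1f} ms, "
            f"MF {np.median(self.maps.mf_map[m]):6.3f}",
            f"  match quality: median {np.median(q):.5f}, min {q.min():.5f}",
        ]
        return "\n".join(lines)
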