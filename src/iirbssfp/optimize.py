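"""Scan-parameter search: signal amplitude and inter-tissue contrast surfaces.

The acquisition has two free knobs once resolution and coverage are fixed:
the flip angle and the inversion interval.  Larger flip angles buy signal
(up to the bSSFP optimum) but compress the differences between tissue
evolution curves; the sweep quantifies both as surfaces over an
(FA, T_inv) grid and the joint optimum averages the two argmax ridges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bloch import simulate_single_pool_batch
from .params import ParameterError, SequenceParams, SinglePoolTissue

__all__ = [
    "TissuePanel",
    "OptSurface",
    "default_tissue_panel",
    "sweep_surfaces",
    "optimal_fa",
]


def default_tissue_panel() -> "TissuePanel":
    """Five representative brain tissues at 3 T (literature relaxation values)."""
    return TissuePanel(
        {
            "WM": SinglePoolTissue(850.0, 70.0),
            "GM": SinglePoolTissue(1400.0, 90.0),
            "CSF": SinglePoolTissue(4000.0, 1800.0),
            "glioma": SinglePoolTissue(1700.0, 140.0),
            "edema": SinglePoolTissue(1500.0, 110.0),
        }
    )


@dataclass(frozen=True)
class TissuePanel:
    """Named collection of single-compartment tissues."""

    tissues: dict

    def __post_init__(self):
        if len(self.tissues) < 1:
            raise ParameterError("panel must contain at least one tissue")
        for name, t in self.tissues.items():
            if not isinstance(t, SinglePoolTissue):
                raise ParameterError(f"panel entry {name!r} is not a SinglePoolTissue")

    def __len__(self):
        return len(self.tissues)

    @property
    def names(self):
        return list(self.tissues)

    def arrays(self):
        t1 = np.array([t.t1_ms for t in self.tissues.values()])
        t2 = np.array([t.t2_ms for t in self.tissues.values()])
        pd = np.array([t.pd for t in self.tissues.values()])
        return t1, t2, pd


@dataclass(frozen=True)
class OptSurface:
    """Amplitude and inter-tissue distance over a (FA, T_inv) grid.

    ``amplitude[f, t]`` is the mean over tissues and frames of the frame
    magnitudes; ``distance[f, t]`` the mean pairwise Euclidean distance
    between the tissues' frame curves (curves compared unnormalized, so
    amplitude keeps its SNR meaning).
    """

    fa_grid_deg: np.ndarray
    tinv_grid_ms: np.ndarray
    amplitude: np.ndarray
    distance: np.ndarray

    def __post_init__(self):
        shape = (len(self.fa_grid_deg), len(self.tinv_grid_ms))
        if self.amplitude.shape != shape or self.distance.shape != shape:
            raise ParameterError("surface shapes must be |fa_grid| x |tinv_grid|")

    def to_frame(self):
        """Long-format table (fa_deg, tinv_ms, amplitude, distance)."""
        import pandas as pd

        fa, ti = np.meshgrid(self.fa_grid_deg, self.tinv_grid_ms, indexing="ij")
        return pd.DataFrame(
            {
                "fa_deg": fa.ravel(),
                "tinv_ms": ti.ravel(),
                "amplitude": self.amplitude.ravel(),
                "distance": self.distance.ravel(),
            }
        )


def sweep_surfaces(
    panel: TissuePanel,
    fa_grid_deg=None,
    tinv_grid_ms=None,
    seq_template: SequenceParams | None = None,
) -> OptSurface:
    """Simulate every (FA, T_inv) grid point and tabulate amplitude/contrast.

    Default grids cover 10-60 degrees in 2-degree steps and 1-5 s in 250 ms
    steps.  Frame curves (``seq_template.n_frames`` points) keep every T_inv
    comparable-length.  Deterministic: no randomness anywhere.
    """
    if len(panel) < 2:
        raise ParameterError("inter-tissue distance needs at least two tissues")
    fa_grid = np.asarray(
        np.arange(10.0, 60.0 + 1e-9, 2.0) if fa_grid_deg is None else fa_grid_deg,
        dtype=float,
    )
    tinv_grid = np.asarray(
        np.arange(1000.0, 5000.0 + 1e-9, 250.0) if tinv_grid_ms is None else tinv_grid_ms,
        dtype=float,
    )
    if fa_grid.size == 0 or tinv_grid.size == 0:
        raise ParameterError("grids must be non-empty")
    seq0 = seq_template or SequenceParams(n_cycles_max=100)
    # short inversion intervals need many cycles to settle for long-T1 tissues
    seq0 = seq0.replace(n_cycles_max=max(seq0.n_cycles_max, 100))

    t1, t2, pd = panel.arrays()
    n_tis, n_fa = len(panel), fa_grid.size
    amplitude = np.empty((n_fa, tinv_grid.size))
    distance = np.empty((n_fa, tinv_grid.size))
    iu, ju = np.triu_indices(n_tis, k=1)

    for j, tinv in enumerate(tinv_grid):
        seq = seq0.replace(tinv_ms=float(tinv))
        # batch = flip angles x tissues, one simulation per T_inv
        res = simulate_single_pool_batch(
            np.tile(t1, n_fa),
            np.tile(t2, n_fa),
            np.tile(pd, n_fa),
            seq,
            flip_angle_deg=np.repeat(fa_grid, n_tis),
            record="frames",
        )
        curves = np.abs(res.signal.reshape(n_fa, n_tis, seq.n_frames))
        amplitude[:, j] = curves.mean(axis=(1, 2))
        diffs = curves[:, iu, :] - curves[:, ju, :]
        distance[:, j] = np.linalg.norm(diffs, axis=2).mean(axis=1)

    return OptSurface(fa_grid, tinv_grid, amplitude, distance)


def optimal_fa(surface: OptSurface, tinv_lo_ms: float, tinv_hi_ms: float) -> float:
    """Joint optimal flip angle over an inversion-interval window.

    Per T_inv column the amplitude-maximizing and distance-maximizing flip
    angles are averaged; the result is the mean of those averages over the
    columns inside ``[tinv_lo_ms, tinv_hi_ms]``.
    """
    sel = (surface.tinv_grid_ms >= tinv_lo_ms) & (surface.tinv_grid_ms <= tinv_hi_ms)
    if not np.any(sel):
        raise ParameterError(
            f"window [{tinv_lo_ms}, {tinv_hi_ms}] ms does not intersect the T_inv grid"
        )
    fa_amp = surface.fa_grid_deg[np.argmax(surface.amplitude[:, sel], axis=0)]
    fa_dist = surface.fa_grid_deg[np.argmax(surface.distance[:, sel], axis=0)]
    return float(np.mean((fa_amp + fa_dist) / 2.0))
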