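"""Domain types: acquisition settings, tissue models, signal curves.

All times are in milliseconds unless a field name says otherwise
(``t2b_us``, ``k_exchange_per_s``).  Proton density ``pd`` is an arbitrary
positive scale; every derived signal is proportional to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ParameterError",
    "ConvergenceError",
    "SequenceParams",
    "SinglePoolTissue",
    "TwoPoolTissue",
    "SignalCurve",
]


class ParameterError(ValueError):
    """A tissue or sequence parameter violates its physical constraint."""


class ConvergenceError(RuntimeError):
    """The periodic steady state was not reached within ``n_cycles_max``.

    Attributes
    ----------
    residual : float
        Maximum relative cycle-to-cycle change at the last simulated cycle.
    """

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class SequenceParams:
    """Timing and excitation settings of an inversion-prepared bSSFP train.

    An inversion pulse is applied every ``tinv_ms`` milliseconds; the gap is
    filled with the maximal number ``n_readouts = floor(tinv_ms / tr_ms)`` of
    balanced SSFP repetitions with sign-alternating flip angles.  Echoes are
    sampled at ``te_ms`` after each excitation.  The readout train is divided
    into ``n_frames`` equal temporal windows when images (frames) are formed.

    ``catalyzation`` enables the standard alpha/2 preparation pulse followed
    by a TR/2 delay after each inversion, which smooths the transient
    oscillations.  ``invert_bound_pool`` controls whether the inversion pulse
    acts on the macromolecular pool (by default it does not: its microsecond
    T2 destroys any coherent rotation).
    """

    flip_angle_deg: float = 30.0
    tr_ms: float = 4.0
    te_ms: float = 2.0
    tinv_ms: float = 3000.0
    n_frames: int = 20
    n_cycles_max: int = 10
    convergence_tol: float = 1e-6
    catalyzation: bool = True
    invert_bound_pool: bool = False
    rf_pulse_duration_us: float = 600.0

    def __post_init__(self):
        if not 0.0 < self.flip_angle_deg <= 90.0:
            raise ParameterError(
                f"flip_angle_deg must be in (0, 90], got {self.flip_angle_deg}"
            )
        if self.tr_ms <= 0:
            raise ParameterError(f"tr_ms must be positive, got {self.tr_ms}")
        if not 0.0 < self.te_ms <= self.tr_ms:
            raise ParameterError(
                f"te_ms must be in (0, tr_ms], got te={self.te_ms}, tr={self.tr_ms}"
            )
        if self.tinv_ms < self.tr_ms:
            raise ParameterError("tinv_ms must allow at least one readout")
        if self.n_frames < 1 or self.n_frames > self.n_readouts:
            raise ParameterError(
                f"n_frames must be in [1, n_readouts={self.n_readouts}], "
                f"got {self.n_frames}"
            )
        if self.n_cycles_max < 2:
            raise ParameterError("n_cycles_max must be at least 2")
        if self.convergence_tol <= 0:
            raise ParameterError("convergence_tol must be positive")

    @property
    def n_readouts(self) -> int:
        """Maximal number of TRs that fit in one inversion interval."""
        return int(math.floor(self.tinv_ms / self.tr_ms))

    @property
    def frame_width_ms(self) -> float:
        """Temporal footprint of one reconstructed frame (TI window)."""
        return self.tinv_ms / self.n_frames

    def replace(self, **kwargs) -> "SequenceParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SinglePoolTissue:
    """Free-water tissue described by a single relaxing compartment."""

    t1_ms: float
    t2_ms: float
    pd: float = 1.0

    def __post_init__(self):
        if self.t2_ms <= 0:
            raise ParameterError(f"t2_ms must be positive, got {self.t2_ms}")
        if self.t1_ms < self.t2_ms:
            raise ParameterError(
                f"t1_ms must be >= t2_ms, got T1={self.t1_ms}, T2={self.t2_ms}"
            )
        if self.pd < 0:
            raise ParameterError(f"pd must be non-negative, got {self.pd}")


@dataclass(frozen=True)
class TwoPoolTissue:
    """Free water pool plus a macromolecular (bound) pool in exchange.

    ``mf`` is the macromolecular proton fraction: the bound pool holds
    ``mf * pd`` of the equilibrium magnetization and the free pool the rest.
    Exchange follows detailed balance with fundamental rate constant
    ``k_exchange_per_s`` (forward rate ``k * mf``, backward ``k * (1 - mf)``),
    so the equilibrium pool sizes are preserved.  The bound pool has a
    microsecond-scale T2 (``t2b_us``) and is therefore never observed
    directly; it only saturates under RF and exchanges longitudinal
    magnetization.
    """

    t1f_ms: float
    t2f_ms: float
    mf: float
    t1b_ms: float = 1000.0
    t2b_us: float = 10.0
    k_exchange_per_s: float = 19.0
    pd: float = 1.0

    def __post_init__(self):
        if self.t2f_ms <= 0 or self.t1f_ms < self.t2f_ms:
            raise ParameterError(
                f"need t1f_ms >= t2f_ms > 0, got T1={self.t1f_ms}, T2={self.t2f_ms}"
            )
        if not 0.0 <= self.mf <= 0.5:
            raise ParameterError(f"mf must be in [0, 0.5], got {self.mf}")
        if self.t1b_ms <= 0 or self.t2b_us <= 0:
            raise ParameterError("bound-pool relaxation times must be positive")
        if self.k_exchange_per_s < 0:
            raise ParameterError("exchange rate must be non-negative")
        if self.pd < 0:
            raise ParameterError(f"pd must be non-negative, got {self.pd}")


@dataclass(frozen=True)
class SignalCurve:
    """A signal evolution sampled at increasing inversion times.

    ``values`` follow the magnitude convention (non-negative); signed curves
    are handled internally where zero-crossing information matters.
    """

    ti_ms: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ti = np.asarray(self.ti_ms, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if ti.ndim != 1 or ti.shape != vals.shape:
            raise ParameterError("ti_ms and values must be 1-D with equal length")
        if len(ti) > 1 and not np.all(np.diff(ti) > 0):
            raise ParameterError("ti_ms must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ParameterError("values must be finite")
        object.__setattr__(self, "ti_ms", ti)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.ti_ms)

    def to_csv(self, path) -> None:
        """Write as two-column CSV with header ``ti_ms,value``."""
        arr = np.column_stack([self.ti_ms, self.values])
        np.savetxt(path, arr, delimiter=",", header="ti_ms,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "SignalCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        arr = np.atleast_2d(arr)
        return cls(ti_ms=arr[:, 0], values=arr[:, 1])
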