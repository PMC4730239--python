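"""The four classical two-way admixture models as gene-flow matrices.

Each model has two parameters: the admixture proportion ``m`` of population
1 (by convention the minor ancestry, ``m <= 0.5``) and the admixture time
``T`` in generations.

HI   : hybrid isolation — a single founding pulse ``(m, 1-m)``, nothing after.
GA   : gradual admixture — both ancestries keep contributing; the inflow at
       generation ``t`` is ``(m/t, (1-m)/t)``, which keeps the ancestry
       proportion of population 1 at ``m`` in every generation and makes
       every generation's cohort contribute exactly ``1/T`` of the present
       gene pool.
CGFR : continuous gene flow, population 1 the recipient — population 1
       founds alone and population 2 donates a constant fraction ``a`` per
       generation with ``(1-a)^(T-1) = m``.
CGFD : continuous gene flow, population 1 the donor — population 2 founds
       alone and population 1 donates ``a`` per generation with
       ``1 - (1-a)^(T-1) = m``.

All four yield ``H_1(T) = m`` exactly.  With ``T = 1`` the continuous
models have no post-founding generations and collapse to HI.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import AdmixtureMatrix, build_trajectory, track_length_distribution

__all__ = [
    "MODEL_NAMES",
    "TwoWayModelSpec",
    "build_matrix",
    "model_distributions",
    "hi_density",
    "expectation_ratio",
]

MODEL_NAMES = ("HI", "GA", "CGFR", "CGFD")


@dataclass(frozen=True)
class TwoWayModelSpec:
    """One of the four two-parameter models: name, proportion m, time T."""

    name: str
    m: float
    T: int

    def __post_init__(self) -> None:
        name = self.name.upper()
        if name not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}, got {self.name!r}")
        if not (0.0 < self.m < 1.0):
            raise ValueError(f"admixture proportion must lie in (0, 1), got {self.m}")
        if int(self.T) != self.T or self.T < 1:
            raise ValueError(f"admixture time must be a positive integer, got {self.T}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "T", int(self.T))


def build_matrix(
    spec: TwoWayModelSpec, labels: tuple[str, str] = ("1", "2")
) -> AdmixtureMatrix:
    """Realize a two-way model spec as a K=2 gene-flow matrix."""
    if spec.m > 0.5:
        warnings.warn(
            "population 1 is conventionally the minor ancestry (m <= 0.5); "
            f"m = {spec.m} keeps your labelling as given",
            stacklevel=2,
        )
    m, T = spec.m, spec.T
    vals = np.zeros((2, T))
    if spec.name == "HI":
        vals[:, 0] = (m, 1.0 - m)
    elif spec.name == "GA":
        t = np.arange(1, T + 1, dtype=float)
        vals[0] = m / t
        vals[1] = (1.0 - m) / t
    elif spec.name == "CGFR":
        vals[:, 0] = (1.0, 0.0) if T > 1 else (m, 1.0 - m)
        if T > 1:
            a = 1.0 - m ** (1.0 / (T - 1))
            vals[1, 1:] = a
    else:  # CGFD
        vals[:, 0] = (0.0, 1.0) if T > 1 else (m, 1.0 - m)
        if T > 1:
            a = 1.0 - (1.0 - m) ** (1.0 / (T - 1))
            vals[0, 1:] = a
    return AdmixtureMatrix(vals, labels)


def model_distributions(spec: TwoWayModelSpec, labels: tuple[str, str] = ("1", "2")):
    """Convenience: the pair of track-length distributions (pop 1, pop 2)."""
    traj = build_trajectory(build_matrix(spec, labels))
    return (
        track_length_distribution(traj, 0),
        track_length_distribution(traj, 1),
    )


def hi_density(m: float, T: int, l) -> float | np.ndarray:
    """Closed-form HI track-length density for population 1.

    ``f(l) = (1-m) T exp(-(1-m) T l)``; substituting ``m -> 1-m`` gives
    population 2.
    """
    if not (0.0 < m < 1.0):
        raise ValueError("m must lie in (0, 1)")
    if T < 1:
        raise ValueError("T must be >= 1")
    rate = (1.0 - m) * T
    l = np.asarray(l, dtype=float)
    with np.errstate(under="ignore"):
        out = rate * np.exp(-rate * l)
    return out if out.ndim else float(out)


def expectation_ratio(m: float) -> float:
    """E[L_1] / E[L_2] = m / (1 - m), for any two-way admixture history."""
    if not (0.0 < m < 1.0):
        raise ValueError("m must lie in (0, 1)")
    return m / (1.0 - m)
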