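"""Track-length theory for arbitrary admixture histories.

An admixture history with ``K`` ancestral populations over ``T`` generations
is fully described by a gene-flow matrix ``M = (m_i(t))``: the fraction of
the admixed gene pool replaced by migrants from ancestry ``i`` at generation
``t`` (``t = 1`` founds the population, ``t = T`` is the present).  From
``M`` alone one can derive, per ancestry, the distribution of the lengths of
ancestral tracks — maximal chromosome segments of a single ancestry — as a
finite mixture of exponentials: material that entered at generation ``t``
survives to the present in proportion ``s_i(t)`` and has accumulated an
*effective* recombination rate ``u_i(t)`` (only crossovers joining segments
of different ancestries change observable track lengths), so its surviving
tracks are exponential with rate ``u_i(t)`` and the number of such tracks is
proportional to ``s_i(t) * u_i(t)``.

Chromosome ends and genetic drift are ignored, exactly as in the derivation
of the theory; all lengths are in Morgans (1 Morgan = 100 cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdmixtureMatrix",
    "AncestryTrajectory",
    "TrackLengthDistribution",
    "build_trajectory",
    "track_length_distribution",
    "truncate",
    "tail_probability",
    "moments",
]

_ATOL = 1e-9  # slack for column-sum checks on user-supplied floats


@dataclass(frozen=True)
class AdmixtureMatrix:
    """Gene-flow matrix ``m_i(t)``, row = ancestry, column = generation.

    Column 1 (index 0) founds the admixed population and must sum to 1;
    every later column sums to at most 1, the remainder ``h(t)`` being
    inherited from the previous generation.
    """

    values: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("gene-flow matrix must be 2-dimensional (K x T)")
        K, T = vals.shape
        if K < 2 or T < 1:
            raise ValueError(f"need K >= 2 ancestries and T >= 1 generations, got {K} x {T}")
        if np.any(vals < 0) or np.any(vals > 1):
            bad = int(np.where(np.any((vals < 0) | (vals > 1), axis=0))[0][0])
            raise ValueError(f"entries of column {bad + 1} fall outside [0, 1]")
        sums = vals.sum(axis=0)
        if abs(sums[0] - 1.0) > _ATOL:
            raise ValueError(
                f"founding column (t=1) must sum to 1, got {sums[0]:.6g}"
            )
        later = np.where(sums[1:] > 1.0 + _ATOL)[0]
        if later.size:
            t = int(later[0]) + 2
            raise ValueError(
                f"column t={t} sums to {sums[t - 1]:.6g} > 1; at most the whole "
                "gene pool can be replaced in one generation"
            )
        labels = tuple(self.labels) if self.labels else tuple(
            str(i + 1) for i in range(K)
        )
        if len(labels) != K:
            raise ValueError(f"{len(labels)} labels for {K} ancestries")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labels)

    @property
    def n_ancestries(self) -> int:
        return self.values.shape[0]

    @property
    def n_generations(self) -> int:
        return self.values.shape[1]

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Plain table: rows = ancestries, columns = generation indices 1..T."""
        return pd.DataFrame(
            self.values,
            index=list(self.labels),
            columns=[t + 1 for t in range(self.n_generations)],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AdmixtureMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(str(i) for i in frame.index))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "values": [list(map(float, row)) for row in self.values],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdmixtureMatrix":
        return cls(np.asarray(d["values"], dtype=float), tuple(d.get("labels") or ()))


@dataclass(frozen=True)
class AncestryTrajectory:
    """Per-generation quantities derived from a gene-flow matrix.

    h : (T,)   fraction of the gene pool inherited from the previous
               generation, ``1 - sum_i m_i(t)``.
    H : (K, T) total ancestry proportion of population i at generation t.
    s : (K, T) survival proportion at the present of the cohort that entered
               at generation t: ``m_i(t) * prod_{r>t} h(r)``.
    u : (K, T) effective recombination rate (expected ancestry junctions per
               Morgan) accumulated by cohort (i, t):
               ``sum_{r=t..T} (1 - H_i(r))``.
    """

    matrix: AdmixtureMatrix
    h: np.ndarray
    H: np.ndarray
    s: np.ndarray
    u: np.ndarray

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrix.labels


def build_trajectory(M: AdmixtureMatrix) -> AncestryTrajectory:
    """Derive ``h``, ``H``, ``s`` and ``u`` from a gene-flow matrix.

    ``H`` follows the recursion ``H_i(t) = H_i(t-1) h(t) + m_i(t)`` with
    ``H_i(0) = 0``; ``s`` and ``u`` follow by backward products/sums.
    """
    m = M.values
    K, T = m.shape
    h = 1.0 - m.sum(axis=0)
    h[0] = 0.0  # founding column sums to 1 exactly by contract

    H = np.empty((K, T))
    prev = np.zeros(K)
    for t in range(T):
        prev = prev * h[t] + m[:, t]
        H[:, t] = prev

    # survival: s_i(t) = m_i(t) * prod_{r=t+1..T} h(r)
    # suffix products of h, excluding the cohort's own generation
    suffix = np.ones(T)
    for t in range(T - 2, -1, -1):
        suffix[t] = suffix[t + 1] * h[t + 1]
    s = m * suffix[None, :]

    # effective recombination: u_i(t) = sum_{r=t..T} (1 - H_i(r))
    u = np.cumsum((1.0 - H)[:, ::-1], axis=1)[:, ::-1]

    return AncestryTrajectory(matrix=M, h=h, H=H, s=s, u=u)


@dataclass(frozen=True)
class TrackLengthDistribution:
    """Mixture-of-exponentials track-length distribution for one ancestry.

    ``rates`` are junctions per Morgan, ``weights`` sum to 1.  When
    ``threshold`` is positive the density is the conditional one on
    ``(threshold, inf)``; the stored weights remain those of the
    *untruncated* mixture and the conditional density renormalizes by the
    tail probability at the threshold.
    """

    rates: np.ndarray
    weights: np.ndarray
    ancestry: str = "1"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if r.shape != w.shape or r.ndim != 1 or r.size == 0:
            raise ValueError("rates and weights must be matching 1-d arrays")
        if np.any(r <= 0):
            raise ValueError("all mixture rates must be strictly positive")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if self.threshold < 0:
            raise ValueError("length threshold must be nonnegative")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)

    # -- evaluation --------------------------------------------------------

    def pdf(self, l):
        """Density at length ``l`` (Morgans); conditional if truncated."""
        l = np.asarray(l, dtype=float)
        with np.errstate(under="ignore"):
            f = np.einsum(
                "k,k,...k->...",
                self.weights,
                self.rates,
                np.exp(-np.multiply.outer(l, self.rates)),
            )
        if self.threshold > 0.0:
            f = np.where(l >= self.threshold, f / self._norm(), 0.0)
        return f if f.ndim else float(f)

    def sf(self, l):
        """Survival function P(L > l); conditional if truncated."""
        l = np.asarray(l, dtype=float)
        with np.errstate(under="ignore"):
            p = np.exp(-np.multiply.outer(l, self.rates)) @ self.weights
        if self.threshold > 0.0:
            p = np.where(l >= self.threshold, p / self._norm(), 1.0)
        p = np.minimum(p, 1.0)
        return p if p.ndim else float(p)

    def cdf(self, l):
        return 1.0 - self.sf(l)

    def logpdf(self, l):
        l = np.asarray(l, dtype=float)
        a = -np.multiply.outer(l, self.rates) + np.log(self.weights * self.rates)
        m = a.max(axis=-1, keepdims=True)
        with np.errstate(under="ignore"):
            out = np.squeeze(m, -1) + np.log(np.exp(a - m).sum(axis=-1))
        if self.threshold > 0.0:
            out = out - np.log(self._norm())
        return out if out.ndim else float(out)

    def mean(self) -> float:
        if self.threshold > 0.0:
            # E[L | L > C] = C + sum_k w_k e^{-u_k C} / u_k / norm
            with np.errstate(under="ignore"):
                tail_k = self.weights * np.exp(-self.rates * self.threshold)
            return self.threshold + float(
                (tail_k / self.rates).sum() / tail_k.sum()
            )
        return float((self.weights / self.rates).sum())

    def _norm(self) -> float:
        with np.errstate(under="ignore"):
            n = float(np.exp(-self.rates * self.threshold) @ self.weights)
        return n


def track_length_distribution(
    traj: AncestryTrajectory, i: int | str
) -> TrackLengthDistribution:
    """Mixture-exponential length distribution of ancestry ``i`` tracks.

    Cohort ``t`` contributes an exponential component with rate ``u_i(t)``
    and weight proportional to ``s_i(t) * u_i(t)`` (the expected number of
    its tracks per Morgan).  Cohorts with zero survival or zero effective
    recombination contribute no tracks and are dropped.

    Parameters
    ----------
    i
        Ancestry label, or integer row index into the matrix.
    """
    idx = _ancestry_index(traj, i)
    s, u = traj.s[idx], traj.u[idx]
    if traj.H[idx, -1] <= 0:
        raise ValueError(
            f"ancestry {traj.labels[idx]!r} is absent from the present-day "
            "population (H_i(T) = 0); it has no tracks"
        )
    raw = s * u
    keep = raw > 0
    if not np.any(keep):
        raise ValueError(
            f"ancestry {traj.labels[idx]!r} has no track-producing cohorts"
        )
    w = raw[keep]
    return TrackLengthDistribution(
        rates=u[keep], weights=w / w.sum(), ancestry=traj.labels[idx]
    )


def truncate(dist: TrackLengthDistribution, C: float) -> TrackLengthDistribution:
    """Condition the distribution on track length > ``C`` (Morgans).

    For a single-component (pulse-admixture) distribution this is the
    memoryless shift ``f(l - C)``; in general the density is renormalized by
    the tail probability at ``C``.
    """
    if C < 0:
        raise ValueError("threshold C must be nonnegative")
    if C == 0:
        return TrackLengthDistribution(
            dist.rates, dist.weights, dist.ancestry, 0.0
        )
    p = tail_probability(dist, C)
    if p <= 0.0:
        raise ValueError(
            f"P(L > {C:g} Morgan) underflows to zero under this history; "
            "choose a smaller threshold"
        )
    return TrackLengthDistribution(dist.rates, dist.weights, dist.ancestry, C)


def tail_probability(dist: TrackLengthDistribution, C: float) -> float:
    """P(L > C) of the *untruncated* mixture: ``sum_k w_k exp(-u_k C)``."""
    if C < 0:
        raise ValueError("threshold C must be nonnegative")
    with np.errstate(under="ignore"):
        return float(np.exp(-dist.rates * C) @ dist.weights)


def moments(traj: AncestryTrajectory, i: int | str) -> tuple[float, float]:
    """Mean and variance (Morgan, Morgan^2) of ancestry-``i`` track lengths.

    mean = H_i(T) / sum_t s_i(t) u_i(t);
    var  = sum_t w_i(t) * 2 / u_i(t)^2 - mean^2.
    """
    dist = track_length_distribution(traj, i)
    mean = float((dist.weights / dist.rates).sum())
    second = float((dist.weights * 2.0 / dist.rates**2).sum())
    return mean, second - mean**2


def _ancestry_index(traj: AncestryTrajectory, i: int | str) -> int:
    if isinstance(i, str):
        try:
            return traj.labels.index(i)
        except ValueError:
            raise KeyError(
                f"unknown ancestry {i!r}; matrix has {traj.labels}"
            ) from None
    return int(i)
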