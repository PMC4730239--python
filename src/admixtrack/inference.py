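"""Admixture-history inference from observed ancestral track lengths.

Given the lengths of local-ancestry tracks from a two-way admixed
population, estimate the admixture proportion ``m`` (from total track
lengths, or from the mean-length ratio ``E[L_1]/E[L_2] = m/(1-m)``), then,
with ``m`` held fixed, estimate the admixture time ``T`` for each candidate
model (HI, GA, CGFR, CGFD) by maximizing the conditional likelihood of the
track lengths above the analysis threshold ``C``, and select the optimal
model by AIC.  All four models have the same number of parameters, so AIC
selection reduces to picking the highest likelihood.  Bootstrap resampling
of tracks provides a support rate for the selected model and a confidence
interval for the admixture time.

Using the ``C``-truncated (conditional) density in the likelihood is what
makes the time estimate robust to the choice of threshold: the short tracks
that local-ancestry callers cannot resolve are conditioned away rather than
modelled as missing mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import core_model
from .models import MODEL_NAMES, TwoWayModelSpec, model_distributions

__all__ = [
    "TrackSet",
    "ModelFit",
    "SelectionResult",
    "estimate_proportion",
    "ancestry_proportions",
    "log_likelihood",
    "fit_model",
    "select_model",
    "bootstrap",
    "likelihood_ratio_test",
    "relative_error",
    "average_relative_error",
]


# ---------------------------------------------------------------------------
# track container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackSet:
    """Observed or simulated ancestral tracks.

    lengths are in Morgans; ``threshold`` records the minimum length the set
    was filtered at (0 for unfiltered data).
    """

    ancestries: np.ndarray
    lengths: np.ndarray
    haplotypes: np.ndarray | None = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        anc = np.asarray(self.ancestries, dtype=object)
        lens = np.asarray(self.lengths, dtype=float)
        if anc.shape != lens.shape or lens.ndim != 1:
            raise ValueError("ancestries and lengths must be matching 1-d arrays")
        if lens.size == 0:
            raise ValueError("empty track set")
        if np.any(lens <= 0):
            raise ValueError("all track lengths must be positive")
        if self.threshold > 0 and np.any(lens < self.threshold):
            raise ValueError(
                f"track shorter than the declared threshold {self.threshold:g} Morgan"
            )
        object.__setattr__(self, "ancestries", anc)
        object.__setattr__(self, "lengths", lens)
        if self.haplotypes is not None:
            hap = np.asarray(self.haplotypes)
            if hap.shape != lens.shape:
                raise ValueError("haplotypes must match lengths in shape")
            object.__setattr__(self, "haplotypes", hap)

    def __len__(self) -> int:
        return self.lengths.size

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.ancestries.tolist())))

    def lengths_of(self, label) -> np.ndarray:
        return self.lengths[self.ancestries == label]

    def total_lengths(self) -> dict:
        return {
            lab: float(self.lengths_of(lab).sum()) for lab in self.labels
        }

    def filter(self, C: float) -> "TrackSet":
        """Keep tracks of length >= C (Morgans); records C as the threshold."""
        if C < 0:
            raise ValueError("threshold must be nonnegative")
        if C <= self.threshold:
            return self
        keep = self.lengths >= C
        if not np.any(keep):
            raise ValueError(f"no tracks left above threshold {C:g} Morgan")
        return TrackSet(
            self.ancestries[keep],
            self.lengths[keep],
            None if self.haplotypes is None else self.haplotypes[keep],
            threshold=C,
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"ancestry": self.ancestries, "length_morgan": self.lengths}
        if self.haplotypes is not None:
            d["haplotype"] = self.haplotypes
        return pd.DataFrame(d)

    @classmethod
    def from_records(cls, records, threshold: float = 0.0) -> "TrackSet":
        """Build from an iterable of (ancestry, length_morgan[, haplotype])."""
        recs = list(records)
        anc = np.asarray([r[0] for r in recs], dtype=object)
        lens = np.asarray([r[1] for r in recs], dtype=float)
        haps = None
        if recs and len(recs[0]) > 2:
            haps = np.asarray([r[2] for r in recs])
        return cls(anc, lens, haps, threshold)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit of one two-way model at fixed m."""

    spec: TwoWayModelSpec
    m_hat: float
    loglik: float
    aic: float
    at_boundary: bool = False
    failed: bool = False

    @property
    def t_hat(self) -> int:
        return self.spec.T


@dataclass(frozen=True)
class SelectionResult:
    """AIC model selection outcome, optionally with bootstrap summaries."""

    best: str
    fits: dict
    m_hat: float
    pop1: str
    support: float | None = None
    t_hat: float | None = None
    ci95: tuple[float, float] | None = None

    @property
    def best_fit(self) -> ModelFit:
        return self.fits[self.best]

    @property
    def t_mle(self) -> int:
        return self.best_fit.t_hat


# ---------------------------------------------------------------------------
# proportion estimation
# ---------------------------------------------------------------------------

def ancestry_proportions(tracks: TrackSet, method: str = "total-length") -> dict:
    """Per-ancestry admixture proportion estimates.

    ``total-length`` divides each ancestry's summed track length by the
    grand total; ``mean-ratio`` inverts the mean-length ratio identity
    ``E[L_1]/E[L_2] = m/(1-m)`` (two ancestries only).
    """
    labels = tracks.labels
    if len(labels) < 2:
        raise ValueError("need at least two ancestries to estimate proportions")
    if method == "total-length":
        totals = tracks.total_lengths()
        grand = sum(totals.values())
        return {lab: totals[lab] / grand for lab in labels}
    if method == "mean-ratio":
        if len(labels) != 2:
            raise ValueError("mean-ratio estimator is defined for two ancestries")
        means = {lab: float(tracks.lengths_of(lab).mean()) for lab in labels}
        a, b = labels
        return {
            a: means[a] / (means[a] + means[b]),
            b: means[b] / (means[a] + means[b]),
        }
    raise ValueError(f"unknown method {method!r}")


def estimate_proportion(tracks: TrackSet, method: str = "total-length") -> float:
    """Admixture proportion of population 1 (the minor ancestry)."""
    return min(ancestry_proportions(tracks, method).values())


def minor_ancestry(tracks: TrackSet, method: str = "total-length") -> str:
    """Label of the minor ancestry (population 1 by convention)."""
    props = ancestry_proportions(tracks, method)
    return min(sorted(props), key=lambda lab: props[lab])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _pop_lengths(tracks: TrackSet, pop1: str | None) -> tuple[str, str, np.ndarray, np.ndarray]:
    labels = tracks.labels
    if len(labels) == 1 and pop1 is not None:
        # all observed tracks belong to one ancestry; the other contributes
        # an empty sample (legal for likelihood evaluation when the caller
        # says which population the observed tracks are)
        other = np.empty(0, dtype=float)
        if labels[0] == pop1:
            return pop1, "", tracks.lengths, other
        return pop1, labels[0], other, tracks.lengths
    if len(labels) != 2:
        raise ValueError(
            f"two-way inference needs exactly two ancestries, got {labels}"
        )
    if pop1 is None:
        pop1 = minor_ancestry(tracks)
    if pop1 not in labels:
        raise KeyError(f"unknown ancestry {pop1!r}")
    pop2 = labels[1] if labels[0] == pop1 else labels[0]
    return pop1, pop2, tracks.lengths_of(pop1), tracks.lengths_of(pop2)


def log_likelihood(
    tracks: TrackSet,
    spec: TwoWayModelSpec,
    C: float = 0.0,
    pop1: str | None = None,
) -> float:
    """Conditional log-likelihood of the tracks under a two-way model.

    Each ancestry's tracks are scored with its model distribution truncated
    at ``C``; the two ancestry contributions add.  Tracks shorter than ``C``
    are an error — filter first.
    """
    _, _, l1, l2 = _pop_lengths(tracks, pop1)
    if C > 0 and (np.any(l1 < C) or np.any(l2 < C)):
        raise ValueError(
            f"tracks shorter than C={C:g} Morgan present; apply TrackSet.filter(C) first"
        )
    d1, d2 = model_distributions(spec)
    total = 0.0
    for d, ls in ((d1, l1), (d2, l2)):
        if ls.size == 0:
            continue
        dt = core_model.truncate(d, C) if C > 0 else d
        total += float(np.sum(dt.logpdf(ls)))
    return total


def _compress(lengths: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram lengths onto a log-spaced grid, representing each occupied
    bin by its count-weighted mean length.  Exact to second order in the
    bin width for any smooth log-density."""
    lo = lengths.min()
    hi = lengths.max()
    if hi <= lo or lengths.size <= n_bins:
        return lengths, np.ones(lengths.size)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0] *= 0.999999
    edges[-1] *= 1.000001
    counts, _ = np.histogram(lengths, bins=edges)
    sums, _ = np.histogram(lengths, bins=edges, weights=lengths)
    occ = counts > 0
    return sums[occ] / counts[occ], counts[occ].astype(float)


def _weighted_loglik(spec, C, reps_and_counts) -> float:
    d1, d2 = model_distributions(spec)
    total = 0.0
    for d, (rep, cnt) in zip((d1, d2), reps_and_counts):
        if rep.size == 0:
            continue
        dt = core_model.truncate(d, C) if C > 0 else d
        total += float(cnt @ dt.logpdf(rep))
    return total


def _candidate_ladder(t_max: int) -> np.ndarray:
    ts = np.unique(np.round(np.geomspace(1, t_max, 45)).astype(int))
    return ts[(ts >= 1) & (ts <= t_max)]


def fit_model(
    tracks: TrackSet,
    name: str,
    m_hat: float,
    C: float = 0.0,
    t_max: int = 500,
    pop1: str | None = None,
    approx_threshold: int = 2000,
    n_bins: int = 1024,
) -> ModelFit:
    """MLE of the admixture time under one model, with m fixed at ``m_hat``.

    The time is optimized on the integer grid ``1..t_max``: a coarse
    geometric ladder locates the likelihood peak, then every integer inside
    the winning bracket is scored (ties go to the smaller time).  Ancestry
    samples larger than ``approx_threshold`` tracks are compressed onto
    ``n_bins`` log-spaced length bins before scoring; the `log_likelihood`
    function itself always scores every track.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    _, _, l1, l2 = _pop_lengths(tracks, pop1)
    if C > 0:
        if np.any(l1 < C) or np.any(l2 < C):
            raise ValueError("tracks shorter than C present; filter first")
    rc = []
    for ls in (l1, l2):
        if ls.size > approx_threshold:
            rc.append(_compress(ls, n_bins))
        else:
            rc.append((ls, np.ones(ls.size)))

    def score(T: int) -> float:
        try:
            return _weighted_loglik(TwoWayModelSpec(name, m_hat, T), C, rc)
        except ValueError:  # e.g. tail underflow at this T
            return -np.inf

    ladder = _candidate_ladder(t_max)
    vals = np.array([score(int(T)) for T in ladder])
    if not np.any(np.isfinite(vals)):
        return ModelFit(
            TwoWayModelSpec(name, m_hat, 1), m_hat, -np.inf, np.inf, failed=True
        )
    k = int(np.argmax(vals))
    lo = int(ladder[max(0, k - 1)])
    hi = int(ladder[min(len(ladder) - 1, k + 1)])
    fine = np.arange(lo, hi + 1)
    fvals = np.array([score(int(T)) for T in fine])
    j = int(np.argmax(fvals))
    t_best, l_best = int(fine[j]), float(fvals[j])
    at_boundary = t_best == t_max
    if at_boundary:
        warnings.warn(
            f"{name}: fitted admixture time hit the search bound t_max={t_max}; "
            "consider increasing t_max",
            stacklevel=2,
        )
    k_params = 2  # m and T
    return ModelFit(
        TwoWayModelSpec(name, m_hat, t_best),
        m_hat,
        l_best,
        2.0 * k_params - 2.0 * l_best,
        at_boundary=at_boundary,
    )


def select_model(
    tracks: TrackSet,
    C: float = 0.0,
    t_max: int = 500,
    models=MODEL_NAMES,
    proportion_method: str = "total-length",
    **fit_kwargs,
) -> SelectionResult:
    """Fit all candidate models with a shared m-hat and select by AIC.

    All candidates have two parameters, so minimum AIC is maximum
    likelihood; ties break toward the fixed model order HI, GA, CGFR, CGFD.
    """
    pop1 = minor_ancestry(tracks, proportion_method)
    m_hat = ancestry_proportions(tracks, proportion_method)[pop1]
    fits = {}
    for name in models:
        fits[name] = fit_model(
            tracks, name, m_hat, C=C, t_max=t_max, pop1=pop1, **fit_kwargs
        )
    ok = [n for n in models if not fits[n].failed]
    if not ok:
        raise ValueError("all model fits failed (non-finite likelihood)")
    best = max(ok, key=lambda n: fits[n].loglik)
    # deterministic tie-break toward the fixed model order
    for n in ok:
        if fits[n].loglik == fits[best].loglik:
            best = n
            break
    return SelectionResult(best=best, fits=fits, m_hat=m_hat, pop1=pop1)


def bootstrap(
    tracks: TrackSet,
    B: int = 100,
    seed: int | None = None,
    C: float = 0.0,
    t_max: int = 500,
    models=MODEL_NAMES,
    **fit_kwargs,
) -> SelectionResult:
    """Bootstrap support and CI for the AIC-selected model.

    Tracks are resampled with replacement, stratified by ancestry (each
    ancestry keeps its observed track count).  ``support`` is the fraction
    of replicates whose selected model matches the full-data choice;
    ``t_hat`` is the mean, and ``ci95`` the 2.5/97.5 percentile interval, of
    the replicate time estimates under the full-data model.  Replicates in
    which the full-data model cannot be fit count against support and are
    excluded from the time summaries.
    """
    full = select_model(tracks, C=C, t_max=t_max, models=models, **fit_kwargs)
    if B == 0:
        return full
    rng = np.random.default_rng(seed)
    by_label = {lab: np.where(tracks.ancestries == lab)[0] for lab in tracks.labels}
    agree = 0
    t_vals = []
    for _ in range(B):
        idx = np.concatenate(
            [rng.choice(ix, size=ix.size, replace=True) for ix in by_label.values()]
        )
        rep = TrackSet(
            tracks.ancestries[idx], tracks.lengths[idx], threshold=tracks.threshold
        )
        try:
            res = select_model(rep, C=C, t_max=t_max, models=models, **fit_kwargs)
        except ValueError:
            continue
        if res.best == full.best:
            agree += 1
        fit = res.fits.get(full.best)
        if fit is not None and not fit.failed:
            t_vals.append(fit.t_hat)
    t_arr = np.asarray(t_vals, dtype=float)
    t_hat = float(t_arr.mean()) if t_arr.size else None
    ci = (
        tuple(float(q) for q in np.percentile(t_arr, [2.5, 97.5]))
        if t_arr.size
        else None
    )
    return SelectionResult(
        best=full.best,
        fits=full.fits,
        m_hat=full.m_hat,
        pop1=full.pop1,
        support=agree / B,
        t_hat=t_hat,
        ci95=ci,
    )


# ---------------------------------------------------------------------------
# auxiliary statistics
# ---------------------------------------------------------------------------

def likelihood_ratio_test(fit_null: ModelFit, fit_alt: ModelFit, df: int) -> float:
    """LRT p-value for nested models: 2(l_alt - l_null) ~ chi2(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        warnings.warn(
            "alternative likelihood below null (optimizer noise); statistic clamped at 0",
            stacklevel=2,
        )
        stat = 0.0
    return float(stats.chi2.sf(stat, df))


def relative_error(t_true: float, t_hat: float) -> float:
    """|T_true - T_hat| / T_true."""
    if t_true <= 0:
        raise ValueError("t_true must be positive")
    return abs(t_true - t_hat) / t_true


def average_relative_error(pairs) -> float:
    """Arithmetic mean of relative errors over (t_true, t_hat) pairs."""
    errs = [relative_error(t, th) for t, th in pairs]
    if not errs:
        raise ValueError("no pairs given")
    return float(np.mean(errs))
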