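"""Forward-time Wright-Fisher simulation of admixture with segment tracking.

The population is a pool of ``2 N`` haploid chromosomes evolving under
discrete generations; an "individual" is a sampled pair of chromosomes.
Each generation the gamete pool first receives migrant chromosomes of pure
ancestry according to the corresponding column of the gene-flow matrix
(deterministic largest-remainder counts), then the whole next generation is
produced by random mating: every offspring chromosome recombines two
distinct, uniformly chosen parent chromosomes with a Poisson(map length)
number of crossovers at uniform positions (Haldane model, no interference).
The founding migrants mate immediately, so material that entered at
generation ``t`` goes through ``T - t + 1`` meioses by the present — the
same bookkeeping the mixture-of-exponentials theory uses.

No selection, no mutation, one chromosome per simulation; replicates stand
in for multiple chromosomes.  Coordinates are continuous Morgans on the
half-open interval ``[0, chrom_length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._wf_kernel import run_wright_fisher
from .core_model import AdmixtureMatrix
from .inference import TrackSet
from .models import TwoWayModelSpec, build_matrix

__all__ = ["SimulationConfig", "Chromosome", "simulate", "extract_tracks"]


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of one forward simulation.

    Defaults mirror a standard design: a constant diploid population of
    5000, one 3-Morgan chromosome (roughly human chromosome 1), 400 sampled
    individuals.
    """

    matrix: AdmixtureMatrix
    chrom_length: float = 3.0
    pop_size: int = 5000
    sample_individuals: int = 400
    seed: int | None = None

    def __post_init__(self) -> None:
        M = self.matrix
        if isinstance(M, TwoWayModelSpec):
            object.__setattr__(self, "matrix", build_matrix(M))
            M = self.matrix
        if not isinstance(M, AdmixtureMatrix):
            raise TypeError("matrix must be an AdmixtureMatrix or TwoWayModelSpec")
        if self.chrom_length <= 0:
            raise ValueError("chromosome length must be positive (Morgans)")
        if self.pop_size < 2:
            raise ValueError("population size must be at least 2")
        if self.sample_individuals < 1 or self.sample_individuals > self.pop_size:
            raise ValueError(
                "sample size must be between 1 and the population size "
                f"(asked for {self.sample_individuals} of {self.pop_size})"
            )


@dataclass(frozen=True)
class Chromosome:
    """A single haploid chromosome as ancestry segments.

    ``ends`` are the right edges of the segments in Morgans (the last equals
    the chromosome length); ``ancestries`` the matching labels.  Segments
    are half-open ``[start, end)``, gap-free and non-overlapping.
    """

    ends: np.ndarray
    ancestries: np.ndarray
    haplotype: int = 0

    @property
    def segments(self):
        """List of (start, end, ancestry) tuples."""
        starts = np.concatenate(([0.0], self.ends[:-1]))
        return list(zip(starts, self.ends, self.ancestries))


def _migrant_counts(M: AdmixtureMatrix, pool: int) -> np.ndarray:
    """Largest-remainder integer migrant counts per generation (T, K)."""
    frac = M.values.T * pool  # (T, K)
    base = np.floor(frac).astype(np.int64)
    rem = frac - base
    # founding generation must fill the whole pool exactly
    deficit0 = pool - base[0].sum()
    order = np.argsort(-rem[0])
    base[0, order[: int(deficit0)]] += 1
    # later generations: round the column sum, then distribute
    for t in range(1, M.n_generations):
        target = int(np.round(frac[t].sum()))
        deficit = target - base[t].sum()
        order = np.argsort(-rem[t])
        base[t, order[: int(deficit)]] += 1
    return base


def simulate(config: SimulationConfig) -> tuple[list[Chromosome], TrackSet]:
    """Run the simulation; return sampled chromosomes and their tracks.

    Sampling draws ``2 * sample_individuals`` distinct chromosomes from the
    final pool (an individual is a chromosome pair).  Reproducible given
    ``config.seed``.
    """
    M = config.matrix
    pool = 2 * config.pop_size
    counts = _migrant_counts(M, pool)
    bad = np.where(counts.sum(axis=1) > pool)[0]
    if bad.size:
        raise ValueError(
            f"migrant replacement exceeds the gene pool at generation {bad[0] + 1}"
        )
    ss = np.random.SeedSequence(config.seed)
    kernel_seed = int(ss.generate_state(1, np.uint32)[0])
    rng = np.random.default_rng(ss.spawn(1)[0])

    ends, anc, off = run_wright_fisher(counts, config.chrom_length, pool, kernel_seed)

    chosen = rng.choice(pool, size=2 * config.sample_individuals, replace=False)
    labels = np.asarray(M.labels, dtype=object)
    chroms = []
    for h, c in enumerate(chosen):
        lo, hi = off[c], off[c + 1]
        chroms.append(
            Chromosome(
                ends=ends[lo:hi].copy(),
                ancestries=labels[anc[lo:hi]],
                haplotype=h,
            )
        )
    return chroms, extract_tracks(chroms, chrom_length=config.chrom_length)


def extract_tracks(
    chromosomes, C: float = 0.0, chrom_length: float | None = None
) -> TrackSet:
    """Maximal same-ancestry runs of each chromosome as a TrackSet.

    Adjacent same-ancestry segments are merged; chromosome-end tracks are
    included.  An optional minimum length ``C`` (Morgans) is applied
    afterwards and recorded on the TrackSet.
    """
    anc_out, len_out, hap_out = [], [], []
    for chrom in chromosomes:
        ends = np.asarray(chrom.ends, dtype=float)
        anc = np.asarray(chrom.ancestries, dtype=object)
        if ends.size == 0 or ends.size != anc.size:
            raise ValueError("malformed chromosome: empty or mismatched segments")
        if np.any(np.diff(ends) <= 0):
            raise ValueError("malformed chromosome: segment ends not increasing")
        if chrom_length is not None and abs(ends[-1] - chrom_length) > 1e-9:
            raise ValueError(
                "segments do not cover the chromosome "
                f"(last end {ends[-1]:g}, expected {chrom_length:g})"
            )
        # merge runs of identical ancestry
        new_run = np.empty(anc.size, dtype=bool)
        new_run[0] = True
        new_run[1:] = anc[1:] != anc[:-1]
        run_ends = ends[np.concatenate((np.where(new_run)[0][1:] - 1, [anc.size - 1]))]
        starts = np.concatenate(([0.0], run_ends[:-1]))
        anc_out.append(anc[new_run])
        len_out.append(run_ends - starts)
        hap_out.append(np.full(int(new_run.sum()), chrom.haplotype))
    tracks = TrackSet(
        np.concatenate(anc_out),
        np.concatenate(len_out),
        np.concatenate(hap_out),
        threshold=0.0,
    )
    if C > 0:
        tracks = tracks.filter(C)
    return tracks
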