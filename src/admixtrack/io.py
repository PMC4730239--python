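"""Readers and writers for track tables and configuration files.

Two plain-text dialects are supported, both tab-separated with a header:

``flat``
    One track per row: ``ancestry  length`` — the flat list a local-ancestry
    post-processing step typically produces.

``segments``
    BED-like per-haplotype ancestry calls: ``haplotype  start  end
    ancestry``.  Adjacent same-ancestry segments of a haplotype are merged
    into maximal tracks before lengths are taken.

Lengths/coordinates may be in centiMorgans (the common convention of
local-ancestry callers) or Morgans; internally everything is Morgans
(1 cM = 0.01 Morgan exactly).  When no unit is declared, cM is assumed with
a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import AdmixtureMatrix
from .inference import SelectionResult, TrackSet
from .models import TwoWayModelSpec

__all__ = [
    "read_tracks",
    "write_tracks",
    "matrix_from_config",
    "read_config",
    "report_to_dict",
]

logger = logging.getLogger("admixtrack")

CM_PER_MORGAN = 100.0


def _unit_factor(units: str | None) -> float:
    """Factor converting declared units to Morgans."""
    if units is None:
        warnings.warn("no length unit declared; assuming centiMorgans", stacklevel=3)
        units = "cM"
    u = units.lower()
    if u in ("cm", "centimorgan", "centimorgans"):
        return 1.0 / CM_PER_MORGAN
    if u in ("m", "morgan", "morgans"):
        return 1.0
    raise ValueError(f"unknown length unit {units!r} (use 'cM' or 'Morgan')")


def read_tracks(
    path,
    kind: str = "flat",
    units: str | None = "cM",
    ancestries: tuple[str, ...] | None = None,
) -> TrackSet:
    """Read a track file into a TrackSet (lengths in Morgans).

    ``ancestries``, when given, is the declared label set; rows with other
    labels raise with their line number.
    """
    factor = _unit_factor(units)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no track records found")
    if kind == "flat":
        cols = {c.lower().split("_")[0]: c for c in df.columns}
        try:
            anc_col, len_col = cols["ancestry"], cols["length"]
        except KeyError:
            raise ValueError(
                f"{path}: flat track table needs 'ancestry' and 'length' columns, "
                f"got {list(df.columns)}"
            ) from None
        lengths = pd.to_numeric(df[len_col], errors="coerce").to_numpy() * factor
        anc = df[anc_col].astype(str).to_numpy(dtype=object)
        bad = np.where(~np.isfinite(lengths) | (lengths <= 0))[0]
        if bad.size:
            raise ValueError(
                f"{path}: non-positive or unparseable length on line {bad[0] + 2}"
            )
        _check_labels(anc, ancestries, path)
        return TrackSet(anc, lengths)
    if kind == "segments":
        cols = {c.lower().split("_")[0]: c for c in df.columns}
        try:
            h, s, e, a = (cols[k] for k in ("haplotype", "start", "end", "ancestry"))
        except KeyError:
            raise ValueError(
                f"{path}: segment table needs haplotype/start/end/ancestry columns, "
                f"got {list(df.columns)}"
            ) from None
        start = pd.to_numeric(df[s], errors="coerce").to_numpy() * factor
        end = pd.to_numeric(df[e], errors="coerce").to_numpy() * factor
        bad = np.where(~np.isfinite(start) | ~np.isfinite(end) | (end <= start))[0]
        if bad.size:
            raise ValueError(f"{path}: malformed segment on line {bad[0] + 2}")
        anc = df[a].astype(str).to_numpy(dtype=object)
        _check_labels(anc, ancestries, path)
        recs = []
        sub = pd.DataFrame(
            {"hap": df[h].to_numpy(), "start": start, "end": end, "anc": anc}
        )
        for hap, grp in sub.groupby("hap", sort=True):
            grp = grp.sort_values("start")
            cur_anc, cur_len = None, 0.0
            for st, en, an in zip(grp["start"], grp["end"], grp["anc"]):
                if an == cur_anc:
                    cur_len += en - st
                else:
                    if cur_anc is not None:
                        recs.append((cur_anc, cur_len, hap))
                    cur_anc, cur_len = an, en - st
            recs.append((cur_anc, cur_len, hap))
        return TrackSet.from_records(recs)
    raise ValueError(f"unknown track-file kind {kind!r}")


def _check_labels(anc, declared, path):
    if declared is None:
        return
    unknown = np.where(~np.isin(anc, np.asarray(declared, dtype=object)))[0]
    if unknown.size:
        raise ValueError(
            f"{path}: undeclared ancestry {anc[unknown[0]]!r} on line "
            f"{unknown[0] + 2} (declared: {declared})"
        )


def write_tracks(tracks: TrackSet, path, units: str = "cM") -> None:
    """Write a TrackSet as a flat TSV in the requested units."""
    factor = 1.0 / _unit_factor(units)
    unit_tag = "cM" if factor == CM_PER_MORGAN else "morgan"
    df = pd.DataFrame(
        {"ancestry": tracks.ancestries, f"length_{unit_tag}": tracks.lengths * factor}
    )
    # %.10g keeps any decimal-limited caller output (e.g. "12.5" cM) exact
    # through the Morgan round trip
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_segments(chromosomes, path, units: str = "cM") -> None:
    """Write simulated chromosomes as a BED-like segment TSV."""
    factor = 1.0 / _unit_factor(units)
    unit_tag = "cM" if factor == CM_PER_MORGAN else "morgan"
    rows = []
    for chrom in chromosomes:
        start = 0.0
        for st, en, an in chrom.segments:
            rows.append((chrom.haplotype, st * factor, en * factor, an))
            start = en
    pd.DataFrame(
        rows, columns=["haplotype", f"start_{unit_tag}", f"end_{unit_tag}", "ancestry"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def matrix_from_config(cfg: dict) -> AdmixtureMatrix:
    """Build a gene-flow matrix from a config mapping.

    Either a named two-way model, ``{"model": "CGFD", "m": 0.3, "T": 50}``,
    or an explicit matrix, ``{"labels": [...], "values": [[...], ...]}``.
    """
    if "model" in cfg:
        from .models import build_matrix

        spec = TwoWayModelSpec(cfg["model"], float(cfg["m"]), int(cfg["T"]))
        return build_matrix(spec, tuple(cfg.get("labels", ("1", "2"))))
    if "values" in cfg:
        return AdmixtureMatrix.from_dict(cfg)
    raise ValueError("config needs either a 'model' block or a 'values' matrix")


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def report_to_dict(
    result: SelectionResult, years_per_generation: float = 29.0
) -> dict:
    """JSON-serializable inference report with all four fits."""
    out = {
        "pop1": result.pop1,
        "m_hat": result.m_hat,
        "best_model": result.best,
        "t_mle": result.t_mle,
        "fits": {
            name: {
                "T": fit.t_hat,
                "loglik": None if not np.isfinite(fit.loglik) else fit.loglik,
                "aic": None if not np.isfinite(fit.aic) else fit.aic,
                "at_boundary": fit.at_boundary,
                "failed": fit.failed,
            }
            for name, fit in result.fits.items()
        },
    }
    if result.support is not None:
        out["bootstrap"] = {
            "support": result.support,
            "t_hat": result.t_hat,
            "ci95": list(result.ci95) if result.ci95 else None,
        }
    t_report = result.t_hat if result.t_hat is not None else result.t_mle
    out["years_before_present"] = (
        None if t_report is None else t_report * years_per_generation
    )
    return out
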