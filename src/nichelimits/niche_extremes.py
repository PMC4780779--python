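"""Trimmed climatic extremes per species and descriptive classifications.

The niche limit of a species for a climate variable is its minimum or maximum
value across occurrence records after discarding a fixed fraction of records
at each tail (default 5%), which guards the extremes against misidentified
specimens and imprecise georeferences. Trimming is record-based: with n values
and fraction f, k = floor(f·n) records are dropped per tail and the limits are
the k-th and (n-1-k)-th order statistics (0-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .occurrence_climate import ClimateSample

ARIDITY_LABELS = ("hyper_arid", "arid", "semi_arid", "dry_subhumid", "humid")
# UNEP category bounds, resolved half-open low-inclusive.
_ARIDITY_BOUNDS = (0.03, 0.2, 0.5, 0.65)

TROPICAL_MEAN_ANNUAL_T = 18.0  # Köppen tropical threshold, °C


@dataclass
class VariableLimits:
    trimmed_min: float
    trimmed_max: float
    n_records_used: int


@dataclass
class SpeciesClimateSummary:
    """Per-species trimmed climatic limits, the PGLS response rows."""

    species_id: str
    state: str
    limits: dict[str, VariableLimits] = field(default_factory=dict)


def trim_extremes(values, fraction: float = 0.05) -> tuple[float, float]:
    """Trimmed (min, max) of ``values`` after dropping floor(fraction·n) per tail."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot trim an empty value list")
    if not 0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    k = math.floor(fraction * values.size)
    s = np.sort(values)
    return float(s[k]), float(s[values.size - 1 - k])


def trim_extremes_interpolated(values, fraction: float = 0.05) -> tuple[float, float]:
    """Percentile-interpolation variant of :func:`trim_extremes` (optional flag)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot trim an empty value list")
    if not 0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    lo, hi = np.quantile(values, [fraction, 1.0 - fraction])
    return float(lo), float(hi)


def summarize_species(
    samples_by_species: Mapping[str, list[ClimateSample]],
    states: Mapping[str, str],
    fraction: float = 0.05,
    interpolate: bool = False,
) -> list[SpeciesClimateSummary]:
    """Trimmed limits per retained species, independently per variable.

    ``samples_by_species`` should be the output of
    :func:`nichelimits.occurrence_climate.filter_min_records`. Trimming is
    marginal: a record extreme in AI can be trimmed for AI yet still
    contribute to the temperature limits. Every species must have a state.
    """
    trim = trim_extremes_interpolated if interpolate else trim_extremes
    out = []
    for sp, group in samples_by_species.items():
        if sp not in states:
            raise ConfigurationError(f"species {sp!r} has no photosynthetic state")
        limits: dict[str, VariableLimits] = {}
        variables = group[0].values.keys()
        for var in variables:
            vals = [s.values[var] for s in group if s.values.get(var) is not None]
            if not vals:
                continue
            lo, hi = trim(vals, fraction)
            limits[var] = VariableLimits(lo, hi, len(vals))
        out.append(SpeciesClimateSummary(sp, states[sp], limits))
    return out


def classify_aridity(ai: float) -> str:
    """UNEP aridity category of an aridity-index value (half-open, low-inclusive).

    [0, 0.03) hyper_arid, [0.03, 0.2) arid, [0.2, 0.5) semi_arid,
    [0.5, 0.65) dry_subhumid, [0.65, inf) humid.
    """
    if ai < 0:
        raise ValueError(f"aridity index must be >= 0, got {ai}")
    for bound, label in zip(_ARIDITY_BOUNDS, ARIDITY_LABELS):
        if ai < bound:
            return label
    return ARIDITY_LABELS[-1]


def bin_temperature(t: float, width: float = 5.0, anchor: float = 0.0) -> tuple[float, float]:
    """The [lower, lower+width) bin containing temperature ``t`` (low-inclusive)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    lower = anchor + width * math.floor((t - anchor) / width)
    return lower, lower + width


def tropical_flag(mean_annual_t: float) -> bool:
    """True iff the mean annual temperature meets the 18°C tropical threshold."""
    return mean_annual_t >= TROPICAL_MEAN_ANNUAL_T


def summaries_to_frame(summaries: list[SpeciesClimateSummary]) -> pd.DataFrame:
    """Tidy one-row-per-species table: species, state, then n/min/max per variable."""
    variables: list[str] = []
    for s in summaries:
        for var in s.limits:
            if var not in variables:
                variables.append(var)
    rows = []
    for s in summaries:
        row: dict[str, object] = {"species": s.species_id, "state": s.state}
        for var in variables:
            lim = s.limits.get(var)
            row[f"n_{var}"] = lim.n_records_used if lim else 0
            row[f"{var}_min"] = lim.trimmed_min if lim else np.nan
            row[f"{var}_max"] = lim.trimmed_max if lim else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary_csv(summaries: list[SpeciesClimateSummary], dest: str | IO[str]) -> None:
    summaries_to_frame(summaries).to_csv(dest, index=False)


def read_summary_csv(source: str | IO[str]) -> list[SpeciesClimateSummary]:
    """Inverse of :func:`write_summary_csv`."""
    df = pd.read_csv(source)
    variables = [c[2:] for c in df.columns if c.startswith("n_")]
    out = []
    for _, row in df.iterrows():
        limits = {}
        for var in variables:
            n = int(row[f"n_{var}"])
            if n > 0 and np.isfinite(row[f"{var}_min"]):
                limits[var] = VariableLimits(
                    float(row[f"{var}_min"]), float(row[f"{var}_max"]), n
                )
        out.append(SpeciesClimateSummary(str(row["species"]), str(row["state"]), limits))
    return out
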