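"""Fossil occurrence tables: I/O, validation, cleaning filters and age randomisation.

An occurrence table is a plain :class:`pandas.DataFrame` with the fixed column
schema :data:`OCCURRENCE_COLUMNS`.  One row is one dated, located, taxonomically
classified fossil occurrence.  Ages are in Ma (mega-annum before present),
coordinates are palaeogeographic degrees.  All cleaning operations return new
frames and never mutate their input; the column schema is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

#: Fixed column schema of an occurrence table (CSV column order).
OCCURRENCE_COLUMNS = [
    "occurrence_id",
    "locality_id",
    "suborder",
    "superfamily",
    "genus",
    "species",
    "max_ma",
    "min_ma",
    "plon",
    "plat",
    "stage",
]

_TEXT_COLUMNS = [
    "occurrence_id", "locality_id", "suborder", "superfamily",
    "genus", "species", "stage",
]
_NUMERIC_COLUMNS = ["max_ma", "min_ma", "plon", "plat"]

#: Reference stratigraphic-range table schema (taxon, oldest and youngest age in Ma).
RANGE_COLUMNS = ["taxon", "oldest_ma", "youngest_ma"]


class OccurrenceFormatError(ValueError):
    """Raised when an input file does not follow the occurrence CSV contract."""


class OccurrenceValidationError(ValueError):
    """Raised (in strict mode) when a row violates an occurrence invariant."""


def _invalid_mask(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows violating the occurrence invariants."""
    bad = ~(table["max_ma"] > table["min_ma"])
    bad |= table["min_ma"] < 0
    bad |= table["plon"].abs() > 180
    bad |= table["plat"].abs() > 90
    bad |= table["genus"].str.len() == 0
    bad |= table[_NUMERIC_COLUMNS].isna().any(axis=1)
    return bad


def validate_occurrences(table: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate an occurrence frame; drop (lenient) or reject (strict) bad rows."""
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise OccurrenceFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    table = table[OCCURRENCE_COLUMNS].copy()
    for col in _TEXT_COLUMNS:
        table[col] = table[col].fillna("").astype(str)
    for col in _NUMERIC_COLUMNS:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    bad = _invalid_mask(table)
    if bad.any():
        if strict:
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise OccurrenceValidationError(
                f"row {row} (occurrence_id={table['occurrence_id'].iloc[row]!r}) "
                "violates occurrence invariants (require max_ma > min_ma >= 0, "
                "coordinates in range, non-empty genus)"
            )
        logger.warning("dropping %d invalid occurrence row(s)", int(bad.sum()))
        table = table.loc[~bad]
    return table.reset_index(drop=True)


def read_occurrences(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate an occurrence CSV.

    Empty ``species`` strings denote occurrences not resolved to species level.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_occurrences(raw, strict=strict)


def write_occurrences(table: pd.DataFrame, path) -> None:
    """Write an occurrence table back to CSV (UTF-8, '.' decimal separator)."""
    table[OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_reference_ranges(path) -> pd.DataFrame:
    """Read a reference stratigraphic-range CSV (taxon, oldest_ma, youngest_ma)."""
    ranges = pd.read_csv(path)
    missing = [c for c in RANGE_COLUMNS if c not in ranges.columns]
    if missing:
        raise OccurrenceFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    ranges = ranges[RANGE_COLUMNS].copy()
    if not (ranges["oldest_ma"] > ranges["youngest_ma"]).all():
        raise OccurrenceValidationError("reference ranges require oldest_ma > youngest_ma")
    if ranges["taxon"].duplicated().any():
        raise OccurrenceValidationError("taxon names in reference ranges must be unique")
    return ranges


# ---------------------------------------------------------------------------
# cleaning filters
# ---------------------------------------------------------------------------

def filter_age_uncertainty(table: pd.DataFrame, max_uncertainty: float = 10.0) -> pd.DataFrame:
    """Drop occurrences whose stratigraphic age uncertainty exceeds a threshold.

    The interval width ``max_ma - min_ma`` must *exceed* ``max_uncertainty``
    (in Myr) for a row to be removed; rows exactly at the boundary are kept.
    """
    if max_uncertainty < 0:
        raise ValueError("max_uncertainty must be non-negative")
    keep = (table["max_ma"] - table["min_ma"]) <= max_uncertainty
    return table.loc[keep].reset_index(drop=True)


def flag_range_outliers(table: pd.DataFrame, ranges: pd.DataFrame) -> pd.DataFrame:
    """Flag occurrences against reference stratigraphic ranges of their genus.

    Returns a frame with columns ``occurrence_id`` and ``flag``; flags are
    ``inside``, ``older_than_range``, ``younger_than_range``, ``straddles``
    (interval overlaps a range boundary) or ``no_reference`` (genus absent
    from the reference set).  An occurrence is *outside* only when its whole
    ``[min_ma, max_ma]`` interval lies outside ``[youngest_ma, oldest_ma]``.
    """
    if ranges["taxon"].duplicated().any():
        raise OccurrenceValidationError("taxon names in reference ranges must be unique")
    lookup = ranges.set_index("taxon")
    oldest = table["genus"].map(lookup["oldest_ma"])
    youngest = table["genus"].map(lookup["youngest_ma"])
    flag = np.full(len(table), "straddles", dtype=object)
    inside = (table["max_ma"] <= oldest) & (table["min_ma"] >= youngest)
    older = table["min_ma"] > oldest
    younger = table["max_ma"] < youngest
    flag[inside.to_numpy()] = "inside"
    flag[older.to_numpy()] = "older_than_range"
    flag[younger.to_numpy()] = "younger_than_range"
    flag[oldest.isna().to_numpy()] = "no_reference"
    return pd.DataFrame({"occurrence_id": table["occurrence_id"], "flag": flag})


def _genus_profile(sub: pd.DataFrame, step: float, method: str):
    """Age-frequency profile of a genus on a regular age grid.

    Each occurrence contributes total mass 1, spread uniformly over the grid
    cells its ``[min_ma, max_ma]`` interval overlaps (histogram method), or
    Gaussian-kernel smoothed with Silverman's bandwidth (kernel method).
    Returns (grid cell edges ascending, probability mass per cell).
    """
    lo = float(sub["min_ma"].min())
    hi = float(sub["max_ma"].max())
    n_cells = max(1, int(np.ceil((hi - lo) / step - 1e-9)))
    edges = lo + step * np.arange(n_cells + 1)
    edges[-1] = max(edges[-1], hi)
    mass = np.zeros(n_cells)
    if method == "histogram":
        for a, b in zip(sub["min_ma"].to_numpy(), sub["max_ma"].to_numpy()):
            overlap = np.clip(np.minimum(edges[1:], b) - np.maximum(edges[:-1], a), 0.0, None)
            total = overlap.sum()
            if total > 0:
                mass += overlap / total
        mass /= mass.sum()
    elif method == "kernel":
        # densify each interval at the step size, then smooth
        pts = []
        for a, b in zip(sub["min_ma"].to_numpy(), sub["max_ma"].to_numpy()):
            k = max(2, int(round((b - a) / step)) + 1)
            pts.append(np.linspace(a, b, k))
        weights = np.concatenate([np.full(len(p), 1.0 / len(p)) for p in pts])
        pts = np.concatenate(pts)
        centres = 0.5 * (edges[:-1] + edges[1:])
        if np.ptp(pts) < 1e-12:
            mass[np.argmin(np.abs(centres - pts[0]))] = 1.0
        else:
            kde = gaussian_kde(pts, bw_method="silverman", weights=weights)
            mass = kde(centres)
            mass /= mass.sum()
    else:
        raise ValueError(f"unknown tail-flagging method {method!r}")
    return edges, mass


def flag_range_tails(
    table: pd.DataFrame,
    tail_proportion: float,
    tail_ci: float = 0.05,
    step: float = 0.1,
    method: str = "histogram",
):
    """Flag genera with anomalously long stratigraphic-range tails.

    For each genus the occurrence age intervals are densified at ``step`` Myr
    into an age-frequency profile.  The tails are the portions of the genus
    duration lying below the ``tail_ci`` and above the ``1 - tail_ci``
    quantiles of that profile.  When the summed tail lengths exceed
    ``tail_proportion`` of the genus duration, the genus is flagged, together
    with every occurrence whose interval lies entirely within a tail
    (typically isolated, misdated or misidentified records).

    Returns ``(genus_flags, occurrence_flags)`` frames.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    genus_rows = []
    occ_flag = pd.Series("ok", index=table.index, dtype=object)
    for genus, sub in table.groupby("genus", sort=True):
        lo = float(sub["min_ma"].min())
        hi = float(sub["max_ma"].max())
        duration = hi - lo
        if duration <= 0:
            genus_rows.append((genus, False, 0.0))
            continue
        edges, mass = _genus_profile(sub, step, method)
        cum = np.concatenate([[0.0], np.cumsum(mass)])
        cum[-1] = 1.0
        # quantile ages by linear interpolation on the cumulative profile
        q_low = float(np.interp(tail_ci, cum, edges))
        q_high = float(np.interp(1.0 - tail_ci, cum, edges))
        tails = (q_low - lo) + (hi - q_high)
        frac = tails / duration
        flagged = frac > tail_proportion
        genus_rows.append((genus, bool(flagged), frac))
        if flagged:
            in_tail = (sub["max_ma"] < q_low) | (sub["min_ma"] > q_high)
            occ_flag.loc[sub.index[in_tail]] = "tail"
    genus_flags = pd.DataFrame(genus_rows, columns=["genus", "flagged", "tail_fraction"])
    occurrence_flags = pd.DataFrame(
        {"occurrence_id": table["occurrence_id"], "flag": occ_flag.to_numpy()}
    )
    return genus_flags, occurrence_flags


# ---------------------------------------------------------------------------
# age randomisation
# ---------------------------------------------------------------------------

@dataclass
class AgeReplicate:
    """One age-randomised replicate: a point age per occurrence.

    Occurrences sharing a locality share a point age (drawn uniformly from the
    intersection of their stratigraphic intervals) so that within-locality age
    structure is preserved across replicates.
    """

    replicate_index: int
    seed: int
    point_age: np.ndarray
    conflicting_localities: list = field(default_factory=list)


def randomize_ages(table: pd.DataFrame, n_replicates: int = 10, seed: int = 0) -> list[AgeReplicate]:
    """Draw locality-consistent point ages within stratigraphic bounds.

    Each replicate ``k`` uses an independent random stream seeded ``seed + k``
    so any replicate can be regenerated in isolation.  If the occurrence
    intervals at a locality have an empty intersection, ages at that locality
    fall back to independent per-occurrence draws (logged).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    max_ma = table["max_ma"].to_numpy(float)
    min_ma = table["min_ma"].to_numpy(float)
    groups = table.groupby("locality_id", sort=True).indices
    replicates = []
    for k in range(n_replicates):
        rep_seed = seed + k
        rng = np.random.default_rng(rep_seed)
        ages = np.empty(len(table))
        conflicts = []
        for loc in sorted(groups):
            idx = groups[loc]
            lo = min_ma[idx].max()
            hi = max_ma[idx].min()
            if lo <= hi:
                ages[idx] = rng.uniform(lo, hi)
            else:
                conflicts.append(loc)
                ages[idx] = rng.uniform(min_ma[idx], max_ma[idx])
        if conflicts and k == 0:
            logger.warning(
                "%d locality(ies) have conflicting age intervals; "
                "falling back to independent draws there", len(conflicts)
            )
        replicates.append(AgeReplicate(k + 1, rep_seed, ages, conflicts))
    return replicates
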