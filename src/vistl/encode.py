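"""Timeline encoding: sparse observations -> normalized V x 48 images.

The encoding pipeline mirrors standard bedside practice for gridding EHR
data: observations are blocked at hourly intervals with the most recent
observation carried forward (LOCF); cells still missing are imputed with
location-specific medians fitted on the training split; values are then
normalized to [0, 1] by one of two schemes (plain min-max, or a
direction-aware "custom" scheme where 0 means clinically normal and 1
abnormal); finally rows are permuted by one of three ordering schemes
(standard group order, correlation clustering within groups, or across all
groups). The result is a grayscale image: black = low/absent, white =
high/present.

Static admission attributes (demographics, comorbidities, admission
location) are rendered as constant rows across all 48 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from PIL import Image

from .catalogue import Catalogue, Direction, Group, Kind, STATIC_GROUPS
from .simulate import AdmissionRecord, Cohort, LOCATIONS, Observation

N_HOURS = 48


@dataclass
class HourlyGrid:
    """Hourly-blocked values in native units; NaN marks missing cells."""

    values: np.ndarray  # (V, n_hours), float, NaN = missing
    observed_mask: np.ndarray  # (V, n_hours) bool: has in-hour or carried value
    catalogue: Catalogue
    admission_location: str
    n_dropped: int = 0  # observations at time >= n_hours, dropped with warning

    def __post_init__(self):
        V, H = self.values.shape
        if V != len(self.catalogue):
            raise ValueError(f"grid has {V} rows, catalogue has {len(self.catalogue)}")

    @property
    def complete(self) -> bool:
        return not np.isnan(self.values).any()


@dataclass
class TimelineImage:
    """Normalized visual timeline: pixels in [0,1], variables x hours."""

    pixels: np.ndarray  # (V, 48) in [0, 1]
    row_labels: List[str]
    normalization: str  # "min_max" | "custom"
    ordering: str  # "standard" | "within_group" | "across_group"
    admission_id: Optional[str] = None
    outcome: Optional[str] = None

    def __post_init__(self):
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("timeline pixels must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def scheme(self) -> Tuple[str, str]:
        return (self.normalization, self.ordering)


def _obs_to_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    return pd.DataFrame(
        [(o.variable, o.time_h, o.value) for o in observations],
        columns=["variable", "time_h", "value"],
    )


def _ffill(values: np.ndarray) -> np.ndarray:
    """Forward-fill NaNs along the last (hour) axis."""
    mask = ~np.isnan(values)
    idx = np.where(mask, np.arange(values.shape[-1]), -1)
    np.maximum.accumulate(idx, axis=-1, out=idx)
    filled = np.take_along_axis(values, np.maximum(idx, 0), axis=-1)
    filled[idx < 0] = np.nan
    return filled


def block_hourly(observations, catalogue: Catalogue, n_hours: int = N_HOURS,
                 admission_location: str = "ward") -> HourlyGrid:
    """Block observations at hourly intervals with LOCF.

    Hour bins are 0-based half-open [h, h+1). Within a bin the latest
    timestamp wins (ties: later input order). Observations at or beyond
    ``n_hours`` are dropped (counted in ``n_dropped``); unknown variables
    are rejected.
    """
    obs = _obs_to_frame(observations)
    V = len(catalogue)
    values = np.full((V, n_hours), np.nan)
    n_dropped = 0
    if len(obs):
        names = obs["variable"].astype(str).to_numpy()
        unknown = [n for n in names if n not in catalogue]
        if unknown:
            raise ValueError(f"unknown variable(s) in observations: {sorted(set(unknown))[:5]}")
        t = obs["time_h"].to_numpy(dtype=float)
        if (t < 0).any():
            raise ValueError("negative observation time")
        keep = t < n_hours
        n_dropped = int((~keep).sum())
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} observation(s) at time >= {n_hours} h")
        names, t = names[keep], t[keep]
        vals = obs["value"].to_numpy(dtype=float)[keep]
        var_idx = np.array([catalogue.index(n) for n in names])
        hour = t.astype(int)
        order = np.lexsort((t, hour, var_idx))  # stable: ties keep input order
        key = var_idx[order] * n_hours + hour[order]
        if len(key):
            last = np.flatnonzero(np.r_[key[1:] != key[:-1], True])
            flat = values.reshape(-1)
            flat[key[last]] = vals[order[last]]
    in_hour = ~np.isnan(values)
    values = _ffill(values)
    mask = ~np.isnan(values)
    return HourlyGrid(values, mask, catalogue, admission_location, n_dropped)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

@dataclass
class ImputationStats:
    """Per-variable per-location medians fitted on the training split.

    Fallback chain: location median -> global median -> plausible-range
    midpoint; binary variables impute 0 (absence).
    """

    location_medians: np.ndarray  # (V, 4) NaN where never observed at location
    global_medians: np.ndarray  # (V,)
    fallback: np.ndarray  # (V,) midpoint / 0 for binary
    catalogue: Catalogue
    fitted_on: str = "unspecified"
    fitted_ids: Optional[frozenset] = None

    def value_for(self, var_index: int, location: str) -> float:
        li = LOCATIONS.index(location)
        v = self.location_medians[var_index, li]
        if np.isnan(v):
            v = self.global_medians[var_index]
        if np.isnan(v):
            v = self.fallback[var_index]
        return float(v)

    def fill_vector(self, location: str) -> np.ndarray:
        li = LOCATIONS.index(location)
        v = self.location_medians[:, li].copy()
        v = np.where(np.isnan(v), self.global_medians, v)
        return np.where(np.isnan(v), self.fallback, v)


def fit_imputation_stats(cohort: Cohort, ids: Optional[Sequence[str]] = None,
                         split_id: str = "train") -> ImputationStats:
    """Fit per-variable, per-admission-location medians of observed values."""
    adm = cohort.admissions
    obs = cohort.observations
    if ids is not None:
        ids = set(ids)
        adm = adm[adm["id"].isin(ids)]
        obs = obs[obs["id"].isin(ids)]
    if len(adm) == 0:
        raise ValueError("cannot fit imputation statistics on an empty cohort")
    cat = cohort.catalogue
    V = len(cat)
    loc_of = pd.Series(
        [LOCATIONS.index(l) for l in adm["admission_location"].astype(str)],
        index=adm["id"].astype(str))
    var_idx = pd.Categorical(obs["variable"], categories=cat.names).codes
    loc_idx = obs["id"].astype(str).map(loc_of).to_numpy(dtype=int) \
        if len(obs) else np.array([], dtype=int)
    vals = obs["value"].to_numpy(dtype=float)
    loc_med = np.full((V, 4), np.nan)
    glob_med = np.full(V, np.nan)
    if len(obs):
        df = pd.DataFrame({"v": var_idx, "l": loc_idx, "x": vals})
        for (v, l), g in df.groupby(["v", "l"], sort=False):
            loc_med[v, l] = g["x"].median()
        for v, g in df.groupby("v", sort=False):
            glob_med[v] = g["x"].median()
    fallback = np.array([
        0.0 if spec.kind is Kind.BINARY else spec.midpoint for spec in cat
    ])
    ids_frozen = frozenset(adm["id"]) if ids is None else frozenset(ids)
    return ImputationStats(loc_med, glob_med, fallback, cat,
                           fitted_on=split_id, fitted_ids=ids_frozen)


def impute_missing(grid: HourlyGrid, stats: ImputationStats) -> HourlyGrid:
    """Fill remaining missing cells with the admission-location median chain.

    Observed (including carried-forward) cells are untouched; the original
    observed mask is preserved for audit.
    """
    if len(stats.catalogue) != len(grid.catalogue):
        raise ValueError("imputation stats do not cover this catalogue")
    fill = stats.fill_vector(grid.admission_location)
    values = np.where(np.isnan(grid.values), fill[:, None], grid.values)
    return HourlyGrid(values, grid.observed_mask.copy(), grid.catalogue,
                      grid.admission_location, grid.n_dropped)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizerStats:
    """Training-split normalization statistics.

    ``low``/``high`` are the 1st/99th percentiles of training cells per
    variable (clipped to the plausible range; raw min/max when
    ``percentile_bounds=False``); ``mean`` is the training mean, used by the
    custom scheme for bidirectional variables.
    """

    low: np.ndarray  # (V,)
    high: np.ndarray  # (V,)
    mean: np.ndarray  # (V,)
    scheme: str  # "min_max" | "custom"
    catalogue: Catalogue
    fitted_on: str = "unspecified"
    fitted_ids: Optional[frozenset] = None


def _grids_to_array(grids) -> np.ndarray:
    if isinstance(grids, np.ndarray):
        return grids
    return np.stack([g.values if isinstance(g, HourlyGrid) else g for g in grids])


def fit_normalizer(training_grids, scheme: str, catalogue: Catalogue,
                   percentile_bounds: bool = True, split_id: str = "train",
                   fitted_ids: Optional[frozenset] = None) -> NormalizerStats:
    """Fit normalization bounds on complete training grids (native units)."""
    if scheme not in ("min_max", "custom"):
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    arr = _grids_to_array(training_grids)  # (n, V, H)
    if np.isnan(arr).any():
        raise ValueError("normalizer must be fitted on complete (imputed) grids")
    V = len(catalogue)
    cells = arr.transpose(1, 0, 2).reshape(V, -1)
    if percentile_bounds:
        low = np.percentile(cells, 1, axis=1)
        high = np.percentile(cells, 99, axis=1)
    else:
        low = cells.min(axis=1)
        high = cells.max(axis=1)
    mean = cells.mean(axis=1)
    for i, spec in enumerate(catalogue):
        if spec.kind is Kind.BINARY:
            low[i], high[i] = 0.0, 1.0
            continue
        lo, hi = spec.plausible_range
        low[i] = max(low[i], lo)
        high[i] = min(high[i], hi)
        if not low[i] < high[i]:
            warnings.warn(f"variable {spec.name!r} constant in training data; "
                          f"bounds widened to plausible range")
            low[i], high[i] = lo, hi
    return NormalizerStats(low, high, mean, scheme, catalogue,
                           fitted_on=split_id, fitted_ids=fitted_ids)


def _normalize_array(arr: np.ndarray, stats: NormalizerStats) -> np.ndarray:
    """Vectorized normalization of (..., V, H) native-unit arrays."""
    cat = stats.catalogue
    low = stats.low.reshape(-1, 1)
    high = stats.high.reshape(-1, 1)
    span = high - low
    out = np.empty_like(arr, dtype=float)
    minmax = np.clip((arr - low) / span, 0.0, 1.0)
    if stats.scheme == "min_max":
        out[:] = minmax
    else:
        out[:] = minmax  # higher_abnormal (and default)
        for i, spec in enumerate(cat):
            if spec.kind is Kind.BINARY:
                continue
            if spec.direction is Direction.LOWER:
                out[..., i, :] = np.clip((high[i] - arr[..., i, :]) / span[i], 0.0, 1.0)
            elif spec.direction is Direction.BIDIRECTIONAL:
                m = stats.mean[i]
                denom = max(m - low[i, 0], high[i, 0] - m)
                if denom <= 0:
                    denom = span[i, 0]
                out[..., i, :] = np.minimum(np.abs(arr[..., i, :] - m) / denom, 1.0)
    for i, spec in enumerate(cat):
        if spec.kind is Kind.BINARY:
            out[..., i, :] = np.clip(arr[..., i, :], 0.0, 1.0)
    return out


def apply_normalizer(grid: HourlyGrid, stats: NormalizerStats) -> TimelineImage:
    """Normalize a complete native-unit grid to a [0,1] timeline image.

    min-max: ``(x-low)/(high-low)`` clipped. Custom: higher-abnormal as
    min-max; lower-abnormal inverted (``(high-x)/(high-low)``);
    bidirectional as distance from the training mean scaled by the larger
    one-sided span. Binary rows pass through (absence 0 / presence 1).
    """
    if stats.scheme not in ("min_max", "custom"):
        raise ValueError("normalizer scheme unset")
    if not grid.complete:
        raise ValueError("grid must be imputed before normalization")
    pixels = _normalize_array(grid.values, stats)
    return TimelineImage(pixels, stats.catalogue.names, stats.scheme, "standard")


# ---------------------------------------------------------------------------
# Variable ordering
# ---------------------------------------------------------------------------

@dataclass
class VariableOrdering:
    """Row permutation of the catalogue (display order)."""

    permutation: np.ndarray  # new row r shows catalogue variable permutation[r]
    scheme: str

    def __post_init__(self):
        p = np.asarray(self.permutation)
        if sorted(p.tolist()) != list(range(len(p))):
            raise ValueError("ordering is not a permutation")
        self.permutation = p


def _corr_leaf_order(rows: np.ndarray) -> np.ndarray:
    """Dendrogram leaf order from complete-linkage clustering of 1-r."""
    k = rows.shape[0]
    if k <= 2:
        return np.arange(k)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(rows)
    r = np.nan_to_num(r, nan=0.0)  # zero-variance rows: r = 0 to all others
    np.fill_diagonal(r, 1.0)
    dist = 1.0 - r
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(k, 1)]
    Z = sch.linkage(condensed, method="complete")
    return np.asarray(sch.leaves_list(Z))


def fit_ordering(training_images, scheme: str, catalogue: Catalogue) -> VariableOrdering:
    """Fit a row ordering from training images.

    ``standard`` is the identity. Cluster schemes compute Pearson
    correlations between variable rows pooled over (admission x hour) cells,
    cluster on distance 1-r with complete linkage, and use the dendrogram
    leaf order — within each group block (``within_group``) or globally
    (``across_group``).
    """
    V = len(catalogue)
    if scheme == "standard":
        return VariableOrdering(np.arange(V), "standard")
    if scheme not in ("within_group", "across_group"):
        raise ValueError(f"unknown ordering scheme {scheme!r}")
    arr = _grids_to_array(
        [im.pixels if isinstance(im, TimelineImage) else im for im in training_images])
    if arr.shape[0] < 2:
        raise ValueError("cluster orderings need at least 2 training images")
    rows = arr.transpose(1, 0, 2).reshape(V, -1)
    if scheme == "across_group":
        return VariableOrdering(_corr_leaf_order(rows), "across_group")
    perm = np.arange(V)
    for g, sl in catalogue.group_slices().items():
        idx = np.arange(sl.start, sl.stop)
        perm[sl] = idx[_corr_leaf_order(rows[sl])]
    return VariableOrdering(perm, "within_group")


def reorder(image: TimelineImage, ordering: VariableOrdering) -> TimelineImage:
    p = ordering.permutation
    return TimelineImage(image.pixels[p], [image.row_labels[i] for i in p],
                         image.normalization, ordering.scheme,
                         image.admission_id, image.outcome)


# ---------------------------------------------------------------------------
# Static rows + full composition
# ---------------------------------------------------------------------------

def _static_values(admission: AdmissionRecord, catalogue: Catalogue) -> Dict[int, float]:
    """Native-unit constant-row values for static variables."""
    out: Dict[int, float] = {}
    for i, spec in enumerate(catalogue):
        if spec.group not in STATIC_GROUPS:
            continue
        name = spec.name
        if name == "age_years":
            out[i] = admission.age
        elif name == "female":
            out[i] = float(admission.female)
        elif name == "race_black":
            out[i] = float(admission.race_black)
        elif name.startswith("comorbidity_"):
            out[i] = float(admission.comorbidity_flags.get(name, 0))
        elif name.startswith("loc_"):
            loc = {"loc_ward": "ward", "loc_ed": "ED", "loc_icu": "ICU",
                   "loc_other": "other"}[name]
            out[i] = float(admission.admission_location == loc)
        else:
            out[i] = 0.0
    return out


def fill_static_rows(grid: HourlyGrid, admission: AdmissionRecord) -> HourlyGrid:
    """Render demographics/comorbidities/location as constant rows."""
    values = grid.values.copy()
    mask = grid.observed_mask.copy()
    for i, v in _static_values(admission, grid.catalogue).items():
        values[i, :] = v
        mask[i, :] = True
    return HourlyGrid(values, mask, grid.catalogue, grid.admission_location,
                      grid.n_dropped)


def native_hourly_grid(admission: AdmissionRecord, catalogue: Catalogue,
                       imputation_stats: ImputationStats,
                       n_hours: int = N_HOURS) -> HourlyGrid:
    """Complete native-unit grid: block -> LOCF -> static rows -> impute."""
    grid = block_hourly(admission.observations, catalogue, n_hours,
                        admission_location=admission.admission_location)
    grid = fill_static_rows(grid, admission)
    return impute_missing(grid, imputation_stats)


def encode_admission(admission: AdmissionRecord, catalogue: Catalogue,
                     imputation_stats: ImputationStats,
                     normalizer: NormalizerStats,
                     ordering: Optional[VariableOrdering] = None) -> TimelineImage:
    """Full encoding of one admission into a timeline image.

    All fitted statistics must come from the training split; encoding a
    training-split admission with stats fitted on itself is fine, but the
    model-fitting layer enforces that validation admissions never appear in
    the stats' fitted id set.
    """
    grid = native_hourly_grid(admission, catalogue, imputation_stats)
    image = apply_normalizer(grid, normalizer)
    image.admission_id = admission.id
    image.outcome = admission.outcome
    if ordering is not None:
        image = reorder(image, ordering)
    return image


# ---------------------------------------------------------------------------
# Vectorized cohort encoding (identical semantics to the per-admission path)
# ---------------------------------------------------------------------------

def blocked_cohort_grids(cohort: Cohort, ids: Optional[Sequence[str]] = None,
                         n_hours: int = N_HOURS) -> Tuple[np.ndarray, np.ndarray]:
    """Hourly-blocked LOCF grids for many admissions at once.

    Returns ``(grids, ids)`` with grids of shape (n, V, n_hours) in native
    units, NaN where missing. Static rows are filled; imputation is not.
    """
    cat = cohort.catalogue
    adm = cohort.admissions
    if ids is not None:
        sel = adm["id"].isin(set(ids))
        adm = adm[sel].reset_index(drop=True)
    id_list = adm["id"].to_numpy()
    pos = {a: i for i, a in enumerate(id_list)}
    obs = cohort.observations
    obs = obs[obs["id"].isin(pos)]
    n, V = len(id_list), len(cat)
    grid = np.full(n * V * n_hours, np.nan, dtype=float)
    if len(obs):
        if isinstance(obs["id"].dtype, pd.CategoricalDtype):
            cats = obs["id"].cat.categories
            mapping = np.array([pos.get(c, -1) for c in cats], dtype=np.int64)
            adm_idx = mapping[obs["id"].cat.codes.to_numpy()]
        else:
            adm_idx = obs["id"].map(pos).to_numpy(dtype=np.int64)
        var_idx = pd.Categorical(obs["variable"], categories=cat.names).codes.astype(np.int64)
        t = obs["time_h"].to_numpy(dtype=float)
        vals = obs["value"].to_numpy(dtype=float)
        keep = t < n_hours
        adm_idx, var_idx, t, vals = adm_idx[keep], var_idx[keep], t[keep], vals[keep]
        hour = t.astype(np.int64)
        order = np.lexsort((t, hour, var_idx, adm_idx))
        key = (adm_idx[order] * V + var_idx[order]) * n_hours + hour[order]
        if len(key):
            last = np.flatnonzero(np.r_[key[1:] != key[:-1], True])
            grid[key[last]] = vals[order[last]]
    grids = _ffill(grid.reshape(n, V, n_hours))
    # static rows
    static = {}
    for i, spec in enumerate(cat):
        if spec.group in STATIC_GROUPS:
            static[i] = spec.name
    locs = adm["admission_location"].astype(str).to_numpy()
    for i, name in static.items():
        if name == "age_years":
            col = adm["age"].to_numpy(dtype=float)
        elif name in ("female", "race_black") or name.startswith("comorbidity_"):
            col = adm[name].to_numpy(dtype=float) if name in adm else np.zeros(n)
        elif name.startswith("loc_"):
            loc = {"loc_ward": "ward", "loc_ed": "ED", "loc_icu": "ICU",
                   "loc_other": "other"}[name]
            col = (locs == loc).astype(float)
        else:
            col = np.zeros(n)
        grids[:, i, :] = col[:, None]
    return grids, id_list


def encode_cohort(cohort: Cohort, imputation_stats: ImputationStats,
                  normalizer: NormalizerStats,
                  ordering: Optional[VariableOrdering] = None,
                  ids: Optional[Sequence[str]] = None,
                  return_native: bool = False):
    """Encode many admissions at once.

    Returns ``(images, ids, labels)`` — images (n, V, 48) in [0,1], labels 1
    for died — or additionally the imputed native grids when
    ``return_native`` is set.
    """
    grids, id_list = blocked_cohort_grids(cohort, ids)
    adm = cohort.admissions.set_index("id").loc[id_list]
    locs = adm["admission_location"].astype(str).to_numpy()
    fills = {l: imputation_stats.fill_vector(l) for l in LOCATIONS}
    fill = np.stack([fills[l] for l in locs])  # (n, V)
    grids = np.where(np.isnan(grids), fill[:, :, None], grids)
    images = _normalize_array(grids, normalizer)
    if ordering is not None:
        images = images[:, ordering.permutation, :]
    labels = (adm["outcome"].to_numpy() == "died").astype(int)
    if return_native:
        return images, id_list, labels, grids
    return images, id_list, labels


# ---------------------------------------------------------------------------
# PNG export
# ---------------------------------------------------------------------------

def write_png(image: TimelineImage, path) -> None:
    """8-bit grayscale PNG; byte = round(255*value); row 0 top, hour 0 left."""
    arr = np.round(255.0 * image.pixels).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


def read_png(path, row_labels: Optional[List[str]] = None,
             normalization: str = "min_max",
             ordering: str = "standard") -> TimelineImage:
    """Read a grayscale timeline PNG back into a TimelineImage."""
    try:
        arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    except Exception as e:  # pragma: no cover - message wrapping
        raise ValueError(f"cannot read PNG at {path}: {e}") from e
    labels = row_labels if row_labels is not None else [f"row_{i}" for i in range(arr.shape[0])]
    return TimelineImage(arr, labels, normalization, ordering)
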