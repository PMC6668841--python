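"""MEWS and SOFA early-warning scores: hourly values and 48-hour maxima.

Both scores are computed on the *imputed native-unit* hourly grid
(pre-normalization), matching how the scores are used at the bedside. The
component banding tables are shipped as CSV fixtures
(``data/mews_bands.csv``, ``data/sofa_bands.csv``) rather than hard-coded,
so a site using variant bands can swap the data file.

Band convention: each fixture row gives an exclusive ``upper`` edge; a value
``x`` receives the points of the first row (per component, in file order)
whose ``upper`` exceeds ``x``, i.e. intervals are half-open
``[previous_upper, upper)``. The SOFA cardiovascular component takes the
maximum of the MAP band and the vasopressor-flag band (any vasopressor
counts 3 points — a dose-free simplification, since the generator emits a
flag, not a dose). The SOFA renal component uses creatinine hourly; 24-hour
urine output is only meaningful from hour 24 on and is off by default
(``include_urine``).

MEWS totals lie in [0, 14]; SOFA totals in [0, 24].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .catalogue import Catalogue
from .encode import ImputationStats, native_hourly_grid
from .simulate import AdmissionRecord

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")


def _load_bands(name: str) -> Dict[str, Tuple[str, np.ndarray, np.ndarray]]:
    """component -> (variable, ascending upper edges, points per interval)."""
    with resources.files("vistl").joinpath("data", name).open() as f:
        df = pd.read_csv(f)
    out = {}
    for comp, g in df.groupby("component", sort=False):
        uppers = g["upper"].astype(float).to_numpy()
        if not np.all(np.diff(uppers) > 0):
            raise ValueError(f"{name}: band edges for {comp} not ascending")
        out[comp] = (g["variable"].iloc[0], uppers, g["points"].to_numpy(dtype=int))
    return out


MEWS_BANDS = _load_bands("mews_bands.csv")
SOFA_BANDS = _load_bands("sofa_bands.csv")


def band_points(component_bands, x) -> np.ndarray:
    """Vectorized interval lookup: points of the first band with upper > x."""
    _, uppers, points = component_bands
    idx = np.searchsorted(uppers, np.asarray(x, dtype=float), side="right")
    idx = np.minimum(idx, len(points) - 1)  # x == inf guard
    return points[idx]


@dataclass(frozen=True)
class VitalPanel:
    """One hour's vital signs for MEWS."""

    systolic_bp: float
    heart_rate: float
    resp_rate: float
    temperature: float
    avpu: str  # alert | voice | pain | unresponsive

    def avpu_level(self) -> int:
        if self.avpu not in AVPU_LEVELS:
            raise ValueError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
        return AVPU_LEVELS.index(self.avpu)


@dataclass(frozen=True)
class OrganPanel:
    """One hour's organ-function values for SOFA."""

    pao2_fio2_ratio: float
    platelets: float
    bilirubin: float
    mean_arterial_pressure: float
    vasopressor_in_use: int
    gcs: float
    creatinine: float
    urine_output_24h: Optional[float] = None


@dataclass
class ScoreResult:
    hourly: np.ndarray  # (48,) int
    max48: int
    which: str  # "MEWS" | "SOFA"

    def __post_init__(self):
        assert self.max48 == int(self.hourly.max())


def mews_at_hour(panel: VitalPanel) -> int:
    """MEWS total for one hour: five banded components, each 0-3."""
    total = 0
    for comp, key in (("systolic_bp", "systolic_bp"), ("heart_rate", "heart_rate"),
                      ("resp_rate", "resp_rate"), ("temperature", "temperature")):
        total += int(band_points(MEWS_BANDS[comp], getattr(panel, key)))
    total += int(band_points(MEWS_BANDS["consciousness"], panel.avpu_level()))
    return total


def sofa_at_hour(panel: OrganPanel, include_urine: bool = False) -> int:
    """SOFA total for one hour: six organ components, each 0-4."""
    if not 3 <= panel.gcs <= 15:
        raise ValueError(f"gcs must be in [3, 15], got {panel.gcs}")
    total = int(band_points(SOFA_BANDS["respiration"], panel.pao2_fio2_ratio))
    total += int(band_points(SOFA_BANDS["coagulation"], panel.platelets))
    total += int(band_points(SOFA_BANDS["liver"], panel.bilirubin))
    cardio = int(band_points(SOFA_BANDS["cardiovascular_map"], panel.mean_arterial_pressure))
    cardio = max(cardio, int(band_points(SOFA_BANDS["cardiovascular_vasopressor"],
                                         float(panel.vasopressor_in_use))))
    total += cardio
    total += int(band_points(SOFA_BANDS["cns"], panel.gcs))
    renal = int(band_points(SOFA_BANDS["renal_creatinine"], panel.creatinine))
    if include_urine and panel.urine_output_24h is not None:
        renal = max(renal, int(band_points(SOFA_BANDS["renal_urine"], panel.urine_output_24h)))
    total += renal
    return total


# ---------------------------------------------------------------------------
# Vectorized grid scorers
# ---------------------------------------------------------------------------

def _row(grids: np.ndarray, catalogue: Catalogue, name: str) -> np.ndarray:
    return grids[..., catalogue.index(name), :]


def mews_hourly(grids: np.ndarray, catalogue: Catalogue) -> np.ndarray:
    """MEWS per hour for (..., V, 48) imputed native-unit grids."""
    total = np.zeros(grids.shape[:-2] + (grids.shape[-1],), dtype=int)
    for comp in ("systolic_bp", "heart_rate", "resp_rate", "temperature"):
        total += band_points(MEWS_BANDS[comp], _row(grids, catalogue, comp))
    avpu = np.round(_row(grids, catalogue, "avpu_level"))
    total += band_points(MEWS_BANDS["consciousness"], avpu)
    return total


def sofa_hourly(grids: np.ndarray, catalogue: Catalogue,
                include_urine: bool = False) -> np.ndarray:
    """SOFA per hour for (..., V, 48) imputed native-unit grids."""
    total = band_points(SOFA_BANDS["respiration"], _row(grids, catalogue, "pao2_fio2_ratio"))
    total = total + band_points(SOFA_BANDS["coagulation"], _row(grids, catalogue, "platelets"))
    total = total + band_points(SOFA_BANDS["liver"], _row(grids, catalogue, "bilirubin"))
    cardio = band_points(SOFA_BANDS["cardiovascular_map"],
                         _row(grids, catalogue, "mean_arterial_pressure"))
    vaso = band_points(SOFA_BANDS["cardiovascular_vasopressor"],
                       _row(grids, catalogue, "med_vasopressor"))
    total = total + np.maximum(cardio, vaso)
    gcs = np.clip(np.round(_row(grids, catalogue, "gcs_total")), 3, 15)
    total = total + band_points(SOFA_BANDS["cns"], gcs)
    renal = band_points(SOFA_BANDS["renal_creatinine"], _row(grids, catalogue, "creatinine"))
    if include_urine:
        # hourly urine rate scaled to a 24h volume, applied from hour 24 on
        urine24 = 24.0 * _row(grids, catalogue, "urine_output_rate")
        upts = band_points(SOFA_BANDS["renal_urine"], urine24)
        upts[..., :24] = 0
        renal = np.maximum(renal, upts)
    total = total + renal
    return total


def max_score_48h(admission: AdmissionRecord, which: str,
                  imputation_stats: ImputationStats, catalogue: Catalogue,
                  include_urine: bool = False) -> ScoreResult:
    """Hourly score vector and 48-hour maximum for one admission.

    Builds the imputed native-unit hourly grid (the same blocking/LOCF/
    imputation stages as the image encoder) and scores each hour.
    """
    which = which.upper()
    if which not in ("MEWS", "SOFA"):
        raise ValueError(f"which must be 'MEWS' or 'SOFA', got {which!r}")
    grid = native_hourly_grid(admission, catalogue, imputation_stats)
    if which == "MEWS":
        hourly = mews_hourly(grid.values, catalogue)
    else:
        hourly = sofa_hourly(grid.values, catalogue, include_urine=include_urine)
    return ScoreResult(hourly.astype(int), int(hourly.max()), which)


def max_scores_cohort(grids: np.ndarray, catalogue: Catalogue,
                      include_urine: bool = False) -> Dict[str, np.ndarray]:
    """48-hour maximum MEWS and SOFA for a batch of imputed native grids."""
    return {
        "MEWS": mews_hourly(grids, catalogue).max(axis=-1),
        "SOFA": sofa_hourly(grids, catalogue, include_urine).max(axis=-1),
    }
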