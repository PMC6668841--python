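"""Variable catalogue for visual-timeline encoding.

A catalogue is an ordered list of clinical variables grouped into eight
categories (vital signs, laboratory results, medications, interventions,
nurse examinations, diagnostic tests, clinical characteristics, hospital
location). The list order defines the "standard ordering" of image rows:
variables arranged by group, groups contiguous.

Two presets are shipped:

* ``demo`` — ~50 clinically named variables covering every group, including
  all inputs required by the MEWS and SOFA early-warning scores.
* ``full`` — the demo variables padded with generic numbered lab and
  medication channels up to exactly 156 rows, matching the 156 x 48 matrix
  shape used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence, Tuple


class Group(str, Enum):
    VITALS = "vitals"
    LABS = "labs"
    MEDICATIONS = "medications"
    INTERVENTIONS = "interventions"
    NURSE_EXAM = "nurse_exam"
    DIAGNOSTIC_TESTS = "diagnostic_tests"
    CLINICAL_CHARACTERISTICS = "clinical_characteristics"
    LOCATION = "location"


class Kind(str, Enum):
    CONTINUOUS = "continuous"
    BINARY = "binary"


class Direction(str, Enum):
    """Clinical abnormality direction, used by the custom normalization.

    ``higher_abnormal``: large values are abnormal (e.g. creatinine);
    ``lower_abnormal``: small values are abnormal (e.g. urine output);
    ``bidirectional``: both tails are abnormal (e.g. heart rate);
    ``none``: binary variables (presence itself is the signal).
    """

    HIGHER = "higher_abnormal"
    LOWER = "lower_abnormal"
    BIDIRECTIONAL = "bidirectional"
    NONE = "none"


@dataclass(frozen=True)
class VariableSpec:
    """One catalogue entry.

    Parameters
    ----------
    name
        Unique variable name.
    group
        One of the eight variable groups.
    kind
        ``continuous`` or ``binary``.
    direction
        Abnormality direction (``none`` iff binary).
    plausible_range
        Physiologically plausible ``(low, high)`` in native units
        (continuous variables only). Used for value clipping and as the
        final fallback for imputation and normalization bounds.
    units
        Native units, informational.
    normal_value
        Resting value of a healthy patient in native units; defaults to the
        plausible-range midpoint. Drives the synthetic emission model and
        is deliberately allowed to differ from the midpoint (SpO2's normal
        value is ~98, not the middle of its plausible range).
    """

    name: str
    group: Group
    kind: Kind
    direction: Direction
    plausible_range: Optional[Tuple[float, float]] = None
    units: str = ""
    normal_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is Kind.CONTINUOUS:
            if self.plausible_range is None:
                raise ValueError(f"{self.name}: continuous variable needs a plausible_range")
            lo, hi = self.plausible_range
            if not lo < hi:
                raise ValueError(f"{self.name}: plausible_range low must be < high")
            if self.direction is Direction.NONE:
                raise ValueError(f"{self.name}: continuous variable needs a direction")
            if self.normal_value is None:
                object.__setattr__(self, "normal_value", 0.5 * (lo + hi))
        else:
            if self.direction is not Direction.NONE:
                raise ValueError(f"{self.name}: binary variable must have direction 'none'")

    @property
    def midpoint(self) -> float:
        if self.plausible_range is None:
            return 0.0
        lo, hi = self.plausible_range
        return 0.5 * (lo + hi)


# Variables whose image rows are constant over the 48 hours, filled from
# admission-level fields rather than timestamped observations.
STATIC_GROUPS = (Group.CLINICAL_CHARACTERISTICS, Group.LOCATION)

FULL_SIZE = 156


@dataclass
class Catalogue:
    """Ordered collection of :class:`VariableSpec`; order = standard ordering."""

    variables: Sequence[VariableSpec]
    preset: str = "custom"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names in catalogue: {dupes}")
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, key) -> VariableSpec:
        if isinstance(key, str):
            return self.variables[self._index[key]]
        return self.variables[key]

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def names(self) -> list:
        return [v.name for v in self.variables]

    def group_slices(self) -> dict:
        """Contiguous index ranges per group (standard ordering blocks)."""
        out: dict = {}
        for i, v in enumerate(self.variables):
            if v.group not in out:
                out[v.group] = [i, i + 1]
            else:
                if out[v.group][1] != i:
                    raise ValueError(f"group {v.group.value} is not contiguous at index {i}")
                out[v.group][1] = i + 1
        return {g: slice(a, b) for g, (a, b) in out.items()}

    def is_static(self, name: str) -> bool:
        return self[name].group in STATIC_GROUPS


def _v(name, group, kind, direction, rng=None, units="", normal=None) -> VariableSpec:
    return VariableSpec(
        name=name,
        group=Group(group),
        kind=Kind(kind),
        direction=Direction(direction),
        plausible_range=rng,
        units=units,
        normal_value=normal,
    )


def _demo_variables() -> list:
    C, B = "continuous", "binary"
    hi, lo, bi, no = "higher_abnormal", "lower_abnormal", "bidirectional", "none"
    return [
        # --- vitals -------------------------------------------------------
        _v("heart_rate", "vitals", C, bi, (20, 220), "/min", 75),
        _v("systolic_bp", "vitals", C, bi, (40, 250), "mmHg", 120),
        _v("diastolic_bp", "vitals", C, bi, (20, 150), "mmHg", 72),
        _v("mean_arterial_pressure", "vitals", C, lo, (30, 180), "mmHg", 88),
        _v("resp_rate", "vitals", C, bi, (4, 60), "/min", 14),
        _v("temperature", "vitals", C, bi, (32.0, 42.5), "degC", 36.9),
        _v("spo2", "vitals", C, lo, (50, 100), "%", 98),
        _v("fio2", "vitals", C, hi, (21, 100), "%", 21),
        _v("urine_output_rate", "vitals", C, lo, (0, 300), "mL/h", 70),
        # --- labs ---------------------------------------------------------
        _v("wbc", "labs", C, bi, (0.5, 60), "10^3/uL", 8),
        _v("hemoglobin", "labs", C, lo, (3, 20), "g/dL", 13.5),
        _v("platelets", "labs", C, lo, (5, 800), "10^3/uL", 250),
        _v("sodium", "labs", C, bi, (110, 170), "mmol/L", 140),
        _v("potassium", "labs", C, bi, (1.5, 9), "mmol/L", 4.1),
        _v("bicarbonate", "labs", C, bi, (5, 45), "mmol/L", 24),
        _v("creatinine", "labs", C, hi, (0.2, 15), "mg/dL", 0.9),
        _v("bun", "labs", C, hi, (2, 150), "mg/dL", 15),
        _v("glucose", "labs", C, bi, (20, 800), "mg/dL", 105),
        _v("bilirubin", "labs", C, hi, (0.1, 30), "mg/dL", 0.7),
        _v("lactate", "labs", C, hi, (0.3, 20), "mmol/L", 1.0),
        _v("albumin", "labs", C, lo, (1, 6), "g/dL", 4.0),
        _v("pao2_fio2_ratio", "labs", C, lo, (40, 600), "mmHg", 450),
        # --- medications (binary: given within the hour) -------------------
        _v("med_vasopressor", "medications", B, no),
        _v("med_antibiotic", "medications", B, no),
        _v("med_opioid", "medications", B, no),
        _v("med_anticoagulant", "medications", B, no),
        _v("med_insulin", "medications", B, no),
        _v("med_diuretic", "medications", B, no),
        # --- interventions --------------------------------------------------
        _v("mechanical_ventilation", "interventions", B, no),
        _v("supplemental_oxygen", "interventions", B, no),
        _v("central_line", "interventions", B, no),
        _v("foley_catheter", "interventions", B, no),
        _v("dialysis", "interventions", B, no),
        # --- nurse examinations --------------------------------------------
        _v("morse_score", "nurse_exam", C, hi, (0, 125), "points", 20),
        _v("braden_score", "nurse_exam", C, lo, (6, 23), "points", 21),
        _v("avpu_level", "nurse_exam", C, hi, (0, 3), "AVPU 0=alert..3=unresponsive", 0),
        _v("gcs_total", "nurse_exam", C, lo, (3, 15), "points", 15),
        _v("pain_score", "nurse_exam", C, hi, (0, 10), "0-10", 1),
        # --- diagnostic tests ----------------------------------------------
        _v("chest_xray", "diagnostic_tests", B, no),
        _v("ecg", "diagnostic_tests", B, no),
        _v("ct_scan", "diagnostic_tests", B, no),
        _v("blood_culture", "diagnostic_tests", B, no),
        # --- clinical characteristics (static rows) ------------------------
        _v("age_years", "clinical_characteristics", C, hi, (18, 100), "years", 55),
        _v("female", "clinical_characteristics", B, no),
        _v("race_black", "clinical_characteristics", B, no),
        _v("comorbidity_chf", "clinical_characteristics", B, no),
        _v("comorbidity_copd", "clinical_characteristics", B, no),
        _v("comorbidity_diabetes", "clinical_characteristics", B, no),
        _v("comorbidity_ckd", "clinical_characteristics", B, no),
        # --- admission location (static one-hot rows) ----------------------
        _v("loc_ward", "location", B, no),
        _v("loc_ed", "location", B, no),
        _v("loc_icu", "location", B, no),
        _v("loc_other", "location", B, no),
    ]


def _full_variables() -> list:
    """Demo variables padded with generic channels to exactly 156 rows.

    The padding is inserted group-contiguously: extra numbered lab channels
    after the named labs and extra medication-class channels after the named
    medications, preserving standard-ordering group blocks.
    """
    demo = _demo_variables()
    n_missing = FULL_SIZE - len(demo)
    n_labs = (2 * n_missing) // 3
    n_meds = n_missing - n_labs
    extra_labs = [
        _v(f"lab_generic_{i:02d}", "labs", "continuous",
           "higher_abnormal" if i % 2 else "bidirectional", (0.0, 100.0), "arb", 25.0)
        for i in range(1, n_labs + 1)
    ]
    extra_meds = [
        _v(f"med_class_{i:02d}", "medications", "binary", "none")
        for i in range(1, n_meds + 1)
    ]
    out = []
    for v in demo:
        out.append(v)
        if v.name == "pao2_fio2_ratio":
            out.extend(extra_labs)
        if v.name == "med_diuretic":
            out.extend(extra_meds)
    return out


def default_catalogue(preset: str = "demo") -> Catalogue:
    """Build a preset catalogue.

    ``demo`` has ~50 named variables across all eight groups; ``full`` pads
    to exactly 156 rows. Unknown presets are rejected.
    """
    if preset == "demo":
        return Catalogue(_demo_variables(), preset="demo")
    if preset == "full":
        cat = Catalogue(_full_variables(), preset="full")
        assert len(cat) == FULL_SIZE
        return cat
    raise ValueError(f"unknown catalogue preset {preset!r}; expected 'demo' or 'full'")


# Inputs the early-warning scores need; asserted present in both presets.
MEWS_INPUTS = ("systolic_bp", "heart_rate", "resp_rate", "temperature", "avpu_level")
SOFA_INPUTS = (
    "pao2_fio2_ratio",
    "platelets",
    "bilirubin",
    "mean_arterial_pressure",
    "med_vasopressor",
    "gcs_total",
    "creatinine",
    "urine_output_rate",
)
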