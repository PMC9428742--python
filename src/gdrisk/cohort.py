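"""Participant-level domain types, gestational-diabetes case definition, and
the eligibility/exclusion cascade.

Gestational diabetes (GD) is diagnosed from oral glucose tolerance tests
(GTT) using the standard mg/dL thresholds: a fasting 3-hour 100-g test is
positive with at least two abnormal values (fasting >=95, 1h >=180,
2h >=155, 3h >=140); a fasting 2-hour 75-g test with a single abnormal
value (fasting >=92, 1h >=180, 2h >=153); a non-fasting 50-g screen with a
value >=200 when no fasting test was performed.  A clinical diagnosis is
used only in the absence of GTT data.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Iterable, Optional, Sequence

import pandas as pd

MGDL_TO_MMOLL = 0.0555


class GttKind(str, enum.Enum):
    FASTING_100G_3H = "fasting_100g_3h"
    FASTING_75G_2H = "fasting_75g_2h"
    NONFASTING_50G = "nonfasting_50g"


_N_VALUES = {
    GttKind.FASTING_100G_3H: 4,
    GttKind.FASTING_75G_2H: 3,
    GttKind.NONFASTING_50G: 1,
}

# mg/dL cutoffs, ordered as the measurements (fasting first).
_THRESHOLDS = {
    GttKind.FASTING_100G_3H: (95.0, 180.0, 155.0, 140.0),
    GttKind.FASTING_75G_2H: (92.0, 180.0, 153.0),
    GttKind.NONFASTING_50G: (200.0,),
}

# abnormal values required for a positive test
_N_ABNORMAL = {
    GttKind.FASTING_100G_3H: 2,
    GttKind.FASTING_75G_2H: 1,
    GttKind.NONFASTING_50G: 1,
}


class UndeterminableOutcomeError(ValueError):
    """Raised when neither GTT data nor a clinical diagnosis is available."""


@dataclass(frozen=True)
class GttResult:
    """One oral glucose tolerance test: protocol kind + ordered glucose
    measurements in mg/dL (fasting, 1h, 2h, 3h as applicable)."""

    kind: GttKind
    values: tuple[float, ...]

    def __post_init__(self):
        kind = GttKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        expected = _N_VALUES[kind]
        if len(self.values) != expected:
            raise ValueError(
                f"{kind.value} requires {expected} glucose values, got {len(self.values)}"
            )
        if any((not math.isfinite(v)) or v <= 0 for v in self.values):
            raise ValueError(f"glucose values must be finite and > 0, got {self.values}")

    @property
    def n_abnormal(self) -> int:
        cuts = _THRESHOLDS[self.kind]
        return sum(v >= c for v, c in zip(self.values, cuts))

    @property
    def is_fasting(self) -> bool:
        return self.kind is not GttKind.NONFASTING_50G

    def to_mmol_l(self) -> tuple[float, ...]:
        """Display-only conversion; all internal comparisons stay in mg/dL."""
        return tuple(v * MGDL_TO_MMOLL for v in self.values)


def diagnose_gd(
    gtt: GttResult | Sequence[GttResult] | None,
    clinical: Optional[bool] = None,
) -> bool:
    """Determine GD status from GTT data, falling back to clinical diagnosis.

    Thresholds are inclusive ("at least").  When multiple tests are supplied
    the fasting protocols are applied independently and GD is called if any
    qualifies; the 50-g non-fasting screen only counts when no fasting test
    was performed.  A clinical diagnosis is consulted only when no GTT data
    exist at all.
    """
    if gtt is None:
        tests: list[GttResult] = []
    elif isinstance(gtt, GttResult):
        tests = [gtt]
    else:
        tests = list(gtt)
    if not tests:
        if clinical is None:
            raise UndeterminableOutcomeError(
                "GD outcome undeterminable: no GTT data and no clinical diagnosis"
            )
        return bool(clinical)
    any_fasting = any(t.is_fasting for t in tests)
    for t in tests:
        if t.kind is GttKind.NONFASTING_50G and any_fasting:
            continue  # screen superseded by a fasting confirmatory test
        if t.n_abnormal >= _N_ABNORMAL[t.kind]:
            return True
    return False


@dataclass
class Participant:
    """One member of the analysis cohort.

    Continuous covariates (age in years, BMI in kg/m^2, waist in cm, METs in
    MET·min/wk, PRS on the raw weighted-allele scale) are optional; the
    derived boolean flags (``prs_top25`` etc.) are normally computed from
    them but may be set directly when a cohort is expanded from published
    contingency counts.
    """

    id: str
    age: Optional[float] = None
    bmi: Optional[float] = None
    waist: Optional[float] = None
    family_history_diabetes: Optional[bool] = None
    pcos: Optional[bool] = None
    hypertension: Optional[bool] = None
    prior_diabetes: bool = False
    prediabetes: bool = False
    gtt: Optional[GttResult] = None
    clinical_gd_diagnosis: Optional[bool] = None
    mets: Optional[float] = None
    prs: Optional[float] = None
    gd: Optional[bool] = None
    eligible_ancestry: bool = True
    race_ethnicity: Optional[str] = None
    # derived subgroup flags
    prs_top25: Optional[bool] = None
    prs_bottom25: Optional[bool] = None
    mets_low: Optional[bool] = None
    age_ge35: Optional[bool] = None
    bmi_ge25: Optional[bool] = None

    def __post_init__(self):
        if self.age is not None and not self.age > 0:
            raise ValueError(f"participant {self.id}: age must be > 0, got {self.age}")
        if self.bmi is not None and not self.bmi > 0:
            raise ValueError(f"participant {self.id}: bmi must be > 0, got {self.bmi}")
        if self.mets is not None and not self.mets >= 0:
            raise ValueError(f"participant {self.id}: mets must be >= 0, got {self.mets}")


@dataclass
class Cohort:
    """A list of participants plus a free-text audit trail of the filters
    that produced it."""

    participants: list[Participant]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            raise ValueError("participant ids must be unique")

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(Participant) if f.name != "gtt"]
        rows = [{c: getattr(p, c) for c in cols} for p in self.participants]
        return pd.DataFrame(rows, columns=cols)


_MISSING_ALL_FIELDS = (
    "age", "bmi", "waist", "family_history_diabetes", "pcos", "hypertension", "mets",
)


def _valid_mets(p: Participant) -> bool:
    return p.mets is not None and math.isfinite(p.mets) and p.mets >= 0


def apply_eligibility(cohort: Cohort) -> tuple[Cohort, list[dict]]:
    """Apply the eligibility cascade, returning the retained cohort and an
    ordered per-step exclusion report ``[{"step": ..., "n_removed": ...}]``.

    Steps, in order: missing all covariates; prediabetes; pre-pregnancy
    diabetes; ancestry-ineligible (an opaque caller-supplied flag); no GD
    testing and no clinical diagnosis; missing or invalid METs; missing PRS.
    GD status is derived from GTT/clinical data for every retained
    participant whose ``gd`` is unset.  Filtering is idempotent.
    """
    steps: list[tuple[str, Callable[[Participant], bool]]] = [
        ("missing_all_covariates",
         lambda p: all(getattr(p, f) is None for f in _MISSING_ALL_FIELDS)),
        ("prediabetes", lambda p: bool(p.prediabetes)),
        ("pre_pregnancy_diabetes", lambda p: bool(p.prior_diabetes)),
        ("ineligible_ancestry", lambda p: not p.eligible_ancestry),
        ("no_gd_testing",
         lambda p: p.gtt is None and p.clinical_gd_diagnosis is None and p.gd is None),
        ("missing_or_invalid_mets", lambda p: not _valid_mets(p)),
        ("missing_prs", lambda p: p.prs is None or not math.isfinite(p.prs)),
    ]
    remaining = list(cohort.participants)
    report: list[dict] = []
    for name, hit in steps:
        removed = [p for p in remaining if hit(p)]
        remaining = [p for p in remaining if not hit(p)]
        report.append({"step": name, "n_removed": len(removed)})
    retained = []
    for p in remaining:
        if p.gd is None:
            p = replace(p, gd=diagnose_gd(p.gtt, p.clinical_gd_diagnosis))
        retained.append(p)
    if not retained:
        warnings.warn("eligibility filter removed every participant", stacklevel=2)
    provenance = cohort.provenance + [
        "eligibility: " + ", ".join(f"{r['step']}={r['n_removed']}" for r in report)
    ]
    return Cohort(retained, provenance), report


def write_exclusion_report(report: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


# ---------------------------------------------------------------------------
# phenotype CSV dialect: one row per participant; the GTT is encoded as a
# kind column plus semicolon-separated mg/dL values.

_BOOL_COLS = (
    "family_history_diabetes", "pcos", "hypertension", "prior_diabetes",
    "prediabetes", "clinical_gd_diagnosis", "gd", "eligible_ancestry",
)
_NUM_COLS = ("age", "bmi", "waist", "mets", "prs")


def _parse_bool(x):
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    if isinstance(x, (bool,)):
        return x
    s = str(x).strip().lower()
    if s in {"1", "true", "t", "yes"}:
        return True
    if s in {"0", "false", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean value {x!r}")


def read_phenotypes(path) -> Cohort:
    """Load the participant CSV (columns documented in the README)."""
    df = pd.read_csv(path, dtype={"id": str})
    participants = []
    for _, row in df.iterrows():
        kw: dict = {"id": row["id"]}
        for c in _NUM_COLS:
            if c in df.columns and pd.notna(row[c]):
                kw[c] = float(row[c])
        for c in _BOOL_COLS:
            if c in df.columns:
                v = _parse_bool(row[c])
                if v is not None:
                    kw[c] = v
        if "gtt_kind" in df.columns and pd.notna(row["gtt_kind"]) and row["gtt_kind"] != "":
            vals = tuple(float(v) for v in str(row["gtt_values"]).split(";"))
            kw["gtt"] = GttResult(GttKind(row["gtt_kind"]), vals)
        participants.append(Participant(**kw))
    return Cohort(participants, provenance=[f"loaded from {path}"])


def write_phenotypes(cohort: Cohort, path) -> None:
    rows = []
    for p in cohort.participants:
        row = {"id": p.id}
        for c in _NUM_COLS:
            row[c] = getattr(p, c)
        for c in _BOOL_COLS:
            row[c] = getattr(p, c)
        row["gtt_kind"] = p.gtt.kind.value if p.gtt is not None else ""
        row["gtt_values"] = ";".join(f"{v:g}" for v in p.gtt.values) if p.gtt else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
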