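"""Lesion-level treatment-response classification.

Per-lesion categories follow the single-lesion criteria of Reiter and
colleagues rather than RECIST sums: a lesion responds if its longest
diameter shrinks by at least 30%, progresses if it grows by at least 10%,
and is stable in between.  Boundaries belong to the extreme categories, so
"stable" is the open interval (-30, +10).

A patient with at least two measurable lesions is evaluable.  Among
evaluable patients with at least one responding lesion, the response is
*mixed* when any other lesion progresses or any new lesion appears (even if
every existing lesion responds), and *homogeneous* otherwise.  Evaluable
patients without a responding lesion are non-responders.  The RECIST
sum-of-diameters category is computed alongside so that mixed responses
hidden inside RECIST PR/SD calls can be cross-tabulated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, fisher_exact_two_sided, mann_whitney_u, \
    median_abs_deviation, ContingencyTable2x2

__all__ = [
    "RESPONSE_THRESHOLD",
    "PROGRESSION_THRESHOLD",
    "LesionRecord",
    "LesionCategory",
    "LesionCall",
    "PatientCategory",
    "PatientAssessment",
    "classify_lesion",
    "classify_patient",
    "patient_mad",
    "recist_sum_category",
    "cohort_summary",
    "records_from_table",
]

RESPONSE_THRESHOLD = -30.0   # percent change at or below which a lesion responds
PROGRESSION_THRESHOLD = 10.0  # percent change at or above which a lesion progresses


class LesionCategory(str, Enum):
    RESPONSE = "response"
    STABLE = "stable"
    PROGRESSION = "progression"
    NEW_LESION = "new_lesion"


class PatientCategory(str, Enum):
    HOMOGENEOUS_RESPONSE = "homogeneous_response"
    MIXED_RESPONSE = "mixed_response"
    NON_RESPONDER = "non_responder"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class LesionRecord:
    """One lesion's longest diameter at baseline and one follow-up scan.

    New lesions (absent at baseline) carry baseline_diameter 0 and
    ``is_new=True``; every other lesion must have a positive baseline.
    """

    patient_id: str
    lesion_id: str
    baseline_diameter: float
    followup_diameter: float
    is_new: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_diameter) and np.isfinite(self.followup_diameter)):
            raise ValueError("lesion diameters must be finite")
        if self.followup_diameter < 0:
            raise ValueError("follow-up diameter must be >= 0")
        if self.is_new:
            if self.baseline_diameter != 0:
                raise ValueError("a new lesion must have baseline diameter 0")
        elif self.baseline_diameter <= 0:
            raise ValueError(
                f"lesion {self.lesion_id}: baseline diameter must be > 0 "
                "unless is_new is set"
            )


@dataclass(frozen=True)
class LesionCall:
    category: LesionCategory
    percent_change: float | None


@dataclass(frozen=True)
class PatientAssessment:
    patient_id: str
    category: PatientCategory
    n_lesions: int           # measurable (non-new) lesions
    has_new_lesion: bool
    mad_percent_change: float | None
    lesion_calls: tuple[LesionCall, ...] = field(default=(), compare=False)


def classify_lesion(r: LesionRecord) -> LesionCall:
    """Categorize one lesion from its percent diameter change."""
    if r.is_new:
        return LesionCall(LesionCategory.NEW_LESION, None)
    change = 100.0 * (r.followup_diameter - r.baseline_diameter) / r.baseline_diameter
    if change <= RESPONSE_THRESHOLD:
        cat = LesionCategory.RESPONSE
    elif change >= PROGRESSION_THRESHOLD:
        cat = LesionCategory.PROGRESSION
    else:
        cat = LesionCategory.STABLE
    return LesionCall(cat, change)


def classify_patient(records: Sequence[LesionRecord]) -> PatientAssessment:
    """Classify one patient from all of their lesions at one assessment."""
    if not records:
        raise ValueError("no lesion records supplied")
    pids = {r.patient_id for r in records}
    if len(pids) > 1:
        raise ValueError(f"records span multiple patients: {sorted(pids)}")
    calls = tuple(classify_lesion(r) for r in records)
    measurable = [c for c in calls if c.category is not LesionCategory.NEW_LESION]
    has_new = len(measurable) < len(calls)
    changes = [c.percent_change for c in measurable]
    mad = median_abs_deviation(changes) if changes else None
    if len(measurable) < 2:
        category = PatientCategory.NOT_EVALUABLE
    elif any(c.category is LesionCategory.RESPONSE for c in measurable):
        progressing = any(c.category is LesionCategory.PROGRESSION for c in measurable)
        if progressing or has_new:
            category = PatientCategory.MIXED_RESPONSE
        else:
            category = PatientCategory.HOMOGENEOUS_RESPONSE
    else:
        category = PatientCategory.NON_RESPONDER
    return PatientAssessment(
        patient_id=records[0].patient_id,
        category=category,
        n_lesions=len(measurable),
        has_new_lesion=has_new,
        mad_percent_change=mad,
        lesion_calls=calls,
    )


def patient_mad(records: Sequence[LesionRecord]) -> float:
    """MAD of per-lesion percent changes; new lesions have no defined change."""
    changes = [
        classify_lesion(r).percent_change for r in records if not r.is_new
    ]
    if not changes:
        raise ValueError("no measurable lesions: MAD undefined")
    return median_abs_deviation(changes)


def recist_sum_category(records: Sequence[LesionRecord]) -> str:
    """RECIST-style category from the change in summed diameters.

    PR at <= -30% sum change; PD at >= +20% or on any new lesion; SD
    otherwise.  Returns one of "PR", "SD", "PD".
    """
    baseline = [r for r in records if not r.is_new]
    if not baseline:
        raise ValueError("RECIST sum requires at least one baseline-measurable lesion")
    if any(r.is_new for r in records):
        return "PD"
    s0 = sum(r.baseline_diameter for r in baseline)
    s1 = sum(r.followup_diameter for r in baseline)
    change = 100.0 * (s1 - s0) / s0
    if change <= -30.0:
        return "PR"
    if change >= 20.0:
        return "PD"
    return "SD"


def records_from_table(table: pd.DataFrame) -> dict[str, list[LesionRecord]]:
    """Build per-patient lesion records from a long lesion table.

    Expects columns patient_id, lesion_id, timepoint, diameter_mm, is_new
    with timepoints "baseline" and "followup"; a lesion present only at
    follow-up (or flagged is_new) is treated as new.
    """
    records: dict[str, list[LesionRecord]] = {}
    for (pid, lid), grp in table.groupby(["patient_id", "lesion_id"], sort=True):
        by_tp = grp.set_index("timepoint")
        is_new = bool(grp["is_new"].any()) if "is_new" in grp else False
        base = float(by_tp["diameter_mm"].get("baseline", 0.0))
        follow = float(by_tp["diameter_mm"].get("followup", np.nan))
        if not np.isfinite(follow):
            raise ValueError(f"lesion {pid}/{lid} has no follow-up measurement")
        if base == 0.0:
            is_new = True
        records.setdefault(str(pid), []).append(
            LesionRecord(str(pid), str(lid), base, follow, is_new=is_new)
        )
    return records


def cohort_summary(
    assessments: Mapping[str, Iterable[PatientAssessment]],
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Summarize per-group response categories and compare groups.

    ``assessments`` maps group label -> patient assessments.  For every
    group pair, mixed-vs-homogeneous and new-lesion proportions among
    responders are compared with Fisher's exact test, and per-patient MADs
    with a two-sided Mann-Whitney U test.
    """
    groups: dict[str, list[PatientAssessment]] = {}
    for label, items in assessments.items():
        evaluable = [
            a for a in items if a.category is not PatientCategory.NOT_EVALUABLE
        ]
        if not evaluable:
            warnings.warn(f"group {label!r} has no evaluable patients; excluded",
                          stacklevel=2)
            continue
        groups[label] = evaluable
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with evaluable patients")

    rows = []
    for label, items in groups.items():
        n_mixed = sum(a.category is PatientCategory.MIXED_RESPONSE for a in items)
        n_homog = sum(
            a.category is PatientCategory.HOMOGENEOUS_RESPONSE for a in items
        )
        rows.append({
            "group": label,
            "n_evaluable": len(items),
            "n_responders": n_mixed + n_homog,
            "n_mixed": n_mixed,
            "n_homogeneous": n_homog,
            "n_new_lesion": sum(a.has_new_lesion for a in items),
            "median_mad": float(np.median([
                a.mad_percent_change for a in items
                if a.mad_percent_change is not None
            ])),
        })
    summary = pd.DataFrame(rows).set_index("group")

    tests: dict[str, TestResult] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        s1, s2 = summary.loc[g1], summary.loc[g2]
        tests[f"mixed:{g1}|{g2}"] = fisher_exact_two_sided(ContingencyTable2x2(
            int(s1.n_mixed), int(s1.n_homogeneous),
            int(s2.n_mixed), int(s2.n_homogeneous),
        ))
        tests[f"new_lesion:{g1}|{g2}"] = fisher_exact_two_sided(ContingencyTable2x2(
            int(s1.n_new_lesion), int(s1.n_evaluable - s1.n_new_lesion),
            int(s2.n_new_lesion), int(s2.n_evaluable - s2.n_new_lesion),
        ))
        mads1 = [a.mad_percent_change for a in groups[g1]
                 if a.mad_percent_change is not None]
        mads2 = [a.mad_percent_change for a in groups[g2]
                 if a.mad_percent_change is not None]
        tests[f"mad:{g1}|{g2}"] = mann_whitney_u(mads1, mads2)
    return summary, tests
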