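"""Dual-layered cohort selection, analysis windows and risk-factor extraction.

Case/control assignment requires agreement between coded encounters and the
note text: a JIA patient needs at least one JIA billing code *and* an
affirmative diagnosis-confirmation mention; a chronic-uveitis case
additionally needs a chronic-uveitis code (364.1x) *and* an affirmative
uveitis mention.  Patients whose only uveitis codes are acute (364.0x) are
excluded, as are patients under the note-count floor that balances
documentation depth between the cohorts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import CodedEncounter, PatientFeatureMatrix
from .lexicon import CodeSet, Lexicon, code_matches

DAYS_PER_YEAR = 365.25
SIX_MONTHS_DAYS = 183


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class CohortAssignment:
    patient_id: str
    status: str  # 'case' | 'control' | 'excluded'
    exclusion_reason: str  # 'acute_only' | 'too_few_notes' | 'no_text_confirmation' | 'over_age' | 'none'
    arthritis_date: dt.date
    uveitis_date: dt.date | None
    note_count: int


@dataclass(frozen=True)
class AnalysisWindow:
    """Last date from which a patient's notes contribute text features.

    Cases: the day before the first chronic-uveitis code; controls: the
    arthritis date plus the median case delay, so both cohorts contribute
    comparable spans of pre-outcome documentation.
    """

    patient_id: str
    window_end: dt.date


@dataclass(frozen=True)
class RiskFactorVector:
    patient_id: str
    ana_positive: bool
    rf_positive: bool
    oligoarticular_onset: bool
    psoriasis_self_or_family: bool
    allergy_terms: bool
    allergy_drug_any: bool
    sinusitis: bool
    age_at_diagnosis: float
    gender: str
    race: str


def _first_coded_date(codes: Sequence[CodedEncounter], code_set: CodeSet) -> dt.date | None:
    dates = [e.date for e in codes if code_matches(e.icd9, code_set)]
    return min(dates) if dates else None


def select_cohorts(encounters: Sequence[CodedEncounter],
                   matrix: PatientFeatureMatrix,
                   demographics: pd.DataFrame,
                   note_counts: Mapping[str, int],
                   code_sets: Mapping[str, CodeSet],
                   min_notes: int = 25,
                   max_age: float = 16.0) -> list[CohortAssignment]:
    """Assign case / control / excluded status to every JIA-coded patient.

    ``demographics`` needs columns ``patient_id, gender, race, birth_date``.
    Raises :class:`CohortError` for a coded patient with no demographics row.
    """
    demo = demographics.set_index("patient_id")
    by_patient: dict[str, list[CodedEncounter]] = {}
    for e in encounters:
        by_patient.setdefault(e.patient_id, []).append(e)

    jia_set = code_sets["jia"]
    acute_set = code_sets["uveitis_acute"]
    chronic_set = code_sets["uveitis_chronic"]

    out = []
    for pid in sorted(by_patient):
        encs = by_patient[pid]
        arthritis_date = _first_coded_date(encs, jia_set)
        if arthritis_date is None:
            continue  # not a JIA-coded patient
        if pid not in demo.index:
            raise CohortError(f"patient {pid} has coded encounters but no demographics")
        birth = demo.loc[pid, "birth_date"]
        if isinstance(birth, str):
            birth = dt.date.fromisoformat(birth)
        age = (arthritis_date - birth).days / DAYS_PER_YEAR
        n_notes = int(note_counts.get(pid, 0))
        chronic_date = _first_coded_date(encs, chronic_set)
        acute_date = _first_coded_date(encs, acute_set)

        def assign(status, reason, uv=None):
            out.append(CohortAssignment(pid, status, reason, arthritis_date, uv, n_notes))

        if age >= max_age:
            assign("excluded", "over_age")
            continue
        if not matrix.has_affirmative(pid, "jia"):
            assign("excluded", "no_text_confirmation")
            continue
        if chronic_date is not None:
            if matrix.has_affirmative(pid, "uveitis"):
                if n_notes < min_notes:
                    assign("excluded", "too_few_notes", chronic_date)
                else:
                    assign("case", "none", chronic_date)
            else:
                assign("excluded", "no_text_confirmation", chronic_date)
            continue
        if acute_date is not None:
            assign("excluded", "acute_only")
            continue
        if n_notes < min_notes:
            assign("excluded", "too_few_notes")
            continue
        assign("control", "none")
    return out


def compute_median_offset(assignments: Sequence[CohortAssignment]) -> float:
    """Median days from first arthritis code to first chronic-uveitis code."""
    offsets = [(a.uveitis_date - a.arthritis_date).days
               for a in assignments if a.status == "case"]
    if not offsets:
        raise CohortError("no cases; median offset undefined")
    return float(np.median(offsets))


def build_windows(assignments: Sequence[CohortAssignment],
                  median_offset: float) -> list[AnalysisWindow]:
    """Pre-outcome extraction windows for analyzed (case/control) patients."""
    if median_offset < 0:
        raise CohortError("median offset must be non-negative")
    days = int(round(median_offset))
    out = []
    for a in assignments:
        if a.status == "case":
            out.append(AnalysisWindow(a.patient_id, a.uveitis_date - dt.timedelta(days=1)))
        elif a.status == "control":
            out.append(AnalysisWindow(a.patient_id, a.arthritis_date + dt.timedelta(days=days)))
    return out


def extract_risk_factors(assignment: CohortAssignment,
                         matrix: PatientFeatureMatrix,
                         lexicon: Lexicon,
                         demographics: pd.DataFrame,
                         six_month_days: int = SIX_MONTHS_DAYS,
                         window_restrict_all: bool = False,
                         window: AnalysisWindow | None = None) -> RiskFactorVector:
    """One analyzed patient's factor booleans and adjustment covariates.

    Factor booleans derive from the presence of a first affirmative mention;
    psoriasis also counts a family-attributed mention.  Diphenhydramine
    contributes to ``allergy_drug_any`` only when first mentioned strictly
    before the case's uveitis date (it is given prophylactically with
    biologics used to treat uveitis, so later mentions are confounded); other
    drugs count regardless of date.  ``window_restrict_all`` is a sensitivity
    switch restricting every factor to the analysis window.
    """
    if assignment.status not in ("case", "control"):
        raise CohortError(f"cannot extract factors for excluded patient {assignment.patient_id}")
    pid = assignment.patient_id
    demo = demographics.set_index("patient_id")
    row = demo.loc[pid]
    birth = row["birth_date"]
    if isinstance(birth, str):
        birth = dt.date.fromisoformat(birth)
    cutoff = window.window_end if (window_restrict_all and window is not None) else None

    def present(concept: str) -> bool:
        d = matrix.affirmative_date(pid, concept)
        if d is None:
            return False
        return cutoff is None or d <= cutoff

    oligo_date = matrix.affirmative_date(pid, "oligoarticular")
    oligo = (oligo_date is not None
             and oligo_date <= assignment.arthritis_date + dt.timedelta(days=six_month_days)
             and (cutoff is None or oligo_date <= cutoff))

    pso_family = matrix.family_date(pid, "psoriasis")
    psoriasis = present("psoriasis") or (
        pso_family is not None and (cutoff is None or pso_family <= cutoff))

    drug_any = False
    for generic in lexicon.drug_concepts():
        d = matrix.affirmative_date(pid, generic)
        if d is None:
            continue
        if cutoff is not None and d > cutoff:
            continue
        if (generic == "diphenhydramine" and assignment.status == "case"
                and assignment.uveitis_date is not None and d >= assignment.uveitis_date):
            continue
        drug_any = True
        break

    return RiskFactorVector(
        patient_id=pid,
        ana_positive=present("ana_positive"),
        rf_positive=present("rf_positive"),
        oligoarticular_onset=oligo,
        psoriasis_self_or_family=psoriasis,
        allergy_terms=present("allergy_terms"),
        allergy_drug_any=drug_any,
        sinusitis=present("sinusitis"),
        age_at_diagnosis=(assignment.arthritis_date - birth).days / DAYS_PER_YEAR,
        gender=str(row["gender"]),
        race=str(row["race"]),
    )


def factors_frame(assignments: Sequence[CohortAssignment],
                  matrix: PatientFeatureMatrix,
                  lexicon: Lexicon,
                  demographics: pd.DataFrame,
                  windows: Sequence[AnalysisWindow] | None = None,
                  **kwargs) -> pd.DataFrame:
    """Risk-factor table over all analyzed patients (one row each), with a
    0/1 ``case`` column."""
    win_by_pid = {w.patient_id: w for w in (windows or [])}
    rows = []
    for a in assignments:
        if a.status not in ("case", "control"):
            continue
        v = extract_risk_factors(a, matrix, lexicon, demographics,
                                 window=win_by_pid.get(a.patient_id), **kwargs)
        rows.append({
            "patient_id": v.patient_id,
            "case": int(a.status == "case"),
            "ana_positive": int(v.ana_positive),
            "oligoarticular": int(v.oligoarticular_onset),
            "psoriasis": int(v.psoriasis_self_or_family),
            "rf_positive": int(v.rf_positive),
            "allergy_terms": int(v.allergy_terms),
            "allergy_drug": int(v.allergy_drug_any),
            "sinusitis": int(v.sinusitis),
            "age": v.age_at_diagnosis,
            "gender": v.gender,
            "race": v.race,
        })
    return pd.DataFrame(rows)


def assignments_frame(assignments: Sequence[CohortAssignment]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "patient_id": a.patient_id,
            "status": a.status,
            "exclusion_reason": a.exclusion_reason,
            "arthritis_date": a.arthritis_date.isoformat(),
            "uveitis_date": a.uveitis_date.isoformat() if a.uveitis_date else "",
            "note_count": a.note_count,
        }
        for a in assignments
    ])
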