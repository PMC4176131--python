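"""Shared fixtures: the default study corpus (generated once per session)
and a scaled-down corpus for cheap unit tests."""

from __future__ import annotations

import pandas as pd
import pytest

import uveprof as uv


def _process(gen_config: uv.GeneratorConfig) -> dict:
    """Generate a corpus and run it through annotation + cohort selection."""
    notes, encounters, truth = uv.generate_fixture(gen_config)
    lexicon = uv.load_lexicon()
    mentions = uv.annotate_corpus(notes, lexicon)
    matrix = uv.build_matrix(mentions, sorted(truth.patients))
    demographics = pd.DataFrame([
        {"patient_id": p.patient_id, "gender": p.gender, "race": p.race,
         "birth_date": p.birth_date}
        for p in truth.patients.values()
    ])
    note_counts = {p.patient_id: p.note_count for p in truth.patients.values()}
    assignments = uv.select_cohorts(encounters, matrix, demographics,
                                    note_counts, lexicon.code_sets)
    median = uv.compute_median_offset(assignments)
    windows = uv.build_windows(assignments, median)
    factors = uv.factors_frame(assignments, matrix, lexicon, demographics, windows)
    return {
        "config": gen_config,
        "notes": notes,
        "encounters": encounters,
        "truth": truth,
        "lexicon": lexicon,
        "mentions": mentions,
        "matrix": matrix,
        "demographics": demographics,
        "note_counts": note_counts,
        "assignments": assignments,
        "median_offset": median,
        "windows": windows,
        "factors": factors,
    }


@pytest.fixture(scope="session")
def lexicon() -> uv.Lexicon:
    return uv.load_lexicon()


@pytest.fixture(scope="session")
def study() -> dict:
    """The default packaged fixture, fully processed (602 patients)."""
    return _process(uv.GeneratorConfig())


def small_generator_config(seed: int = 42, **overrides) -> uv.GeneratorConfig:
    """A 32-patient corpus with the same structure as the default fixture."""
    kwargs = dict(
        seed=seed,
        n_uveitis_confirmed=6,
        n_acute_only=1,
        n_controls_eligible=20,
        n_controls_fewnotes=5,
        gender_margins={"case": {"Female": 4, "Male": 2},
                        "control": {"Female": 13, "Male": 7}},
        race_margins={"case": {"Asian": 1, "Black": 0, "Other": 1, "White": 4},
                      "control": {"Asian": 2, "Black": 1, "Other": 3, "White": 14}},
        exposure_counts={
            "ana_positive": (3, 4),
            "oligoarticular": (3, 5),
            "psoriasis": (2, 2),
            "rf_positive": (0, 2),
            "allergy_terms": (3, 6),
            "allergy_drug": (4, 7),
            "sinusitis": (1, 3),
        },
        n_benadryl_decoy_cases=1,
    )
    kwargs.update(overrides)
    return uv.GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_study() -> dict:
    return _process(small_generator_config())
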