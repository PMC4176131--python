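"""End-to-end orchestration: generate → annotate → select → associate → cluster.

Each stage writes its product as a plain-text table next to the others, and
``run_pipeline`` glues them together deterministically: identical config and
seed give byte-identical output bundles.  Stage failures abort with a
stage-named :class:`PipelineError` after removing partial outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import cluster as clu
from . import cohort as coh
from . import stats as st
from . import synthetic_ehr as gen
from .lexicon import load_lexicon, excluded_cluster_concepts

log = logging.getLogger("uveprof")

FORCED_COVARIATES = ["age", "gender", "race"]
CANDIDATE_FACTORS = ["ana_positive", "oligoarticular", "psoriasis", "rf_positive",
                     "allergy_terms", "allergy_drug", "sinusitis"]

BUNDLE_FILES = ("cohort.tsv", "factors.tsv", "bivariate.tsv", "multivariate.tsv",
                "dendrogram.nwk", "main_cluster.tsv", "influence.tsv",
                "report.md", "resolved_config.yaml")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run settings; defaults reproduce the documented study protocol."""

    out_dir: str = "uveprof_out"
    input_dir: str | None = None  # read notes/encounters from here instead of generating
    lexicon_path: str | None = None
    seed: int = 2013
    min_notes: int = 25
    max_age_years: float = 16.0
    six_month_days: int = 183
    stepwise_criterion: str = "aic"
    linkage: str = "complete"
    window_restrict_all_factors: bool = False  # sensitivity switch
    exclude_allergy_drug: bool = False  # offer terms without the drug variable
    residual_signal: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt_s = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", stage, dt_s)
            else:
                log.error("stage %s: failed after %.2fs: %s", stage, dt_s, exc)
            return False

    return _Ctx()


def _demographics_frame(truth: gen.GroundTruth) -> pd.DataFrame:
    return pd.DataFrame([
        {"patient_id": p.patient_id, "gender": p.gender, "race": p.race,
         "birth_date": p.birth_date}
        for p in truth.patients.values()
    ])


def run_pipeline(config: PipelineConfig,
                 generator_config: gen.GeneratorConfig | None = None) -> dict:
    """Run every stage and write the report bundle; returns the in-memory bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, text: str) -> None:
        p = out / name
        p.write_text(text, encoding="utf-8")
        written.append(p)

    def emit_frame(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)

    try:
        stage = "generate"
        with _timed(stage):
            lexicon = load_lexicon(config.lexicon_path)
            if config.input_dir is not None:
                notes, encounters = gen.read_ehr(config.input_dir)
                truth = gen.read_truth(config.input_dir)
            else:
                gcfg = generator_config or gen.GeneratorConfig(seed=config.seed)
                gcfg.residual_signal = config.residual_signal
                notes, encounters, truth = gen.generate_fixture(gcfg)
            demographics = _demographics_frame(truth)
            note_counts = {p.patient_id: p.note_count for p in truth.patients.values()}

        stage = "annotate"
        with _timed(stage):
            mentions = ann.annotate_corpus(notes, lexicon)
            matrix = ann.build_matrix(mentions, sorted(truth.patients))

        stage = "select"
        with _timed(stage):
            assignments = coh.select_cohorts(
                encounters, matrix, demographics, note_counts,
                lexicon.code_sets, min_notes=config.min_notes,
                max_age=config.max_age_years)
            median_offset = coh.compute_median_offset(assignments)
            windows = coh.build_windows(assignments, median_offset)
            factors = coh.factors_frame(
                assignments, matrix, lexicon, demographics, windows,
                six_month_days=config.six_month_days,
                window_restrict_all=config.window_restrict_all_factors)

        stage = "associate"
        with _timed(stage):
            bivariate = st.bivariate_associations(factors, CANDIDATE_FACTORS)
            candidates = [f for f in CANDIDATE_FACTORS
                          if not (config.exclude_allergy_drug and f == "allergy_drug")]
            final = st.stepwise_select(candidates, FORCED_COVARIATES, factors)
            multivariate = _multivariate_frame(final, candidates, factors)
            gender_p = st.fisher_exact_2x2(_gender_table(factors))
            race_p = st.fisher_exact_rxc(_race_table(factors))
            age_p = st.welch_t_test(factors.loc[factors["case"] == 1, "age"],
                                    factors.loc[factors["case"] == 0, "age"])

        stage = "cluster"
        with _timed(stage):
            bmat = clu.build_binary_matrix(matrix, windows,
                                           excluded_cluster_concepts(lexicon))
            dist = clu.euclidean_distances(bmat)
            dendro = clu.agglomerate(dist, linkage=config.linkage,
                                     leaf_ids=bmat.patients)
            labels = {a.patient_id: a.status for a in assignments
                      if a.status in ("case", "control")}
            members, n_case_in, n_ctrl_in, cluster_p = clu.find_main_cluster(dendro, labels)
            _, cluster_perm_p = clu.main_cluster_permutation_p(
                dendro, labels, seed=config.seed)
            influence = clu.feature_influence(bmat, members)
            newick = clu.export_newick(dendro, labels)

        stage = "report"
        with _timed(stage):
            emit_frame("cohort.tsv", coh.assignments_frame(assignments))
            emit_frame("factors.tsv", factors)
            emit_frame("bivariate.tsv", bivariate)
            emit_frame("multivariate.tsv", multivariate)
            emit("dendrogram.nwk", newick + "\n")
            emit_frame("main_cluster.tsv", pd.DataFrame([
                {"patient_id": pid, "label": labels[pid],
                 "in_main_cluster": int(pid in members)}
                for pid in bmat.patients
            ]))
            emit_frame("influence.tsv", influence)
            emit("resolved_config.yaml", yaml.safe_dump(asdict(config), sort_keys=True))
            bundle = {
                "assignments": assignments,
                "median_offset": median_offset,
                "factors": factors,
                "bivariate": bivariate,
                "multivariate": multivariate,
                "final_fit": final,
                "gender_p": gender_p, "race_p": race_p, "age_p": age_p,
                "main_cluster": members,
                "main_cluster_composition": (n_case_in, n_ctrl_in),
                "main_cluster_p": cluster_p,
                "main_cluster_perm_p": cluster_perm_p,
                "influence": influence,
                "newick": newick,
                "truth": truth,
                "out_dir": out,
            }
            emit("report.md", make_report(bundle))
        return bundle
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def _gender_table(factors: pd.DataFrame):
    g = factors.groupby(["gender", "case"]).size().unstack(fill_value=0)
    return [[int(g.loc["Female", 0]), int(g.loc["Female", 1])],
            [int(g.loc["Male", 0]), int(g.loc["Male", 1])]]


def _race_table(factors: pd.DataFrame):
    r = factors.groupby(["race", "case"]).size().unstack(fill_value=0)
    r = r.reindex(sorted(r.index), fill_value=0)
    return [[int(r.loc[lvl, 0]), int(r.loc[lvl, 1])] for lvl in r.index]


def _multivariate_frame(fit: st.LogisticFit, candidates: list[str],
                        factors: pd.DataFrame) -> pd.DataFrame:
    rows = []
    in_final = set(fit.terms)
    for term in fit.terms:
        if term == "intercept":
            continue
        or_, lo, hi = fit.adjusted_or(term)
        rows.append({"term": term, "coefficient": fit.coef(term),
                     "se": fit.se(term), "adjusted_or": or_,
                     "ci_low": lo, "ci_high": hi, "p": fit.wald_p(term),
                     "in_final_model": 1})
    for cand in candidates:
        if cand not in in_final:
            rows.append({"term": cand, "coefficient": float("nan"),
                         "se": float("nan"), "adjusted_or": float("nan"),
                         "ci_low": float("nan"), "ci_high": float("nan"),
                         "p": float("nan"), "in_final_model": 0})
    return pd.DataFrame(rows)


def make_report(bundle: dict) -> str:
    """Human-readable summary; every number is copied from a bundle table."""
    a = bundle["assignments"]
    n_case = sum(1 for x in a if x.status == "case")
    n_ctrl = sum(1 for x in a if x.status == "control")
    excl = {}
    for x in a:
        if x.status == "excluded":
            excl[x.exclusion_reason] = excl.get(x.exclusion_reason, 0) + 1
    n_case_in, n_ctrl_in = bundle["main_cluster_composition"]
    lines = [
        "# JIA / chronic-uveitis risk-factor profile",
        "",
        "## Cohort",
        f"- cases (chronic uveitis): {n_case}",
        f"- controls: {n_ctrl}",
    ]
    for reason in sorted(excl):
        lines.append(f"- excluded ({reason}): {excl[reason]}")
    lines += [
        f"- median arthritis-to-uveitis delay: {bundle['median_offset']:.0f} days",
        "",
        "## Demographic balance",
        f"- gender Fisher p: {bundle['gender_p']:.3f}",
        f"- race Fisher p: {bundle['race_p']:.3f}",
        f"- age Welch p: {bundle['age_p']:.2e}",
        "",
        "## Bivariate associations (factor, OR, 95% CI, Fisher p)",
    ]
    for _, r in bundle["bivariate"].iterrows():
        lines.append(f"- {r['factor']}: OR {r['odds_ratio']:.2f} "
                     f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.4g}")
    lines += ["", "## Adjusted model (stepwise AIC; age, gender, race forced)"]
    for _, r in bundle["multivariate"].iterrows():
        if r["in_final_model"] == 1:
            lines.append(f"- {r['term']}: adjusted OR {r['adjusted_or']:.2f} "
                         f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), p={r['p']:.4g}")
        else:
            lines.append(f"- {r['term']}: eliminated by stepwise selection")
    lines += [
        "",
        "## Residual-feature clustering",
        f"- main cluster: {n_case_in} cases / {n_ctrl_in} controls "
        f"(enrichment p={bundle['main_cluster_p']:.3g}, "
        f"permutation-calibrated p={bundle['main_cluster_perm_p']:.3g})",
        "- most influential concepts:",
    ]
    for _, r in bundle["influence"].head(5).iterrows():
        lines.append(f"  - {r['concept']}: p={r['p']:.3g}")
    return "\n".join(lines) + "\n"
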