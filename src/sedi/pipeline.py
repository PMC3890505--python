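"""End-to-end pipeline: read → exclude → score → cutoffs → classify →
stats → report, with a run-id, config hash and artefact manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import ExclusionPolicy, apply_exclusions, compute_age, read_roster
from .instrument import DOMAINS, default_registry, load_registry
from .reporting import MIN_CELL_DEFAULT, build_report
from .scoring import score_cohort, scores_frame
from .stats import adjusted_odds_ratio, chi_square, cronbach_alpha, oneway_anova
from .vulnerability import (
    CutoffSet,
    classify_cohort,
    compute_cutoffs,
    profiles_frame,
    summarize_vulnerability,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("sedi")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    roster_path: str
    out_dir: str
    registry_path: str | None = None
    cutoff_mode: str = "compute"  # "compute" or a path to a cutoffs JSON
    band_convention: str = "strict-below"
    min_cell: int = MIN_CELL_DEFAULT
    seed: int = 0
    strict: bool = True
    exclusion_policy: ExclusionPolicy = field(default_factory=ExclusionPolicy)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["exclusion_policy"] = dataclasses.asdict(self.exclusion_policy)
        text = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(name, str(err)) from err
        return wrapper
    return deco


def _stats_block(analysed, frame, prof_frame, reg):
    """Standard inference battery on the analysed cohort (pairwise deletion).

    Reliability (overall and per domain), quintile ANOVA per domain,
    age-adjusted gender odds ratios for >=1/>=2-domain vulnerability,
    age+gender-adjusted quintile odds ratios (single five-level model,
    most-affluent quintile as reference), a first-language contrast, and
    chi-square associations for the four teacher indicators.
    """
    item_scores = {}
    from .scoring import convert_item_response

    for it in reg.scored_items:
        col = []
        for rec in analysed:
            raw = rec.responses.get(it.item_id)
            col.append(float("nan") if raw is None
                       else convert_item_response(it, raw))
        item_scores[it.item_id] = col
    items_df = pd.DataFrame(item_scores, index=frame.index)

    reliability = {}
    overall = cronbach_alpha(items_df, scale="overall")
    reliability["overall"] = {"k": overall.k, "n": overall.n_used,
                              "alpha": overall.alpha,
                              "low_items": overall.low_items}
    for d in DOMAINS:
        cols = [it.item_id for it in reg.domain_items(d)]
        r = cronbach_alpha(items_df[cols], scale=d)
        reliability[d] = {"k": r.k, "n": r.n_used, "alpha": r.alpha,
                          "low_items": r.low_items}

    meta = pd.DataFrame({
        "gender": [r.gender for r in analysed],
        "quintile": [r.simd_quintile for r in analysed],
        "age": [compute_age(r) for r in analysed],
        "lang_ok": [r.first_language_ok for r in analysed],
        **{c: [bool(r.indicators.get(c)) for r in analysed]
           for c in analysed[0].indicators},
    }, index=frame.index)

    anova = {}
    for d in DOMAINS:
        res = oneway_anova(frame[d], meta["quintile"])
        anova[d] = {"F": res.F, "df": [res.df_between, res.df_within],
                    "p": res.p_value, "n": res.n_used}

    inference = {"anova_by_quintile": anova, "odds_ratios": [], "chi_square": {}}

    def add_or(label, outcome_col, mask, exposure, reference, covars):
        sub = meta[mask]
        out = prof_frame.loc[sub.index, outcome_col].astype(float)
        exp_ser = sub[exposure]
        if pd.api.types.is_numeric_dtype(exp_ser) or exp_ser.dtype == bool:
            exp_ser = exp_ser.astype(float).astype(int)
            reference = int(float(reference))
        results = adjusted_odds_ratio(out, exp_ser.astype(str),
                                      str(reference), covars(sub))
        for r in results:
            inference["odds_ratios"].append({
                "analysis": label, "contrast": r.contrast,
                "or": r.odds_ratio, "ci": [r.ci_low, r.ci_high],
                "adjusted_for": list(r.adjusted_for), "n": r.n_used,
                "estimable": r.estimable,
            })

    recorded = meta["gender"].isin(["male", "female"])
    add_or("ge1 by gender (age-adjusted)", "vulnerable_ge1", recorded,
           "gender", "female", lambda s: s[["age"]])
    add_or("ge2 by gender (age-adjusted)", "vulnerable_ge2", recorded,
           "gender", "female", lambda s: s[["age"]])
    has_q = meta["quintile"].notna() & recorded
    add_or("ge1 by quintile (age+gender-adjusted)", "vulnerable_ge1", has_q,
           "quintile", 5, lambda s: s[["age", "gender"]])
    add_or("ge2 by quintile (age+gender-adjusted)", "vulnerable_ge2", has_q,
           "quintile", 5, lambda s: s[["age", "gender"]])
    has_lang = meta["lang_ok"].notna() & recorded
    if meta.loc[has_lang, "lang_ok"].nunique() == 2:
        add_or("ge2 by first-language adequacy (age+gender-adjusted)",
               "vulnerable_ge2", has_lang, "lang_ok", True,
               lambda s: s[["age", "gender"]])

    for c in analysed[0].indicators:
        tab = pd.crosstab(meta[c], prof_frame["vulnerable_ge1"])
        if tab.shape == (2, 2):
            r = chi_square(tab.to_numpy())
            inference["chi_square"][c] = {"statistic": r.statistic,
                                          "df": r.df, "p": r.p_value}
    return reliability, inference


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and write all artefacts.

    Returns the manifest (also written to ``manifest.json``).  Any stage
    error is re-raised as :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_id = cfg.config_hash()
    log.info("run %s: starting", run_id)

    reg = _stage("load_registry")(
        lambda: load_registry(Path(cfg.registry_path).read_text(),
                              strict=cfg.strict)
        if cfg.registry_path else default_registry()
    )()

    parsed = _stage("read_roster")(read_roster)(cfg.roster_path, reg)
    if cfg.strict and parsed.issues:
        raise PipelineError("read_roster",
                            f"{len(parsed.issues)} parse issues in strict mode;"
                            f" first: {parsed.issues[0]}")

    analysed, excl_log = _stage("apply_exclusions")(apply_exclusions)(
        parsed.records, reg, cfg.exclusion_policy)
    if not analysed:
        raise PipelineError("apply_exclusions", "empty analysed cohort")

    scored = _stage("score_domains")(score_cohort)(analysed, reg)
    frame = scores_frame(scored)

    if cfg.cutoff_mode == "compute":
        cuts = _stage("compute_cutoffs")(compute_cutoffs)(scored)
    else:
        cuts = _stage("load_cutoffs")(
            lambda: CutoffSet.from_json(Path(cfg.cutoff_mode).read_text()))()
    cuts.run_id = run_id

    profiles = _stage("classify")(classify_cohort)(
        scored, cuts, cfg.band_convention)
    prof_frame = profiles_frame(profiles)

    gender_map = {r.pupil_id: r.gender for r in analysed
                  if r.gender != "unrecorded"}
    quint_map = {r.pupil_id: int(r.simd_quintile) for r in analysed
                 if r.simd_quintile is not None}
    summaries = {
        "overall": summarize_vulnerability(profiles),
        "gender": summarize_vulnerability(profiles, gender_map),
        "quintile": summarize_vulnerability(profiles, quint_map),
    }
    for s in summaries.values():
        s.run_id = run_id

    reliability, inference = _stage("stats")(_stats_block)(
        analysed, frame, prof_frame, reg)

    report = _stage("build_report")(build_report)(
        scored, cuts, summaries,
        strata_maps={"gender": gender_map, "quintile": quint_map},
        reliability=reliability, inference=inference,
        exclusion_summary=json.loads(excl_log.to_json()),
        min_cell=cfg.min_cell,
    )
    report.run_id = run_id

    artefacts = {
        "exclusion_log.csv": excl_log.to_csv(),
        "exclusion_summary.json": excl_log.to_json(),
        "scored_cohort.csv": frame.to_csv(),
        "cutoffs.json": cuts.to_json(),
        "classification.csv": prof_frame.to_csv(),
        "report.json": report.to_json(),
        "domain_summary.csv": report.domain_summary_csv(),
        "multi_vulnerability.csv": report.multi_vuln_csv(),
    }
    for name, summary_name in (("band_table_gender.csv", "gender"),
                               ("band_table_quintile.csv", "quintile")):
        artefacts[name] = report.band_table_csv(summary_name)
    for name, text in artefacts.items():
        (out / name).write_text(text)

    manifest = {
        "run_id": run_id,
        "version": __version__,
        "config_hash": run_id,
        "roster_n": excl_log.roster_n,
        "analysed_n": excl_log.analysed_n,
        "artefacts": sorted(artefacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    log.info("run %s: wrote %d artefacts to %s", run_id, len(artefacts), out)
    return manifest
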