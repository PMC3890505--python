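"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators live here:

* :func:`generate_cohort` — a seeded latent-variable simulator.  Each pupil
  draws five equicorrelated latent developmental abilities (multivariate
  normal, exchangeable correlation ``rho``), shifted additively by
  deprivation quintile, gender, English-as-a-second-language status and
  first-language adequacy.  Every scored item adds independent normal noise
  to its domain's latent and thresholds the result into the item's response
  categories, which yields correlated domains, socioeconomic gradients in
  domain means, tunable vulnerability odds ratios, and a realistic ceiling
  in the short communication/general-knowledge scale.  Missingness and the
  four exclusion scenarios (opt-out, short enrolment, special needs, heavy
  missingness) are overlaid at configurable rates.

* :func:`fixture_printed_marginals` — a deterministic 1,180-pupil roster
  built (no RNG) so that the default pipeline reproduces a fixed set of
  reference marginals: 18 opt-outs and 72 further exclusions leaving 1,090
  analysed pupils (524 female / 563 male / 3 unrecorded), with 193 boys,
  104 girls and 1 unrecorded-gender pupil vulnerable in at least one
  domain (298 = 27.3%) and 111 / 56 / 1 vulnerable in two or more
  (168 = 15.4%).  The construction self-verifies by running the pipeline
  before returning.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import (
    INDICATOR_COLUMNS,
    PupilRecord,
    apply_exclusions,
    read_roster,
)
from .instrument import DOMAINS, InstrumentRegistry, default_registry
from .scoring import score_cohort, token_for_score
from .vulnerability import classify_cohort, compute_cutoffs

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_domain_scores",
    "implied_vulnerability_or",
    "fixture_printed_marginals",
    "FixtureConstructionError",
]

QUINTILES = (1, 2, 3, 4, 5)


@dataclass
class SyntheticConfig:
    """Generator parameters.

    Latent scale: each domain ability is standard normal before shifts; all
    shift parameters are in latent standard-deviation units.  Default rates
    and sample size emulate a single school-district entry cohort: ~1,100
    pupils, a small most-deprived quintile (~4%), ESL prevalence ~2.4%,
    inadequate first-language communication ~0.8%, and exclusion-scenario
    rates matching 18 opt-outs / 30 short enrolments / 42 special needs per
    1,180 recruits.
    """

    n_pupils: int = 1100
    rng_seed: int = 0

    # demographics
    quintile_probs: tuple = (0.04, 0.21, 0.25, 0.25, 0.25)
    quintile_missing_rate: float = 0.0064
    male_prob: float = 0.5165
    unrecorded_gender_prob: float = 0.00275
    age_range: tuple = (4.5, 6.5)
    assessment_date: date = date(2012, 5, 15)

    # latent structure
    rho: float = 0.5  # equicorrelation between the five domain latents
    noise_sd: float = 1.1  # per-item noise on top of the domain latent
    domain_mu: dict = field(default_factory=lambda: {d: 0.0 for d in DOMAINS})

    # item thresholds (per domain), calibrated by simulation so the default
    # output has domain means in the mid-8s on the ten-point scale, SDs
    # ~1.8-1.9, and a ceiling (median = 10) in the 8-item CGK scale only
    binary_tau: dict = field(default_factory=lambda: {
        "PHWB": -2.2, "SC": -2.2, "EM": -2.2, "LC": -2.2, "CGK": -2.3,
    })
    likert_tau: dict = field(default_factory=lambda: {
        "PHWB": (-2.66, -1.46), "SC": (-2.66, -1.46), "EM": (-2.55, -1.35),
        "LC": (-2.66, -1.46), "CGK": (-2.66, -1.46),
    })

    # structured effects (latent shifts); defaults imply a boys-vs-girls
    # vulnerability odds ratio near 2.4 and a most-vs-least-deprived
    # quintile odds ratio near 3
    quintile_shifts: tuple = (-0.62, -0.48, -0.27, -0.13, 0.0)
    gender_shift: float = -0.45  # applied to boys
    esl_prevalence: float = 0.024
    esl_shift: float = -0.30
    lang_inadequate_prevalence: float = 0.008
    lang_shift: float = -1.30

    # data-quality scenarios
    item_missing_rate: float = 0.01
    optout_rate: float = 0.0153
    short_enrolment_rate: float = 0.0254
    special_needs_rate: float = 0.0356
    heavy_missingness_rate: float = 0.0

    def validate(self) -> None:
        if abs(sum(self.quintile_probs) - 1.0) > 1e-9:
            raise ValueError("quintile_probs must sum to 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1) for a positive-definite"
                             " latent covariance")
        rates = {
            "quintile_missing_rate": self.quintile_missing_rate,
            "esl_prevalence": self.esl_prevalence,
            "lang_inadequate_prevalence": self.lang_inadequate_prevalence,
            "item_missing_rate": self.item_missing_rate,
            "optout_rate": self.optout_rate,
            "short_enrolment_rate": self.short_enrolment_rate,
            "special_needs_rate": self.special_needs_rate,
            "heavy_missingness_rate": self.heavy_missingness_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total_excl = (self.optout_rate + self.short_enrolment_rate
                      + self.special_needs_rate + self.heavy_missingness_rate)
        if total_excl > 1.0:
            raise ValueError("exclusion-scenario rates sum beyond 1")

    def null(self) -> "SyntheticConfig":
        """Copy with every structured effect removed (exchangeable cohort)."""
        return dataclasses.replace(
            self,
            quintile_shifts=(0.0,) * 5,
            gender_shift=0.0,
            esl_shift=0.0,
            lang_shift=0.0,
            rho=0.0,
        )


def _quintile_shift_matrix(cfg: SyntheticConfig) -> np.ndarray:
    """(5 quintiles x 5 domains) latent shift matrix from config (the
    configured shifts may be scalar-per-quintile or fully per-domain)."""
    arr = np.asarray(cfg.quintile_shifts, dtype=float)
    if arr.ndim == 1:
        return np.repeat(arr[:, None], len(DOMAINS), axis=1)
    if arr.shape == (5, len(DOMAINS)):
        return arr
    raise ValueError("quintile_shifts must be length 5 or shape (5, 5)")


def _draw_population(cfg: SyntheticConfig, rng: np.random.Generator):
    """Demographics plus latent ability matrix ``z`` (n x 5)."""
    n = cfg.n_pupils
    u = rng.random(n)
    gender = np.where(u < cfg.unrecorded_gender_prob, "unrecorded",
                      np.where(u < cfg.unrecorded_gender_prob
                               + cfg.male_prob, "male", "female"))
    quintile = rng.choice(QUINTILES, size=n, p=cfg.quintile_probs).astype(float)
    quintile[rng.random(n) < cfg.quintile_missing_rate] = np.nan
    esl = rng.random(n) < cfg.esl_prevalence
    lang_bad = rng.random(n) < cfg.lang_inadequate_prevalence
    age = rng.uniform(*cfg.age_range, size=n)

    mu = np.array([cfg.domain_mu[d] for d in DOMAINS])
    shifts = np.tile(mu, (n, 1))
    qmat = _quintile_shift_matrix(cfg)
    has_q = ~np.isnan(quintile)
    shifts[has_q] += qmat[quintile[has_q].astype(int) - 1]
    # quintile-missing pupils get the average shift so they are typical
    shifts[~has_q] += qmat.T @ np.asarray(cfg.quintile_probs)
    shifts[gender == "male"] += cfg.gender_shift
    shifts[esl] += cfg.esl_shift
    shifts[lang_bad] += cfg.lang_shift

    common = rng.standard_normal(n)
    indiv = rng.standard_normal((n, len(DOMAINS)))
    z = shifts + math.sqrt(cfg.rho) * common[:, None] + math.sqrt(1 - cfg.rho) * indiv

    meta = pd.DataFrame({
        "gender": gender,
        "quintile": quintile,
        "esl": esl,
        "lang_inadequate": lang_bad,
        "age": age,
    })
    return meta, z


def _item_scores(cfg, rng, z, reg: InstrumentRegistry):
    """Numeric ten-point item scores (n x 103), columns ordered as
    ``reg.scored_items``.  Polarity does not enter here: these are
    development scores; reverse wording appears only at token emission."""
    n = z.shape[0]
    items = reg.scored_items
    out = np.empty((n, len(items)))
    dom_index = {d: i for i, d in enumerate(DOMAINS)}
    for j, it in enumerate(items):
        u = z[:, dom_index[it.domain]] + cfg.noise_sd * rng.standard_normal(n)
        if it.response_kind == "binary":
            out[:, j] = 10.0 * (u > cfg.binary_tau[it.domain])
        else:
            t1, t2 = cfg.likert_tau[it.domain]
            out[:, j] = 5.0 * ((u > t1).astype(int) + (u > t2).astype(int))
    return out


def generate_domain_scores(cfg: SyntheticConfig,
                           reg: InstrumentRegistry | None = None,
                           rng: np.random.Generator | None = None):
    """Fast path: (meta, domain-score frame) without building a roster.

    Uses exactly the same latent and item model as :func:`generate_cohort`;
    intended for calibration studies and Monte-Carlo tests where the CSV
    round-trip would dominate runtime.
    """
    cfg.validate()
    reg = reg or default_registry()
    rng = rng or np.random.default_rng(cfg.rng_seed)
    meta, z = _draw_population(cfg, rng)
    item = _item_scores(cfg, rng, z, reg)
    cols = {}
    items = reg.scored_items
    for d in DOMAINS:
        idx = [j for j, it in enumerate(items) if it.domain == d]
        cols[d] = item[:, idx].mean(axis=1)
    scores = pd.DataFrame(cols)
    scores.index = [f"S{i:05d}" for i in range(len(scores))]
    scores.index.name = "pupil_id"
    meta.index = scores.index
    return meta, scores


@dataclass
class SyntheticCohort:
    """Roster (CSV dialect) plus the generating truth."""

    roster: pd.DataFrame
    truth: dict

    def to_csv(self) -> str:
        return self.roster.to_csv(index=False)

    def records(self, reg: InstrumentRegistry):
        """Parse the roster through the standard reader."""
        return read_roster(self.to_csv(), reg)


def generate_cohort(cfg: SyntheticConfig,
                    reg: InstrumentRegistry | None = None) -> SyntheticCohort:
    """Generate a full roster in the standard CSV dialect.

    Reproducible: the same config (including ``rng_seed``) yields a
    byte-identical roster.  The returned truth record carries the config,
    the per-pupil latent abilities, and the drawn group labels, so
    parameter-recovery tests are self-contained.
    """
    cfg.validate()
    reg = reg or default_registry()
    rng = np.random.default_rng(cfg.rng_seed)
    meta, z = _draw_population(cfg, rng)
    item = _item_scores(cfg, rng, z, reg)
    n = cfg.n_pupils
    items = reg.scored_items

    # exclusion scenarios: at most one per pupil
    u = rng.random(n)
    edges = np.cumsum([cfg.optout_rate, cfg.short_enrolment_rate,
                       cfg.special_needs_rate, cfg.heavy_missingness_rate])
    scenario = np.select(
        [u < edges[0], u < edges[1], u < edges[2], u < edges[3]],
        ["optout", "short", "special", "heavy"], default="none",
    )

    missing = rng.random(item.shape) < cfg.item_missing_rate
    heavy_rows = scenario == "heavy"
    if heavy_rows.any():
        missing[heavy_rows] |= rng.random((heavy_rows.sum(), item.shape[1])) < 0.5

    cols: dict[str, object] = {}
    cols["pupil_id"] = [f"S{i:05d}" for i in range(n)]
    cols["gender"] = np.where(meta["gender"] == "unrecorded", "", meta["gender"])
    dob = [
        (cfg.assessment_date - timedelta(days=round(a * 365.25))).isoformat()
        for a in meta["age"]
    ]
    cols["date_of_birth"] = dob
    cols["assessment_date"] = cfg.assessment_date.isoformat()
    months = np.where(scenario == "short", "0.5", "8")
    cols["months_in_class"] = months
    cols["simd_quintile"] = [
        "" if np.isnan(q) else str(int(q)) for q in meta["quintile"]
    ]
    cols["first_language_ok"] = np.where(meta["lang_inadequate"], "no", "yes")
    cols["esl"] = np.where(meta["esl"], "yes", "no")
    cols["special_needs"] = np.where(scenario == "special", "yes", "no")
    cols["opted_out"] = np.where(scenario == "optout", "yes", "no")

    # indicator flags correlate with low latent ability
    overall = z.mean(axis=1)
    lo = np.quantile(overall, 0.25)
    struggling = overall < lo
    cols["struggles_with_schoolwork"] = np.where(struggling, "yes", "no")
    cols["needs_assessment"] = np.where(overall < np.quantile(overall, 0.10),
                                        "yes", "no")
    cols["on_waiting_list"] = np.where(overall < np.quantile(overall, 0.05),
                                       "yes", "no")
    cols["receiving_supports"] = np.where(overall < np.quantile(overall, 0.08),
                                          "yes", "no")

    for j, it in enumerate(items):
        toks = _tokens_for_item(it, item[:, j])
        toks[missing[:, j]] = ""
        cols[it.item_id] = toks

    roster = pd.DataFrame(cols)
    truth = {
        "config": dataclasses.asdict(cfg),
        "latents": z,
        "meta": meta,
        "scenario": scenario,
    }
    return SyntheticCohort(roster, truth)


def _tokens_for_item(item, scores: np.ndarray) -> np.ndarray:
    """Vectorized inverse conversion (score level -> canonical raw token)."""
    lut = {lv: token_for_score(item, lv) for lv in (0.0, 5.0, 10.0)}
    out = np.empty(scores.shape, dtype=object)
    for lv, tok in lut.items():
        out[scores == lv] = tok
    return out


def implied_vulnerability_or(cfg: SyntheticConfig, contrast: str = "gender",
                             n_ref: int = 150_000, seed: int = 12345) -> float:
    """Large-sample vulnerability odds ratio implied by a configuration.

    The latent shifts do not map to a closed-form odds ratio (vulnerability
    is defined through cohort-relative cutoffs over five correlated ordinal
    scales), so the implied value is measured on a large reference cohort
    drawn from the same model.  ``contrast``: ``"gender"`` (boys vs girls)
    or ``"q1_vs_q5"``.
    """
    big = dataclasses.replace(cfg, n_pupils=n_ref, rng_seed=seed,
                              item_missing_rate=0.0)
    meta, scores = generate_domain_scores(big)
    cuts = compute_cutoffs(scores)
    vuln = np.zeros(len(scores), dtype=bool)
    for d in DOMAINS:
        vuln |= scores[d].to_numpy() < cuts[d]["c10"]
    if contrast == "gender":
        a = (meta["gender"] == "male").to_numpy()
        b = (meta["gender"] == "female").to_numpy()
    elif contrast == "q1_vs_q5":
        a = (meta["quintile"] == 1).to_numpy()
        b = (meta["quintile"] == 5).to_numpy()
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    n11 = (vuln & a).sum()
    n10 = (~vuln & a).sum()
    n01 = (vuln & b).sum()
    n00 = (~vuln & b).sum()
    return float((n11 * n00) / (n10 * n01))


# ---------------------------------------------------------------------------
# Deterministic fixture with fixed reference marginals
# ---------------------------------------------------------------------------

class FixtureConstructionError(RuntimeError):
    """The deterministic fixture failed its own verification (bug guard)."""


# analysed-cohort composition: (gender, n with 2 vulnerable domains,
# n with exactly 1, n with 0)
_FIXTURE_GROUPS = (
    ("male", 111, 82, 370),
    ("female", 56, 48, 420),
    ("unrecorded", 1, 0, 2),
)
_FIXTURE_QUINTILE_COUNTS = {1: 44, 2: 232, 3: 269, 4: 269, 5: 269}  # + 7 missing
_ASSESS = date(2012, 5, 15)


def _level_responses(reg, levels: dict) -> dict:
    """Raw responses hitting, per domain, a target count of top-scored items.

    ``levels`` maps domain -> m; the first ``m`` items of the domain are
    answered at the top of the ten-point scale and the rest at the bottom,
    so the domain mean is ``10 m / k``.
    """
    responses = {}
    for d in DOMAINS:
        items = reg.domain_items(d)
        m = levels[d]
        for i, it in enumerate(items):
            responses[it.item_id] = token_for_score(it, 10.0 if i < m else 0.0)
    return responses


def fixture_printed_marginals(reg: InstrumentRegistry | None = None):
    """Deterministic 1,180-pupil roster with fixed reference marginals.

    Running the default pipeline on the result yields exactly:

    * 18 opt-outs, 30 short-enrolment, 42 special-needs exclusions
      (one short-enrolment pupil also has two fully missing domains, so the
      missingness rule alone never fires) — 1,090 analysed pupils;
    * analysed gender split 563 male / 524 female / 3 unrecorded;
    * vulnerable in >=1 domain: 298 pupils (193 boys, 104 girls, 1
      unrecorded), i.e. 27.3%;
    * vulnerable in >=2 domains: 168 pupils (111 boys, 56 girls, 1
      unrecorded), i.e. 15.4%;
    * a ceiling in the CGK domain (median = maximum, so no pupil lies above
      the median cutoff).

    The roster is built backwards from those targets: each pupil's
    vulnerable domains are assigned round-robin, per-domain score levels
    are chosen so the nearest-rank cutoffs land between the engineered
    blocks, and the construction re-runs the pipeline to verify every count
    before returning.  Raises :class:`FixtureConstructionError` on any
    mismatch.
    """
    reg = reg or default_registry()
    k = {d: len(reg.domain_items(d)) for d in DOMAINS}

    # per-domain score levels, expressed as number of top-scored items
    level_v = {d: 3 for d in DOMAINS}            # vulnerable block
    level_a = {d: k[d] - 4 for d in DOMAINS}     # at-risk block (= c10)
    level_b = {d: k[d] - 2 for d in DOMAINS}     # on-track-1 block (= c25)
    level_c = {d: k[d] - 1 for d in DOMAINS}     # on-track-1 block (= c50)
    level_d = {d: k[d] for d in DOMAINS}         # above-median block
    level_c["CGK"] = k["CGK"]                    # ceiling: median = max = 10

    # assign vulnerable domains: singles and pairs round-robin
    pupils = []  # (gender, tuple of vulnerable domains)
    cyc = 0
    for gender, n2, n1, n0 in _FIXTURE_GROUPS:
        for _ in range(n2):
            pair = (DOMAINS[cyc % 5], DOMAINS[(cyc + 1) % 5])
            pupils.append((gender, pair))
            cyc += 1
        for _ in range(n1):
            pupils.append((gender, (DOMAINS[cyc % 5],)))
            cyc += 1
        for _ in range(n0):
            pupils.append((gender, ()))

    n_analysed = len(pupils)
    v_counts = {d: sum(1 for _, vs in pupils if d in vs) for d in DOMAINS}

    # block quotas per domain over the analysed cohort (nearest-rank targets:
    # rank 109 -> at-risk level, rank 273 -> level_b, rank 545 -> level_c)
    quotas = {}
    for d in DOMAINS:
        n_a = 272 - v_counts[d]
        n_b = 272
        n_c = n_analysed - v_counts[d] - n_a - n_b if d == "CGK" else 356
        n_d = n_analysed - v_counts[d] - n_a - n_b - n_c
        quotas[d] = [n_a, n_b, n_c, n_d]

    levels_by_block = {
        d: [level_a[d], level_b[d], level_c[d], level_d[d]] for d in DOMAINS
    }

    # deal non-vulnerable pupils into blocks, filling quotas in order; a
    # deterministic stride decorrelates block membership across domains
    per_pupil_levels = [dict() for _ in range(n_analysed)]
    for di, d in enumerate(DOMAINS):
        order = [(i * 7 + di * 131) % n_analysed for i in range(n_analysed)]
        seen = set()
        order = [i for i in order if not (i in seen or seen.add(i))]
        remaining = list(quotas[d])
        for i in order:
            gender, vs = pupils[i]
            if d in vs:
                per_pupil_levels[i][d] = level_v[d]
                continue
            for b in range(4):
                if remaining[b] > 0:
                    remaining[b] -= 1
                    per_pupil_levels[i][d] = levels_by_block[d][b]
                    break
        if any(r != 0 for r in remaining):
            raise FixtureConstructionError(f"block quotas unfilled for {d}")

    # quintiles: 7 missing, the rest dealt by a coprime stride for mixing
    slots: list = []
    for q, cnt in _FIXTURE_QUINTILE_COUNTS.items():
        slots.extend([q] * cnt)
    quintile_of = {}
    with_quintile = [i for i in range(n_analysed) if i % 156 != 5][: len(slots)]
    no_quintile = [i for i in range(n_analysed) if i not in set(with_quintile)]
    if len(no_quintile) != 7:
        raise FixtureConstructionError("quintile-missing count != 7")
    m = len(slots)
    for j, i in enumerate(with_quintile):
        quintile_of[i] = slots[(j * 7) % m]

    records: list[PupilRecord] = []
    esl_assigned = 0
    lang_assigned = 0
    for i, (gender, vs) in enumerate(pupils):
        age = 4.6 + 1.8 * ((i * 37) % n_analysed) / (n_analysed - 1)
        if i == 0:
            age = 4.49
        elif i == 1:
            age = 6.94
        dob = _ASSESS - timedelta(days=round(age * 365.25))
        esl = False
        if esl_assigned < 26 and len(vs) == 0 and i % 40 == 3:
            esl = True
            esl_assigned += 1
        lang_ok = True
        if lang_assigned < 7 and len(vs) == 2 and i % 24 == 0:
            lang_ok = False
            lang_assigned += 1
        records.append(PupilRecord(
            pupil_id=f"F{i:04d}",
            gender=gender,
            date_of_birth=dob,
            assessment_date=_ASSESS,
            months_in_class=8.0,
            simd_quintile=quintile_of.get(i),
            first_language_ok=lang_ok,
            esl=esl,
            special_needs=False,
            opted_out=False,
            indicators={
                "struggles_with_schoolwork": len(vs) >= 1 or i % 9 == 0,
                "needs_assessment": len(vs) >= 2,
                "on_waiting_list": len(vs) >= 2 and i % 2 == 0,
                "receiving_supports": len(vs) >= 1 and i % 3 == 0,
            },
            responses=_level_responses(reg, per_pupil_levels[i]),
        ))

    # excluded pupils: 18 opt-outs (11 F / 7 M, one also short-enrolled),
    # 30 short enrolments (one with two fully missing domains, five with
    # time-in-class unrecorded), 42 special needs
    typical = _level_responses(reg, level_c)
    j = n_analysed

    def excl(gender, months, special=False, optout=False, responses=None):
        nonlocal j
        rec = PupilRecord(
            pupil_id=f"F{j:04d}", gender=gender,
            date_of_birth=_ASSESS - timedelta(days=round(5.5 * 365.25)),
            assessment_date=_ASSESS, months_in_class=months,
            simd_quintile=3, first_language_ok=True, esl=False,
            special_needs=special, opted_out=optout,
            indicators={c: False for c in INDICATOR_COLUMNS},
            responses=dict(typical) if responses is None else responses,
        )
        j += 1
        return rec

    for idx in range(18):
        gender = "female" if idx < 11 else "male"
        months = 0.5 if idx == 0 else 8.0
        records.append(excl(gender, months, optout=True, responses={}))
    two_missing = dict(typical)
    for d in ("PHWB", "SC"):
        for it in reg.domain_items(d):
            two_missing.pop(it.item_id, None)
    records.append(excl("male", 0.5, responses=two_missing))
    for idx in range(29):
        months = None if idx < 5 else 0.5
        records.append(excl("male" if idx % 2 else "female", months))
    for idx in range(42):
        records.append(excl("female" if idx % 2 else "male", 8.0, special=True))

    _verify_fixture(records, reg)
    return records


def _verify_fixture(records, reg) -> None:
    analysed, log = apply_exclusions(records, reg)
    checks = {
        "roster_n": (log.roster_n, 1180),
        "analysed_n": (log.analysed_n, 1090),
        "optout": (log.counts["excluded_optout"], 18),
        "short": (log.counts["excluded_short_enrolment"], 30),
        "special": (log.counts["excluded_special_needs"], 42),
        "missingness": (log.counts["excluded_missingness"], 0),
    }
    scored = score_cohort(analysed, reg)
    cuts = compute_cutoffs(scored)
    profiles = classify_cohort(scored, cuts)
    gender_of = {r.pupil_id: r.gender for r in analysed}
    ge1 = {g: 0 for g in ("male", "female", "unrecorded")}
    ge2 = {g: 0 for g in ("male", "female", "unrecorded")}
    for p in profiles:
        g = gender_of[p.pupil_id]
        ge1[g] += p.overall_vulnerable
        ge2[g] += p.multi_vulnerable
    checks.update({
        "ge1_total": (sum(ge1.values()), 298),
        "ge2_total": (sum(ge2.values()), 168),
        "ge1_male": (ge1["male"], 193),
        "ge1_female": (ge1["female"], 104),
        "ge2_male": (ge2["male"], 111),
        "ge2_female": (ge2["female"], 56),
        "cgk_ceiling_c50": (cuts["CGK"]["c50"], 10.0),
    })
    n_female = sum(1 for r in analysed if r.gender == "female")
    n_male = sum(1 for r in analysed if r.gender == "male")
    checks["female_n"] = (n_female, 524)
    checks["male_n"] = (n_male, 563)
    bad = {k: v for k, v in checks.items() if v[0] != v[1]}
    if bad:
        raise FixtureConstructionError(f"fixture self-verification failed: {bad}")
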