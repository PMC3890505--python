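"""Cohort-relative percentile cutoffs and vulnerability banding.

Cutoffs are nearest-rank empirical quantiles: ``c_p`` is the smallest
*observed* score such that at least ``p``% of the cohort's non-missing
scores lie at or below it, so every cutoff is an attainable score.  Bands
under the default ``strict-below`` convention:

* ``vulnerable``   — score < c10 (bottom 10% of the cohort)
* ``at_risk``      — c10 ≤ score < c25
* ``on_track_1``   — c25 ≤ score ≤ c50
* ``on_track_2``   — score > c50

With a ceiling (median equal to the observed maximum) this convention puts
the whole upper half into ``on_track_1`` and leaves ``on_track_2`` empty,
which is exactly how a piled-at-10 domain presents in community reports.
An ``at-or-below`` variant (vulnerable iff score ≤ c10) is available as a
configuration switch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instrument import DOMAINS
from .scoring import scores_frame

__all__ = [
    "BANDS",
    "CutoffSet",
    "VulnerabilityProfile",
    "VulnerabilitySummary",
    "CutoffError",
    "compute_cutoffs",
    "classify_pupil",
    "classify_cohort",
    "profiles_frame",
    "summarize_vulnerability",
]

BANDS = ("vulnerable", "at_risk", "on_track_1", "on_track_2")
PERCENTILES = (10, 25, 50)


class CutoffError(ValueError):
    """Raised when a cutoff cannot be computed (e.g. empty domain)."""


def nearest_rank(values, p: float) -> float:
    """Smallest observed value with cumulative proportion >= p percent."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    rank = max(int(math.ceil(p / 100.0 * n)), 1)
    return float(arr[rank - 1])


@dataclass
class CutoffSet:
    """Per-domain {c10, c25, c50} scores plus provenance."""

    cutoffs: dict  # domain -> {"c10": float, "c25": float, "c50": float}
    provenance: str = "computed-from-cohort"
    run_id: str | None = None

    def __getitem__(self, domain: str) -> dict:
        return self.cutoffs[domain]

    def to_json(self) -> str:
        return json.dumps(
            {"provenance": self.provenance, "cutoffs": self.cutoffs},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CutoffSet":
        obj = json.loads(text)
        return cls(cutoffs=obj["cutoffs"], provenance=obj.get("provenance", "loaded-external"))


def compute_cutoffs(cohort, percentiles=PERCENTILES) -> CutoffSet:
    """Nearest-rank percentile cutoffs per domain over the analysed cohort.

    Pupils missing a domain's score are excluded from that domain's quantile
    base only.  Raises :class:`CutoffError` if a domain has no scores at all.
    """
    frame = scores_frame(cohort)
    cuts: dict[str, dict] = {}
    for d in DOMAINS:
        vals = frame[d].dropna().to_numpy()
        if vals.size == 0:
            raise CutoffError(f"domain {d}: no non-missing scores in cohort")
        cuts[d] = {f"c{p}": nearest_rank(vals, p) for p in percentiles}
    return CutoffSet(cuts)


@dataclass
class VulnerabilityProfile:
    """One pupil's band per domain and multi-domain vulnerability flags."""

    pupil_id: str
    bands: dict  # domain -> band name or None
    n_vulnerable_domains: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_vulnerable_domains = sum(
            1 for b in self.bands.values() if b == "vulnerable"
        )

    @property
    def overall_vulnerable(self) -> bool:
        return self.n_vulnerable_domains >= 1

    @property
    def multi_vulnerable(self) -> bool:
        return self.n_vulnerable_domains >= 2


def _band(score: float, c: dict, convention: str) -> str:
    if convention == "strict-below":
        if score < c["c10"]:
            return "vulnerable"
    elif convention == "at-or-below":
        if score <= c["c10"]:
            return "vulnerable"
    else:
        raise ValueError(f"unknown band convention {convention!r}")
    if score < c["c25"]:
        return "at_risk"
    if score <= c["c50"]:
        return "on_track_1"
    return "on_track_2"


def classify_pupil(sp, cuts: CutoffSet, convention: str = "strict-below") -> VulnerabilityProfile:
    """Band one scored pupil against a cutoff set.

    A missing domain score yields a missing band and does not count toward
    ``n_vulnerable_domains``.
    """
    bands = {}
    for d in DOMAINS:
        s = sp.domain_scores[d]
        bands[d] = None if s is None else _band(s, cuts[d], convention)
    return VulnerabilityProfile(sp.pupil_id, bands)


def classify_cohort(scored, cuts: CutoffSet, convention: str = "strict-below") -> list:
    return [classify_pupil(sp, cuts, convention) for sp in scored]


def profiles_frame(profiles) -> pd.DataFrame:
    """One row per pupil: band per domain, count and the two flags."""
    rows = []
    for p in profiles:
        row = {"pupil_id": p.pupil_id}
        row.update({d: p.bands[d] for d in DOMAINS})
        row["n_vulnerable_domains"] = p.n_vulnerable_domains
        row["vulnerable_ge1"] = p.overall_vulnerable
        row["vulnerable_ge2"] = p.multi_vulnerable
        rows.append(row)
    return pd.DataFrame(rows).set_index("pupil_id")


@dataclass
class VulnerabilitySummary:
    """Stratified band percentages and multi-domain vulnerability rates.

    ``band_pct[stratum][domain][band]`` holds percentages of pupils with a
    non-missing band in that domain (each row sums to 100); ``multi`` maps
    stratum -> {n, n_ge1, n_ge2, pct_ge1, pct_ge2} with the stratum's
    analysed count as denominator.
    """

    band_pct: dict
    band_n: dict
    multi: dict
    run_id: str | None = None


def summarize_vulnerability(profiles, strata=None) -> VulnerabilitySummary:
    """Aggregate profiles into band percentages and >=1/>=2-domain rates.

    ``strata`` maps pupil_id -> stratum label; pupils absent from the map
    (e.g. missing deprivation quintile) are dropped from stratified rows but
    always retained in the ``"overall"`` stratum.  Empty strata are simply
    absent from the output.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to summarize")

    groups: dict[str, list] = {"overall": profiles}
    if strata is not None:
        for p in profiles:
            label = strata.get(p.pupil_id)
            if label is None:
                continue
            groups.setdefault(str(label), []).append(p)

    band_pct: dict = {}
    band_n: dict = {}
    multi: dict = {}
    for label, members in groups.items():
        band_pct[label] = {}
        band_n[label] = {}
        for d in DOMAINS:
            counts = {b: 0 for b in BANDS}
            for p in members:
                b = p.bands[d]
                if b is not None:
                    counts[b] += 1
            total = sum(counts.values())
            band_n[label][d] = counts
            band_pct[label][d] = {
                b: (100.0 * c / total if total else float("nan"))
                for b, c in counts.items()
            }
        n = len(members)
        n1 = sum(1 for p in members if p.overall_vulnerable)
        n2 = sum(1 for p in members if p.multi_vulnerable)
        multi[label] = {
            "n": n,
            "n_ge1": n1,
            "n_ge2": n2,
            "pct_ge1": 100.0 * n1 / n,
            "pct_ge2": 100.0 * n2 / n,
        }
    return VulnerabilitySummary(band_pct, band_n, multi)
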