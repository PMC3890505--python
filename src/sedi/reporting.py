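"""Community-level report assembly and the data-collection cost model.

Reports aggregate only: strata smaller than a minimum cell size (default 5
pupils) are suppressed with a reason code, so no output can be read at the
individual-child level.  Numbers are kept at full precision internally and
rounded only at serialization — scores to 2 decimals, percentages to 1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .instrument import DOMAINS
from .scoring import scores_frame
from .vulnerability import BANDS, CutoffSet, VulnerabilitySummary

__all__ = [
    "CohortReport",
    "CostEstimate",
    "ConsistencyError",
    "build_report",
    "cost_model",
]

MIN_CELL_DEFAULT = 5


class ConsistencyError(ValueError):
    """Raised when report inputs come from different pipeline runs."""


@dataclass
class CostEstimate:
    """Cost of one instrument sweep over a community's school entrants.

    ``cohort_size_per_wave = population x crude_birth_rate``;
    ``per_wave_cost = cohort_size x per_child_cost``;
    ``annualized_cost = per_wave_cost / wave_interval_years``.
    """

    per_child_cost: float
    cohort_size_per_wave: float
    per_wave_cost: float
    wave_interval_years: float
    annualized_cost: float
    currency: str = "GBP"


def cost_model(
    population: float,
    crude_birth_rate: float,
    per_child_cost: float,
    wave_interval_years: float,
    currency: str = "GBP",
) -> CostEstimate:
    """Cost of periodic cohort-wide data collection for a community.

    ``crude_birth_rate`` is a fraction per year (0.01 = 1%), so the cohort
    reaching school entry each year is ``population x rate``; one wave
    assesses a single entry cohort, repeated every ``wave_interval_years``.
    """
    if population < 0 or crude_birth_rate < 0 or per_child_cost < 0:
        raise ValueError("population, birth rate and per-child cost must be >= 0")
    if wave_interval_years <= 0:
        raise ValueError("wave interval must be positive")
    cohort = population * crude_birth_rate
    per_wave = cohort * per_child_cost
    return CostEstimate(
        per_child_cost=per_child_cost,
        cohort_size_per_wave=cohort,
        per_wave_cost=per_wave,
        wave_interval_years=wave_interval_years,
        annualized_cost=per_wave / wave_interval_years,
        currency=currency,
    )


@dataclass
class CohortReport:
    """Full community report: score distributions, band tables, multi-domain
    vulnerability, stratum means, reliability/inference results, exclusion
    accounting and cutoff provenance."""

    domain_summary: dict  # domain -> {min,max,mean,sd,c10,c25,c50,n}
    band_tables: dict  # stratification -> stratum -> domain -> band pcts (+mean)
    multi_vuln: dict  # stratification -> stratum -> {n, pct_ge1, pct_ge2}
    stratum_means: dict  # stratification -> stratum -> domain -> mean
    suppressed: dict  # stratification -> [stratum labels suppressed]
    reliability: dict
    inference: dict
    exclusion_summary: dict
    cutoff_provenance: str
    min_cell: int
    run_id: str | None = None

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        """Deterministic JSON with presentation rounding applied."""
        obj = asdict(self)
        obj = _round_tree(obj)
        return json.dumps(obj, indent=2, sort_keys=True, allow_nan=True)

    def domain_summary_csv(self) -> str:
        rows = []
        for d in DOMAINS:
            s = self.domain_summary[d]
            rows.append({
                "domain": d,
                "min": round(s["min"], 2), "max": round(s["max"], 2),
                "mean": round(s["mean"], 2), "sd": round(s["sd"], 2),
                "c10": round(s["c10"], 2), "c25": round(s["c25"], 2),
                "c50": round(s["c50"], 2), "n": s["n"],
            })
        return pd.DataFrame(rows).to_csv(index=False)

    def band_table_csv(self, stratification: str) -> str:
        rows = []
        for stratum, per_domain in self.band_tables[stratification].items():
            for d in DOMAINS:
                cells = per_domain[d]
                row = {"stratum": stratum, "domain": d,
                       "mean": round(self.stratum_means[stratification][stratum][d], 2)}
                row.update({b: round(cells[b], 1) for b in BANDS})
                rows.append(row)
        return pd.DataFrame(rows).to_csv(index=False)

    def multi_vuln_csv(self) -> str:
        rows = []
        for stratification, strata in self.multi_vuln.items():
            for stratum, m in strata.items():
                rows.append({
                    "stratification": stratification, "stratum": stratum,
                    "n": m["n"],
                    "pct_ge1": round(m["pct_ge1"], 1),
                    "pct_ge2": round(m["pct_ge2"], 1),
                })
        return pd.DataFrame(rows).to_csv(index=False)


def _round_tree(obj, ndigits=4):
    if isinstance(obj, dict):
        return {k: _round_tree(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_tree(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def _check_run_ids(*components) -> str | None:
    run_ids = {c.run_id for c in components
               if getattr(c, "run_id", None) is not None}
    if len(run_ids) > 1:
        raise ConsistencyError(f"inputs from different runs: {sorted(run_ids)}")
    return run_ids.pop() if run_ids else None


def build_report(
    scores,
    cutoffs: CutoffSet,
    summaries: dict,
    strata_maps: dict | None = None,
    reliability: dict | None = None,
    inference: dict | None = None,
    exclusion_summary: dict | None = None,
    min_cell: int = MIN_CELL_DEFAULT,
) -> CohortReport:
    """Assemble the community report.

    Parameters
    ----------
    scores:
        Scored cohort (list of ``ScoredPupil`` or a scores frame).
    cutoffs:
        The cutoff set used for banding (provenance is echoed in the report).
    summaries:
        Mapping stratification name -> :class:`VulnerabilitySummary`
        (e.g. ``{"overall": ..., "gender": ..., "quintile": ...}``).
    strata_maps:
        Mapping stratification name -> (pupil_id -> stratum), used for
        stratum mean scores.
    min_cell:
        Strata with fewer pupils are suppressed with a reason code.
    """
    frame = scores_frame(scores)
    run_id = _check_run_ids(cutoffs, *summaries.values())

    domain_summary = {}
    for d in DOMAINS:
        vals = frame[d].dropna()
        domain_summary[d] = {
            "min": float(vals.min()), "max": float(vals.max()),
            "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
            "n": int(vals.size),
            **{k: float(v) for k, v in cutoffs[d].items()},
        }

    band_tables: dict = {}
    multi_vuln: dict = {}
    stratum_means: dict = {}
    suppressed: dict = {}
    strata_maps = strata_maps or {}
    for name, summary in summaries.items():
        if not isinstance(summary, VulnerabilitySummary):
            raise TypeError(f"summaries[{name!r}] must be a VulnerabilitySummary")
        band_tables[name] = {}
        multi_vuln[name] = {}
        stratum_means[name] = {}
        suppressed[name] = []
        smap = strata_maps.get(name)
        for stratum, m in summary.multi.items():
            if m["n"] < min_cell:
                suppressed[name].append(
                    f"{stratum}: n={m['n']} below minimum cell size {min_cell}"
                )
                continue
            band_tables[name][stratum] = summary.band_pct[stratum]
            multi_vuln[name][stratum] = dict(m)
            if stratum == "overall" or smap is None:
                member_index = frame.index
            else:
                member_index = [pid for pid in frame.index
                                if str(smap.get(pid)) == stratum]
            sub = frame.loc[member_index]
            stratum_means[name][stratum] = {
                d: float(sub[d].mean()) for d in DOMAINS
            }

    return CohortReport(
        domain_summary=domain_summary,
        band_tables=band_tables,
        multi_vuln=multi_vuln,
        stratum_means=stratum_means,
        suppressed=suppressed,
        reliability=reliability or {},
        inference=inference or {},
        exclusion_summary=exclusion_summary or {},
        cutoff_provenance=cutoffs.provenance,
        min_cell=min_cell,
        run_id=run_id,
    )
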