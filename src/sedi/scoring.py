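"""Raw responses → ten-point item scores → per-pupil domain means.

Every scored response is mapped linearly onto [0, 10]: yes/no items to
{0, 10}, three-point Likert items to {0, 5, 10}.  Reverse-worded items
(polarity −1, e.g. "is shy") have the mapping flipped so that 10 always
means better development.  A pupil's domain score is the arithmetic mean of
the converted, non-missing items of that domain — no imputation; a domain
with no answered item has a missing score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instrument import DOMAINS, InstrumentRegistry, ItemDefinition

__all__ = [
    "ScoredPupil",
    "ConversionError",
    "convert_item_response",
    "score_domains",
    "score_cohort",
    "scores_frame",
    "token_for_score",
    "valid_tokens",
]

#: Ordered category tokens, worst-to-best development for polarity +1.
BINARY_TOKENS = ("no", "yes")
LIKERT3_TOKENS = ("never", "sometimes", "often")

_TOKEN_ALIASES = {
    "binary": {"no": 0, "n": 0, "0": 0, "yes": 1, "y": 1, "1": 1},
    "likert3": {
        "never": 0, "never or not true": 0, "0": 0,
        "sometimes": 1, "sometimes or somewhat true": 1, "1": 1,
        "often": 2, "often or very true": 2, "2": 2,
    },
}


class ConversionError(ValueError):
    """Raised for an unknown response token on a scored item."""


def valid_tokens(item: ItemDefinition) -> set:
    """Accepted (lower-cased) raw tokens for a scored item."""
    return set(_TOKEN_ALIASES[item.response_kind])


def convert_item_response(item: ItemDefinition, raw) -> float | None:
    """Map one raw token to its ten-point item score, honouring polarity.

    Missing input stays missing.  Unknown tokens raise
    :class:`ConversionError` naming item and token (roster parsing screens
    tokens earlier, so this fires only on programmatic misuse).
    """
    if raw is None:
        return None
    if item.response_kind == "categorical_info":
        raise ConversionError(f"{item.item_id}: informational item is never scored")
    table = _TOKEN_ALIASES[item.response_kind]
    tok = str(raw).strip().lower()
    if tok not in table:
        raise ConversionError(f"{item.item_id}: unknown response token {raw!r}")
    level = table[tok]
    n_levels = 2 if item.response_kind == "binary" else 3
    score = 10.0 * level / (n_levels - 1)
    if item.polarity < 0:
        score = 10.0 - score
    return score


def token_for_score(item: ItemDefinition, score: float) -> str:
    """Inverse of :func:`convert_item_response` (canonical token for a score).

    Used by generators that construct rosters with known domain means.
    """
    if item.polarity < 0:
        score = 10.0 - score
    if item.response_kind == "binary":
        return BINARY_TOKENS[int(round(score / 10.0))]
    return LIKERT3_TOKENS[int(round(score / 5.0))]


@dataclass
class ScoredPupil:
    """Per-domain mean scores with answered-item accounting."""

    pupil_id: str
    domain_scores: dict  # domain -> float in [0, 10], or None
    answered_counts: dict  # domain -> int


def score_domains(rec, reg: InstrumentRegistry) -> ScoredPupil:
    """Compute one pupil's five domain mean scores."""
    sums = {d: 0.0 for d in DOMAINS}
    counts = {d: 0 for d in DOMAINS}
    for item in reg.scored_items:
        raw = rec.responses.get(item.item_id)
        if raw is None:
            continue
        try:
            s = convert_item_response(item, raw)
        except ConversionError as err:
            raise ConversionError(f"pupil {rec.pupil_id}: {err}") from err
        sums[item.domain] += s
        counts[item.domain] += 1
    scores = {
        d: (sums[d] / counts[d] if counts[d] else None) for d in DOMAINS
    }
    return ScoredPupil(rec.pupil_id, scores, counts)


def score_cohort(records, reg: InstrumentRegistry) -> list:
    """Score every record; returns a list of :class:`ScoredPupil`."""
    return [score_domains(r, reg) for r in records]


def scores_frame(scored) -> pd.DataFrame:
    """Tabulate scored pupils: one row per pupil, one column per domain,
    plus ``n_<domain>`` answered-count columns.  Missing scores become NaN.
    """
    if isinstance(scored, pd.DataFrame):
        return scored
    rows = []
    for sp in scored:
        row = {"pupil_id": sp.pupil_id}
        for d in DOMAINS:
            v = sp.domain_scores[d]
            row[d] = np.nan if v is None else v
            row[f"n_{d}"] = sp.answered_counts[d]
        rows.append(row)
    return pd.DataFrame(rows).set_index("pupil_id")
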