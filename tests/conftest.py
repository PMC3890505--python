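import io

import pytest

from sedi.cohort import INDICATOR_COLUMNS, MANDATORY_COLUMNS
from sedi.instrument import default_registry
from sedi.synthetic import fixture_printed_marginals


@pytest.fixture(scope="session")
def reg():
    return default_registry()


@pytest.fixture(scope="session")
def reference_roster(reg):
    """Deterministic 1,180-pupil roster with the engineered marginals."""
    return fixture_printed_marginals(reg)


def make_roster_csv(rows, reg, default_response="yes"):
    """Small roster CSV text from a list of per-pupil override dicts.

    Every mandatory column and every scored item column is present; scored
    items default to the top response for the item kind so toy cohorts are
    fully answered unless a test overrides a cell (None blanks it).
    """
    from sedi.scoring import token_for_score

    item_ids = [it.item_id for it in reg.scored_items]
    header = list(MANDATORY_COLUMNS) + item_ids
    defaults = {
        "gender": "female",
        "date_of_birth": "2006-11-01",
        "assessment_date": "2012-05-15",
        "months_in_class": "8",
        "simd_quintile": "3",
        "first_language_ok": "yes",
        "esl": "no",
        "special_needs": "no",
        "opted_out": "no",
        **{c: "no" for c in INDICATOR_COLUMNS},
        **{it.item_id: token_for_score(it, 10.0) for it in reg.scored_items},
    }
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    for i, row in enumerate(rows):
        cells = dict(defaults)
        cells["pupil_id"] = f"T{i:03d}"
        for k, v in row.items():
            cells[k] = "" if v is None else str(v)
        buf.write(",".join(cells.get(c, "") for c in header) + "\n")
    return buf.getvalue()
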