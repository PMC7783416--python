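"""Fixed item maps for the self-report scales.

The YPI (Youth Psychopathic traits Inventory) has 50 items answered on a
1-4 Likert scale.  Callous-unemotional (CU) traits are scored from three
5-item subscales -- remorselessness, unemotionality and callousness -- and
the DSM-5 Limited Prosocial Emotions (LPE) specifier is proxied by the
two-or-more-traits rule: a trait counts as *endorsed* when at least one of
its items is answered "applies very well" (a response of 4), and LPE is
met when two or more of the three traits are endorsed.

The published YPI does not come with a canonical 1-50 numbering that is
stable across translations, so the item->subscale map below is this
package's own fixed convention.  It is the single source of truth for both
the synthetic item generator and the scorer; exporting it (``cu_item_table``)
yields the documented data table.

The RPQ (Reactive-Proactive aggression Questionnaire) has 23 items on a
0-2 scale; the reactive/proactive split below follows the published
instrument (11 reactive, 12 proactive items).
"""

from __future__ import annotations

import pandas as pd

N_YPI_ITEMS = 50
N_RPQ_ITEMS = 23

# 1-based YPI item indices per CU-trait subscale (5 items each, 15 CU items).
CU_SUBSCALES: dict[str, tuple[int, ...]] = {
    "remorselessness": (4, 12, 21, 33, 42),
    "unemotionality": (7, 15, 26, 37, 46),
    "callousness": (2, 10, 24, 31, 49),
}

CU_ITEMS: tuple[int, ...] = tuple(
    sorted(i for items in CU_SUBSCALES.values() for i in items)
)

# 1-based RPQ item indices (published instrument split).
RPQ_REACTIVE: tuple[int, ...] = (1, 3, 5, 7, 8, 11, 13, 14, 16, 19, 22)
RPQ_PROACTIVE: tuple[int, ...] = (2, 4, 6, 9, 10, 12, 15, 17, 18, 20, 21, 23)

YPI_RESPONSE_RANGE = (1, 4)
RPQ_RESPONSE_RANGE = (0, 2)

# Endorsement threshold: "applies very well".
YPI_ENDORSE_VALUE = 4
LPE_MIN_TRAITS = 2


def cu_item_table() -> pd.DataFrame:
    """The CU item map as a tidy table (subscale, ypi_item)."""
    rows = [
        {"subscale": sub, "ypi_item": item}
        for sub, items in CU_SUBSCALES.items()
        for item in items
    ]
    return pd.DataFrame(rows)


def rpq_item_table() -> pd.DataFrame:
    """The RPQ item partition as a tidy table (subscale, rpq_item)."""
    rows = [{"subscale": "reactive", "rpq_item": i} for i in RPQ_REACTIVE] + [
        {"subscale": "proactive", "rpq_item": i} for i in RPQ_PROACTIVE
    ]
    return pd.DataFrame(rows)
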