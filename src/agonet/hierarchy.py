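"""Social rank classification from degree centrality.

Each animal with at least one agonistic contact gets a Social Rank Index
SI = out-degree / all-degree, the fraction of its agonistic edges that it
initiated. SI >= 0.70 is classified Dominant (attacks many, attacked by
few), SI < 0.70 Subordinate. Animals with all-degree zero took part in no
agonistic interaction at all and are classified Isolated; their SI is
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DOMINANT",
    "SUBORDINATE",
    "ISOLATED",
    "SI_THRESHOLD",
    "SocialRank",
    "social_rank_index",
    "classify_pen",
    "category_proportions",
]

DOMINANT = "Dominant"
SUBORDINATE = "Subordinate"
ISOLATED = "Isolated"

#: Dominant/Subordinate boundary; the boundary itself is Dominant.
SI_THRESHOLD = 0.70

CATEGORIES = (DOMINANT, SUBORDINATE, ISOLATED)


@dataclass(frozen=True)
class SocialRank:
    animal_id: str
    si: float | None
    category: str


def social_rank_index(out_degree: int, all_degree: int) -> float | None:
    """SI = out-degree / all-degree; ``None`` (undefined) when all-degree is 0."""
    if out_degree < 0 or all_degree < 0:
        raise ValueError("degrees must be non-negative")
    if out_degree > all_degree:
        raise ValueError(
            f"out-degree {out_degree} exceeds all-degree {all_degree}"
        )
    if all_degree == 0:
        return None
    return out_degree / all_degree


def _categorize(si: float | None) -> str:
    if si is None:
        return ISOLATED
    return DOMINANT if si >= SI_THRESHOLD else SUBORDINATE


def classify_pen(centralities: pd.DataFrame) -> list[SocialRank]:
    """Label every animal in a centrality table Dominant/Subordinate/Isolated.

    ``centralities`` needs ``animal_id``, ``out_degree`` and ``all_degree``
    columns (one row per roster animal).
    """
    ranks: list[SocialRank] = []
    for row in centralities.itertuples(index=False):
        si = social_rank_index(int(row.out_degree), int(row.all_degree))
        ranks.append(
            SocialRank(animal_id=row.animal_id, si=si, category=_categorize(si))
        )
    return ranks


def ranks_frame(ranks: list[SocialRank], pen_id: str | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in ranks],
            "si": [r.si for r in ranks],
            "category": [r.category for r in ranks],
        }
    )
    if pen_id is not None:
        frame.insert(0, "pen_id", pen_id)
    return frame


def category_proportions(ranks: list[SocialRank]) -> dict[str, float]:
    """Percentage of animals per category; the three values sum to 100."""
    if not ranks:
        raise ValueError("no animals to classify")
    n = len(ranks)
    return {
        cat: 100.0 * sum(1 for r in ranks if r.category == cat) / n
        for cat in CATEGORIES
    }
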