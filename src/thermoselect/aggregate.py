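"""Cross-method coincidence ranking.

Features that appear in the top-``window`` of *every* supplied ranking are
collected; each receives as final rank its best (numerically smallest)
position across the methods; candidates whose final rank is not below
``max_rank`` are discarded. The surviving features are listed in ascending
final rank (ties broken by name) with a rank-interval bucket (<10, <20, <30,
<50).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .selectors import RankingResult

_BUCKETS = (10, 20, 30, 50)


@dataclass
class CoincidenceEntry:
    feature: str
    final_rank: int
    bucket: str
    per_method_rank: dict[str, int]


@dataclass
class CoincidenceReport:
    window: int
    max_rank: int
    methods: list[str]
    entries: list[CoincidenceEntry]

    @property
    def features(self) -> list[str]:
        return [e.feature for e in self.entries]

    def to_json(self) -> dict:
        return {
            "window": self.window,
            "max_rank": self.max_rank,
            "methods": self.methods,
            "entries": [
                {
                    "feature": e.feature,
                    "final_rank": e.final_rank,
                    "bucket": e.bucket,
                    "per_method_rank": e.per_method_rank,
                }
                for e in self.entries
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


def _bucket(rank: int) -> str:
    for b in _BUCKETS:
        if rank < b:
            return f"<{b}"
    return f">={_BUCKETS[-1]}"


def coincidence(
    rankings: list[RankingResult],
    window: int = 30,
    max_rank: int = 50,
) -> CoincidenceReport:
    """Features ranked in the top-``window`` by every method.

    Final rank = the minimum (best) rank across all methods; features with a
    final rank of ``max_rank`` or worse are dropped. The report is invariant
    to the order in which rankings are supplied.
    """
    if len(rankings) < 2:
        raise ValueError("coincidence needs at least two rankings")
    names = set(rankings[0].feature_names)
    for r in rankings[1:]:
        if set(r.feature_names) != names:
            raise ValueError("rankings cover different feature sets")

    per_method = {r.method: r.rank_of() for r in rankings}
    candidates = set.intersection(*(set(r.top(window)) for r in rankings))

    entries = []
    for feat in candidates:
        ranks = {m: per_method[m][feat] for m in per_method}
        final = min(ranks.values())
        if final < max_rank:
            entries.append(
                CoincidenceEntry(
                    feature=feat,
                    final_rank=final,
                    bucket=_bucket(final),
                    per_method_rank=ranks,
                )
            )
    entries.sort(key=lambda e: (e.final_rank, e.feature))
    return CoincidenceReport(
        window=window,
        max_rank=max_rank,
        methods=sorted(per_method),
        entries=entries,
    )
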