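"""Shared feature-ranking container used by the t-test and autoencoder rankers."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RankedFeature:
    pathway_id: str
    score: float
    rank: int


@dataclass
class FeatureRanking:
    """An ordered list of pathway features with their ranking scores.

    ``method`` records the comparator: ``"ttest"`` ranks by ascending p-value,
    ``"da"`` by descending absolute mean encoder weight.  Ranks are 1-based and
    unique; ties are broken lexicographically by pathway id.
    """

    entries: list[RankedFeature]
    method: str

    def __post_init__(self) -> None:
        ranks = [e.rank for e in self.entries]
        if sorted(ranks) != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be exactly 1..K")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ordered_ids(self) -> list[str]:
        return [e.pathway_id for e in sorted(self.entries, key=lambda e: e.rank)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.pathway_id, e.score, e.rank)
             for e in sorted(self.entries, key=lambda e: e.rank)],
            columns=["pathway_id", "score", "rank"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
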