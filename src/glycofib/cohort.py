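"""The cohort feature table: samples x channel-prefixed glycan percentiles.

Each row is one serum sample; feature columns are ``<channel>.<glycan>``
(e.g. ``IgG1.A2G1F``) holding the glycan's relative percentile (0-100) of
that capture channel's total glycan profile.  Two metadata columns carry the
fibrosis grouping used throughout the analysis:

* ``group`` — 1 (no fibrosis: healthy or METAVIR stage 0), 2 (early to
  moderate: stages 1-2), 3 (advanced or cirrhosis: stages 3-4);
* ``stage`` — the per-sample METAVIR stage (``healthy`` or ``0``..``4``),
  kept so alternative regroupings remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glycans import parse_channel_feature

META_COLUMNS = ("group", "stage")

#: METAVIR-stage composition of each fibrosis group.
GROUP_STAGES = {1: ("healthy", "0"), 2: ("1", "2"), 3: ("3", "4")}


@dataclass
class CohortTable:
    """Samples x glycan-feature matrix with fibrosis labels.

    ``data`` is indexed by sample id with columns ``group``, ``stage`` and
    the feature columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes}")
        for col in META_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"cohort table missing {col!r} column")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def channels(self) -> list[str]:
        return sorted({parse_channel_feature(c).channel for c in self.feature_columns})

    def channel_features(self, channel: str) -> list[str]:
        return [
            c
            for c in self.feature_columns
            if parse_channel_feature(c).channel == channel
        ]

    def validate_closure(self, atol: float = 1e-6) -> None:
        """Check that per-channel percentiles sum to 100 for every sample
        with any signal in that channel."""
        for channel in self.channels():
            block = self.data[self.channel_features(channel)]
            sums = block.sum(axis=1).to_numpy(dtype=float)
            has_signal = sums > 0
            if not np.allclose(sums[has_signal], 100.0, atol=atol):
                bad = self.data.index[has_signal][
                    ~np.isclose(sums[has_signal], 100.0, atol=atol)
                ]
                raise ValueError(
                    f"channel {channel}: percentiles do not sum to 100 for "
                    f"samples {list(bad[:5])}"
                )

    def binary_subset(self, group_a: int, group_b: int) -> tuple[pd.DataFrame, np.ndarray]:
        """Feature matrix and 0/1 labels for one pairwise group comparison
        (label 1 = the more-advanced group ``group_b``)."""
        mask = self.groups.isin([group_a, group_b])
        X = self.features[mask]
        y = (self.groups[mask] == group_b).to_numpy(dtype=int)
        return X, y

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(
            path, sep="\t", index_col="sample_id", dtype={"stage": str}
        )
        return cls(df)
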