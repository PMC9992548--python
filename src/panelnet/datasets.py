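"""Ordinal item panel containers.

The package analyses wide tables of ordinal item responses: 7 anxiety items
(GAD-7, ``A1``-``A7``), 7 depression items (CES-D short form, ``D1``-``D7``)
and 3 loneliness items (UCLA-3, ``L1``-``L3``), observed at one or two waves.
Responses are coded ``1..n_categories``.  :class:`OrdinalPanelDataset` holds a
single wave; :class:`TwoWavePanel` holds a pair of waves observed on the same
participants (row ``i`` of both waves is the same person).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANXIETY_ITEMS = [f"A{i}" for i in range(1, 8)]
DEPRESSION_ITEMS = [f"D{i}" for i in range(1, 8)]
LONELINESS_ITEMS = [f"L{i}" for i in range(1, 4)]
DEFAULT_ITEMS = ANXIETY_ITEMS + DEPRESSION_ITEMS + LONELINESS_ITEMS

#: item -> instrument/community name used throughout the pipeline
DEFAULT_COMMUNITIES = {
    **{it: "anxiety" for it in ANXIETY_ITEMS},
    **{it: "depression" for it in DEPRESSION_ITEMS},
    **{it: "loneliness" for it in LONELINESS_ITEMS},
}

#: depression items are scored with most mass in the top category in this
#: population, i.e. they behave like reverse-keyed items relative to the
#: positively skewed anxiety/loneliness items.
DEFAULT_REVERSE_CODED = {it: (it in DEPRESSION_ITEMS) for it in DEFAULT_ITEMS}


class DataValidationError(ValueError):
    """Raised when an ordinal panel violates its contract."""


@dataclass
class OrdinalPanelDataset:
    """One wave of ordinal item responses.

    Parameters
    ----------
    responses:
        ``(n, p)`` integer array, categories coded ``1..n_categories``.
    item_labels:
        Length-``p`` item names (e.g. ``A1``).
    community_labels:
        Map from item label to community/instrument name.
    wave_id:
        ``"T1"`` or ``"T2"``.
    reverse_coded:
        Per-item flag; items whose mass sits in the top category.
    n_categories:
        Number of response categories per item (default 4).
    """

    responses: np.ndarray
    item_labels: list[str] = field(default_factory=lambda: list(DEFAULT_ITEMS))
    community_labels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMMUNITIES)
    )
    wave_id: str = "T1"
    reverse_coded: dict[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_REVERSE_CODED)
    )
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise DataValidationError("responses must be a 2-D array")
        if self.responses.shape[1] != len(self.item_labels):
            raise DataValidationError(
                f"{self.responses.shape[1]} columns but "
                f"{len(self.item_labels)} item labels"
            )
        if not np.issubdtype(self.responses.dtype, np.integer):
            as_int = self.responses.astype(int)
            if not np.array_equal(as_int, self.responses) or np.isnan(
                self.responses.astype(float)
            ).any():
                raise DataValidationError("responses must be integers, no missing")
            self.responses = as_int
        lo, hi = self.responses.min(), self.responses.max()
        if lo < 1 or hi > self.n_categories:
            raise DataValidationError(
                f"responses must lie in [1, {self.n_categories}]; saw [{lo}, {hi}]"
            )
        for j, label in enumerate(self.item_labels):
            if np.unique(self.responses[:, j]).size < 2:
                raise DataValidationError(
                    f"item {label} has fewer than 2 observed categories"
                )
            if label not in self.community_labels:
                raise DataValidationError(f"item {label} has no community label")

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    @property
    def p(self) -> int:
        return self.responses.shape[1]

    @property
    def communities(self) -> list[str]:
        """Community name per column, in item order."""
        return [self.community_labels[it] for it in self.item_labels]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, columns=self.item_labels)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        wave_id: str = "T1",
        community_labels: dict[str, str] | None = None,
        reverse_coded: dict[str, bool] | None = None,
        n_categories: int = 4,
    ) -> "OrdinalPanelDataset":
        """Build a dataset from a wide table, listwise-deleting missing rows."""
        df = df.dropna(axis=0, how="any")
        labels = list(df.columns)
        if community_labels is None:
            community_labels = {
                it: DEFAULT_COMMUNITIES.get(it, "unknown") for it in labels
            }
        if reverse_coded is None:
            reverse_coded = {
                it: DEFAULT_REVERSE_CODED.get(it, False) for it in labels
            }
        return cls(
            responses=df.to_numpy(),
            item_labels=labels,
            community_labels=community_labels,
            wave_id=wave_id,
            reverse_coded=reverse_coded,
            n_categories=n_categories,
        )


@dataclass
class TwoWavePanel:
    """Paired two-wave panel: both waves observed on the same participants."""

    t1: OrdinalPanelDataset
    t2: OrdinalPanelDataset

    def __post_init__(self) -> None:
        if self.t1.n != self.t2.n:
            raise DataValidationError(
                f"waves are not paired: n={self.t1.n} vs n={self.t2.n}"
            )
        if self.t1.item_labels != self.t2.item_labels:
            raise DataValidationError("waves have different item sets")

    @property
    def n(self) -> int:
        return self.t1.n

    @property
    def item_labels(self) -> list[str]:
        return self.t1.item_labels

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table, one row per participant, columns ``A1_T1..L3_T2``."""
        d1 = self.t1.to_dataframe().add_suffix("_T1")
        d2 = self.t2.to_dataframe().add_suffix("_T2")
        return pd.concat([d1, d2], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TwoWavePanel":
        df = df.dropna(axis=0, how="any")
        t1_cols = [c for c in df.columns if c.endswith("_T1")]
        t2_cols = [c for c in df.columns if c.endswith("_T2")]
        if not t1_cols or not t2_cols:
            raise DataValidationError("expected columns suffixed _T1 and _T2")
        d1 = df[t1_cols].rename(columns=lambda c: c[:-3])
        d2 = df[t2_cols].rename(columns=lambda c: c[:-3])
        return cls(
            t1=OrdinalPanelDataset.from_dataframe(d1, wave_id="T1", **kwargs),
            t2=OrdinalPanelDataset.from_dataframe(d2, wave_id="T2", **kwargs),
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TwoWavePanel":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)
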