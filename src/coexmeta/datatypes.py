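"""Core in-memory containers shared across pipeline stages.

The unit of per-study analysis is :class:`ExpressionStudy`: a feature x sample
matrix (pandas DataFrame) with group labels (control vs case), a disease class
(lung cancer ``LC`` vs other lung disease ``LD``) and a scale tag (``raw``
scanner intensities vs variance-stabilized ``glog2``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

DISEASE_CLASSES = ("LC", "LD")
GROUPS = ("control", "case")
SCALES = ("raw", "glog2")


@dataclass
class ExpressionStudy:
    """One study's expression matrix plus sample annotation.

    Parameters
    ----------
    study_id : str
        Unique study label.
    disease_class : {"LC", "LD"}
        Lung cancer vs other lung disease.
    values : pandas.DataFrame
        Feature x sample matrix; index = feature labels, columns = sample
        labels.
    group : pandas.Series
        Maps each sample label to ``"control"`` or ``"case"``.
    scale : {"raw", "glog2"}
        ``raw`` intensities before normalization, ``glog2`` after.
    """

    study_id: str
    disease_class: str
    values: pd.DataFrame
    group: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.disease_class not in DISEASE_CLASSES:
            raise FormatError(
                f"study {self.study_id!r}: disease_class must be one of "
                f"{DISEASE_CLASSES}, got {self.disease_class!r}"
            )
        if self.scale not in SCALES:
            raise FormatError(
                f"study {self.study_id!r}: scale must be one of {SCALES}, "
                f"got {self.scale!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(
                f"study {self.study_id!r}: duplicate feature labels {dups[:5]}"
            )
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise FormatError(
                f"study {self.study_id!r}: duplicate sample labels {dups[:5]}"
            )
        missing = set(self.values.columns) - set(self.group.index)
        if missing:
            raise FormatError(
                f"study {self.study_id!r}: samples without group annotation: "
                f"{sorted(missing)[:5]}"
            )
        self.group = self.group.loc[self.values.columns]
        bad = set(self.group.unique()) - set(GROUPS)
        if bad:
            raise FormatError(
                f"study {self.study_id!r}: unknown group labels {sorted(bad)}"
            )
        for g in GROUPS:
            if int((self.group == g).sum()) < 2:
                raise FormatError(
                    f"study {self.study_id!r}: fewer than 2 samples in group "
                    f"{g!r}"
                )
        if self.scale == "glog2" and not np.isfinite(
            self.values.to_numpy(dtype=float)
        ).all():
            raise FormatError(
                f"study {self.study_id!r}: non-finite values on glog2 scale"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def case_mask(self) -> np.ndarray:
        return (self.group.to_numpy() == "case")

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionStudy":
        """Return a copy carrying a new matrix (same annotation)."""
        return ExpressionStudy(
            study_id=self.study_id,
            disease_class=self.disease_class,
            values=values,
            group=self.group.copy(),
            scale=scale,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (functional categories or TF -> target sets).

    ``sets`` maps a unique set name to ``(description, frozenset of gene
    labels)``; every set is non-empty.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]
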