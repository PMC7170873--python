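"""Symptom-matrix container, column standardization and endorsement profiles.

The clustering consumes the 16 ordinal QIDS items after per-item
standardization (subtract the mean, divide by the sample standard deviation)
so that every item carries the same weight in the Euclidean geometry.
Endorsement profiles summarise each subtype as the percentage of its members
scoring at or above a threshold on each item, i.e. the quantity shown on a
radar plot of subtype symptom patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .items import MAX_SCORE, MIN_SCORE, QIDS_ITEMS


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class SymptomMatrix:
    """Subjects x items table of ordinal symptom scores.

    Parameters
    ----------
    subject_ids
        Unique subject labels, one per row.
    scores
        Integer array of shape (n_subjects, n_items) with entries in
        {0, 1, 2, 3}.
    item_names
        Item labels in canonical QIDS order.
    """

    subject_ids: list[str]
    scores: np.ndarray
    item_names: tuple[str, ...] = QIDS_ITEMS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.scores.shape
        if len(self.subject_ids) != n:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n} score rows"
            )
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject ids are not unique")
        if p != len(self.item_names):
            raise ValidationError(
                f"{p} score columns for {len(self.item_names)} item names"
            )
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(np.isfinite(self.scores)):
                bad = [
                    self.subject_ids[i]
                    for i in np.unique(np.nonzero(~np.isfinite(self.scores))[0])
                ]
                raise ValidationError(f"missing entries for subjects: {bad}")
            rounded = np.rint(self.scores)
            if not np.allclose(self.scores, rounded):
                raise ValidationError("scores must be integers")
            self.scores = rounded.astype(np.int64)
        if self.scores.min() < MIN_SCORE or self.scores.max() > MAX_SCORE:
            raise ValidationError(
                f"scores must lie in [{MIN_SCORE}, {MAX_SCORE}]"
            )

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "subject_id"
                       ) -> "SymptomMatrix":
        if id_column in df.columns:
            ids = df[id_column].tolist()
            items = [c for c in df.columns if c != id_column]
        else:
            ids = [str(i) for i in df.index]
            items = list(df.columns)
        return cls(ids, df[items].to_numpy(), tuple(items))

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(self.scores, columns=list(self.item_names))
        out.insert(0, "subject_id", self.subject_ids)
        return out

    @classmethod
    def from_csv(cls, path) -> "SymptomMatrix":
        return cls.from_dataframe(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def item_sum(self) -> np.ndarray:
        """Plain sum of item scores per subject (severity proxy)."""
        return self.scores.sum(axis=1)


@dataclass
class ScaledMatrix:
    """Column-standardized symptom matrix in clustering space."""

    values: np.ndarray
    item_means: np.ndarray
    item_sds: np.ndarray
    item_names: tuple[str, ...]
    subject_ids: list[str]
    dropped_items: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def unscale(self) -> np.ndarray:
        """Map standardized values back to the raw score scale."""
        return self.values * self.item_sds + self.item_means


@dataclass
class EndorsementProfile:
    """Per-subtype symptom endorsement percentages (radar-plot rows)."""

    subtype: str
    percentages: dict[str, float]
    threshold: int
    n_subjects: int


def scale_items(matrix: SymptomMatrix,
                zero_variance_policy: str = "drop") -> ScaledMatrix:
    """Standardize each item column to mean 0, sample sd 1.

    Uses the n-1 (sample) standard deviation.  Columns with zero variance are
    either dropped with a warning (``zero_variance_policy="drop"``) or raise
    (``"error"``), since a constant item carries no clustering information and
    cannot be standardized.
    """
    if zero_variance_policy not in ("drop", "error"):
        raise ValueError(f"unknown zero_variance_policy {zero_variance_policy!r}")
    x = matrix.scores.astype(float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero = sds == 0.0
    if zero.any():
        names = [matrix.item_names[i] for i in np.nonzero(zero)[0]]
        if zero_variance_policy == "error":
            raise ValidationError(f"zero-variance items: {names}")
        warnings.warn(
            f"dropping zero-variance items: {names}", UserWarning, stacklevel=2
        )
    keep = ~zero
    values = (x[:, keep] - means[keep]) / sds[keep]
    return ScaledMatrix(
        values=values,
        item_means=means[keep],
        item_sds=sds[keep],
        item_names=tuple(n for n, k in zip(matrix.item_names, keep) if k),
        subject_ids=list(matrix.subject_ids),
        dropped_items=tuple(
            n for n, k in zip(matrix.item_names, keep) if not k
        ),
    )


def endorsement_profiles(matrix: SymptomMatrix, labels,
                         threshold: int = 1) -> list[EndorsementProfile]:
    """Percentage of subjects per subtype scoring >= ``threshold`` per item.

    ``labels`` may be a sequence aligned with ``matrix.subject_ids`` or a
    mapping subject_id -> subtype.
    """
    if threshold not in (1, 2, 3):
        raise ValueError("threshold must be 1, 2 or 3")
    if isinstance(labels, dict):
        unknown = set(labels) - set(matrix.subject_ids)
        if unknown:
            raise ValidationError(f"labels for unknown subjects: {sorted(unknown)}")
        lab = np.asarray([labels[s] for s in matrix.subject_ids])
    else:
        lab = np.asarray(list(labels))
        if lab.shape[0] != matrix.n_subjects:
            raise ValidationError(
                f"{lab.shape[0]} labels for {matrix.n_subjects} subjects"
            )
    profiles = []
    for subtype in sorted(map(str, np.unique(lab.astype(str)))):
        mask = lab.astype(str) == subtype
        endorsed = (matrix.scores[mask] >= threshold).mean(axis=0) * 100.0
        profiles.append(
            EndorsementProfile(
                subtype=subtype,
                percentages=dict(zip(matrix.item_names, endorsed.tolist())),
                threshold=threshold,
                n_subjects=int(mask.sum()),
            )
        )
    return profiles


def profiles_to_frame(profiles: list[EndorsementProfile]) -> pd.DataFrame:
    """Tidy (subtype, item, percent) table for plotting or export."""
    rows = [
        {"subtype": p.subtype, "item": item, "percent": pct}
        for p in profiles
        for item, pct in p.percentages.items()
    ]
    return pd.DataFrame(rows)
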