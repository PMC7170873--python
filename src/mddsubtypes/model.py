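"""Model/Results interface over the subtyping pipeline.

`SymptomSubtypeModel` is constructed from a subjects x items table and owns
the scaled clustering space; `fit()` runs k selection (unless k is given) and
maximin-seeded k-means, returning a `SubtypeResults` object that carries the
solution and exposes the downstream analyses — endorsement profiles,
subsample stability, and the permutation test of the cluster-validity index.
`RoiComparisonModel` wraps the covariate-adjusted ROI group comparison the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import groupstats, kselect, prep, stability
from .cluster import ClusterSolution, kmeans
from .items import ROI_NAMES


class SymptomSubtypeModel:
    """Symptom-based subtyping of a cohort's ordinal item scores.

    Parameters
    ----------
    matrix
        A :class:`~mddsubtypes.prep.SymptomMatrix`.
    zero_variance_policy
        Passed to :func:`~mddsubtypes.prep.scale_items`.
    """

    def __init__(self, matrix: prep.SymptomMatrix,
                 zero_variance_policy: str = "drop"):
        self.matrix = matrix
        self.scaled = prep.scale_items(matrix, zero_variance_policy)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, id_column: str = "subject_id",
                       **kwargs) -> "SymptomSubtypeModel":
        return cls(prep.SymptomMatrix.from_dataframe(df, id_column), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SymptomSubtypeModel":
        return cls(prep.SymptomMatrix.from_csv(path), **kwargs)

    def select_k(self, k_range: tuple[int, int] = (2, 6),
                 battery=kselect.DEFAULT_BATTERY,
                 clusterer: str = "ward") -> kselect.KSelectionReport:
        """Validity-index vote for the number of clusters."""
        return kselect.select_k(self.scaled.values, k_range, battery,
                                clusterer)

    def fit(self, k: int | None = None, *, k_range: tuple[int, int] = (2, 6),
            seed: int = 0, refine_first: bool = False,
            **kmeans_kwargs) -> "SubtypeResults":
        """Cluster the cohort; choose k by index vote when not given."""
        k_report = None
        if k is None:
            k_report = self.select_k(k_range)
            k = k_report.chosen_k
        solution = kmeans(self.scaled.values, k, seed=seed,
                          refine_first=refine_first, **kmeans_kwargs)
        return SubtypeResults(model=self, solution=solution,
                              k_report=k_report)


@dataclass
class SubtypeResults:
    """A fitted subtype solution plus its validity/stability analyses."""

    model: SymptomSubtypeModel
    solution: ClusterSolution
    k_report: kselect.KSelectionReport | None = None
    _cached: dict = field(default_factory=dict, repr=False)

    @property
    def k(self) -> int:
        return self.solution.k

    @property
    def labels_(self) -> np.ndarray:
        return self.solution.labels

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.model.scaled.subject_ids,
            "cluster": self.labels_,
        })

    def centroids_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": c, "item": item, "value": v}
            for c, row in enumerate(self.solution.centroids)
            for item, v in zip(self.model.scaled.item_names, row)
        ]
        return pd.DataFrame(rows)

    def endorsement_profiles(self, threshold: int = 1
                             ) -> list[prep.EndorsementProfile]:
        return prep.endorsement_profiles(self.model.matrix, self.labels_,
                                         threshold)

    def stability(self, config: stability.StabilityConfig | None = None,
                  **kwargs) -> stability.StabilityReport:
        """Subsample/LDA-reassignment stability against this solution."""
        if config is None:
            kwargs.setdefault("k", self.k)
            config = stability.StabilityConfig(**kwargs)
        return stability.run_stability(self.model.scaled.values,
                                       self.solution, config)

    def permutation_test(self, index_name: str = "scott",
                         n_perm: int = 999, seed: int | None = None,
                         clusterer: str = "ward"
                         ) -> kselect.PermutationReport:
        """Permutation null for the validity index at the fitted k."""
        return kselect.permutation_test_index(
            self.model.scaled.values, self.k, index_name, n_perm, seed,
            clusterer,
        )

    def summary(self) -> str:
        sizes = np.bincount(self.labels_, minlength=self.k)
        lines = [
            "Symptom subtype solution",
            "=" * 40,
            f"subjects: {self.model.scaled.n_subjects}    items: "
            f"{len(self.model.scaled.item_names)}",
            f"k: {self.k}    within-SS: {self.solution.within_ss:.4f}    "
            f"iterations: {self.solution.n_iter}",
            "cluster sizes: " + ", ".join(
                f"{i}: {s}" for i, s in enumerate(sizes)),
        ]
        if self.model.scaled.dropped_items:
            lines.append("dropped zero-variance items: "
                         + ", ".join(self.model.scaled.dropped_items))
        if self.k_report is not None:
            kr = self.k_report
            lines.append(
                f"k vote over {kr.k_range}: "
                + ", ".join(f"k={k}: {c}" for k, c in kr.vote_counts.items())
                + (" (tie broken toward smaller k)" if kr.tie_broken else "")
            )
            if kr.degenerate_indices:
                lines.append("degenerate indices: "
                             + ", ".join(kr.degenerate_indices))
        return "\n".join(lines)


class RoiComparisonModel:
    """Covariate-adjusted group comparison of ROI measures.

    Expects a table with columns subject_id, group, age, sex, icv and the 13
    ROI measures.
    """

    def __init__(self, table: pd.DataFrame, roi_names=ROI_NAMES):
        missing = [c for c in ("group", "age", "sex", "icv") +
                   tuple(roi_names) if c not in table.columns]
        if missing:
            raise prep.ValidationError(f"ROI table missing columns: {missing}")
        self.table = table
        self.roi_names = tuple(roi_names)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RoiComparisonModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, fdr_gate: float = 0.05) -> "RoiComparisonResults":
        results = groupstats.run_roi_analysis(self.table, self.roi_names,
                                              fdr_gate)
        return RoiComparisonResults(model=self, results=results,
                                    fdr_gate=fdr_gate)


@dataclass
class RoiComparisonResults:
    model: RoiComparisonModel
    results: list[groupstats.RoiGroupResult]
    fdr_gate: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return groupstats.roi_results_to_frame(self.results)

    def significant(self) -> list[groupstats.RoiGroupResult]:
        return [r for r in self.results if r.p_fdr is not None
                and r.p_fdr < self.fdr_gate]

    def summary(self) -> str:
        df = self.to_frame()
        cols = ["roi", "F", "p_raw", "p_fdr"]
        lines = [
            "ROI group comparison (ANCOVA, BH-FDR over "
            f"{len(self.results)} measures)",
            "=" * 60,
            df[cols].to_string(index=False,
                               float_format=lambda v: f"{v:.4f}"),
        ]
        for r in self.significant():
            lines.append(f"post hoc ({r.roi_name}): " + "; ".join(
                f"{a} vs {b}: p={p:.4f}"
                for (a, b), p in sorted(r.posthoc.items())
            ))
        return "\n".join(lines)
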