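"""End-to-end pipeline: scale -> select k -> cluster -> stability ->
permutation -> profiles -> (optional) ROI statistics, with a config snapshot
and per-stage logging so a run directory is exactly reproducible."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kselect, prep, stability
from .model import RoiComparisonModel, SymptomSubtypeModel


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    symptom_table: str
    output_dir: str
    roi_table: str | None = None
    k: int | None = None
    k_range: tuple[int, int] = (2, 6)
    battery: tuple[str, ...] = kselect.DEFAULT_BATTERY
    endorsement_threshold: int = 1
    stability_n_reps: int = 500
    stability_subsample: int = 100
    stability_train_fraction: float = 0.70
    permutation_index: str = "scott"
    n_perm: int = 199
    fdr_gate: float = 0.05
    subset_filter_column: str | None = None
    subset_filter_value: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise prep.ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in doc:
            doc["k_range"] = tuple(doc["k_range"])
        if "battery" in doc:
            doc["battery"] = tuple(doc["battery"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["k_range"] = list(self.k_range)
        doc["battery"] = list(self.battery)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def log(self, msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"[{stamp}] {msg}")
        self.path.write_text("\n".join(self.lines) + "\n")


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage, writing all artifacts into the run directory.

    Stage errors abort the run with a stage-named message; partial outputs
    are retained next to a FAILED marker.  Re-running with the same config is
    byte-identical for label outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log = _RunLog(out / "run.log")
    stage = "load"
    try:
        df = pd.read_csv(config.symptom_table)
        if config.subset_filter_column:
            before = len(df)
            df = df[df[config.subset_filter_column].astype(str)
                    == str(config.subset_filter_value)]
            log.log(f"subset filter {config.subset_filter_column}="
                    f"{config.subset_filter_value}: {before} -> {len(df)} "
                    "subjects")
            df = df.drop(columns=[config.subset_filter_column])
        model = SymptomSubtypeModel.from_dataframe(df)
        if model.scaled.dropped_items:
            log.log("dropped zero-variance items: "
                    + ", ".join(model.scaled.dropped_items))
        log.log(f"loaded {model.scaled.n_subjects} subjects, "
                f"{len(model.scaled.item_names)} items")

        stage = "select_k"
        results = model.fit(k=config.k, k_range=config.k_range,
                            seed=config.seed)
        if results.k_report is not None:
            kdf = pd.DataFrame([
                {"index": iv.index_name, "k": iv.k, "value": iv.value,
                 "degenerate": iv.degenerate,
                 "best_k": results.k_report.votes.get(iv.index_name)}
                for iv in results.k_report.index_values
            ])
            kdf.to_csv(out / "k_selection.csv", index=False)
            log.log(f"k vote: {results.k_report.vote_counts} -> "
                    f"k={results.k}")
        else:
            log.log(f"k fixed by config: k={results.k}")

        stage = "cluster"
        results.labels_frame().to_csv(out / "labels.csv", index=False)
        results.centroids_frame().to_csv(out / "centroids.csv", index=False)
        log.log(f"k-means (seed {config.seed}): within-SS "
                f"{results.solution.within_ss:.6f}")

        stage = "stability"
        subsample = min(config.stability_subsample,
                        int(config.stability_train_fraction
                            * model.scaled.n_subjects))
        rep = results.stability(config=stability.StabilityConfig(
            n_reps=config.stability_n_reps,
            subsample_size=subsample,
            train_fraction=config.stability_train_fraction,
            k=results.k,
            seed=config.seed + 1,
        ))
        pd.DataFrame({
            "replicate": np.arange(rep.adjusted_rand.size),
            "adjusted_rand": rep.adjusted_rand,
            "cluster_to_cluster": rep.cluster_to_cluster,
        }).to_csv(out / "stability.csv", index=False)
        log.log(f"stability: mean ARI {rep.mean_ari:.4f}, mean "
                f"cluster-to-cluster {rep.mean_c2c:.4f}, "
                f"{rep.n_skipped} replicates skipped")

        stage = "permutation"
        perm = results.permutation_test(config.permutation_index,
                                        config.n_perm,
                                        seed=config.seed + 2)
        pd.DataFrame({"null_value": perm.null_values}).to_csv(
            out / "permutation_null.csv", index=False)
        log.log(f"permutation ({perm.index_name}, k={perm.k}): observed "
                f"{perm.observed:.4f}, p={perm.p_value:.4f}")

        stage = "profiles"
        profiles = results.endorsement_profiles(config.endorsement_threshold)
        prep.profiles_to_frame(profiles).to_csv(out / "profiles.csv",
                                                index=False)

        stage = "roi_stats"
        if config.roi_table:
            roi = RoiComparisonModel.from_csv(config.roi_table)
            fit = roi.fit(config.fdr_gate)
            fit.to_frame().to_csv(out / "roi_stats.csv", index=False)
            log.log(f"ROI stats: {len(fit.significant())} of "
                    f"{len(fit.results)} measures pass FDR "
                    f"{config.fdr_gate}")
        else:
            log.log("no ROI table configured; ROI stage skipped")

        stage = "report"
        (out / "summary.txt").write_text(
            results.summary() + "\n\n"
            + f"stability mean ARI: {rep.mean_ari:.4f}\n"
            + f"stability mean cluster-to-cluster: {rep.mean_c2c:.4f}\n"
            + f"permutation {perm.index_name} p-value: {perm.p_value:.4f}\n"
        )
        (out / "provenance.json").write_text(json.dumps({
            "seed": config.seed,
            "stages": ["scale", "select_k", "cluster", "stability",
                       "permutation", "profiles", "roi_stats", "report"],
        }, indent=2))
        log.log("run complete")
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        log.log(f"FAILED at stage {stage}: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
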