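"""CSV interchange, pipeline configuration and the end-to-end driver.

Interchange dialect: comma-separated UTF-8 with a header row and "."
decimals; times in hours relative to administration, retention times in
minutes, masses in Da. The feature table is tidy (one row per feature ×
sample) and joins to a sample-metadata table on ``sample_id``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import annotate_features, build_family_graph
from .eia import attribute_fraction_activity, default_crossreactivity, rank_assays
from .screen import FeatureTimecourse, ScreenConfig, screen_study
from .simulate import SimulationConfig, simulate_fraction_study, simulate_study

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "read_feature_table",
    "write_feature_table",
    "timecourses_from_frames",
    "features_by_animal",
    "run_pipeline",
]

log = logging.getLogger("fcmid")

FEATURE_COLUMNS = ["feature_id", "mass", "rt", "polarity", "sample_id", "intensity"]
META_COLUMNS = ["sample_id", "animal", "time_h", "epoch"]


class PipelineError(RuntimeError):
    """A stage failure with the stage name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths, thresholds and nested configs for a full run."""

    out_dir: str = "fcmid_out"
    features_csv: str | None = None
    metadata_csv: str | None = None
    simulate: bool = True
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    ppm_tol: float = 10.0
    rt_tol_min: float = 0.15
    rt_mode: str | None = "rp"
    residual_fraction: float = 0.2
    cr_floor_pct: float = 1.0
    simulation: SimulationConfig | None = None
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "screen" in data:
            data["screen"] = ScreenConfig(**data["screen"])
        if data.get("simulation") is not None:
            sim = data["simulation"]
            sim = {k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            data["simulation"] = SimulationConfig(**sim)
        return cls(**data)

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_feature_table(features: pd.DataFrame, metadata: pd.DataFrame,
                        features_path, metadata_path) -> None:
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    missing = set(META_COLUMNS) - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    features[FEATURE_COLUMNS].to_csv(features_path, index=False)
    metadata[META_COLUMNS].to_csv(metadata_path, index=False)


def read_feature_table(features_path, metadata_path) -> list[FeatureTimecourse]:
    """Read and validate the tidy feature table + metadata pair.

    Raises on missing columns (naming the column), non-numeric intensities
    (naming the row), sample ids absent from the metadata, and BC/AC
    labels inconsistent with the sign of the collection time.
    """
    features = pd.read_csv(features_path)
    metadata = pd.read_csv(metadata_path)
    for col in FEATURE_COLUMNS:
        if col not in features.columns:
            raise ValueError(f"feature table missing column: {col!r}")
    for col in META_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"metadata missing column: {col!r}")
    intens = pd.to_numeric(features["intensity"], errors="coerce")
    bad = intens.isna() & features["intensity"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-numeric intensity at feature-table row {row + 2}")
    features["intensity"] = intens

    expected = np.where(metadata["time_h"] < 0, "BC", "AC")
    mismatch = metadata["epoch"].to_numpy() != expected
    if mismatch.any():
        sid = metadata.loc[np.flatnonzero(mismatch)[0], "sample_id"]
        raise ValueError(f"epoch label inconsistent with time sign for sample {sid!r}")
    unknown = set(features["sample_id"]) - set(metadata["sample_id"])
    if unknown:
        raise ValueError(f"unknown sample ids in feature table: {sorted(unknown)[:5]}")

    return timecourses_from_frames(features, metadata)


def timecourses_from_frames(features: pd.DataFrame, metadata: pd.DataFrame) -> list[FeatureTimecourse]:
    """Join a tidy feature table with sample metadata into timecourses.

    Each feature must live entirely within one animal's samples (animals
    are acquired and processed independently).
    """
    sample_animal = metadata.set_index("sample_id")["animal"]
    n_animals = features["sample_id"].map(sample_animal).groupby(features["feature_id"]).nunique()
    multi = n_animals[n_animals > 1]
    if len(multi):
        raise ValueError(f"feature {multi.index[0]!r} spans multiple animals")

    wide = features.pivot(index="feature_id", columns="sample_id", values="intensity")
    info = features.drop_duplicates("feature_id").set_index("feature_id")
    out: list[FeatureTimecourse] = []
    for animal, meta_a in metadata.groupby("animal", sort=True):
        meta_a = meta_a.sort_values("time_h")
        cols = meta_a["sample_id"].tolist()
        sub = wide.reindex(columns=cols)
        present = sub.notna().all(axis=1)
        times = meta_a["time_h"].to_numpy(dtype=float)
        block = sub.loc[present].to_numpy(dtype=float)
        for fid, intensities in zip(sub.index[present], block):
            row = info.loc[fid]
            out.append(FeatureTimecourse(
                feature_id=str(fid),
                neutral_mass=float(row["mass"]),
                retention_time=float(row["rt"]),
                polarity=str(row["polarity"]),
                times=times,
                intensities=intensities,
                animal=str(animal),
            ))
    out.sort(key=lambda f: f.feature_id)
    return out


def features_by_animal(features: Sequence[FeatureTimecourse]) -> dict[str, list[FeatureTimecourse]]:
    grouped: dict[str, list[FeatureTimecourse]] = {}
    for f in features:
        grouped.setdefault(f.animal, []).append(f)
    return grouped


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute simulate → screen → annotate → deconvolve → rank.

    Writes every report to ``config.out_dir`` and returns the in-memory
    bundle. Deterministic under a fixed seed. Each excluded feature is
    logged with the rule that excluded it.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, object] = {}

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate or config.features_csv is None:
            sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
            study = simulate_study(sim_cfg)
            write_feature_table(study.features, study.metadata,
                                out / "features.csv", out / "samples.csv")
            study.eia_series.to_csv(out / "eia_series.csv", index=False)
            study.truth.to_csv(out / "feature_truth.csv", index=False)
            feats = read_feature_table(out / "features.csv", out / "samples.csv")
            bundle["study"] = study
        else:
            sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
            feats = read_feature_table(config.features_csv, config.metadata_csv)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # --- screen -----------------------------------------------------------
    try:
        grouped = features_by_animal(feats)
        reports, intersection = screen_study(grouped, config.screen)
        for animal, rep in reports.items():
            rep.to_csv(out / f"screen_{animal}.csv", index=False)
            for _, row in rep[~rep["retained"]].iterrows():
                log.debug("excluded %s (%s): %s", row["feature_id"], animal, row["reason"])
        intersection.to_csv(out / "screen_intersection.csv", index=False)
        bundle["screen_reports"] = reports
        bundle["intersection"] = intersection
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    # --- annotate ---------------------------------------------------------
    try:
        retained = [
            f for f in feats
            if f.feature_id in set(
                pd.concat([rep[rep["retained"]]["feature_id"] for rep in reports.values()])
            )
        ] if reports else []
        annotations = annotate_features(
            retained, tol_ppm=config.ppm_tol,
            rt_tol_min=config.rt_tol_min, rt_mode=config.rt_mode,
        )
        annotations.to_csv(out / "annotations.csv", index=False)
        graph = build_family_graph(
            {row["group_id"]: row["mean_mass"] for _, row in intersection.iterrows()},
            tol_ppm=config.ppm_tol,
        ) if len(intersection) else None
        bundle["annotations"] = annotations
        bundle["family_graph"] = graph
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc

    # --- deconvolve + rank (simulated fraction study) ----------------------
    if config.simulate or config.features_csv is None:
        try:
            matrix = default_crossreactivity()
            fractions = simulate_fraction_study(sim_cfg)
            attributions: dict[str, dict] = {}
            for animal, series in fractions.items():
                attributions[animal] = {}
                for assay in matrix.assays:
                    result = attribute_fraction_activity(
                        series, matrix, assay,
                        cr_floor_pct=config.cr_floor_pct,
                        residual_fraction=config.residual_fraction,
                    )
                    result.table.to_csv(out / f"attribution_{animal}_{assay}.csv", index=False)
                    attributions[animal][assay] = result
            ranking = rank_assays(attributions)
            ranking.to_csv(out / "assay_ranking.csv", index=False)
            bundle["attributions"] = attributions
            bundle["ranking"] = ranking
        except Exception as exc:
            raise PipelineError("deconvolve", str(exc)) from exc

    return bundle
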