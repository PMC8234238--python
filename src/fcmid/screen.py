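"""Baseline-vs-challenge screening of untargeted LC-MS feature time courses.

A feature is a candidate administration-induced metabolite when (1) its
maximum intensity after administration is at least ``fold_threshold`` times
the highest pre-administration sample (with a detection floor standing in
for an all-zero baseline), and (2) its elevation is sustained — the longest
run of consecutive high post-administration samples reaches ``min_run`` —
so single-sample spikes from chemical noise or integration artifacts are
excluded. Retained features are further classified kinetically: an
early-peaking, rapidly declining profile is parent-drug-like; a delayed
broad profile is metabolite-like. Because animals are analysed
independently, screening is per animal with a final intersection step that
pairs features across animals by mass (ppm tolerance) and polarity.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTimecourse",
    "ScreenConfig",
    "KineticClass",
    "ScreenDecision",
    "normalize_timecourse",
    "baseline_fold_filter",
    "consecutive_run_filter",
    "classify_kinetics",
    "profile_correlation",
    "screen_animal",
    "intersect_animals",
    "screen_study",
]


@dataclass(frozen=True)
class FeatureTimecourse:
    """One untargeted LC-MS feature observed over the sampling window.

    Times are hours relative to administration at t = 0; samples before
    administration (t < 0) form the BC epoch, samples after form AC.
    """

    feature_id: str
    neutral_mass: float
    retention_time: float
    polarity: str  # "positive" | "negative"
    times: np.ndarray
    intensities: np.ndarray
    animal: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.intensities, dtype=float)
        if t.shape != v.shape:
            raise ValueError(f"{self.feature_id}: times/intensities length mismatch")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.feature_id}: sample times must be strictly increasing")
        if (v < 0).any():
            raise ValueError(f"{self.feature_id}: negative intensity")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"{self.feature_id}: bad polarity {self.polarity!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", v)

    @property
    def bc_mask(self) -> np.ndarray:
        return self.times < 0

    @property
    def ac_mask(self) -> np.ndarray:
        return self.times > 0


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the two-stage screen.

    fold_threshold: AC max must exceed this multiple of the BC max.
    baseline_floor: stand-in for an all-(near-)zero baseline; if None it is
        set to 1% of the median nonzero intensity of the feature table.
    min_run: minimum number of consecutive high AC samples.
    high_fraction: a sample is "high" at this fraction of the AC maximum.
    intersect_ppm: mass tolerance for pairing features across animals.
    """

    fold_threshold: float = 10.0
    baseline_floor: float | None = None
    min_run: int = 3
    high_fraction: float = 0.5
    intersect_ppm: float = 10.0

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.min_run < 2:
            raise ValueError("min_run must be at least 2")
        if not 0 < self.high_fraction < 1:
            raise ValueError("high_fraction must be in (0, 1)")


@dataclass(frozen=True)
class KineticClass:
    label: str  # "parent-like" | "metabolite-like" | "unclassified"
    peak_time: float
    onset_time: float | None = None


@dataclass
class ScreenDecision:
    feature_id: str
    retained: bool
    reason: str
    fold: float = float("nan")
    run_length: int = 0
    kinetic: str = ""


def normalize_timecourse(f: FeatureTimecourse) -> FeatureTimecourse:
    """Scale intensities to the series maximum (max becomes 1)."""
    peak = f.intensities.max() if len(f.intensities) else 0.0
    if peak <= 0:
        raise ValueError(f"{f.feature_id}: cannot normalize all-zero series")
    return replace(f, intensities=f.intensities / peak)


def resolve_floor(features: Iterable[FeatureTimecourse], config: ScreenConfig) -> float:
    """Detection floor: configured value, else 1% of the table's median
    nonzero intensity (a literal fold change over zero is always true)."""
    if config.baseline_floor is not None:
        return config.baseline_floor
    nonzero = np.concatenate(
        [f.intensities[f.intensities > 0] for f in features] or [np.array([1.0])]
    )
    if len(nonzero) == 0:
        return 1.0
    return 0.01 * float(np.median(nonzero))


def baseline_fold_filter(
    features: Sequence[FeatureTimecourse], config: ScreenConfig, floor: float | None = None
) -> list[ScreenDecision]:
    """Retain features whose AC maximum is ≥ fold_threshold × the BC
    maximum (or the detection floor when the baseline is below it)."""
    if floor is None:
        floor = resolve_floor(features, config)
    decisions = []
    for f in features:
        ac = f.intensities[f.ac_mask]
        if ac.size == 0:
            decisions.append(ScreenDecision(f.feature_id, False, "no-ac-samples"))
            continue
        bc = f.intensities[f.bc_mask]
        baseline = max(bc.max() if bc.size else 0.0, floor)
        fold = ac.max() / baseline
        retained = ac.max() >= config.fold_threshold * baseline
        reason = "fold-ok" if retained else "below-fold-threshold"
        decisions.append(ScreenDecision(f.feature_id, retained, reason, fold=fold))
    return decisions


def _longest_high_run(ac: np.ndarray, high_fraction: float) -> int:
    if ac.size == 0 or ac.max() <= 0:
        return 0
    high = ac >= high_fraction * ac.max()
    best = run = 0
    for h in high:
        run = run + 1 if h else 0
        best = max(best, run)
    return best


def consecutive_run_filter(
    features: Sequence[FeatureTimecourse], config: ScreenConfig
) -> list[ScreenDecision]:
    """Exclude features whose elevation is not sustained: the longest run
    of consecutive high AC samples (≥ high_fraction × AC max) must reach
    min_run."""
    decisions = []
    for f in features:
        run = _longest_high_run(f.intensities[f.ac_mask], config.high_fraction)
        retained = run >= config.min_run
        reason = "run-ok" if retained else "non-consecutive-high-values"
        decisions.append(ScreenDecision(f.feature_id, retained, reason, run_length=run))
    return decisions


def classify_kinetics(
    f: FeatureTimecourse,
    injection_time: float = 0.0,
    high_fraction: float = 0.5,
    centroid_delay_h: float = 10.0,
) -> KineticClass:
    """Classify a retained feature's AC profile.

    Both classes must decline (mean of the final quarter of the window
    below 10% of the maximum) — a profile still elevated at the end of the
    window is unclassifiable. The discriminator is the intensity-weighted
    centroid of the high (≥ ``high_fraction`` × max) region: metabolite
    formation and gut transit delay excretion by several hours, so a
    centroid at or beyond ``centroid_delay_h`` is metabolite-like, while a
    parent-like compound spills into the earliest collections and keeps
    its centroid short of it. The centroid is used instead of the raw
    argmax because it averages over every elevated sample and is far less
    sensitive to single-sample intensity noise.
    """
    ac = f.ac_mask
    t = f.times[ac] - injection_time
    v = f.intensities[ac]
    if v.size == 0 or v.max() <= 0:
        return KineticClass("unclassified", float("nan"))
    v = v / v.max()
    window = float(t[-1]) if t[-1] > 0 else 1.0
    peak_time = float(t[int(np.argmax(v))])
    high = v >= high_fraction
    if not high.any():
        return KineticClass("unclassified", peak_time)
    onset_time = float(t[int(np.argmax(high))])
    centroid = float(np.sum(t[high] * v[high]) / np.sum(v[high]))
    terminal = v[t >= 0.75 * window]
    declined = terminal.size > 0 and float(terminal.mean()) < 0.10
    if not declined:
        return KineticClass("unclassified", peak_time, onset_time)
    if centroid >= centroid_delay_h:
        return KineticClass("metabolite-like", peak_time, onset_time)
    if peak_time <= 0.25 * window:
        return KineticClass("parent-like", peak_time, onset_time)
    return KineticClass("unclassified", peak_time, onset_time)


def profile_correlation(
    f: FeatureTimecourse,
    ref_times: np.ndarray,
    ref_values: np.ndarray,
    time_tol: float = 1e-6,
) -> tuple[float, int]:
    """Pearson correlation between a feature and a reference series on
    their shared sample times. Returns (r, n_shared); r is NaN when fewer
    than 3 points are shared."""
    ref_times = np.asarray(ref_times, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    idx_f, idx_r = [], []
    j = 0
    for i, t in enumerate(f.times):
        while j < len(ref_times) and ref_times[j] < t - time_tol:
            j += 1
        if j < len(ref_times) and abs(ref_times[j] - t) <= time_tol:
            idx_f.append(i)
            idx_r.append(j)
            j += 1
    n = len(idx_f)
    if n < 3:
        return float("nan"), n
    a = f.intensities[idx_f]
    b = ref_values[idx_r]
    if a.std() == 0 or b.std() == 0:
        return float("nan"), n
    return float(np.corrcoef(a, b)[0, 1]), n


# ---------------------------------------------------------------------------
# Per-animal screen and cross-animal intersection
# ---------------------------------------------------------------------------

def screen_animal(
    features: Sequence[FeatureTimecourse],
    config: ScreenConfig | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """Run the two-stage screen on one animal's features.

    Returns a per-feature report with the realized fold value, the longest
    high run, the kinetic class of retained features, and the rule that
    excluded the rest.
    """
    if config is None:
        config = ScreenConfig()
    if floor is None:
        floor = resolve_floor(features, config)
    fold = {d.feature_id: d for d in baseline_fold_filter(features, config, floor)}
    runs = {d.feature_id: d for d in consecutive_run_filter(features, config)}
    rows = []
    for f in features:
        df, dr = fold[f.feature_id], runs[f.feature_id]
        retained = df.retained and dr.retained
        if df.retained and dr.retained:
            reason = "retained"
        elif not df.retained:
            reason = df.reason
        else:
            reason = dr.reason
        kinetic = classify_kinetics(f, high_fraction=config.high_fraction).label if retained else ""
        rows.append({
            "feature_id": f.feature_id,
            "animal": f.animal,
            "neutral_mass": f.neutral_mass,
            "rt_min": f.retention_time,
            "polarity": f.polarity,
            "retained": retained,
            "reason": reason,
            "fold": df.fold,
            "run_length": dr.run_length,
            "kinetic_class": kinetic,
        })
    return pd.DataFrame(rows)


def intersect_animals(
    reports: Mapping[str, pd.DataFrame],
    ppm_tol: float = 10.0,
) -> pd.DataFrame:
    """Features retained in every animal, paired by mass and polarity.

    Retention times may differ between runs, so the pairing key is mass
    within ``ppm_tol`` (greedy nearest-mass matching) plus identical
    polarity. Returns one row per matched group with per-animal feature
    ids and the mean mass.
    """
    animals = sorted(reports)
    if not animals:
        return pd.DataFrame(columns=["group_id", "mean_mass", "polarity"])
    base = reports[animals[0]]
    retained0 = base[base["retained"]]
    groups = []
    for _, row in retained0.iterrows():
        group = {animals[0]: row}
        for animal in animals[1:]:
            rep = reports[animal]
            cand = rep[
                rep["retained"]
                & (rep["polarity"] == row["polarity"])
            ].copy()
            if cand.empty:
                group = None
                break
            ppm = (cand["neutral_mass"] - row["neutral_mass"]).abs() / row["neutral_mass"] * 1e6
            cand = cand[ppm <= ppm_tol]
            if cand.empty:
                group = None
                break
            best = (cand["neutral_mass"] - row["neutral_mass"]).abs().idxmin()
            group[animal] = cand.loc[best]
        if group is not None:
            groups.append(group)
    rows = []
    for gid, group in enumerate(groups):
        masses = [g["neutral_mass"] for g in group.values()]
        row = {
            "group_id": gid,
            "mean_mass": float(np.mean(masses)),
            "polarity": group[animals[0]]["polarity"],
        }
        for animal in animals:
            row[f"feature_{animal}"] = group[animal]["feature_id"]
            row[f"kinetic_{animal}"] = group[animal]["kinetic_class"]
        rows.append(row)
    return pd.DataFrame(rows)


def screen_study(
    features_by_animal: Mapping[str, Sequence[FeatureTimecourse]],
    config: ScreenConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-animal screens plus the cross-animal intersection."""
    if config is None:
        config = ScreenConfig()
    reports = {
        animal: screen_animal(feats, config)
        for animal, feats in features_by_animal.items()
    }
    return reports, intersect_animals(reports, config.intersect_ppm)
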