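"""Enzyme-immunoassay cross-reactivity modelling and attribution.

An EIA reports a relative concentration: the signal is a cross-reactivity-
weighted sum over every metabolite the antibody recognises, expressed in
equivalents of the assay's own calibration standard. This module provides
the forward model (predict_response), a per-fraction non-negative
least-squares inversion that attributes HPLC-fraction immunoreactivity to
co-eluting metabolites seen by LC-MS (deconvolve_fractions), explicit
flagging of activity that no candidate can explain, and a ranking of
assays by cross-animal consistency of the metabolite each one detects.

Cross-reactivity cells reported only as upper bounds ("<0.001") are kept
as bounds for reporting but contribute zero to predictions: a compound
with negligible cross-reactivity cannot absorb assay signal, which is
exactly the reasoning that excludes near-identical stereoisomers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CrossReactivityMatrix",
    "FractionSeries",
    "AttributionResult",
    "default_crossreactivity",
    "predict_response",
    "deconvolve_fractions",
    "attribute_fraction_activity",
    "rank_assays",
]


class CrossReactivityMatrix:
    """Assay × compound percentage responses relative to each assay's standard.

    ``values`` holds numeric percentages with bound-only cells ("<x") set
    to zero; ``bounds`` flags those cells and ``bound_values`` retains the
    printed bound for reporting.
    """

    def __init__(self, values: pd.DataFrame, bounds: pd.DataFrame | None = None,
                 bound_values: pd.DataFrame | None = None):
        if (values.to_numpy() < 0).any():
            raise ValueError("cross-reactivities must be non-negative")
        self.values = values.astype(float)
        self.bounds = (
            bounds.astype(bool)
            if bounds is not None
            else pd.DataFrame(False, index=values.index, columns=values.columns)
        )
        self.bound_values = (
            bound_values.astype(float)
            if bound_values is not None
            else pd.DataFrame(np.nan, index=values.index, columns=values.columns)
        )

    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    def response_pct(self, assay: str, compound: str) -> float:
        """Numeric cross-reactivity used in prediction (bounds → 0)."""
        return float(self.values.loc[assay, compound])

    @classmethod
    def from_strings(cls, table: Mapping[str, Mapping[str, str | float]]) -> "CrossReactivityMatrix":
        """Build from a nested mapping assay → compound → value, where a
        value may be numeric or a "<x" upper-bound string."""
        assays = list(table)
        compounds = sorted({c for row in table.values() for c in row})
        values = pd.DataFrame(0.0, index=assays, columns=compounds)
        bounds = pd.DataFrame(False, index=assays, columns=compounds)
        bound_values = pd.DataFrame(np.nan, index=assays, columns=compounds)
        for assay, row in table.items():
            for compound, v in row.items():
                if isinstance(v, str) and v.strip().startswith("<"):
                    bounds.loc[assay, compound] = True
                    bound_values.loc[assay, compound] = float(v.strip()[1:])
                else:
                    values.loc[assay, compound] = float(v)
        return cls(values, bounds, bound_values)

    @classmethod
    def from_csv(cls, path) -> "CrossReactivityMatrix":
        """CSV with assay rows, compound columns; "<x" syntax accepted."""
        df = pd.read_csv(path, index_col=0, dtype=str)
        table = {assay: dict(df.loc[assay]) for assay in df.index}
        return cls.from_strings(table)

    def to_csv(self, path) -> None:
        out = self.values.astype(object).copy()
        for assay in self.assays:
            for compound in self.compounds:
                if self.bounds.loc[assay, compound]:
                    out.loc[assay, compound] = f"<{self.bound_values.loc[assay, compound]:g}"
        out.to_csv(path)


def default_crossreactivity() -> CrossReactivityMatrix:
    """The measured cross-reactivities of the cortisol, 50c
    (tetrahydrocorticosterone) and 37e (3β-allotetrahydrocorticosterone)
    EIAs against tetrahydrocortisol isomers and cortolones, plus cortisol
    itself (100% against its own assay by definition)."""
    return CrossReactivityMatrix.from_strings({
        "cortisol": {
            "THF": "<0.001", "allo-THF": 1.4, "3b-THF": 0.1, "3b-allo-THF": 25.0,
            "a-cortolone": "<0.0001", "b-cortolone": "<0.0001", "cortisol": 100.0,
        },
        "50c": {
            "THF": 20.7, "allo-THF": "<0.01", "3b-THF": "<0.001", "3b-allo-THF": "<0.001",
            "a-cortolone": "<0.01", "b-cortolone": "<0.01", "cortisol": 0.0,
        },
        "37e": {
            "THF": "<0.001", "allo-THF": 0.5, "3b-THF": 0.2, "3b-allo-THF": 100.0,
            "a-cortolone": 0.1, "b-cortolone": "<0.001", "cortisol": 0.0,
        },
    })


def predict_response(
    amounts: Mapping[str, float],
    matrix: CrossReactivityMatrix,
    assay: str,
) -> float:
    """Forward model: Σ_m CR[assay, m]/100 × amount_m.

    Linear and homogeneous; amounts are in the assay standard's units so
    the output is a relative response.
    """
    if assay not in matrix.values.index:
        raise ValueError(f"unknown assay: {assay!r}")
    total = 0.0
    for compound, amount in amounts.items():
        if compound not in matrix.values.columns:
            raise ValueError(f"unknown compound: {compound!r}")
        if amount < 0:
            raise ValueError(f"negative amount for {compound!r}")
        total += matrix.response_pct(assay, compound) / 100.0 * amount
    return total


# ---------------------------------------------------------------------------
# Fraction series and deconvolution
# ---------------------------------------------------------------------------

@dataclass
class FractionSeries:
    """Per-HPLC-fraction EIA responses and LC-MS peak areas for one animal.

    ``boundaries`` are contiguous (start, end) minutes; ``eia`` maps assay
    name → response array over fractions; ``areas`` is a fractions ×
    compounds table of LC-MS peak areas.
    """

    animal: str
    boundaries: list[tuple[float, float]]
    eia: dict[str, np.ndarray]
    areas: pd.DataFrame

    def __post_init__(self):
        n = len(self.boundaries)
        for i in range(1, n):
            if not np.isclose(self.boundaries[i][0], self.boundaries[i - 1][1]):
                raise ValueError(f"fraction boundaries not contiguous at index {i}")
        for a, b in self.boundaries:
            if b <= a:
                raise ValueError("fraction end must exceed start")
        for assay, resp in self.eia.items():
            resp = np.asarray(resp, dtype=float)
            if resp.shape != (n,):
                raise ValueError(f"assay {assay}: response length != fraction count")
            self.eia[assay] = resp
        if len(self.areas) != n:
            raise ValueError("areas table length != fraction count")

    @property
    def n_fractions(self) -> int:
        return len(self.boundaries)


@dataclass
class AttributionResult:
    """Outcome of per-fraction NNLS attribution for one assay/animal."""

    animal: str
    assay: str
    table: pd.DataFrame        # fraction, response, predicted, residual, flags
    amounts: pd.DataFrame      # fractions × compounds fitted amounts
    unresolved_groups: list[frozenset] = field(default_factory=list)
    responsible: dict[str, float] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def compound_totals(self) -> pd.Series:
        return self.amounts.sum(axis=0)

    @property
    def unexplained_share(self) -> float:
        """Share of total response sitting in unexplained-flagged fractions."""
        total = self.table["response"].sum()
        if total <= 0:
            return 0.0
        return float(self.table.loc[self.table["unexplained"], "response"].sum() / total)


def deconvolve_fractions(
    series: FractionSeries,
    matrix: CrossReactivityMatrix,
    assay: str,
    residual_fraction: float = 0.2,
    area_floor: float = 0.0,
    rel_area_floor: float = 1e-3,
    cr_merge_rtol: float = 0.01,
) -> AttributionResult:
    """Attribute each fraction's EIA response to co-eluting metabolites.

    Per fraction, the candidate set is the compounds with LC-MS evidence:
    peak area above ``area_floor`` and above ``rel_area_floor`` of that
    compound's maximum area over the series (elution-tail areas are not
    evidence); their amounts are fit by non-negative
    least squares against the observed response with the cross-reactivity
    row as the design. Compounds whose cross-reactivity is zero (including
    bound-only cells) are excluded from the fit — they cannot explain
    signal. Candidates with cross-reactivities equal within
    ``cr_merge_rtol`` are chromatographically/immunologically unresolvable
    and are fit as a merged group, reported in ``unresolved_groups`` rather
    than silently split.

    Fractions whose residual exceeds ``residual_fraction`` × the series
    maximum response are flagged unexplained.
    """
    if assay not in matrix.values.index:
        raise ValueError(f"unknown assay: {assay!r}")
    if assay not in series.eia:
        raise ValueError(f"series has no responses for assay {assay!r}")
    resp = series.eia[assay]
    compounds = [c for c in series.areas.columns if c in matrix.values.columns]
    floors = {
        c: max(area_floor, rel_area_floor * float(series.areas[c].max()))
        for c in compounds
    }
    amounts = pd.DataFrame(0.0, index=series.areas.index, columns=series.areas.columns)
    unresolved: list[frozenset] = []
    rows = []
    threshold = residual_fraction * (resp.max() if len(resp) else 0.0)
    for i, frac_idx in enumerate(series.areas.index):
        observed = float(resp[i])
        present = [c for c in compounds if series.areas.loc[frac_idx, c] > floors[c]]
        fittable = [c for c in present if matrix.response_pct(assay, c) > 0]
        # Merge unresolvable same-CR groups into single fit columns.
        groups: list[list[str]] = []
        for c in fittable:
            cr = matrix.response_pct(assay, c)
            for grp in groups:
                cr0 = matrix.response_pct(assay, grp[0])
                if abs(cr - cr0) <= cr_merge_rtol * max(cr, cr0):
                    grp.append(c)
                    break
            else:
                groups.append([c])
        predicted = 0.0
        if groups and observed > 0:
            design = np.array(
                [[matrix.response_pct(assay, grp[0]) / 100.0 for grp in groups]]
            )
            sol, _ = nnls(design, np.array([observed]))
            predicted = float((design @ sol)[0])
            for grp, fitted in zip(groups, sol):
                if len(grp) > 1:
                    g = frozenset(grp)
                    if g not in unresolved:
                        unresolved.append(g)
                    # split evenly only for bookkeeping; the group is the unit
                    for c in grp:
                        amounts.loc[frac_idx, c] = fitted / len(grp)
                else:
                    amounts.loc[frac_idx, grp[0]] = fitted
        residual = observed - predicted
        rows.append({
            "fraction": frac_idx,
            "start_min": series.boundaries[i][0],
            "end_min": series.boundaries[i][1],
            "response": observed,
            "predicted": predicted,
            "residual": residual,
            "n_candidates": len(present),
            "unexplained": residual > threshold,
        })
    table = pd.DataFrame(rows)
    return AttributionResult(series.animal, assay, table, amounts, unresolved)


def attribute_fraction_activity(
    series: FractionSeries,
    matrix: CrossReactivityMatrix,
    assay: str,
    cr_floor_pct: float = 1.0,
    **deconv_kwargs,
) -> AttributionResult:
    """Deconvolve and then name the compound(s) responsible for activity.

    A compound is named responsible iff its fitted amount is positive and
    its cross-reactivity is at or above ``cr_floor_pct``; co-eluting
    candidates with negligible (or bound-only) cross-reactivity are
    reported as excluded, never as responsible.
    """
    result = deconvolve_fractions(series, matrix, assay, **deconv_kwargs)
    totals = result.compound_totals
    responsible: dict[str, float] = {}
    excluded: dict[str, str] = {}
    seen = series.areas.columns[(series.areas > 0).any(axis=0)]
    for compound in seen:
        if compound not in matrix.values.columns:
            excluded[compound] = "not in cross-reactivity matrix"
            continue
        cr = matrix.response_pct(assay, compound)
        bound = bool(matrix.bounds.loc[assay, compound])
        if totals.get(compound, 0.0) > 0 and cr >= cr_floor_pct:
            responsible[compound] = float(totals[compound])
        elif bound:
            excluded[compound] = (
                f"cross-reactivity bound <{matrix.bound_values.loc[assay, compound]:g}%"
            )
        elif cr < cr_floor_pct:
            excluded[compound] = f"cross-reactivity {cr:g}% below floor {cr_floor_pct:g}%"
        else:
            excluded[compound] = "no fitted amount"
    result.responsible = responsible
    result.excluded = excluded
    return result


# ---------------------------------------------------------------------------
# Assay ranking
# ---------------------------------------------------------------------------

def rank_assays(
    attributions: Mapping[str, Mapping[str, AttributionResult]],
    abundances: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Rank assays by cross-animal consistency of what they detect.

    ``attributions`` maps animal → assay → AttributionResult (from
    :func:`attribute_fraction_activity`). Each assay's primary compound is
    the responsible compound with the largest total attributed amount
    across animals; assays are ordered by (a) the fraction of animals in
    which that compound was detected (higher first), (b) the LC-MS
    abundance rank of the compound (``abundances``: compound → total LC-MS
    area; defaults to the attributed amounts), (c) mean unexplained-
    activity share (lower first), then (d) assay code for stable ties.
    A single-animal input is ranked the same way with a coverage caveat.
    """
    animals = sorted(attributions)
    if not animals:
        raise ValueError("need at least one animal")
    assays = sorted({a for per in attributions.values() for a in per})
    # Pool attributed amounts per assay/compound across animals.
    pooled: dict[str, dict[str, float]] = {a: {} for a in assays}
    detected_in: dict[str, dict[str, set]] = {a: {} for a in assays}
    unexplained: dict[str, list[float]] = {a: [] for a in assays}
    for animal in animals:
        for assay, result in attributions[animal].items():
            for compound, amt in result.responsible.items():
                pooled[assay][compound] = pooled[assay].get(compound, 0.0) + amt
                detected_in[assay].setdefault(compound, set()).add(animal)
            unexplained[assay].append(result.unexplained_share)
    if abundances is None:
        all_compounds: dict[str, float] = {}
        for assay in assays:
            for compound, amt in pooled[assay].items():
                all_compounds[compound] = all_compounds.get(compound, 0.0) + amt
        abundances = all_compounds
    abundance_rank = {
        c: r + 1
        for r, c in enumerate(sorted(abundances, key=lambda c: (-abundances[c], c)))
    }
    rows = []
    for assay in assays:
        if pooled[assay]:
            primary = max(pooled[assay], key=lambda c: (pooled[assay][c], c))
            coverage = len(detected_in[assay][primary]) / len(animals)
            arank = abundance_rank.get(primary, len(abundance_rank) + 1)
        else:
            primary, coverage, arank = "", 0.0, len(abundance_rank) + 1
        rows.append({
            "assay": assay,
            "primary_compound": primary,
            "animal_coverage": coverage,
            "abundance_rank": arank,
            "unexplained_share": float(np.mean(unexplained[assay])) if unexplained[assay] else 0.0,
            "single_animal_caveat": len(animals) == 1,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["animal_coverage", "abundance_rank", "unexplained_share", "assay"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
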