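"""Candidate identification of screened LC-MS features.

Matches feature masses against a library of authentic steroid standards
(directly on neutral mass, or through registered electrospray adducts when
matching raw m/z), confirms candidates by retention time within a named
chromatography mode, scores MS/MS similarity by cosine, and links features
into metabolite families through small formula deltas (oxidation,
hydration, ±CH2, succinate esterification).

Isomer ambiguity is preserved throughout: standards sharing a molecular
formula are always returned together and never resolved arbitrarily —
retention time and MS/MS are the only discriminators.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .chem import (
    AdductSpec,
    DeltaClass,
    MolecularFormula,
    classify_delta,
    default_adducts,
    default_delta_classes,
    monoisotopic_mass,
    neutral_from_adduct,
    parse_formula,
    ppm_diff,
)

__all__ = [
    "StandardRecord",
    "Annotation",
    "RtMatch",
    "default_standard_library",
    "load_standard_library",
    "write_standard_library",
    "match_by_mass",
    "match_by_rt",
    "msms_cosine",
    "build_family_graph",
    "annotate_features",
]


@dataclass(frozen=True)
class StandardRecord:
    """An authentic steroid standard with per-chromatography-mode RTs.

    ``retention_times`` maps a mode name (e.g. ``"rp"`` for the analytical
    reverse-phase method, ``"frac"`` for the fractionation gradient) to a
    retention time in minutes; a standard may lack an RT in some modes.
    """

    name: str
    trivial_name: str
    formula: MolecularFormula
    retention_times: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for mode, rt in self.retention_times.items():
            if rt <= 0:
                raise ValueError(f"standard {self.name}: non-positive RT in mode {mode}")
        object.__setattr__(self, "retention_times", dict(self.retention_times))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def default_standard_library() -> list[StandardRecord]:
    """Tetrahydrocortisol, its ring-A stereoisomers, the cortolones,
    cortisol, and the administered hemisuccinate ester.

    Reverse-phase RTs are the elution times of the authentic standards
    under the analytical gradient; ``frac`` RTs place each compound on the
    preparative fractionation gradient (60 s fractions, 30 s between 22 and
    37 min). β-cortolone carries no reverse-phase RT: matching against it
    is RT-inconclusive by construction.
    """
    def S(name, trivial, formula, rp=None, frac=None):
        rts = {}
        if rp is not None:
            rts["rp"] = rp
        if frac is not None:
            rts["frac"] = frac
        return StandardRecord(name, trivial, parse_formula(formula), rts)

    return [
        S("THF", "tetrahydrocortisol", "C21H34O5", rp=9.13, frac=36.0),
        S("allo-THF", "allotetrahydrocortisol", "C21H34O5", rp=8.80, frac=36.05),
        S("3b-THF", "3β-tetrahydrocortisol", "C21H34O5", rp=6.60, frac=26.7),
        S("3b-allo-THF", "3β-allotetrahydrocortisol", "C21H34O5", rp=6.40, frac=26.3),
        S("a-cortolone", "α-cortolone", "C21H34O5", rp=8.36, frac=34.0),
        S("b-cortolone", "β-cortolone", "C21H34O5", frac=34.5),
        S("cortisol", "cortisol", "C21H30O5", rp=7.80, frac=30.2),
        S("cortisol-succinate", "hydrocortisone succinate", "C25H34O8", rp=10.5, frac=40.0),
    ]


def load_standard_library(path) -> list[StandardRecord]:
    """Read a standards library CSV: columns
    ``name, trivial_name, formula, mode, rt_min`` (one row per mode RT;
    rows with empty mode define RT-less standards)."""
    df = pd.read_csv(path)
    required = {"name", "trivial_name", "formula", "mode", "rt_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"standards library missing columns: {sorted(missing)}")
    records: dict[str, dict] = {}
    for _, row in df.iterrows():
        rec = records.setdefault(
            row["name"],
            {"trivial": row["trivial_name"], "formula": parse_formula(row["formula"]), "rts": {}},
        )
        if isinstance(row["mode"], str) and row["mode"]:
            rec["rts"][row["mode"]] = float(row["rt_min"])
    return [
        StandardRecord(name, rec["trivial"], rec["formula"], rec["rts"])
        for name, rec in records.items()
    ]


def write_standard_library(library: Iterable[StandardRecord], path) -> None:
    rows = []
    for std in library:
        if std.retention_times:
            for mode, rt in std.retention_times.items():
                rows.append((std.name, std.trivial_name, str(std.formula), mode, rt))
        else:
            rows.append((std.name, std.trivial_name, str(std.formula), "", ""))
    pd.DataFrame(rows, columns=["name", "trivial_name", "formula", "mode", "rt_min"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """A candidate assignment of a feature to one or more standards."""

    feature_id: str
    candidates: list[str]  # all co-equal (same-formula) candidate names
    standard: str  # representative candidate (smallest |ppm|; same formula)
    adduct: str  # adduct name or "neutral"
    mass_error_ppm: float
    rt_error_min: float | None = None
    msms_similarity: float | None = None
    evidence: str = "mass-only"  # mass-only | mass+RT | mass+RT+MS2


def match_by_mass(
    observed_mass: float,
    library: Sequence[StandardRecord],
    adducts: Sequence[AdductSpec] | None = None,
    tol_ppm: float = 10.0,
    feature_id: str = "",
    is_mz: bool = False,
    polarity: str | None = None,
) -> list[Annotation]:
    """All standards whose formula mass matches within ``tol_ppm``.

    With ``is_mz=True`` the observed value is an ion m/z and every
    registered adduct of the matching polarity is tried; otherwise the
    observed value is compared to neutral formula masses directly.
    Standards sharing a formula are grouped into a single annotation whose
    ``candidates`` lists every isomer — the ambiguity is preserved.
    """
    if adducts is None:
        adducts = default_adducts()
    hits: list[tuple[float, str, StandardRecord]] = []  # (ppm, adduct name, std)
    for std in library:
        theo = std.mass
        if is_mz:
            for add in adducts:
                if polarity is not None and add.polarity != polarity:
                    continue
                neutral = neutral_from_adduct(observed_mass, add)
                ppm = ppm_diff(neutral, theo)
                if abs(ppm) <= tol_ppm:
                    hits.append((ppm, add.name, std))
        else:
            ppm = ppm_diff(observed_mass, theo)
            if abs(ppm) <= tol_ppm:
                hits.append((ppm, "neutral", std))

    # Group co-equal isomers: same formula and same adduct route.
    groups: dict[tuple[MolecularFormula, str], list[tuple[float, StandardRecord]]] = {}
    for ppm, add_name, std in hits:
        groups.setdefault((std.formula, add_name), []).append((ppm, std))
    annotations = []
    for (formula, add_name), members in groups.items():
        members.sort(key=lambda t: (abs(t[0]), t[1].name))
        ppm, rep = members[0]
        annotations.append(
            Annotation(
                feature_id=feature_id,
                candidates=[std.name for _, std in members],
                standard=rep.name,
                adduct=add_name,
                mass_error_ppm=ppm,
            )
        )
    annotations.sort(key=lambda a: abs(a.mass_error_ppm))
    return annotations


@dataclass(frozen=True)
class RtMatch:
    """Outcome of a retention-time comparison."""

    status: str  # "accept" | "reject" | "inconclusive"
    rt_error_min: float | None


def match_by_rt(
    candidate: StandardRecord,
    observed_rt: float,
    mode: str = "rp",
    tol_min: float = 0.15,
) -> RtMatch:
    """Accept a candidate iff its standard RT in ``mode`` is within
    ``tol_min`` of the observed RT; a missing standard RT is inconclusive,
    never a rejection."""
    std_rt = candidate.retention_times.get(mode)
    if std_rt is None:
        return RtMatch("inconclusive", None)
    err = observed_rt - std_rt
    return RtMatch("accept" if abs(err) <= tol_min else "reject", err)


def msms_cosine(
    spectrum_a: Sequence[tuple[float, float]],
    spectrum_b: Sequence[tuple[float, float]],
    mz_tol: float = 0.01,
) -> float:
    """Cosine similarity of two peak lists after greedy peak pairing.

    Peak pairs are formed greedily by smallest m/z difference within
    ``mz_tol``; unmatched peaks contribute to the norms only. Empty input
    gives 0.
    """
    if not spectrum_a or not spectrum_b:
        return 0.0
    pairs = []
    for i, (mza, _) in enumerate(spectrum_a):
        for j, (mzb, _) in enumerate(spectrum_b):
            d = abs(mza - mzb)
            if d <= mz_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += spectrum_a[i][1] * spectrum_b[j][1]
    norm_a = math.sqrt(sum(inten ** 2 for _, inten in spectrum_a))
    norm_b = math.sqrt(sum(inten ** 2 for _, inten in spectrum_b))
    if norm_a == 0 or norm_b == 0:
        return 0.0
    return dot / (norm_a * norm_b)


# ---------------------------------------------------------------------------
# Family graph
# ---------------------------------------------------------------------------

def build_family_graph(
    features: Mapping[str, float],
    delta_classes: Sequence[DeltaClass] | None = None,
    tol_ppm: float = 10.0,
) -> nx.Graph:
    """Link features whose pairwise mass differences classify to a known
    formula delta.

    ``features`` maps feature id → neutral mass. Edges carry the delta
    class label and the signed label in the low→high mass direction; the
    graph records the maximal-degree node under ``graph.graph["hub"]``.
    """
    if delta_classes is None:
        delta_classes = default_delta_classes()
    g = nx.Graph()
    for fid, mass in features.items():
        g.add_node(fid, mass=float(mass))
    ids = sorted(features)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            lo, hi = sorted((a, b), key=lambda k: features[k])
            match = classify_delta(features[lo], features[hi], tol_ppm, delta_classes)
            if match.label == "unclassified":
                continue
            g.add_edge(lo, hi, label=match.label, signed_label=match.signed_label,
                       ppm_error=match.ppm_error)
    hub = None
    if g.number_of_edges():
        hub = max(g.degree, key=lambda kv: (kv[1], kv[0]))[0]
    g.graph["hub"] = hub
    return g


# ---------------------------------------------------------------------------
# Feature-level driver
# ---------------------------------------------------------------------------

def annotate_features(
    features: Iterable,
    library: Sequence[StandardRecord] | None = None,
    tol_ppm: float = 10.0,
    rt_tol_min: float = 0.15,
    rt_mode: str | None = None,
    spectra: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    library_spectra: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    msms_threshold: float = 0.7,
) -> pd.DataFrame:
    """Annotate screened features by mass, then RT, then MS/MS.

    ``features`` is an iterable of objects with ``feature_id``,
    ``neutral_mass`` and ``retention_time`` attributes (screen output).
    A mass match returns the whole isomer set; when ``rt_mode`` is given,
    retention time is evaluated for every candidate in the set and, where
    one accepts, singles out the representative — the unresolved isomers
    remain listed. With feature and library spectra supplied, a cosine
    similarity at or above ``msms_threshold`` upgrades the evidence level.
    Features with no mass match are reported as unassigned rather than
    dropped — family membership without identity is a valid outcome.
    """
    if library is None:
        library = default_standard_library()
    by_name = {s.name: s for s in library}
    rows = []
    for f in features:
        anns = match_by_mass(
            f.neutral_mass, library, tol_ppm=tol_ppm, feature_id=f.feature_id
        )
        if not anns:
            rows.append((f.feature_id, f.neutral_mass, f.retention_time, "", "", "",
                         float("nan"), float("nan"), float("nan"), "unassigned"))
            continue
        for ann in anns:
            evidence = "mass-only"
            rep = ann.standard
            rt_err = float("nan")
            if rt_mode is not None:
                accepted = []
                for name in ann.candidates:
                    rtm = match_by_rt(by_name[name], f.retention_time, rt_mode, rt_tol_min)
                    if rtm.status == "accept":
                        accepted.append((abs(rtm.rt_error_min), rtm.rt_error_min, name))
                if accepted:
                    accepted.sort()
                    _, rt_err, rep = accepted[0]
                    evidence = "mass+RT"
            sim = float("nan")
            if (
                evidence == "mass+RT"
                and spectra is not None
                and library_spectra is not None
                and f.feature_id in spectra
                and rep in library_spectra
            ):
                sim = msms_cosine(spectra[f.feature_id], library_spectra[rep])
                if sim >= msms_threshold:
                    evidence = "mass+RT+MS2"
            rows.append((f.feature_id, f.neutral_mass, f.retention_time,
                         ";".join(ann.candidates), rep, ann.adduct,
                         ann.mass_error_ppm, rt_err, sim, evidence))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "neutral_mass", "rt_min", "candidates", "standard",
                 "adduct", "mass_error_ppm", "rt_error_min", "msms_similarity",
                 "evidence"],
    )
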