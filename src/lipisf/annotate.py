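"""Exact-mass search and the LO / C / S likelihood ranking.

A lipid ionized in a MALDI source is typically observed as several m/z
features at once: its common adducts plus in-source fragments. The search
matches every (lipid, class-valid transform) hypothesis against the
centroided m/z axis within a ppm tolerance; each candidate lipid is then
scored by

    S = LO * (1 + C)

where LO (lipid occurrences) is the number of distinct ion forms found and
C is the mean pairwise Pearson correlation between the ion images of those
forms. Isobaric candidates that match a peak "by accident" tend to appear
as a single, spatially uncorrelated form and score low; genuine lipids
accumulate several co-localized forms and score high.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import IonTransform, ppm_error
from .library import LipidLibrary, LipidSpecies
from .peakmatrix import PeakMatrix


@dataclass(frozen=True)
class IonMatch:
    """One (lipid, transform) hypothesis matched to one observed peak."""

    lipid: LipidSpecies
    transform: IonTransform
    peak_index: int
    theoretical_mz: float
    observed_mz: float
    ppm_error: float


@dataclass
class LipidAnnotationGroup:
    """One candidate lipid with all its matched ion forms and its score."""

    lipid: LipidSpecies
    matches: List[IonMatch]
    LO: int
    C: float
    S: float


def exact_mass_search(
    pm: PeakMatrix,
    lib: LipidLibrary,
    polarity: Optional[str] = None,
    ppm_tol: Optional[float] = None,
) -> List[IonMatch]:
    """Match every class-valid (lipid, transform) ion against the m/z axis.

    For each hypothesis the single peak minimizing |ppm error| within the
    tolerance is taken, so LO counts distinct ion forms rather than
    tolerance-window multiplicity. One peak may carry matches from many
    lipids (isobars). Empty library or matrix yields an empty list.
    """
    polarity = polarity or pm.polarity
    ppm_tol = pm.ppm_tolerance if ppm_tol is None else ppm_tol
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be > 0")
    matches: List[IonMatch] = []
    if pm.n_mz == 0:
        return matches
    mz = pm.mz
    for lipid, transform, theo in lib.search_space(polarity):
        # tolerance window around the theoretical m/z
        half = theo * ppm_tol * 1e-6
        lo = np.searchsorted(mz, theo - half, side="left")
        hi = np.searchsorted(mz, theo + half, side="right")
        if hi <= lo:
            continue
        window = mz[lo:hi]
        j = lo + int(np.argmin(np.abs(window - theo)))
        matches.append(
            IonMatch(
                lipid=lipid,
                transform=transform,
                peak_index=j,
                theoretical_mz=theo,
                observed_mz=float(mz[j]),
                ppm_error=ppm_error(float(mz[j]), theo),
            )
        )
    return matches


def spatial_correlation(
    pm: PeakMatrix,
    peak_indices: Sequence[int],
    weighted: bool = False,
) -> float:
    """Mean Pearson r over all distinct pairs of the given ion images.

    A single index yields 0 (no pairs to correlate). A zero-variance column
    contributes pairwise r = 0 rather than NaN. With ``weighted=True`` each
    pair is weighted by the product of the two mean ion intensities.
    """
    idx = sorted(set(int(i) for i in peak_indices))
    if not idx:
        raise ValueError("empty peak-index set")
    if any(i < 0 or i >= pm.n_mz for i in idx):
        raise IndexError("peak index out of range")
    if len(idx) == 1:
        return 0.0
    cols = pm.intensity[:, idx]
    std = cols.std(axis=0)
    # corrcoef emits NaN for zero-variance columns; define those pairs as 0
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(cols, rowvar=False)
    r = np.where(np.isnan(r), 0.0, r)
    n = len(idx)
    iu = np.triu_indices(n, k=1)
    pair_r = r[iu]
    if not weighted:
        return float(pair_r.mean())
    mean_int = cols.mean(axis=0)
    w = (mean_int[iu[0]] * mean_int[iu[1]]).astype(float)
    if w.sum() == 0:
        return float(pair_r.mean())
    return float(np.average(pair_r, weights=w))


def score_groups(
    matches: Iterable[IonMatch],
    pm: PeakMatrix,
    weighted_correlation: bool = False,
) -> List[LipidAnnotationGroup]:
    """Group matches per lipid and score each group with S = LO*(1+C)."""
    by_lipid: Dict[str, List[IonMatch]] = {}
    for m in matches:
        by_lipid.setdefault(m.lipid.name, []).append(m)
    groups = []
    for name in sorted(by_lipid):
        ms = by_lipid[name]
        lo = len(ms)
        peaks = {m.peak_index for m in ms}
        c = spatial_correlation(pm, peaks, weighted=weighted_correlation)
        groups.append(
            LipidAnnotationGroup(
                lipid=ms[0].lipid, matches=ms, LO=lo, C=c, S=lo * (1.0 + c)
            )
        )
    return groups


ANNOTATION_COLUMNS = [
    "peak_index", "observed_mz", "lipid", "class", "carbons", "double_bonds",
    "formula", "transform", "kind", "ppm_error", "LO", "C", "S",
    "rank_within_peak",
]


def build_annotation_table(
    groups: Iterable[LipidAnnotationGroup],
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Flatten scored groups into the annotation table, ranked per peak.

    Rows sharing a peak are ranked by descending S; ties break by ascending
    |ppm error|, then lexicographic lipid name, so output is deterministic.
    With ``top_n`` set, rows ranked below it are dropped.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows = []
    for g in groups:
        for m in g.matches:
            rows.append(
                dict(
                    peak_index=m.peak_index,
                    observed_mz=m.observed_mz,
                    lipid=g.lipid.name,
                    **{"class": g.lipid.lipid_class},
                    carbons=g.lipid.carbons,
                    double_bonds=g.lipid.double_bonds,
                    formula=g.lipid.formula.hill(),
                    transform=m.transform.name,
                    kind=m.transform.kind,
                    ppm_error=m.ppm_error,
                    LO=g.LO,
                    C=g.C,
                    S=g.S,
                )
            )
    if not rows:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    df = pd.DataFrame(rows)
    df["_abs_ppm"] = df["ppm_error"].abs()
    df = df.sort_values(
        ["peak_index", "S", "_abs_ppm", "lipid"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    df["rank_within_peak"] = df.groupby("peak_index").cumcount() + 1
    if top_n is not None:
        df = df[df["rank_within_peak"] <= top_n]
    return df.drop(columns="_abs_ppm").reset_index(drop=True)[ANNOTATION_COLUMNS]


def annotate(
    pm: PeakMatrix,
    lib: LipidLibrary,
    polarity: Optional[str] = None,
    ppm_tol: Optional[float] = None,
    top_n: Optional[int] = None,
    weighted_correlation: bool = False,
) -> Tuple[pd.DataFrame, List[LipidAnnotationGroup]]:
    """Search + score + rank in one call; returns (table, groups)."""
    matches = exact_mass_search(pm, lib, polarity=polarity, ppm_tol=ppm_tol)
    groups = score_groups(matches, pm, weighted_correlation=weighted_correlation)
    return build_annotation_table(groups, top_n=top_n), groups
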