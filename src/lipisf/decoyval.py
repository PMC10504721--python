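"""Target-decoy validation: decoy libraries, ROC/AUC, FDR curves.

Because MS1 exact-mass annotation has no ground truth, annotation
performance is estimated by searching the same peak matrix twice: once with
the target lipid library and once with a decoy library of hypotheses that
should not occur in the sample. Two decoy constructions are provided:

* ``implausible_transforms`` — each real adduct/fragment transform is
  replaced by one built from an element foreign to lipid chemistry (B, Si,
  Sc, Ti, Mn) plus a hydrogen adjustment, chosen so the multiset of decoy
  mass shifts tracks the target shifts in count and range;
* ``alternative_compounds`` — the lipid list is replaced by out-of-sample
  compounds resampled so their neutral-mass distribution matches the
  target's (two-sample Kolmogorov-Smirnov distance below a threshold),
  searched with the standard transform table.

Either way, decoy hits are as mass-plausible as target hits, so the decoy
hit rate estimates the false-annotation rate: FDR at a cutoff is D/T
(decoy/target annotations passing it), and ranking quality is summarized as
the ROC AUC of S scores with target annotations as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chem import (
    MONOISOTOPIC_MASS,
    ElementComposition,
    IonTransform,
    parse_formula,
)
from .annotate import annotate, build_annotation_table
from .library import LibraryError, LipidLibrary, LipidSpecies
from .peakmatrix import PeakMatrix

#: elements essentially absent from biological lipids, used for decoys
IMPLAUSIBLE_ELEMENTS = ("B", "Si", "Sc", "Ti", "Mn")

_H = MONOISOTOPIC_MASS["H"]


class DecoyError(ValueError):
    pass


@dataclass
class DecoyLibrary:
    strategy: str            # "implausible_transforms" | "alternative_compounds"
    library: LipidLibrary
    seed: int
    provenance: str = ""


def _all_ion_mz(lib: LipidLibrary) -> np.ndarray:
    mzs = [m for pol in ("positive", "negative")
           for (_s, _t, m) in lib.search_space(pol)]
    return np.sort(np.array(mzs))


def _collides(candidates: np.ndarray, reference: np.ndarray, ppm_tol: float) -> bool:
    """True if any candidate m/z lies within ppm_tol of a reference m/z."""
    if len(reference) == 0 or len(candidates) == 0:
        return False
    pos = np.searchsorted(reference, candidates)
    for c, p in zip(candidates, pos):
        for q in (p - 1, p):
            if 0 <= q < len(reference):
                if abs(c - reference[q]) <= c * ppm_tol * 1e-6:
                    return True
    return False


def make_decoy_transforms(
    target_lib: LipidLibrary,
    seed: int,
    ppm_tol: float = 5.0,
    max_attempts: int = 500,
) -> DecoyLibrary:
    """Build the implausible-transform decoy library.

    One decoy transform is generated per target transform: a gain of one
    implausible-pool element combined with a hydrogen loss sized so the
    decoy mass shift lands near the corresponding target shift (hence the
    decoy shift multiset matches the target's in count and range). Decoy ion
    m/z values are rejected (and redrawn) whenever they fall within
    ``ppm_tol`` of any target ion m/z, so target and decoy hypotheses can
    never hit the same peak. Construction is a pure function of
    (target_lib, seed).
    """
    rng = np.random.default_rng(seed)
    target_mz = _all_ion_mz(target_lib)
    shifts = {name: t.mass_shift() for name, t in target_lib.transforms.items()}
    lo_s, hi_s = min(shifts.values()) - 25.0, max(shifts.values()) + 25.0

    # neutral masses grouped by (class, polarity) to test collisions per decoy
    masses_by_pathway: Dict[Tuple[str, str], np.ndarray] = {}
    for (cls, pol), _names in target_lib.pathways.items():
        masses_by_pathway[(cls, pol)] = np.array(
            [s.neutral_mass for s in target_lib.species if s.lipid_class == cls]
        )

    decoys: Dict[str, IonTransform] = {}
    name_map: Dict[str, str] = {}
    for name, t in target_lib.transforms.items():
        target_shift = shifts[name]
        ok = None
        for _ in range(max_attempts):
            el = str(rng.choice(IMPLAUSIBLE_ELEMENTS))
            jitter = int(rng.integers(-3, 4))
            k = int(round((MONOISOTOPIC_MASS[el] - target_shift) / _H)) + jitter
            if k < 0:
                continue
            cand = IonTransform(
                name=f"DECOY[{el}-{k}H]{name}",
                polarity=t.polarity,
                kind=t.kind,
                gain=ElementComposition({el: 1}),
                loss=ElementComposition({"H": k}),
                charge_carrier="none",
                plausible=False,
            )
            d = cand.mass_shift()
            if not (lo_s <= d <= hi_s):
                continue
            ion_mzs = np.concatenate([
                masses + d
                for (cls, pol), masses in masses_by_pathway.items()
                if pol == t.polarity and name in target_lib.pathways[(cls, pol)]
            ] or [np.array([])])
            if _collides(ion_mzs, target_mz, 2 * ppm_tol):
                continue
            ok = cand
            break
        if ok is None:
            raise DecoyError(
                f"could not place a collision-free decoy for {name!r} after "
                f"{max_attempts} attempts; try a different seed")
        decoys[ok.name] = ok
        name_map[name] = ok.name

    pathways = {
        key: [name_map[n] for n in names]
        for key, names in target_lib.pathways.items()
    }
    lib = LipidLibrary(
        species=list(target_lib.species),
        transforms=decoys,
        pathways=pathways,
        is_decoy=True,
        description=f"implausible-transform decoy (seed={seed})",
    )
    return DecoyLibrary(
        strategy="implausible_transforms",
        library=lib,
        seed=seed,
        provenance=f"pool={IMPLAUSIBLE_ELEMENTS}, seed={seed}, ppm_tol={ppm_tol}",
    )


def make_decoy_compounds(
    compound_table,
    target_lib: LipidLibrary,
    seed: int = 0,
    ks_threshold: float = 0.1,
    ppm_tol: float = 5.0,
) -> DecoyLibrary:
    """Build the alternative-compound decoy library.

    ``compound_table`` is a TSV (or DataFrame) with columns name, formula —
    compounds that should not occur in the sample. Compounds are matched
    one-to-one to target species by nearest neutral mass (without
    replacement) so the decoy mass histogram mirrors the target's; the match
    is rejected if the two-sample Kolmogorov-Smirnov distance exceeds
    ``ks_threshold``. Each decoy inherits a lipid class drawn from the
    target class frequencies so it is searched with the standard transforms.
    """
    if isinstance(compound_table, pd.DataFrame):
        comp = compound_table.copy()
    else:
        comp = pd.read_csv(compound_table, sep="\t", dtype=str)
    if not {"name", "formula"} <= set(comp.columns):
        raise DecoyError("compound table needs columns: name, formula")
    if len(comp) < len(target_lib.species):
        raise DecoyError(
            f"compound table ({len(comp)} rows) smaller than target library "
            f"({len(target_lib.species)} species)")

    rng = np.random.default_rng(seed)
    formulas = [parse_formula(f) for f in comp["formula"]]
    from .chem import monoisotopic_mass
    masses = np.array([monoisotopic_mass(f) for f in formulas])
    target_masses = np.array([s.neutral_mass for s in target_lib.species])
    target_mz = _all_ion_mz(target_lib)

    # greedy nearest-mass matching without replacement
    order = rng.permutation(len(target_masses))
    available = np.ones(len(masses), dtype=bool)
    chosen = np.full(len(target_masses), -1)
    for ti in order:
        diffs = np.where(available, np.abs(masses - target_masses[ti]), np.inf)
        ci = int(np.argmin(diffs))
        if not np.isfinite(diffs[ci]):
            raise DecoyError("ran out of candidate compounds during matching")
        chosen[ti] = ci
        available[ci] = False

    decoy_masses = masses[chosen]
    ks = stats.ks_2samp(decoy_masses, target_masses).statistic
    if ks > ks_threshold:
        raise DecoyError(
            f"decoy mass distribution does not match the target library "
            f"(KS distance {ks:.3f} > {ks_threshold}); supply a compound list "
            "covering the target mass range")

    classes = [s.lipid_class for s in target_lib.species]
    species = []
    for ti in range(len(target_masses)):
        ci = chosen[ti]
        cls = classes[ti]  # pair each decoy with its matched target's class
        species.append(
            LipidSpecies(
                name=f"DECOY:{comp['name'].iloc[ci]}",
                lipid_class=cls,
                carbons=max(1, formulas[ci]["C"]),
                double_bonds=0,
                formula=formulas[ci],
            )
        )
    lib = LipidLibrary(
        species=species,
        transforms=dict(target_lib.transforms),
        pathways=dict(target_lib.pathways),
        is_decoy=True,
        description=f"alternative-compound decoy (seed={seed}, KS={ks:.3f})",
    )
    return DecoyLibrary(
        strategy="alternative_compounds",
        library=lib,
        seed=seed,
        provenance=f"KS={ks:.4f} (threshold {ks_threshold}), seed={seed}",
    )


def mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank formula with average ranks for ties."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def roc_points(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points of the S-score ROC, tie-grouped, from (0,0) to (1,1)."""
    from sklearn.metrics import roc_curve

    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


@dataclass
class ValidationResult:
    scored: pd.DataFrame          # columns: lipid, LO, C, S, is_target
    roc: np.ndarray               # (k, 2) of (FPR, TPR)
    auc: float
    fdr_curve: pd.DataFrame       # columns: top_n, fdr, n_target, n_decoy
    seed: Optional[int] = None
    provenance: str = ""


def fdr_top_n_curve(
    target_table: pd.DataFrame,
    decoy_table: pd.DataFrame,
    top_n_range=range(1, 21),
    estimator: str = "d_over_t",
) -> pd.DataFrame:
    """FDR as a function of the per-peak top-N cutoff.

    Target and decoy annotation rows are pooled per peak and jointly
    re-ranked by S (the competition the search would face in practice); at
    each N the estimate is D/T (default) or D/(D+T) over retained rows,
    capped at 1; T = 0 gives FDR 1.
    """
    if estimator not in ("d_over_t", "d_over_d_plus_t"):
        raise ValueError(f"unknown FDR estimator {estimator!r}")
    t = target_table.copy()
    t["is_target"] = True
    d = decoy_table.copy()
    d["is_target"] = False
    pooled = pd.concat([t, d], ignore_index=True)
    pooled["_abs_ppm"] = pooled["ppm_error"].abs()
    pooled = pooled.sort_values(
        ["peak_index", "S", "_abs_ppm", "lipid"],
        ascending=[True, False, True, True],
        kind="stable",
    )
    pooled["joint_rank"] = pooled.groupby("peak_index").cumcount() + 1
    rows = []
    for n in top_n_range:
        kept = pooled[pooled["joint_rank"] <= n]
        n_t = int(kept["is_target"].sum())
        n_d = int(len(kept) - n_t)
        if estimator == "d_over_t":
            fdr = 1.0 if n_t == 0 else min(1.0, n_d / n_t)
        else:
            fdr = 1.0 if (n_t + n_d) == 0 else n_d / (n_t + n_d)
        rows.append(dict(top_n=int(n), fdr=fdr, n_target=n_t, n_decoy=n_d))
    return pd.DataFrame(rows)


def fdr_at_thresholds(
    target_scores: np.ndarray,
    decoy_scores: np.ndarray,
    thresholds: np.ndarray,
    estimator: str = "d_over_t",
    monotone: bool = True,
) -> np.ndarray:
    """FDR at each S-score threshold (ascending): D/T (or D/(D+T)) among
    scores >= s, capped at 1; T = 0 gives 1.

    With ``monotone=True`` the raw estimates are converted to q-values
    (cumulative minimum over looser cutoffs), which are non-increasing in
    the threshold; raw D/T ratios need not be.
    """
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")
    t = np.sort(np.asarray(target_scores, float))
    d = np.sort(np.asarray(decoy_scores, float))
    out = []
    for s in thresholds:
        n_t = len(t) - np.searchsorted(t, s, side="left")
        n_d = len(d) - np.searchsorted(d, s, side="left")
        if estimator == "d_over_t":
            out.append(1.0 if n_t == 0 else min(1.0, n_d / n_t))
        else:
            out.append(1.0 if n_t + n_d == 0 else n_d / (n_t + n_d))
    out = np.array(out)
    return np.minimum.accumulate(out) if monotone else out


def run_target_decoy(
    pm: PeakMatrix,
    target: LipidLibrary,
    decoy: DecoyLibrary,
    ppm_tol: Optional[float] = None,
    top_n_range=range(1, 21),
    polarity: Optional[str] = None,
    estimator: str = "d_over_t",
    weighted_correlation: bool = False,
) -> ValidationResult:
    """Search the same matrix with target and decoy libraries and compare.

    Both searches use identical tolerance, polarity and scoring. Scores are
    compared at the lipid-group level (one S per candidate lipid); the FDR
    curve is computed on annotation rows under per-peak top-N competition.
    """
    kw = dict(polarity=polarity, ppm_tol=ppm_tol,
              weighted_correlation=weighted_correlation)
    t_table, t_groups = annotate(pm, target, **kw)
    d_table, d_groups = annotate(pm, decoy.library, **kw)
    if not t_groups or not d_groups:
        empty = []
        if not t_groups:
            empty.append("target")
        if not d_groups:
            empty.append("decoy")
        raise DecoyError(f"no annotations from the {' and '.join(empty)} "
                         "library; nothing to validate")

    scored = pd.DataFrame(
        [dict(lipid=g.lipid.name, LO=g.LO, C=g.C, S=g.S, is_target=flag)
         for groups, flag in ((t_groups, True), (d_groups, False))
         for g in groups]
    )
    pos = scored.loc[scored.is_target, "S"].to_numpy()
    neg = scored.loc[~scored.is_target, "S"].to_numpy()
    return ValidationResult(
        scored=scored,
        roc=roc_points(pos, neg),
        auc=mann_whitney_auc(pos, neg),
        fdr_curve=fdr_top_n_curve(t_table, d_table, top_n_range, estimator),
        seed=decoy.seed,
        provenance=f"strategy={decoy.strategy}; {decoy.provenance}",
    )
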