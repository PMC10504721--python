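"""Ground-truthed synthetic MSI peak matrices.

The generator emulates exactly the structure the LO/C/S score exploits: each
planted lipid appears as several ion forms (adducts and in-source fragments
of its class) that share one spatial pattern — a 2-D Gaussian blob — and
therefore correlate strongly across pixels, while noise peaks get
independent patterns and correlate with nothing. Optional heavy-isotope
satellites (+k*1.0033548 Da at declining abundance) exercise the
deisotoping pre-filter. Per-pixel intensities carry multiplicative
log-normal noise (MSI intensities are non-negative and right-skewed) and
the m/z axis carries Gaussian ppm jitter emulating mass-measurement error.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ISOTOPE_SPACING
from .library import LipidLibrary, bundled_library
from .peakmatrix import PeakMatrix


class SynthError(ValueError):
    pass


@dataclass
class PlantedLipid:
    name: str
    transforms: List[str]
    base_intensity: float = 1000.0
    center: Optional[Tuple[float, float]] = None   # None: drawn from seed
    width: float = 8.0                             # blob sigma, pixels
    ion_scales: Optional[List[float]] = None       # per-form intensity scale


@dataclass
class SyntheticSpec:
    grid: Tuple[int, int] = (64, 64)
    planted: List[PlantedLipid] = field(default_factory=list)
    polarity: str = "negative"
    isotopes: bool = False
    isotope_orders: int = 2
    isotope_abundance: float = 0.4   # satellite k scaled by abundance**k
    noise_peaks: int = 30
    noise_mz_range: Tuple[float, float] = (550.0, 1200.0)
    noise_avoid_ppm: float = 15.0    # keep noise outside library ion windows
    background_mz: List[float] = field(default_factory=list)
    mass_error_ppm: float = 2.0
    pixel_noise: float = 0.3         # sd of log-normal multiplicative noise
    seed: int = 0


@dataclass
class GroundTruth:
    # lipid name -> {transform name -> peak index in the emitted matrix}
    planted: Dict[str, Dict[str, int]]
    # satellite index -> (parent peak index, isotope order)
    satellites: Dict[int, Tuple[int, int]]
    noise: List[int]

    def expected_lo(self, lipid: str) -> int:
        return len(self.planted[lipid])


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The reference study conditions: 64x64 grid, 8 lipids x 4 correlated
    ion forms, 30 uncorrelated noise peaks, 2 ppm mass jitter.

    The planted species are chosen so that their ion forms do not alias
    other species of the bundled table (e.g. the PC c:d [M-CH3] vs
    PE c+2:d [M-H] isobar, 0.55 mDa apart, is avoided by picking PC species
    whose +2-carbon PE partner is absent), keeping the planted ground truth
    unambiguous at the 5 ppm working tolerance.
    """
    pc = ["[M-H]-", "[M+Cl]-", "[M-CH3]-", "[M-CH3-NH2]-"]
    pi = ["[M-H]-", "[M-OH]-", "[M-CH3]-", "[M+Na-2H]-"]
    planted = [PlantedLipid(f"PC {c}:{d}", pc) for c, d in
               [(34, 0), (36, 1), (36, 2), (38, 4)]]
    planted += [PlantedLipid(f"PI {c}:{d}", pi) for c, d in
                [(32, 0), (34, 1), (36, 2), (38, 3)]]
    return SyntheticSpec(planted=planted, seed=seed, **overrides)


def _blob(grid: Tuple[int, int], center: Tuple[float, float], sigma: float) -> np.ndarray:
    w, h = grid
    xs, ys = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2)).ravel()


def generate(
    spec: SyntheticSpec,
    library: Optional[LipidLibrary] = None,
) -> Tuple[PeakMatrix, GroundTruth]:
    """Emit a peak matrix plus the ground truth of what was planted where."""
    lib = library if library is not None else bundled_library()
    w, h = spec.grid
    if w < 4 or h < 4:
        raise SynthError(f"grid {spec.grid} too small for Gaussian blobs")
    rng = np.random.default_rng(spec.seed)
    by_name = {s.name: s for s in lib.species}

    mz_list: List[float] = []
    columns: List[np.ndarray] = []
    tags: List[Tuple[str, object]] = []   # ("ion", (lipid, transform)) etc.
    n_pix = w * h

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, spec.mass_error_ppm) * 1e-6)

    def lognoise(n: int) -> np.ndarray:
        if spec.pixel_noise <= 0:
            return np.ones(n)
        return rng.lognormal(mean=0.0, sigma=spec.pixel_noise, size=n)

    for pl in spec.planted:
        if pl.name not in by_name:
            raise SynthError(f"planted lipid {pl.name!r} not in the library")
        lipid = by_name[pl.name]
        valid = {t.name for t in lib.transforms_for(lipid.lipid_class, spec.polarity)}
        bad = [t for t in pl.transforms if t not in valid]
        if bad:
            raise SynthError(f"{pl.name}: transforms {bad} not valid for class "
                             f"{lipid.lipid_class} in {spec.polarity} mode")
        center = (pl.center if pl.center is not None
                  else (rng.uniform(0, w - 1), rng.uniform(0, h - 1)))
        if pl.width >= max(w, h):
            raise SynthError(f"{pl.name}: blob width {pl.width} exceeds grid")
        pattern = _blob(spec.grid, center, pl.width)
        scales = pl.ion_scales or [1.0] * len(pl.transforms)
        for tname, scale in zip(pl.transforms, scales):
            theo = lib.ion_mz(lipid, lib.transforms[tname])
            col = pl.base_intensity * scale * pattern * lognoise(n_pix)
            mz_list.append(jitter(theo))
            columns.append(col)
            tags.append(("ion", (pl.name, tname)))
            if spec.isotopes:
                for k in range(1, spec.isotope_orders + 1):
                    mz_list.append(jitter(theo + k * ISOTOPE_SPACING))
                    columns.append(col * spec.isotope_abundance ** k
                                   * lognoise(n_pix))
                    tags.append(("isotope", (pl.name, tname, k)))

    def independent_peak(m: float, tag) -> None:
        center = (rng.uniform(0, w - 1), rng.uniform(0, h - 1))
        pattern = _blob(spec.grid, center, rng.uniform(3.0, 12.0))
        mz_list.append(m)
        columns.append(rng.uniform(100.0, 2000.0) * pattern * lognoise(n_pix))
        tags.append(tag)

    # background peaks at caller-chosen m/z (e.g. decoy-library ion masses
    # in a validation scenario); independent pattern each, recorded as noise
    for b, m in enumerate(spec.background_mz):
        independent_peak(jitter(m), ("noise", f"bg{b}"))

    lo_mz, hi_mz = spec.noise_mz_range
    if hi_mz <= lo_mz:
        raise SynthError("empty noise m/z range")
    library_ions = np.sort([m for _s, _t, m in lib.search_space(spec.polarity)])
    for i in range(spec.noise_peaks):
        for _ in range(1000):
            m = rng.uniform(lo_mz, hi_mz)
            if any(abs(m - e) <= 0.05 for e in mz_list):
                continue
            # keep random noise outside library ion windows so the planted
            # ground truth (which peak belongs to which lipid) stays exact
            j = np.searchsorted(library_ions, m)
            near = [library_ions[q] for q in (j - 1, j)
                    if 0 <= q < len(library_ions)]
            if any(abs(m - t) <= m * spec.noise_avoid_ppm * 1e-6 for t in near):
                continue
            break
        else:
            raise SynthError("could not place a noise peak away from existing "
                             "m/z values; widen noise_mz_range")
        independent_peak(m, ("noise", i))

    mz = np.array(mz_list)
    order = np.argsort(mz)
    inv = {int(orig): new for new, orig in enumerate(order)}
    if np.any(np.diff(mz[order]) < mz[order][:-1] * 1e-6):
        raise SynthError("planted m/z values collide at the working tolerance; "
                         "change the seed or reduce mass_error_ppm")

    intensity = np.column_stack(columns)[:, order]
    xs, ys = np.meshgrid(np.arange(w), np.arange(h), indexing="ij")
    pm = PeakMatrix(
        pixels=np.column_stack([xs.ravel(), ys.ravel()]),
        mz=mz[order],
        intensity=intensity,
        polarity=spec.polarity,
        source=f"synthetic(seed={spec.seed})",
    )

    planted: Dict[str, Dict[str, int]] = {}
    satellites: Dict[int, Tuple[int, int]] = {}
    noise: List[int] = []
    ion_index: Dict[Tuple[str, str], int] = {}
    for orig, (tag, payload) in enumerate(tags):
        new = inv[orig]
        if tag == "ion":
            lip, tname = payload
            planted.setdefault(lip, {})[tname] = new
            ion_index[(lip, tname)] = new
    for orig, (tag, payload) in enumerate(tags):
        new = inv[orig]
        if tag == "isotope":
            lip, tname, k = payload
            satellites[new] = (ion_index[(lip, tname)], k)
        elif tag == "noise":
            noise.append(new)
    return pm, GroundTruth(planted=planted, satellites=satellites, noise=sorted(noise))


def validation_scenario(
    seed: int,
    library: Optional[LipidLibrary] = None,
    n_background: int = 12,
    ppm_tol: float = 5.0,
    **spec_overrides,
):
    """A self-contained target-decoy validation scenario.

    Builds the implausible-transform decoy library for ``seed``, then
    generates the reference synthetic matrix with ``n_background`` extra
    uncorrelated background peaks placed at ion m/z values of distinct decoy
    species. Real datasets carry a sea of unassigned background peaks, some
    of which inevitably fall in decoy windows; at desk scale that background
    must be planted explicitly or the decoy search has nothing to hit.

    Returns (peak matrix, ground truth, target library, decoy library).
    """
    from .decoyval import make_decoy_transforms

    lib = library if library is not None else bundled_library()
    decoy = make_decoy_transforms(lib, seed=seed, ppm_tol=ppm_tol)
    rng = np.random.default_rng(seed + 10007)
    by_species: Dict[str, List[float]] = {}
    for sp, _t, mz in decoy.library.search_space("negative"):
        by_species.setdefault(sp.name, []).append(mz)
    names = sorted(by_species)
    picked = rng.choice(len(names), size=min(n_background, len(names)),
                        replace=False)
    background = [float(rng.choice(by_species[names[i]])) for i in picked]
    spec = default_spec(seed=seed, background_mz=background, **spec_overrides)
    pm, truth = generate(spec, lib)
    return pm, truth, lib, decoy


def generate_decoy_compounds(
    n: int,
    mass_range: Tuple[float, float],
    seed: int = 0,
) -> pd.DataFrame:
    """n pseudo-compounds with CHNOP formulas, masses ~uniform in range.

    A synthetic stand-in for a real out-of-sample compound list (e.g.
    non-animal metabolites and xenobiotics) for tests and demos only;
    deterministic per seed. Returns a DataFrame with columns name, formula.
    """
    from .chem import MONOISOTOPIC_MASS as EM

    if n <= 0:
        raise SynthError("n must be > 0")
    lo, hi = mass_range
    if hi <= lo or lo <= 0:
        raise SynthError("empty or invalid mass range")
    rng = np.random.default_rng(seed)
    rows = []
    while len(rows) < n:
        u = rng.uniform(lo, hi)
        p = int(rng.integers(0, 2))
        o = int(rng.integers(2, 14))
        nn = int(rng.integers(0, 3))
        rem = u - p * EM["P"] - o * EM["O"] - nn * EM["N"]
        c = int(rem // 13.1)
        if c < 1:
            continue
        hyd = int(round(rem - 12.0 * c))
        if hyd < 0:
            continue
        mass = 12.0 * c + hyd * EM["H"] + nn * EM["N"] + o * EM["O"] + p * EM["P"]
        if not (lo <= mass <= hi):
            continue
        formula = f"C{c}H{hyd}" + (f"N{nn}" if nn else "") + f"O{o}" + ("P" if p else "")
        rows.append(dict(name=f"synthcpd_{len(rows):04d}", formula=formula))
    return pd.DataFrame(rows)
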