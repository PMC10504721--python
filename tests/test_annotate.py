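"""Exact-mass search, spatial correlation and the LO/C/S ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipisf import PeakMatrix
from lipisf.annotate import (
    build_annotation_table,
    exact_mass_search,
    score_groups,
    spatial_correlation,
)
from lipisf.chem import ppm_error
from lipisf.synthdata import default_spec, generate


def _pm_with_mz(mz, n_pixels=4, seed=0):
    rng = np.random.default_rng(seed)
    return PeakMatrix(
        pixels=[(i, 0) for i in range(n_pixels)],
        mz=np.sort(np.asarray(mz, float)),
        intensity=rng.uniform(0, 10, size=(n_pixels, len(mz))),
    )


class TestExactMassSearch:
    def test_exact_peak_matches_with_zero_ppm(self, library):
        pi = next(s for s in library.species if s.name == "PI 38:3")
        theo = library.ion_mz(pi, library.transforms["[M-H]-"])
        pm = _pm_with_mz([600.0, theo, 1000.0])
        hits = [m for m in exact_mass_search(pm, library, "negative", 5.0)
                if m.lipid.name == "PI 38:3" and m.transform.name == "[M-H]-"]
        assert len(hits) == 1
        assert hits[0].ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_peak_outside_tolerance_not_matched(self, library):
        pi = next(s for s in library.species if s.name == "PI 38:3")
        theo = library.ion_mz(pi, library.transforms["[M-H]-"])
        pm = _pm_with_mz([theo * (1 + 10e-6)])
        hits = [m for m in exact_mass_search(pm, library, "negative", 5.0)
                if m.lipid.name == "PI 38:3" and m.transform.name == "[M-H]-"]
        assert hits == []

    def test_isobaric_lipids_share_one_peak(self, library):
        """The bundled library contains real isobars (e.g. the PC [M-CH3]
        vs PE [M-H] methyl/proton pair, 0.55 mDa apart); both candidates
        must be reported on the colliding peak. The pair is found by a
        brute-force scan of all ion m/z collisions."""
        space = library.search_space("negative")
        collision = None
        for i in range(len(space)):
            for j in range(i + 1, len(space)):
                si, ti, mi = space[i]
                sj, tj, mj = space[j]
                if si.name != sj.name and abs(ppm_error(mi, mj)) < 2.0:
                    collision = (mi, si.name, sj.name)
                    break
            if collision:
                break
        assert collision is not None, "bundled library should contain isobars"
        mz, name_a, name_b = collision
        pm = _pm_with_mz([mz])
        hit_names = {m.lipid.name for m in
                     exact_mass_search(pm, library, "negative", 5.0)}
        assert {name_a, name_b} <= hit_names

    def test_empty_matrix_returns_empty(self, library):
        pm = PeakMatrix(pixels=np.empty((0, 2)), mz=[],
                        intensity=np.empty((0, 0)))
        assert exact_mass_search(pm, library, "negative", 5.0) == []

    def test_one_peak_per_hypothesis_minimum_ppm(self, library):
        pc = next(s for s in library.species if s.name == "PC 34:1")
        theo = library.ion_mz(pc, library.transforms["[M-H]-"])
        pm = _pm_with_mz([theo * (1 - 3e-6), theo * (1 + 1e-6)])
        hits = [m for m in exact_mass_search(pm, library, "negative", 5.0)
                if m.lipid.name == "PC 34:1" and m.transform.name == "[M-H]-"]
        assert len(hits) == 1
        assert hits[0].ppm_error == pytest.approx(1.0, abs=1e-3)

    def test_agrees_with_exhaustive_all_pairs_scan(self, library):
        """Oracle equivalence on random small matrices: the searched match
        set equals the brute-force set of within-tolerance minima."""
        rng = np.random.default_rng(42)
        space = library.search_space("negative")
        for trial in range(200):
            k = rng.integers(3, 21)
            idx = rng.choice(len(space), size=rng.integers(3, 21), replace=False)
            sub = [space[i] for i in idx]
            mz = np.sort(rng.uniform(550, 1200, size=k))
            pm = _pm_with_mz(mz, n_pixels=3, seed=trial)
            # restrict the library to the sampled species
            names = {s.name for s, _t, _m in sub}
            import copy
            lib2 = copy.copy(library)
            lib2.species = [s for s in library.species if s.name in names]
            got = {(m.lipid.name, m.transform.name, m.peak_index)
                   for m in exact_mass_search(pm, lib2, "negative", 50.0)}
            expect = set()
            for s, t, theo in lib2.search_space("negative"):
                errs = np.abs(1e6 * (pm.mz - theo) / theo)
                j = int(np.argmin(errs))
                if errs[j] <= 50.0:
                    expect.add((s.name, t.name, j))
            assert got == expect


class TestSpatialCorrelation:
    def test_identical_columns_give_one(self):
        pm = PeakMatrix(pixels=[(i, 0) for i in range(4)],
                        mz=[700.0, 800.0],
                        intensity=np.array([[1, 1], [2, 2], [3, 3], [4, 4.0]]))
        assert spatial_correlation(pm, [0, 1]) == pytest.approx(1.0)

    def test_single_index_gives_zero(self, toy_pm):
        assert spatial_correlation(toy_pm, [0]) == 0.0

    def test_empty_index_set_is_an_error(self, toy_pm):
        with pytest.raises(ValueError):
            spatial_correlation(toy_pm, [])

    def test_mean_over_distinct_pairs_matches_numpy(self, toy_pm):
        """Independent oracle: np.corrcoef on the frozen 5-pixel matrix."""
        r = np.corrcoef(toy_pm.intensity, rowvar=False)
        expected = (r[0, 1] + r[0, 2] + r[1, 2]) / 3.0
        assert spatial_correlation(toy_pm, [0, 1, 2]) == pytest.approx(expected)

    def test_zero_variance_column_contributes_zero(self):
        pm = PeakMatrix(pixels=[(i, 0) for i in range(4)],
                        mz=[700.0, 800.0],
                        intensity=np.array([[5, 1], [5, 2], [5, 3], [5, 4.0]]))
        assert spatial_correlation(pm, [0, 1]) == 0.0

    def test_pixel_permutation_leaves_c_unchanged(self, library):
        pm, _ = generate(default_spec(seed=2, grid=(16, 16), noise_peaks=5),
                         library)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pm.n_pixels)
        pm2 = PeakMatrix(pixels=pm.pixels[perm], mz=pm.mz,
                         intensity=pm.intensity[perm])
        idx = [0, 1, 2, 3]
        assert spatial_correlation(pm2, idx) == pytest.approx(
            spatial_correlation(pm, idx), abs=1e-12)


class TestScoring:
    def test_score_law_on_groups(self, library, synthetic):
        pm, _ = synthetic
        matches = exact_mass_search(pm, library, "negative", 5.0)
        groups = score_groups(matches, pm)
        assert groups
        for g in groups:
            assert g.LO == len(g.matches) >= 1
            assert g.S == g.LO * (1.0 + g.C)
            assert 0.0 <= g.S <= 2.0 * g.LO

    @given(st.integers(1, 10), st.floats(-1, 1))
    @settings(deadline=None)
    def test_score_monotonicity(self, lo, c):
        s = lo * (1.0 + c)
        assert (lo + 1) * (1.0 + c) >= s
        if c < 1.0:
            assert lo * (1.0 + min(1.0, c + 0.1)) >= s

    def test_planted_lipid_with_five_perfect_forms(self, library):
        from lipisf.synthdata import PlantedLipid, SyntheticSpec

        spec = SyntheticSpec(
            grid=(16, 16),
            planted=[PlantedLipid("PI 38:3",
                                  ["[M-H]-", "[M-OH]-", "[M-CH3]-",
                                   "[M+Na-2H]-", "[M-CH3-NH2]-"])],
            noise_peaks=0, pixel_noise=0.0, mass_error_ppm=0.0, seed=7)
        pm, _ = generate(spec, library)
        groups = score_groups(exact_mass_search(pm, library, "negative", 5.0), pm)
        g = next(g for g in groups if g.lipid.name == "PI 38:3")
        assert g.LO == 5
        assert g.C == pytest.approx(1.0, abs=1e-9)
        assert g.S == pytest.approx(10.0, abs=1e-6)


class TestAnnotationTable:
    def test_all_rows_kept_without_top_n(self, library, synthetic):
        pm, _ = synthetic
        matches = exact_mass_search(pm, library, "negative", 5.0)
        groups = score_groups(matches, pm)
        table = build_annotation_table(groups)
        assert len(table) == len(matches)

    def test_rank_within_peak_is_contiguous(self, library, synthetic):
        pm, _ = synthetic
        groups = score_groups(exact_mass_search(pm, library, "negative", 5.0), pm)
        table = build_annotation_table(groups)
        for _, sub in table.groupby("peak_index"):
            assert list(sub.rank_within_peak) == list(range(1, len(sub) + 1))
            assert list(sub.S) == sorted(sub.S, reverse=True)

    def test_top_n_truncates(self, library, synthetic):
        pm, _ = synthetic
        groups = score_groups(exact_mass_search(pm, library, "negative", 5.0), pm)
        table = build_annotation_table(groups, top_n=2)
        assert table.rank_within_peak.max() <= 2

    def test_top_n_must_be_positive(self):
        with pytest.raises(ValueError):
            build_annotation_table([], top_n=0)

    def test_equal_scores_break_ties_by_ppm_then_name(self, library):
        from lipisf.annotate import IonMatch
        from lipisf.chem import IonTransform

        sp = {s.name: s for s in library.species}
        t = library.transforms["[M-H]-"]
        pm = _pm_with_mz([700.0])
        matches = [
            IonMatch(sp["PA 34:1"], t, 0, 700.0, 700.0 + 700e-6 * 1.2, 1.2),
            IonMatch(sp["PG 34:1"], t, 0, 700.0, 700.0 + 700e-6 * 0.3, 0.3),
        ]
        groups = score_groups(matches, pm)
        table = build_annotation_table(groups)
        assert set(table.S) == {1.0}
        assert list(table.lipid) == ["PG 34:1", "PA 34:1"]
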