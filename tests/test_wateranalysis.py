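"""Dipoles, H-bond counts, retention, grids, annuli, dangling OH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chiralsfg import synthetic as syn
from chiralsfg.spectrum import SpectrumResult
from chiralsfg.system import Frame, Subset, orthorhombic_box
from chiralsfg.wateranalysis import (DipoleGrid, annulus_dipole_profile,
                                     dangling_oh_fraction, dipole_grid,
                                     hbond_counts_per_water,
                                     mean_hbonds_per_water,
                                     mirror_asymmetry_score, retention_times,
                                     signal_vs_retention, water_dipole)


class TestWaterDipole:
    def test_template_water_dipole_along_bisector_toward_oxygen(self):
        template = syn.WaterTemplate.tip4pew()
        pos = syn.make_water(np.full(3, 10.0), np.eye(3), template)
        topo = syn.water_topology(1, template)
        frame = Frame(pos, orthorhombic_box(20, 20, 20))
        mu = water_dipole(frame, topo, 0)
        # hydrogens on +z in the template frame: dipole points to -z (toward O)
        assert mu[2] < 0
        assert np.allclose(mu[:2], 0, atol=1e-12)
        assert np.linalg.norm(mu) == pytest.approx(
            template.gas_phase_dipole_debye(), abs=1e-9)

    def test_rotation_equivariance(self):
        template = syn.WaterTemplate.tip4pew()
        rng = np.random.default_rng(2)
        R = syn.random_rotation(rng)
        topo = syn.water_topology(1, template)
        f0 = Frame(syn.make_water(np.full(3, 10.0), np.eye(3), template),
                   orthorhombic_box(20, 20, 20))
        f1 = Frame(syn.make_water(np.full(3, 10.0), R, template),
                   orthorhombic_box(20, 20, 20))
        assert np.allclose(water_dipole(f1, topo, 0),
                           R @ water_dipole(f0, topo, 0), atol=1e-12)

    def test_magnitude_matches_site_sum_oracle(self):
        template = syn.WaterTemplate.tip4pew()
        rng = np.random.default_rng(3)
        pos = syn.make_water(np.full(3, 10.0), syn.random_rotation(rng),
                             template)
        topo = syn.water_topology(1, template)
        frame = Frame(pos, orthorhombic_box(20, 20, 20))
        q = template.charge_array()
        expected = -4.80320425 * sum(q[i] * (pos[i] - pos[0])
                                     for i in range(4))
        assert np.allclose(water_dipole(frame, topo, 0), expected, atol=1e-12)


class TestHBondCounts:
    def test_isolated_water_has_zero(self):
        template = syn.WaterTemplate.tip4pew()
        topo = syn.water_topology(1, template)
        frame = Frame(syn.make_water(np.full(3, 10.0), np.eye(3), template),
                      orthorhombic_box(20, 20, 20))
        assert mean_hbonds_per_water([frame], topo) == 0.0

    def test_dimer_each_partner_counts_one(self):
        from test_shells import _linear_dimer
        topo, frame = _linear_dimer(r_oo=2.8, angle_deg=180.0)
        counts = hbond_counts_per_water(frame, topo)
        assert counts[0] >= 1 and counts[1] >= 1
        assert sum(counts.values()) == 2 * len(
            [1])  # one bond, two participants

    def test_cluster_matches_hand_enumeration(self):
        """A 5-water cross (central donor surrounded by 4 tetrahedral-ish
        acceptors at 2.8 A) has exactly the hand-counted bonds."""
        from test_shells import _h1_along_x
        template = syn.WaterTemplate.tip4pew()
        center = np.full(3, 15.0)
        waters = [syn.make_water(center, _h1_along_x(template), template)]
        # acceptor along +x (H1 points straight at it)
        waters.append(syn.make_water(center + [2.8, 0, 0],
                                     np.diag([-1.0, 1.0, -1.0]), template))
        # far waters that bond to nothing
        waters.append(syn.make_water(center + [0, 9.0, 0], np.eye(3), template))
        waters.append(syn.make_water(center + [0, -9.0, 0], np.eye(3), template))
        topo = syn.water_topology(4, template)
        frame = Frame(np.vstack(waters), orthorhombic_box(30, 30, 30))
        counts = hbond_counts_per_water(frame, topo)
        assert counts[0] == 1 and counts[1] == 1
        assert counts[2] == 0 and counts[3] == 0
        assert mean_hbonds_per_water([frame], topo) == pytest.approx(0.5)


class TestRetention:
    def test_permanent_member_spans_trajectory(self):
        sub = Subset("s", [{7} for _ in range(100)])
        rec = retention_times(sub, time_step=1.0)
        assert rec.mean_retention == 100.0
        assert rec.n_episodes == 1
        assert rec.n_censored == 1

    def test_alternating_membership(self):
        sub = Subset("s", [{1} if i % 2 == 0 else set() for i in range(10)])
        rec = retention_times(sub, time_step=1.0)
        assert rec.mean_retention == 1.0
        assert rec.n_episodes == 5

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_run_length_encoding_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_frames, n_mols = 30, 4
        member = rng.random((n_frames, n_mols)) < 0.4
        if not member.any():
            member[0, 0] = True
        sub = Subset("s", [set(np.flatnonzero(member[f]))
                           for f in range(n_frames)])
        rec = retention_times(sub, time_step=1.0)
        durations = []
        for m in range(n_mols):
            runs = "".join("1" if member[f, m] else "0"
                           for f in range(n_frames)).split("0")
            durations += [float(len(r)) for r in runs if r]
        assert sorted(rec.episode_durations) == sorted(durations)
        if durations:
            assert rec.mean_retention == pytest.approx(np.mean(durations))

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            retention_times(Subset("s", [set(), set()]))


class TestDipoleGrid:
    def _static_system(self, n_frames=10):
        template = syn.WaterTemplate.tip4pew()
        pos = syn.make_water(np.array([4.2, 7.7, 10.0]), np.eye(3), template)
        topo = syn.water_topology(1, template)
        frames = [Frame(pos.copy(), orthorhombic_box(20, 20, 20), "z", float(t))
                  for t in range(n_frames)]
        return topo, frames

    def test_static_water_accumulates_in_one_cell(self):
        topo, frames = self._static_system(10)
        grid = dipole_grid(frames, topo, 1.0, (-50.0, 50.0))
        assert grid.occupancy.sum() == 10
        assert grid.occupancy[4, 7] == 10
        mu = water_dipole(frames[0], topo, 0)
        assert np.allclose(grid.vectors[4, 7], 10 * mu, atol=1e-9)

    def test_total_vector_conserved_under_binning(self, template_system):
        topo, frames = template_system
        grid = dipole_grid(frames, topo, 2.0, (-100.0, 100.0))
        total = np.zeros(3)
        for frame in frames:
            for m in topo.water_molecule_ids():
                total += water_dipole(frame, topo, int(m))
        assert np.allclose(grid.vectors.sum(axis=(0, 1)), total, atol=1e-9)
        assert grid.occupancy.sum() == len(frames) * len(
            topo.water_molecule_ids())

    def test_mirror_paired_waters_give_antisymmetric_inplane_field(self):
        template = syn.WaterTemplate.tip4pew()
        rng = np.random.default_rng(4)
        R = syn.random_rotation(rng)
        p1 = syn.make_water(np.array([12.3, 8.1, 10.0]), R, template)
        p2 = p1.copy()
        p2[:, 0] = 20.0 - p2[:, 0]  # mirror across x = 10
        topo = syn.water_topology(2, template)
        frame = Frame(np.vstack([p1, p2]), orthorhombic_box(20, 20, 20))
        grid = dipole_grid([frame], topo, 1.0, (-50.0, 50.0))
        mu1 = grid.vectors[12, 8]
        mu2 = grid.vectors[7, 8]
        assert mu1[0] == pytest.approx(-mu2[0], abs=1e-12)
        assert mu1[1] == pytest.approx(mu2[1], abs=1e-12)
        assert mu1[2] == pytest.approx(mu2[2], abs=1e-12)

    def test_matches_direct_binning_oracle(self, template_system):
        topo, frames = template_system
        grid = dipole_grid(frames, topo, 1.5, (-100.0, 100.0))
        vectors = np.zeros_like(grid.vectors)
        occ = np.zeros_like(grid.occupancy)
        lx = frames[0].box_vectors[0, 0]
        ly = frames[0].box_vectors[1, 1]
        for frame in frames:
            for m in topo.water_molecule_ids():
                o = topo.water_sites(int(m))["O"]
                x, y = frame.positions[o, 0] % lx, frame.positions[o, 1] % ly
                i, j = int(x / 1.5), int(y / 1.5)
                vectors[i, j] += water_dipole(frame, topo, int(m))
                occ[i, j] += 1
        assert np.array_equal(occ, grid.occupancy)
        assert np.allclose(vectors, grid.vectors, atol=1e-12)


class TestAnnuli:
    def _grid_from_vectors(self, vectors, occupancy, res=1.0):
        return DipoleGrid(vectors, occupancy, res, np.zeros(2), (0, 1),
                          (0.0, 10.0))

    def test_radially_symmetric_field_cancels(self):
        n = 21
        vectors = np.zeros((n, n, 3))
        occ = np.zeros((n, n), dtype=int)
        c = (n - 1) / 2.0 + 0.5
        for i in range(n):
            for j in range(n):
                r = np.array([i + 0.5 - c, j + 0.5 - c, 0.0])
                if 2.0 < np.linalg.norm(r) < 9.0:
                    vectors[i, j] = -r / np.linalg.norm(r)  # inward
                    occ[i, j] = 1
        grid = self._grid_from_vectors(vectors, occ)
        prof = annulus_dipole_profile(grid, (c, c), 1.0)
        busy = prof[prof.occupancy > 4]
        assert (busy.magnitude < 0.35 * busy.occupancy ** 0.5).all()

    def test_single_cell_lands_in_its_ring(self):
        vectors = np.zeros((20, 20, 3))
        occ = np.zeros((20, 20), dtype=int)
        vectors[15, 10] = [0.0, 3.0, 4.0]
        occ[15, 10] = 1
        grid = self._grid_from_vectors(vectors, occ)
        prof = annulus_dipole_profile(grid, (10.0, 10.0), 1.0)
        # cell center (15.5, 10.5) is at r = 5.52 from (10, 10): ring 5-6
        ring = prof[(prof.r_inner == 5.0)].iloc[0]
        assert ring.magnitude == pytest.approx(5.0)
        assert ring.magnitude_inplane == pytest.approx(3.0)
        assert prof[prof.r_inner != 5.0].magnitude.max() == 0.0

    def test_matches_per_cell_ring_sum_oracle(self):
        rng = np.random.default_rng(6)
        vectors = rng.normal(size=(15, 15, 3))
        occ = np.ones((15, 15), dtype=int)
        grid = self._grid_from_vectors(vectors, occ)
        center = (7.0, 7.0)
        prof = annulus_dipole_profile(grid, center, 2.0)
        for _, row in prof.iterrows():
            vsum = np.zeros(3)
            for i in range(15):
                for j in range(15):
                    r = np.hypot(i + 0.5 - center[0], j + 0.5 - center[1])
                    if row.r_inner <= r < row.r_outer:
                        vsum += vectors[i, j]
            assert row.magnitude == pytest.approx(np.linalg.norm(vsum),
                                                  abs=1e-9)

    def test_center_outside_grid_rejected(self):
        grid = self._grid_from_vectors(np.zeros((5, 5, 3)),
                                       np.ones((5, 5), dtype=int))
        with pytest.raises(ValueError, match="outside"):
            annulus_dipole_profile(grid, (40.0, 40.0), 1.0)


class TestMirrorAsymmetryScore:
    def _grid(self, vectors, occ):
        return DipoleGrid(vectors, occ, 1.0, np.zeros(2), (0, 1), (0.0, 10.0))

    def test_symmetric_field_scores_zero(self):
        n = 10
        vectors = np.zeros((n, n, 3))
        occ = np.ones((n, n), dtype=int)
        rng = np.random.default_rng(7)
        for i in range(n // 2):
            for j in range(n):
                v = rng.normal(size=3)
                vectors[i, j] = v
                mirror = v.copy()
                mirror[0] = -mirror[0]
                vectors[n - 1 - i, j] = mirror
        score = mirror_asymmetry_score(self._grid(vectors, occ), 0, n / 2.0)
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_field_scores_twice_rms(self):
        n = 10
        rng = np.random.default_rng(8)
        vectors = np.zeros((n, n, 3))
        occ = np.ones((n, n), dtype=int)
        for i in range(n // 2):
            for j in range(n):
                v = rng.normal(size=3)
                vectors[i, j] = v
                anti = -v.copy()
                anti[0] = v[0]  # negate mirror-even parts -> pure antisymmetry
                vectors[n - 1 - i, j] = anti
        grid = self._grid(vectors, occ)
        score = mirror_asymmetry_score(grid, 0, n / 2.0)
        rms2 = np.sqrt(np.mean(np.sum((2 * vectors) ** 2, axis=2)))
        assert score == pytest.approx(rms2, rel=1e-12)

    def test_matches_direct_per_cell_computation(self):
        rng = np.random.default_rng(9)
        n = 8
        vectors = rng.normal(size=(n, n, 3))
        occ = rng.integers(0, 3, (n, n))
        vectors[occ == 0] = 0.0
        grid = self._grid(vectors, occ.astype(int))
        score = mirror_asymmetry_score(grid, 1, n / 2.0)
        field = grid.mean_field()
        diffs = []
        for i in range(n):
            for j in range(n):
                mj = n - 1 - j
                if occ[i, j] and occ[i, mj]:
                    mv = field[i, mj].copy()
                    mv[1] = -mv[1]
                    diffs.append(field[i, j] - mv)
        expected = np.sqrt(np.mean(np.sum(np.asarray(diffs) ** 2, axis=1)))
        assert score == pytest.approx(expected, abs=1e-12)


class TestDanglingOH:
    def _vertical_oh_water(self, center, template, up=True):
        """Water with H1 pointing along +z (toward vacuum) or -z."""
        from test_shells import _h1_along_x
        rot = _h1_along_x(template)
        swap = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        R = swap @ rot  # lab x -> lab z
        if not up:
            R = np.diag([1.0, -1.0, -1.0]) @ R
        return syn.make_water(center, R, template)

    def test_vacuum_pointing_free_oh_counted(self):
        template = syn.WaterTemplate.tip4pew()
        pos = self._vertical_oh_water(np.full(3, 10.0), template, up=True)
        topo = syn.water_topology(1, template)
        frame = Frame(pos, orthorhombic_box(20, 20, 20))
        assert dangling_oh_fraction([frame], topo, None, 60.0) == 1.0

    def test_downward_oh_not_counted(self):
        template = syn.WaterTemplate.tip4pew()
        pos = self._vertical_oh_water(np.full(3, 10.0), template, up=False)
        topo = syn.water_topology(1, template)
        frame = Frame(pos, orthorhombic_box(20, 20, 20))
        assert dangling_oh_fraction([frame], topo, None, 60.0) == 0.0

    def test_donating_oh_never_counted(self):
        """An upward O-H that donates to an acceptor stays uncounted."""
        template = syn.WaterTemplate.tip4pew()
        donor = self._vertical_oh_water(np.full(3, 10.0), template, up=True)
        h1 = donor[1]
        acc_o = h1 + np.array([0.0, 0.0, 2.8 - template.r_OH])
        acc = syn.make_water(acc_o, np.diag([1.0, -1.0, -1.0]), template)
        topo = syn.water_topology(2, template)
        frame = Frame(np.vstack([donor, acc]), orthorhombic_box(25, 25, 25))
        sub = Subset.constant("donor", [0], 1)
        assert dangling_oh_fraction([frame], topo, sub, 60.0) == 0.0

    def test_hand_counted_fraction(self):
        """10 waters, 3 with free vacuum-pointing OH: fraction 0.30."""
        template = syn.WaterTemplate.tip4pew()
        waters = []
        for k in range(10):
            center = np.array([3.0 + 4.5 * (k % 5), 5.0 + 9.0 * (k // 5), 10.0])
            waters.append(self._vertical_oh_water(center, template, up=k < 3))
        topo = syn.water_topology(10, template)
        frame = Frame(np.vstack(waters), orthorhombic_box(26, 26, 26))
        assert dangling_oh_fraction([frame], topo, None, 60.0) == \
            pytest.approx(0.3)


class TestSignalVsRetention:
    def _fake_result(self, scale):
        grid = np.arange(3000.0, 3500.0, 1.0)
        im = scale * np.exp(-0.5 * ((grid - 3250) / 40.0) ** 2)
        return SpectrumResult(grid, 1j * im, "zyx", "s", 1, 1.0)

    def test_identical_subsets_identical_rows(self):
        subs = [Subset.constant("a", [0], 3), Subset.constant("b", [1], 3)]
        spectra = {"a": self._fake_result(1.0), "b": self._fake_result(1.0)}
        ret = {n: retention_times(Subset(n, [{0}, {0}, set()]))
               for n in ("a", "b")}
        df = signal_vs_retention(subs, spectra, ret, band=(3000.0, 3499.0))
        assert df.per_water_band_area.nunique() == 1
        assert df.mean_retention_ps.nunique() == 1

    def test_monotone_construction_gives_rank_one(self):
        subs = [Subset.constant(n, [0], 4) for n in ("a", "b", "c")]
        spectra = {n: self._fake_result(s)
                   for n, s in zip(("a", "b", "c"), (1.0, 2.0, 3.0))}
        memberships = {"a": [{0}, set(), set(), set()],
                       "b": [{0}, {0}, set(), set()],
                       "c": [{0}, {0}, {0}, set()]}
        ret = {n: retention_times(Subset(n, memberships[n]))
               for n in ("a", "b", "c")}
        df = signal_vs_retention(subs, spectra, ret, band=(3000.0, 3499.0))
        assert df.attrs["rank_correlation"] == pytest.approx(1.0)

    def test_correlation_matches_direct_spearman(self):
        rng = np.random.default_rng(11)
        names = list("abcde")
        subs = [Subset.constant(n, [0], 4) for n in names]
        scales = rng.uniform(0.5, 3.0, 5)
        spectra = {n: self._fake_result(s) for n, s in zip(names, scales)}
        rets = {}
        for n in names:
            k = int(rng.integers(1, 4))
            rets[n] = retention_times(
                Subset(n, [{0}] * k + [set()] * (4 - k)))
        df = signal_vs_retention(subs, spectra, rets, band=(3000.0, 3499.0))
        expected = stats.spearmanr(df.per_water_band_area,
                                   df.mean_retention_ps).statistic
        assert df.attrs["rank_correlation"] == pytest.approx(expected)

    def test_missing_name_rejected(self):
        subs = [Subset.constant("a", [0], 1)]
        with pytest.raises(KeyError):
            signal_vs_retention(subs, {}, {})
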