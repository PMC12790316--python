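"""Sterimol, buried Sterimol, Boltzmann aggregation and the descriptor table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from co2screen.descriptors import (
    aggregate,
    boltzmann_weights,
    build_descriptor_table,
    buried_sterimol,
    co2_affinity,
    radii_for,
    site_b1,
    sterimol,
)
from co2screen.errors import (
    ConsistencyError,
    DegenerateGeometryError,
    GeometryError,
    InputError,
)
from co2screen.fixtures import (
    make_toy_geometries,
    random_geometry,
    random_rotation,
    sterimol_brute_force,
)
from co2screen.units import HARTREE_TO_KCAL, KB_HARTREE, kcal_to_hartree


class TestBoltzmannWeights:
    def test_equal_energies_uniform(self):
        np.testing.assert_allclose(
            boltzmann_weights([0.1, 0.1, 0.1], 298.15), np.full(3, 1 / 3), atol=1e-15
        )

    def test_kT_ln2_gap_gives_two_thirds(self):
        T = 298.15
        gap = KB_HARTREE * T * np.log(2.0)
        w = boltzmann_weights([0.0, gap], T)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_one_kcal_gap_matches_closed_form(self):
        # independent evaluation of the closed form, no min-shift
        T = 298.15
        e = np.array([0.0, kcal_to_hartree(1.0)])
        raw = np.exp(-e / (KB_HARTREE * T))
        expected = raw / raw.sum()
        np.testing.assert_allclose(boltzmann_weights(e, T), expected, atol=1e-14)

    def test_high_T_limit_uniform(self):
        w = boltzmann_weights([0.0, 1e-3, 2e-3], 1e6)
        np.testing.assert_allclose(w, np.full(3, 1 / 3), atol=1e-3)

    def test_low_T_limit_indicator_of_minimum(self):
        w = boltzmann_weights([0.0, 0.01, 0.02], 1.0)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-12)

    def test_large_energies_numerically_stable(self):
        w = boltzmann_weights([-500.0, -500.0 + 1e-3], 298.15)
        assert np.isfinite(w).all() and w.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=8),
        st.floats(1.0, 1e5),
    )
    def test_weights_sum_to_one_and_nonnegative(self, energies, T):
        w = boltzmann_weights(np.array(energies) * 1e-3, T)
        assert w.min() >= 0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            boltzmann_weights([], 298.15)


class TestSterimol:
    def test_collinear_analytic(self):
        toy = make_toy_geometries("collinear")
        sv = sterimol(toy.coordinates, toy.radii, toy.attach_index, toy.axis_index)
        assert sv.L == pytest.approx(toy.expected_L, abs=1e-9)
        assert sv.B1 == pytest.approx(toy.expected_B1, abs=1e-9)
        assert sv.B5 == pytest.approx(toy.expected_B5, abs=1e-9)

    def test_planar_t_analytic(self):
        toy = make_toy_geometries("planar-T")
        sv = sterimol(toy.coordinates, toy.radii, toy.attach_index, toy.axis_index)
        assert sv.B1 == pytest.approx(toy.expected_B1, abs=1e-6)
        assert sv.B5 == pytest.approx(toy.expected_B5, abs=1e-6)

    def test_rigid_motion_invariance(self):
        toy = make_toy_geometries("tetrahedral")
        ref = sterimol(toy.coordinates, toy.radii, 0, 1)
        rng = np.random.default_rng(17)
        for _ in range(5):
            rot = random_rotation(rng)
            moved = toy.coordinates @ rot.T + rng.normal(size=3) * 10
            sv = sterimol(moved, toy.radii, 0, 1)
            assert sv.L == pytest.approx(ref.L, abs=1e-9)
            assert sv.B1 == pytest.approx(ref.B1, abs=1e-9)
            assert sv.B5 == pytest.approx(ref.B5, abs=1e-9)

    def test_matches_fine_grid_oracle_on_asymmetric_toy(self):
        toy = make_toy_geometries("distal-atom")
        sv = sterimol(toy.coordinates, toy.radii, 0, 1)
        assert sv.B1 == pytest.approx(toy.expected_B1, abs=1e-3)
        assert sv.B5 == pytest.approx(toy.expected_B5, abs=1e-3)
        assert sv.L == pytest.approx(toy.expected_L, abs=1e-9)

    def test_b1_never_exceeds_b5_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            coords, radii = random_geometry(rng, n_atoms=6)
            sv = sterimol(coords, radii, 0, 1)
            assert sv.B1 <= sv.B5 + 1e-12

    def test_l_correction_flag(self):
        toy = make_toy_geometries("collinear")
        plain = sterimol(toy.coordinates, toy.radii, 0, 1)
        cpk = sterimol(toy.coordinates, toy.radii, 0, 1, l_correction=0.40)
        assert cpk.L == pytest.approx(plain.L + 0.40, abs=1e-12)

    def test_coincident_axis_atoms_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(GeometryError):
            sterimol(coords, [1.7, 1.7, 1.2], 0, 1)
        with pytest.raises(GeometryError):
            sterimol(coords, [1.7, 1.7, 1.2], 0, 0)


class TestBuriedSterimol:
    def test_everything_inside_sphere_equals_plain(self):
        toy = make_toy_geometries("tetrahedral")
        plain = sterimol(toy.coordinates, toy.radii, 0, 1)
        buried = buried_sterimol(toy.coordinates, toy.radii, 0, 1, buried_radius=50.0)
        assert buried.B1 == pytest.approx(plain.B1, abs=1e-12)
        assert buried.B5 == pytest.approx(plain.B5, abs=1e-12)
        assert buried.L == pytest.approx(plain.L, abs=1e-12)

    def test_excluding_distal_atom_lowers_b5_keeps_b1(self):
        toy = make_toy_geometries("distal-atom")
        plain = sterimol(toy.coordinates, toy.radii, 0, 1)
        buried = buried_sterimol(toy.coordinates, toy.radii, 0, 1, buried_radius=5.5)
        assert buried.B5 < plain.B5
        assert buried.B1 == pytest.approx(plain.B1, abs=1e-6)

    def test_compositional_oracle_on_random_geometries(self):
        # buried == (filter atoms by sphere) -> plain fine-grid Sterimol
        rng = np.random.default_rng(23)
        for _ in range(10):
            coords, radii = random_geometry(rng, n_atoms=8, spread=4.0)
            sphere = 4.0
            inside = np.linalg.norm(coords - coords[0], axis=1) <= sphere
            if inside.sum() < 3 or not inside[1]:
                continue
            buried = buried_sterimol(coords, radii, 0, 1, buried_radius=sphere)
            _, b1_ref, b5_ref = sterimol_brute_force(
                coords, radii, 0, 1, step_degrees=0.01, buried_radius=sphere
            )
            assert buried.B1 == pytest.approx(b1_ref, abs=1e-3)
            assert buried.B5 == pytest.approx(b5_ref, abs=1e-3)

    def test_empty_sphere_is_degenerate(self):
        toy = make_toy_geometries("collinear")
        with pytest.raises(DegenerateGeometryError):
            buried_sterimol(toy.coordinates, toy.radii, 0, 1, buried_radius=0.5)


class TestSiteB1:
    def test_symmetric_molecule_axes_agree(self, parsed_batch, mock_results):
        # malononitrile anion: C1/C2 environments are identical
        record = next(r for r in parsed_batch.records if r.id == "malononitrile_anion")
        ensembles, results = mock_results
        coords = results[record.id][0].optimized_coordinates
        radii = radii_for(record.elements)
        res = site_b1(coords, radii, record)
        assert res.b1_c1 == pytest.approx(res.b1_c2, abs=0.05)
        assert res.value == pytest.approx(0.5 * (res.b1_c1 + res.b1_c2), abs=1e-12)

    def test_mean_of_two_independent_buried_calls(self, indenide, mock_results):
        ensembles, results = mock_results
        coords = results["indenide"][0].optimized_coordinates
        radii = radii_for(indenide.elements)
        res = site_b1(coords, radii, indenide)
        direct1 = buried_sterimol(coords, radii, indenide.ca_index, indenide.c1_index).B1
        direct2 = buried_sterimol(coords, radii, indenide.ca_index, indenide.c2_index).B1
        assert res.value == pytest.approx(0.5 * (direct1 + direct2), abs=1e-12)
        assert min(direct1, direct2) <= res.value <= max(direct1, direct2)


class TestAggregate:
    def test_singleton_all_equal(self):
        agg = aggregate([2.5], [0.0])
        assert agg.min == agg.max == agg.boltz == agg.lowE == 2.5

    def test_equal_energies_boltz_is_mean(self):
        agg = aggregate([1.0, 3.0], [0.0, 0.0])
        assert agg.boltz == pytest.approx(2.0, abs=1e-12)

    def test_kT_ln2_closed_form(self):
        T = 298.15
        gap = KB_HARTREE * T * np.log(2.0)
        agg = aggregate([1.0, 3.0], [0.0, gap], temperature=T)
        assert agg.boltz == pytest.approx(5 / 3, abs=1e-12)

    def test_lowE_tie_resolves_to_lowest_index(self):
        agg = aggregate([7.0, 9.0], [0.5, 0.5])
        assert agg.lowE == 7.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            aggregate([1.0, 2.0], [0.0])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_boltz_bounded_by_min_max(self, n, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n)
        energies = rng.normal(scale=5e-3, size=n)
        agg = aggregate(values, energies)
        assert agg.min - 1e-12 <= agg.boltz <= agg.max + 1e-12
        assert agg.min <= agg.lowE <= agg.max


class TestCo2Affinity:
    def test_thermoneutral_is_zero(self):
        assert co2_affinity(-100.0, -50.0, -50.0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_conversion(self):
        # reaction free energy of -0.005 Hartree
        val = co2_affinity(-100.005, -50.0, -50.0)
        assert val == pytest.approx(0.005 * HARTREE_TO_KCAL, abs=1e-9)
        assert val == pytest.approx(3.1375, abs=1e-4)

    def test_monotone_in_reaction_energy(self):
        affinities = [co2_affinity(-100.0 - dg, -50.0, -50.0) for dg in np.linspace(-0.02, 0.02, 9)]
        assert all(a < b for a, b in zip(affinities, affinities[1:]))

    def test_mixed_settings_rejected(self):
        with pytest.raises(ConsistencyError):
            co2_affinity(-100.0, -50.0, -50.0, settings_hashes=["aaa", "bbb", "aaa"])


class TestDescriptorTable:
    def test_guaranteed_columns_shape(self, parsed_batch, mock_results):
        ensembles, results = mock_results
        table = build_descriptor_table(parsed_batch.records, ensembles, results)
        features = table.feature_names
        assert len(features) == 12  # 3 descriptors x 4 aggregations
        for desc in ("epsilon_homo", "site_dipole", "buried_b1"):
            for agg in ("min", "max", "boltz", "lowE"):
                assert f"{desc}_{agg}" in features

    def test_missing_conformer_results_flag_incomplete(self, parsed_batch, mock_results):
        ensembles, results = mock_results
        broken = dict(results)
        some_id = parsed_batch.records[0].id
        broken[some_id] = broken[some_id][:0]  # drop all results for one record
        table = build_descriptor_table(parsed_batch.records, ensembles, broken)
        assert not table.data.loc[some_id, "complete"]
        assert some_id not in table.complete.index
        # not silently imputed: incomplete row has no descriptor values
        assert table.data.loc[some_id, "epsilon_homo_boltz"] != table.data.loc[some_id, "epsilon_homo_boltz"]

    def test_boltz_columns_bounded_rowwise(self, parsed_batch, mock_results):
        ensembles, results = mock_results
        table = build_descriptor_table(parsed_batch.records, ensembles, results)
        for desc in ("epsilon_homo", "site_dipole", "buried_b1"):
            sub = table.complete
            assert (sub[f"{desc}_boltz"] >= sub[f"{desc}_min"] - 1e-12).all()
            assert (sub[f"{desc}_boltz"] <= sub[f"{desc}_max"] + 1e-12).all()

    def test_csv_round_trip_with_sidecar(self, tmp_path, parsed_batch, mock_results):
        from co2screen.descriptors import DescriptorTable

        ensembles, results = mock_results
        table = build_descriptor_table(parsed_batch.records, ensembles, results)
        path = tmp_path / "desc.csv"
        table.to_csv(path)
        back = DescriptorTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.data, table.data, check_exact=False, check_names=False
        )
        assert back.metadata["units"]["buried_b1"] == "Angstrom"

    def test_unknown_element_radius_is_input_error(self):
        with pytest.raises(InputError):
            radii_for(["C", "Uuo"])
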