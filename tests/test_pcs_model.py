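"""Geometry rows, tensor fitting, Q-factor."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pcsgrid as pg
from pcsgrid.pcs_model import ChiTensor, geometry_row, q_factor

ION = np.zeros(3)


def random_traceless_tensor(seed, scale=38e-32):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((3, 3))
    sym = (m + m.T) / 2
    sym -= np.eye(3) * np.trace(sym) / 3
    return ChiTensor.from_matrix(sym * scale)


class TestGeometryRow:
    def test_on_axis_nucleus_isolates_first_component(self):
        z = 17.0
        row = geometry_row(ION, [0.0, 0.0, z])
        r = z * 1e-10
        expected0 = 1e6 / (12 * np.pi * r**5) * (z * 1e-10) ** 2
        assert row[0] == pytest.approx(expected0, rel=1e-12)
        assert np.allclose(row[1:], 0.0)

    def test_even_under_ion_nucleus_exchange(self):
        pos = np.array([3.0, -7.0, 11.0])
        assert np.allclose(geometry_row(ION, pos), geometry_row(pos, ION), rtol=1e-12)

    def test_doubling_distance_scales_by_one_eighth(self):
        direction = np.array([1.0, 2.0, -0.5])
        row1 = geometry_row(ION, 10 * direction)
        row2 = geometry_row(ION, 20 * direction)
        assert np.allclose(row2, row1 / 8.0, rtol=1e-12)

    def test_coincident_positions_error(self):
        with pytest.raises(ValueError, match="malformed"):
            geometry_row(ION, [0.0, 0.0, 0.01])


class TestForwardPcs:
    def test_zero_tensor_gives_zero(self, structure):
        t = ChiTensor(v=np.zeros(5))
        pcs = pg.forward_pcs(t, structure.ion_position, structure.methyl_sites)
        assert np.allclose(pcs, 0.0)

    def test_axial_on_axis_closed_form(self):
        """Axial tensor, nucleus on the unique axis: PCS = 1e6*d/(4*pi*r^3)."""
        d = 38e-32
        t = ChiTensor.from_matrix(np.diag([-d / 2, -d / 2, d]))
        r_ang = 20.0
        pcs = pg.forward_pcs(t, ION, np.array([[0.0, 0.0, r_ang]]))
        expected = 1e6 * d / (4 * np.pi * (r_ang * 1e-10) ** 3)
        assert pcs[0] == pytest.approx(expected, rel=1e-12)
        assert pcs[0] == pytest.approx(3.78, abs=0.005)

    def test_linearity_in_tensor(self, structure):
        t = random_traceless_tensor(4)
        t2 = ChiTensor(v=2 * t.v)
        p1 = pg.forward_pcs(t, structure.ion_position, structure.methyl_sites)
        p2 = pg.forward_pcs(t2, structure.ion_position, structure.methyl_sites)
        assert np.allclose(p2, 2 * p1, rtol=1e-12)

    def test_frame_covariance(self, structure):
        """Rotating ion + sites + tensor together leaves every PCS unchanged."""
        t = random_traceless_tensor(5)
        rot = pg.euler_to_matrix(pg.EulerOrientation(31, 64, -117))
        pos = structure.positions()
        p0 = pg.forward_pcs(t, structure.ion_position, pos)
        t_rot = ChiTensor.from_matrix(rot @ t.matrix @ rot.T)
        p1 = pg.forward_pcs(t_rot, rot @ structure.ion_position, pos @ rot.T)
        assert np.allclose(p0, p1, rtol=1e-10)


class TestChiTensor:
    def test_matrix_roundtrip_both_conventions(self):
        for conv in ("physical", "literal"):
            t = random_traceless_tensor(7)
            t2 = ChiTensor.from_matrix(t.matrix, convention=conv)
            assert np.abs(t2.matrix - t.matrix).max() < 1e-12 * np.abs(t.matrix).max()

    def test_traceless_symmetric_by_construction(self):
        t = random_traceless_tensor(8)
        m = t.matrix
        assert np.array_equal(m, m.T)
        assert abs(np.trace(m)) < 1e-12 * np.abs(m).max()

    def test_principal_values_sorted_by_magnitude(self):
        t = random_traceless_tensor(9)
        w = t.principal_values
        assert np.all(np.diff(np.abs(w)) >= 0)
        assert w.sum() == pytest.approx(0.0, abs=1e-12 * np.abs(w).max())

    def test_conventions_differ_by_factor_three_in_reconstruction(self):
        v = np.array([3.0, 1.0, 0.5, -0.2, 0.7]) * 1e-32
        phys = ChiTensor(v=v, convention="physical")
        lit = ChiTensor(v=v, convention="literal")
        assert np.allclose(lit.matrix, 3 * phys.matrix)

    def test_json_roundtrip(self):
        t = random_traceless_tensor(10)
        back = ChiTensor.from_json(t.to_json())
        assert np.array_equal(back.v, t.v)
        assert back.convention == t.convention


class TestFitTensor:
    def _measurements(self, structure, tensor, domain="Ig2", noise=0.0, seed=0):
        table, _ = pg.simulate_pcs(structure, tensor, noise, seed)
        return table[(table.domain == domain) & (table.condition == "unbound")]

    def test_noiseless_plant_and_recover(self, structure, tensor):
        meas = self._measurements(structure, tensor)
        fit = pg.fit_tensor(meas, structure.sites_in_domain("Ig2"), structure.ion_position)
        assert np.abs(fit.v - tensor.v).max() < 1e-9 * np.abs(tensor.v).max()
        assert fit.q < 1e-12
        assert np.allclose(
            np.sort(fit.principal_values), np.sort(tensor.principal_values),
            rtol=1e-9,
        )

    def test_underdetermined_below_five(self, structure, tensor):
        meas = self._measurements(structure, tensor).head(4)
        with pytest.raises(ValueError, match="underdetermined"):
            pg.fit_tensor(meas, structure.sites_in_domain("Ig2"), structure.ion_position)

    def test_degenerate_geometry_detected(self, tensor):
        # all sites on one line through the ion -> rank-deficient system
        from pcsgrid.structures import MethylSite, StructureModel

        sites = tuple(
            MethylSite(170 + i, "Ala", "beta", "Ig2", [0.0, 0.0, 10.0 + 2.0 * i])
            for i in range(6)
        )
        model = StructureModel(sites, ION, np.array([50.0, 0, 0]))
        table, _ = pg.simulate_pcs(model, tensor, 0.0, 0, conditions=("unbound",))
        with pytest.raises(ValueError, match="degenerate geometry"):
            pg.fit_tensor(
                table[table.nucleus == "C"], sites, model.ion_position
            )

    def test_unmatched_measurement_errors(self, structure, tensor):
        meas = self._measurements(structure, tensor).copy()
        meas.loc[meas.index[0], "residue_number"] = 9999
        with pytest.raises(ValueError, match="no matching methyl site"):
            pg.fit_tensor(meas, structure.sites_in_domain("Ig2"), structure.ion_position)

    def test_noise_consistency_error_shrinks_with_sd(self, structure, tensor):
        """Median principal-value error at sigma=0.001 is >=10x below sigma=0.01."""
        sites = structure.sites_in_domain("Ig2")
        true_pv = tensor.principal_values

        def median_err(sd):
            errs = []
            for seed in range(500):
                meas = self._measurements(structure, tensor, noise=sd, seed=seed)
                fit = pg.fit_tensor(meas, sites, structure.ion_position)
                errs.append(
                    np.abs(fit.principal_values - true_pv).max() / np.abs(true_pv).max()
                )
            return np.median(errs)

        assert median_err(0.001) <= median_err(0.01) / 10 * 1.5  # 10x within slack

    def test_combined_fit_duplication_invariance(self, structure, tensor):
        meas = self._measurements(structure, tensor)
        sites = structure.sites_in_domain("Ig2")
        single = pg.fit_tensor(meas, sites, structure.ion_position)
        double = pg.fit_tensor_combined(
            [(meas, sites, structure.ion_position)] * 2
        )
        assert np.allclose(single.v, double.v, rtol=1e-12)

    def test_combined_fit_beats_single_fit_under_noise(self, structure, tensor):
        sites = structure.sites_in_domain("Ig2")
        true_pv = tensor.principal_values
        single_errs, pooled_errs = [], []
        for seed in range(300):
            table, _ = pg.simulate_pcs(
                structure, tensor, 0.01, seed,
                planted_rotation=pg.EulerOrientation(20, 40, -10),
            )
            ig2 = table[table.domain == "Ig2"]
            unb = ig2[ig2.condition == "unbound"]
            datasets = [
                (g, sites, structure.ion_position)
                for _, g in ig2.groupby("condition")
            ]
            fs = pg.fit_tensor(unb, sites, structure.ion_position)
            fp = pg.fit_tensor_combined(datasets)
            single_errs.append(np.abs(fs.principal_values - true_pv).max())
            pooled_errs.append(np.abs(fp.principal_values - true_pv).max())
        assert np.median(pooled_errs) < np.median(single_errs)


class TestQFactor:
    def test_perfect_agreement(self):
        assert q_factor([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_zero_calculation_gives_one(self):
        obs = [0.3, -1.2, 0.7]
        assert q_factor(obs, [0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # sum sq dev = 0.01+0.01+0.04 = 0.06; sum obs^2 = 14
        assert q_factor([1, 2, 3], [1.1, 1.9, 3.2]) == pytest.approx(
            0.06 / 14, rel=1e-9
        )

    def test_all_zero_observed_is_undefined(self):
        with pytest.raises(ValueError, match="undefined Q"):
            q_factor([0.0, 0.0], [1.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_invariant_under_common_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        obs = rng.standard_normal(8) + 0.1
        calc = rng.standard_normal(8)
        assert q_factor(obs * scale, calc * scale) == pytest.approx(
            q_factor(obs, calc), rel=1e-9
        )


class TestPcsTableIO:
    def test_roundtrip(self, noiseless_table, tmp_path):
        table, _ = noiseless_table
        path = tmp_path / "pcs.tsv"
        pg.write_pcs_table(table, path)
        back = pg.read_pcs_table(str(path))
        assert len(back) == len(table)
        assert np.allclose(back["pcs_ppm"], table["pcs_ppm"])

    def test_duplicate_rows_rejected(self, noiseless_table, tmp_path):
        table, _ = noiseless_table
        dup = pd.concat([table, table.head(1)])
        path = tmp_path / "dup.tsv"
        dup.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            pg.read_pcs_table(str(path))


class TestPcsChangeSummary:
    def test_mobile_domain_changes_exceed_tagged_domain(self, structure, tensor):
        table, _ = pg.simulate_pcs(
            structure, tensor, 0.005, seed=42,
            planted_rotation=pg.EulerOrientation(-40, 30, 55),
        )
        summary = pg.pcs_change_summary(table).set_index("domain")
        # only Ig1 moved between conditions; Ig2 differences are pure noise
        assert summary.loc["Ig1", "mean_abs_change"] > summary.loc["Ig2", "mean_abs_change"]
        assert summary.loc["Ig2", "mean_abs_change"] < 5 * 0.005 * np.sqrt(2)
        assert summary.loc["Ig1", "n"] == 24
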