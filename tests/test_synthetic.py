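"""Synthetic surface and cohort generators: oracles, determinism, schema."""

import numpy as np
import pandas as pd
import pytest

from neogyri.synthetic import (
    COHORT_COLUMNS,
    CohortSpec,
    SurfaceSpec,
    apply_inclusion_filters,
    generate_bumpy_sphere,
    generate_cohort,
)

from .oracles import bumpy_sphere_area_quadrature


class TestBumpySphere:
    def test_sphere_area_matches_analytic(self):
        m = generate_bumpy_sphere(SurfaceSpec(base_radius=50.0, mesh_subdivisions=5))
        assert m.area == pytest.approx(4 * np.pi * 50.0**2, rel=0.01)

    @pytest.mark.parametrize("a,k", [(0.1, 6), (0.15, 4)])
    def test_area_matches_quadrature_oracle(self, a, k):
        m = generate_bumpy_sphere(
            SurfaceSpec(base_radius=50.0, bump_amplitude=a, bump_frequency=k,
                        mesh_subdivisions=5)
        )
        oracle = bumpy_sphere_area_quadrature(50.0, a, k)
        assert m.area == pytest.approx(oracle, rel=0.02)

    def test_determinism(self):
        spec = SurfaceSpec(base_radius=30.0, bump_amplitude=0.2, bump_frequency=5,
                           mesh_subdivisions=3, seed=42)
        m1, m2 = generate_bumpy_sphere(spec), generate_bumpy_sphere(spec)
        np.testing.assert_array_equal(m1.vertices, m2.vertices)
        np.testing.assert_array_equal(m1.faces, m2.faces)

    def test_area_monotone_in_amplitude(self):
        areas = [
            generate_bumpy_sphere(
                SurfaceSpec(base_radius=20.0, bump_amplitude=a, bump_frequency=6,
                            mesh_subdivisions=4)
            ).area
            for a in (0.0, 0.05, 0.1, 0.15)
        ]
        assert np.all(np.diff(areas) > 0)

    def test_mesh_is_closed_and_manifold(self, bumpy20):
        assert bumpy20.is_watertight
        assert bumpy20.euler_number == 2

    @pytest.mark.parametrize("bad", [
        dict(bump_amplitude=0.5), dict(bump_amplitude=-0.01),
        dict(base_radius=0.0), dict(bump_frequency=-1),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_bumpy_sphere(SurfaceSpec(**{"base_radius": 20.0, **bad}))


class TestCohort:
    def test_empty_cohort_keeps_schema(self):
        t = generate_cohort(CohortSpec(n_reference=0, n_clinical=0))
        assert len(t) == 0
        assert tuple(t.columns) == COHORT_COLUMNS

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortSpec(n_reference=-1))

    def test_determinism(self):
        a = generate_cohort(CohortSpec(seed=3))
        b = generate_cohort(CohortSpec(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_pna_definition(self, default_cohort):
        t = default_cohort
        np.testing.assert_allclose(
            t["pna_days"], 7.0 * (t["pma_scan"] - t["ga_birth"]), atol=1e-9
        )

    def test_null_mode_group_means_equal(self):
        # Monte-Carlo at n=2000 per group: GI means agree within 3 SE
        t = generate_cohort(CohortSpec(n_reference=2000, n_clinical=2000,
                                       seed=5, deficit_mode="none"))
        ref = t[t.group == "reference"]
        clin = t[t.group == "clinical"]
        # compare at matched PMA via the known trend slope
        adj_ref = ref.gi_whole_brain - 0.08 * (ref.pma_scan - 41.5)
        adj_clin = clin.gi_whole_brain - 0.08 * (clin.pma_scan - 41.5)
        se = np.sqrt(adj_ref.var() / len(ref) + adj_clin.var() / len(clin))
        assert abs(adj_ref.mean() - adj_clin.mean()) < 3 * se

    def test_direct_deficit_recovers_injected_gap(self):
        t = generate_cohort(CohortSpec(n_reference=2000, n_clinical=2000, seed=6,
                                       deficit_mode="direct", deficit_size=0.5))
        ref, clin = t[t.group == "reference"], t[t.group == "clinical"]
        adj_ref = ref.gi_whole_brain - 0.08 * (ref.pma_scan - 41.5)
        adj_clin = clin.gi_whole_brain - 0.08 * (clin.pma_scan - 41.5)
        gap = adj_ref.mean() - adj_clin.mean()
        se = np.sqrt(adj_ref.var() / len(ref) + adj_clin.var() / len(clin))
        assert gap == pytest.approx(0.5 * 0.10, abs=3 * se)

    def test_volume_mediated_shifts_stbv(self):
        t = generate_cohort(CohortSpec(n_reference=2000, n_clinical=2000, seed=8,
                                       deficit_mode="volume_mediated"))
        ref, clin = t[t.group == "reference"], t[t.group == "clinical"]
        adj_ref = ref.stbv - 15.0 * (ref.pma_scan - 40.0) - 8.0 * ref.sex
        adj_clin = clin.stbv - 15.0 * (clin.pma_scan - 40.0) - 8.0 * clin.sex
        assert adj_ref.mean() - adj_clin.mean() == pytest.approx(60.0, abs=3.0)

    def test_all_columns_finite(self, default_cohort):
        num = default_cohort.select_dtypes(include=[np.number])
        assert np.isfinite(num.to_numpy(dtype=float)).all()

    def test_csv_round_trip(self, default_cohort, tmp_path):
        from neogyri.io import read_cohort_csv, write_cohort_csv

        p = tmp_path / "cohort.csv"
        write_cohort_csv(default_cohort, p, {"seed": 0})
        back = read_cohort_csv(p)
        pd.testing.assert_frame_equal(back, default_cohort, check_exact=False,
                                      rtol=0, atol=1e-12)


class TestInclusionFilters:
    def make(self, pma, ga=None):
        ga = ga if ga is not None else [38.0] * len(pma)
        return pd.DataFrame({"pma_scan": pma, "ga_birth": ga})

    def test_closed_window_boundaries_retained(self):
        t = self.make([36.0, 46.0, 41.0])
        out = apply_inclusion_filters(t, (36.0, 46.0))
        assert len(out) == 3

    def test_outside_window_removed(self):
        t = self.make([35.9, 46.1, 40.0])
        out = apply_inclusion_filters(t, (36.0, 46.0))
        assert out["pma_scan"].tolist() == [40.0]

    def test_ga_minimum_applied(self):
        t = self.make([40.0, 40.0], ga=[36.5, 37.0])
        out = apply_inclusion_filters(t, (36.0, 46.0), ga_min=37.0)
        assert out["ga_birth"].tolist() == [37.0]

    def test_empty_table_passes_through(self):
        t = self.make([])
        assert len(apply_inclusion_filters(t, (36.0, 46.0))) == 0

    def test_missing_pma_names_row(self):
        t = self.make([40.0, np.nan])
        with pytest.raises(ValueError, match="row 1"):
            apply_inclusion_filters(t, (36.0, 46.0))

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            apply_inclusion_filters(self.make([40.0]), (46.0, 36.0))

    def test_row_order_preserved(self):
        t = self.make([45.0, 38.0, 44.0, 39.0])
        out = apply_inclusion_filters(t, (36.0, 46.0))
        assert out["pma_scan"].tolist() == [45.0, 38.0, 44.0, 39.0]
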