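"""Reporting partitions, anthropic intensity, and their raster application."""

import json

import numpy as np
import pytest

from landmosaic import (
    CodeTable,
    IntensityModel,
    LMCell,
    SchemePartition,
    apply_partition,
    build_partition,
    cell_to_19,
    classify_raster,
    compute_heatmap,
    enumerate_cells,
    group_summary,
    intensity_raster,
    intensity_value,
    simulate_landscape,
    toy_raster,
    window_proportions,
)
from landmosaic.fixtures import LandscapeParams
from landmosaic.raster import LMClassRaster, WindowSpec
from landmosaic.reporting import color_table_csv, intensity_table_csv


def lm103_of(codes_array) -> LMClassRaster:
    return LMClassRaster(np.asarray(codes_array).astype(np.uint8), "103",
                         WindowSpec(3), codes=CodeTable.canonical())


class TestIntensityModel:
    def test_anchor_pure_natural_is_zero(self):
        assert intensity_value(LMCell.corner("N")) == 0.0

    def test_anchor_pure_developed_is_100(self):
        assert intensity_value(LMCell.corner("D")) == 100.0

    def test_anchor_third_cell_on_developed_natural_axis_is_85(self):
        """Counting the corner first, the third cell from the pure-developed
        corner along the developed-natural edge scores 85 by default."""
        assert intensity_value(LMCell.up(0, 1, 8)) == pytest.approx(85.0)

    def test_pure_agriculture_weighted_half(self):
        assert intensity_value(LMCell.corner("A")) == pytest.approx(50.0)

    def test_monotone_in_developed_at_fixed_agriculture(self):
        """With the agriculture decile held, intensity strictly increases
        with the developed decile."""
        for kind, total in (("up", 9), ("down", 8)):
            for la in range(total + 1):
                vals = []
                for ld in range(total - la + 1):
                    cell = LMCell(kind, la, total - la - ld, ld)
                    vals.append(intensity_value(cell))
                assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_override_table(self):
        model = IntensityModel(overrides={LMCell.corner("A"): 77.0})
        assert intensity_value(LMCell.corner("A"), model) == 77.0
        assert intensity_value(LMCell.corner("D"), model) == 100.0

    def test_unknown_override_cell_rejected(self):
        class Fake:
            pass
        with pytest.raises((ValueError, TypeError)):
            IntensityModel(overrides={Fake(): 1.0})

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            IntensityModel(weight_agriculture=1.5)

    def test_bin_edges_validated(self):
        with pytest.raises(ValueError):
            IntensityModel(bin_edges=(0.0, 50.0, 40.0, 100.0))
        with pytest.raises(ValueError):
            IntensityModel(bin_edges=(10.0, 100.0))


class TestBuildPartition:
    def test_background_sizes(self):
        assert build_partition("background").sizes() == {
            "Ax": 17, "Nx": 17, "Dx": 17, "mixed": 52
        }

    def test_background_matches_19_class_regions(self):
        """Dominance groups contain exactly the cells whose 19-label starts
        with the matching uppercase letter (corner included)."""
        part = build_partition("background")
        for cell in enumerate_cells():
            label19 = cell_to_19(cell).name
            group = part.group_of(cell)
            if label19[0].isupper():
                assert group == label19[0] + "x"
            else:
                assert group == "mixed"

    def test_diversity_sizes(self):
        sizes = build_partition("diversity").sizes()
        assert sizes["uniform"] == 9
        assert sizes["intermix"] == 4
        assert sizes["triple"] + sizes["dual"] == 90

    def test_diversity_center_cell_is_intermix(self):
        part = build_partition("diversity")
        assert part.group_of(LMCell.up(3, 3, 3)) == "intermix"

    def test_refined_mixed_sizes(self):
        sizes = build_partition("refined_mixed").sizes()
        assert sizes == {"Ax": 17, "Nx": 17, "Dx": 17,
                         "adn2": 16, "dn2": 12, "an2": 12, "ad2": 12}

    def test_refined_mixed_interface_opposite_minimum(self):
        """A mixed cell short in one component joins the interface class of
        the other two."""
        part = build_partition("refined_mixed")
        assert part.group_of(LMCell.down(0, 4, 4)) == "dn2"   # agriculture minimal
        assert part.group_of(LMCell.down(4, 0, 4)) == "ad2"   # natural minimal
        assert part.group_of(LMCell.down(4, 4, 0)) == "an2"   # developed minimal

    def test_refined_mixed_tie_never_triggered(self):
        """Among the 52 mixed cells needing an interface assignment, the
        minimum component is always unique."""
        bg = build_partition("background")
        mixed = next(g for g in bg.groups if g.label == "mixed").cells
        from landmosaic import cell_centroid
        for cell in mixed:
            c = cell_centroid(cell)
            if min(c.as_tuple()) < 0.2:
                assert sorted(c.as_tuple())[0] != sorted(c.as_tuple())[1]

    def test_intensity_partition_covers_all_bins(self):
        part = build_partition("intensity")
        assert len(part.groups) == 6
        assert sum(len(g.cells) for g in part.groups) == 103

    def test_all_partitions_disjoint_cover(self):
        for scheme in ("background", "diversity", "refined_mixed", "intensity"):
            part = build_partition(scheme)
            cells = [c for g in part.groups for c in g.cells]
            assert len(cells) == 103 and len(set(cells)) == 103

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            build_partition("rainbow")

    def test_out_of_range_parameter_rejected(self):
        with pytest.raises(ValueError):
            build_partition("background", dominance=1.5)

    def test_json_round_trip(self, tmp_path):
        part = build_partition("refined_mixed")
        p = tmp_path / "part.json"
        part.to_json(p)
        back = SchemePartition.from_json(p)
        assert back.name == part.name
        assert [g.label for g in back.groups] == [g.label for g in part.groups]
        assert back.sizes() == part.sizes()

    def test_overlapping_groups_rejected(self):
        part = build_partition("background")
        g0 = part.groups[0]
        bad = (part.groups[0],) + part.groups
        with pytest.raises(ValueError):
            SchemePartition("bad", bad)


class TestApplyPartition:
    def test_all_NN_background(self):
        labels, colors = apply_partition(
            lm103_of(np.full((4, 4), 170)), build_partition("background")
        )
        part = build_partition("background")
        nx_index = [g.label for g in part.groups].index("Nx") + 1
        assert np.all(labels == nx_index)
        assert colors[0][0] == "Ax"

    def test_center_cell_raster_is_intermix(self):
        ct = CodeTable.canonical()
        code = ct.code_of(LMCell.up(3, 3, 3))
        labels, _ = apply_partition(
            lm103_of(np.full((3, 3), code)), build_partition("diversity")
        )
        part = build_partition("diversity")
        intermix_index = [g.label for g in part.groups].index("intermix") + 1
        assert np.all(labels == intermix_index)

    def test_nodata_preserved(self):
        arr = np.array([[170, 0], [0, 190]])
        labels, _ = apply_partition(lm103_of(arr), build_partition("background"))
        assert labels[0, 1] == 0 and labels[1, 0] == 0
        assert labels[0, 0] != 0 and labels[1, 1] != 0

    def test_commutes_with_group_summary(self):
        """Histogram of the labeled raster equals the grouped heatmap."""
        ras = simulate_landscape(LandscapeParams(70, 70, (0.3, 0.4, 0.3), 0.05, 3.0, 2))
        _, lm103 = classify_raster(window_proportions(ras, 7))
        part = build_partition("refined_mixed")
        labels, _ = apply_partition(lm103, part)
        gs = group_summary(compute_heatmap(lm103), part)
        n_valid = (labels != 0).sum()
        for gi, group in enumerate(part.groups, start=1):
            direct = 100.0 * (labels == gi).sum() / n_valid
            assert direct == pytest.approx(gs[group.label], abs=1e-9)

    def test_color_table_export(self, tmp_path):
        p = tmp_path / "colors.csv"
        color_table_csv(build_partition("background"), p)
        lines = p.read_text().splitlines()
        assert lines[0] == "label,R,G,B"
        assert len(lines) == 5


class TestIntensityRaster:
    def test_all_natural_any_scale_is_zero(self):
        for w in (3, 5):
            stack = window_proportions(toy_raster("uniform_n"), w)
            _, lm103 = classify_raster(stack)
            inten = intensity_raster(lm103)
            assert np.all(inten == 0.0)

    def test_all_developed_is_100(self):
        import numpy as np
        from landmosaic import LandCoverRaster
        g = np.full((6, 6), 3, dtype=np.uint8)
        _, lm103 = classify_raster(window_proportions(LandCoverRaster(g), 3))
        assert np.all(intensity_raster(lm103) == 100.0)

    def test_nodata_is_nan(self):
        arr = np.array([[170, 0], [190, 0]])
        inten = intensity_raster(lm103_of(arr))
        assert np.isnan(inten[0, 1]) and np.isnan(inten[1, 1])
        assert inten[0, 0] == 0.0 and inten[1, 0] == 100.0

    def test_monotone_under_development(self, rng):
        """Swapping natural pixels to developed never lowers intensity."""
        from landmosaic import LandCoverRaster
        g = rng.integers(1, 4, size=(40, 40)).astype(np.uint8)
        _, lm1 = classify_raster(window_proportions(LandCoverRaster(g), 7))
        i1 = intensity_raster(lm1)
        g2 = g.copy()
        nat = np.argwhere(g2 == 2)
        for r, c in nat[rng.permutation(len(nat))[:len(nat) // 3]]:
            g2[r, c] = 3
        _, lm2 = classify_raster(window_proportions(LandCoverRaster(g2), 7))
        i2 = intensity_raster(lm2)
        assert np.all(i2 >= i1 - 1e-9)
        assert np.all((i1 >= 0) & (i1 <= 100))

    def test_intensity_table_export(self, tmp_path):
        p = tmp_path / "intensity.csv"
        intensity_table_csv(p)
        lines = p.read_text().splitlines()
        assert len(lines) == 104
        # corner rows carry the anchors
        rows = {int(l.split(",")[0]): float(l.split(",")[5]) for l in lines[1:]}
        assert rows[170] == 0.0 and rows[190] == 100.0 and rows[180] == 50.0
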