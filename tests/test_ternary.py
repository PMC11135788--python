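"""Ternary-chart classification: 19-class rules, decile cells, code tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from landmosaic import (
    CodeTable,
    LMCell,
    TernaryComposition,
    Thresholds19,
    cell_centroid,
    cell_to_19,
    classify103,
    classify19,
    enumerate_cells,
)
from landmosaic.ternary import CORNER_CODES, LM19_CODES, LM19_NAMES


def comp(a, n, d):
    return TernaryComposition(a, n, d)


simplex = st.tuples(
    st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
).map(lambda t: (min(t), max(t))).map(lambda t: (t[0], t[1] - t[0], 1.0 - t[1]))


class TestComposition:
    def test_rejects_bad_sum(self):
        with pytest.raises(ValueError):
            TernaryComposition(0.5, 0.5, 0.5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            TernaryComposition(1.5, -0.5, 0.0)

    def test_from_counts_requires_positive_total(self):
        with pytest.raises(ValueError):
            TernaryComposition.from_counts(0, 0, 0)


class TestThresholds:
    def test_default_ordering(self):
        t = Thresholds19()
        assert 0 < t.presence < t.dominance < t.uniqueness == 1.0

    @pytest.mark.parametrize("pres,dom", [(0.6, 0.1), (0.0, 0.6), (0.5, 0.5)])
    def test_invalid_rejected(self, pres, dom):
        with pytest.raises(ValueError):
            Thresholds19(pres, dom)


class TestClassify19:
    @pytest.mark.parametrize(
        "a,n,d,expected",
        [
            (0, 1, 0, "NN"),            # single-class window
            (1, 0, 0, "AA"),
            (0, 0, 1, "DD"),
            (0.05, 0.85, 0.10, "Nd"),   # dominant N, present d, absent a
            (0.2, 0.5, 0.3, "adn"),     # all three in [0.1, 0.6)
            (0.75, 0.15, 0.10, "Adn"),
            (0.95, 0.05, 0.0, "A"),
            (0.55, 0.05, 0.40, "ad"),
            (0.0, 0.35, 0.65, "Dn"),
            (0.05, 0.3, 0.65, "Dn"),
            (0.3, 0.1, 0.6, "Dan"),     # boundaries are inclusive-lower
            (0.1, 0.9, 0.0, "Na"),
        ],
    )
    def test_labels(self, a, n, d, expected):
        assert classify19(comp(a, n, d)).name == expected

    def test_vocabulary_is_closed_and_exhausted(self):
        """A 0.01-step sweep of the simplex yields exactly the 19 names."""
        seen = set()
        for i in range(101):
            for j in range(101 - i):
                k = 100 - i - j
                seen.add(classify19(comp(i / 100, j / 100, k / 100)).name)
        assert seen == set(LM19_NAMES)
        assert len(LM19_NAMES) == 19

    def test_name_ordering_convention(self):
        # uppercase first, lowercase alphabetical
        for name in LM19_NAMES:
            lowers = [c for c in name if c.islower()]
            assert lowers == sorted(lowers)
            if any(c.isupper() for c in name) and lowers:
                assert name[0].isupper()

    def test_codes_bijective_and_adn_anchor(self):
        assert sorted(LM19_CODES.values()) == list(range(1, 20))
        assert LM19_CODES["adn"] == 16  # published pixel value of the intermixed class


class TestClassify103:
    def test_corners_require_exact_purity(self):
        assert classify103(comp(1, 0, 0)).pole == "A"
        assert classify103(comp(0.9999999, 0.0000001, 0)).kind == "up"

    @pytest.mark.parametrize(
        "a,n,d,kind,idx",
        [
            (0.75, 0.15, 0.10, "up", (7, 1, 1)),
            (0.28, 0.33, 0.39, "down", (2, 3, 3)),
            (0.05, 0.85, 0.10, "up", (0, 8, 1)),
        ],
    )
    def test_floor_binning(self, a, n, d, kind, idx):
        cell = classify103(comp(a, n, d))
        assert (cell.kind, (cell.la, cell.ln, cell.ld)) == (kind, idx)

    @pytest.mark.parametrize(
        "a,n,d",
        [(0.6, 0.4, 0.0), (0.2, 0.5, 0.3), (0.1, 0.6, 0.3), (0.5, 0.5, 0.0),
         (0.3, 0.3, 0.4), (0.1, 0.1, 0.8), (0.4, 0.6, 0.0)],
    )
    def test_gridline_resolution_is_deterministic_and_19_consistent(self, a, n, d):
        """Grid-intersection compositions resolve to an upward cell in the
        same 19-class region, identically on every call."""
        c1, c2 = classify103(comp(a, n, d)), classify103(comp(a, n, d))
        assert c1 == c2
        assert c1.kind == "up"
        assert cell_to_19(c1).name == classify19(comp(a, n, d)).name

    @settings(max_examples=300, deadline=None)
    @given(simplex)
    def test_partition_property(self, t):
        """Every composition maps to exactly one cell whose 19-region it
        shares (off the decile grid lines)."""
        a, n, d = t
        c = comp(a, n, d)
        cell = classify103(c)
        # the correspondence is only promised off the decile grid lines
        on_gridline = any(abs(10 * x - round(10 * x)) < 1e-8 for x in t)
        if not on_gridline:
            assert cell_to_19(cell).name == classify19(c).name

    @settings(max_examples=200, deadline=None)
    @given(simplex)
    def test_permutation_equivariance(self, t):
        """Permuting (a, n, d) permutes the cell's decile indices identically
        (away from exact grid intersections, where ties must be broken)."""
        a, n, d = t
        if sum(int(math.floor(10 * x + 1e-9)) for x in t) == 10 or 1.0 in t:
            return
        c1 = classify103(comp(a, n, d))
        c2 = classify103(comp(d, a, n))  # new (a', n', d') = (d, a, n)
        assert (c2.la, c2.ln, c2.ld) == (c1.ld, c1.la, c1.ln)
        assert c1.kind == c2.kind


class TestCellGeometry:
    def test_centroid_corner_identity(self):
        assert cell_centroid(LMCell.corner("D")).as_tuple() == (0, 0, 1)

    @pytest.mark.parametrize(
        "cell,expected",
        [
            (LMCell.up(0, 1, 8), (1 / 30, 4 / 30, 25 / 30)),
            (LMCell.down(3, 3, 2), (11 / 30, 11 / 30, 8 / 30)),
        ],
    )
    def test_centroid_triangles(self, cell, expected):
        got = cell_centroid(cell).as_tuple()
        assert got == pytest.approx(expected, abs=1e-12)

    def test_centroid_lies_inside_own_cell(self):
        for cell in enumerate_cells():
            if cell.kind == "corner":
                continue
            assert classify103(cell_centroid(cell)) == cell

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            LMCell.up(5, 5, 5)
        with pytest.raises(ValueError):
            LMCell.down(-1, 5, 4)


class TestCellTo19:
    def test_corner(self):
        assert cell_to_19(LMCell.corner("N")).name == "NN"

    def test_dominant_interface_cell(self):
        assert cell_to_19(LMCell.up(7, 1, 1)).name == "Adn"

    def test_intermixed_cell_count(self):
        """The decile scheme refines the fully intermixed class into 37 cells."""
        n_adn = sum(cell_to_19(c).name == "adn" for c in enumerate_cells())
        assert n_adn == 37

    def test_label_constant_over_cell_interior(self, rng):
        """Any interior point of a cell classifies like the centroid."""
        cells = enumerate_cells()
        for cell in (c for c in cells if c.kind != "corner"):
            lbl = cell_to_19(cell).name
            c0 = np.array(cell_centroid(cell).as_tuple())
            for _ in range(3):
                # random point strictly inside: blend centroid with a vertex-ward jitter
                w = rng.dirichlet(np.ones(3))
                p = 0.85 * c0 + 0.15 * (c0 * w / (c0 * w).sum())
                p = p / p.sum()
                cand = TernaryComposition(*p)
                if classify103(cand) == cell:  # stay inside despite float jitter
                    assert classify19(cand).name == lbl

    def test_non_decile_thresholds_rejected(self):
        with pytest.raises(ValueError):
            cell_to_19(LMCell.up(7, 1, 1), Thresholds19(0.15, 0.6))

    def test_dominance_pole_counts(self):
        """17 cells per dominance pole (incl. the corner), 52 mixed."""
        labels = [cell_to_19(c).name for c in enumerate_cells()]
        for pole in "AND":
            assert sum(l[0] == pole for l in labels) == 17
        assert sum(l.islower() for l in labels) == 52


class TestEnumerationAndCodes:
    def test_cell_counts(self):
        cells = enumerate_cells()
        kinds = [c.kind for c in cells]
        assert len(cells) == 103
        assert kinds.count("corner") == 3
        assert kinds.count("up") == 55
        assert kinds.count("down") == 45
        assert len(set(cells)) == 103

    def test_enumeration_stable(self):
        assert enumerate_cells() == enumerate_cells()

    def test_canonical_codes(self):
        ct = CodeTable.canonical()
        assert ct.code_of(LMCell.corner("N")) == 170
        assert ct.code_of(LMCell.corner("A")) == 180
        assert ct.code_of(LMCell.corner("D")) == 190
        tri = sorted(ct.code_of(c) for c in enumerate_cells() if c.kind != "corner")
        assert tri == list(range(1, 101))

    def test_corner_code_anchors_enforced(self):
        ct = CodeTable.canonical()
        codes = dict(ct.codes)
        codes[LMCell.corner("N")], codes[LMCell.corner("A")] = 180, 170
        with pytest.raises(ValueError):
            CodeTable(codes)

    def test_duplicate_codes_rejected(self):
        ct = CodeTable.canonical()
        codes = dict(ct.codes)
        codes[LMCell.up(9, 0, 0)] = codes[LMCell.up(0, 9, 0)]
        with pytest.raises(ValueError):
            CodeTable(codes)

    def test_csv_round_trip(self, tmp_path):
        ct = CodeTable.canonical()
        p = tmp_path / "codes.csv"
        ct.to_csv(p)
        back = CodeTable.from_csv(p)
        assert back.codes == ct.codes
        assert back.provenance == "user-supplied"

    def test_csv_missing_cell_rejected(self, tmp_path):
        p = tmp_path / "codes.csv"
        CodeTable.canonical().to_csv(p)
        lines = p.read_text().splitlines()
        p.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError):
            CodeTable.from_csv(p)
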