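"""Ternary-chart mathematics for the landscape mosaic model.

The landscape mosaic classifies a location by the proportions of three
land-cover base types — agriculture (A), natural (N), developed (D) —
inside a surrounding window.  Composition order is fixed as ``(a, n, d)``
throughout the package.

Two discretizations of the ternary chart are provided:

* the original 19-class scheme, driven by threshold proportions
  0.1 (presence), 0.6 (dominance) and 1.0 (uniqueness);
* the 103-class scheme: the 100 decile sub-triangles obtained by cutting
  the chart at 0.1 steps along each axis (55 upward + 45 downward), plus
  the three exclusive corner classes AA, NN, DD.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "TernaryComposition",
    "Thresholds19",
    "LM19Label",
    "LMCell",
    "CodeTable",
    "LM19_NAMES",
    "LM19_CODES",
    "CORNER_CODES",
    "classify19",
    "classify103",
    "cell_centroid",
    "cell_to_19",
    "enumerate_cells",
]

_EPS_SUM = 1e-9
# guard for floor(10*x) when x is a decile stored in binary floating point
_EPS_DECILE = 1e-9


@dataclass(frozen=True)
class TernaryComposition:
    """Fractions of agriculture, natural and developed land; must sum to 1."""

    a: float
    n: float
    d: float

    def __post_init__(self) -> None:
        for name, v in (("a", self.a), ("n", self.n), ("d", self.d)):
            if not (-_EPS_SUM <= v <= 1 + _EPS_SUM):
                raise ValueError(f"component {name}={v} outside [0, 1]")
        if abs(self.a + self.n + self.d - 1.0) > _EPS_SUM:
            raise ValueError(
                f"composition ({self.a}, {self.n}, {self.d}) does not sum to 1"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.n, self.d)

    @classmethod
    def from_counts(cls, ca: int, cn: int, cd: int) -> "TernaryComposition":
        """Composition from integer window counts (exact purity semantics)."""
        total = ca + cn + cd
        if total <= 0:
            raise ValueError("counts must sum to a positive total")
        return cls(ca / total, cn / total, cd / total)


@dataclass(frozen=True)
class Thresholds19:
    """Presence / dominance / uniqueness proportions of the 19-class scheme."""

    presence: float = 0.1
    dominance: float = 0.6
    uniqueness: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.presence < self.dominance < self.uniqueness):
            raise ValueError(
                "thresholds must satisfy 0 < presence < dominance < uniqueness"
            )
        if self.uniqueness != 1.0:
            raise ValueError("uniqueness threshold is fixed at 1.0")

    def as_fractions(self) -> tuple[Fraction, Fraction]:
        """Presence and dominance as exact rationals (for count arithmetic)."""
        return (
            Fraction(self.presence).limit_denominator(10**6),
            Fraction(self.dominance).limit_denominator(10**6),
        )

    def is_decile(self) -> bool:
        p, d = self.as_fractions()
        return (10 * p).denominator == 1 and (10 * d).denominator == 1


DEFAULT_THRESHOLDS = Thresholds19()

# Canonical 19-class vocabulary and integer codes.  Ordering: the three
# dominance blocks (A, D, N), each listing the pure-dominance name followed
# by its interface names alphabetically; then the two-letter mixtures
# alphabetically, then the fully intermixed adn; corners last.  This places
# adn at code 16, the published pixel value of the intermixed class.
LM19_NAMES: tuple[str, ...] = (
    "A", "Ad", "An", "Adn",
    "D", "Da", "Dn", "Dan",
    "N", "Na", "Nd", "Nad",
    "ad", "an", "dn", "adn",
    "AA", "NN", "DD",
)
LM19_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(LM19_NAMES)}

CORNER_CODES: dict[str, int] = {"NN": 170, "AA": 180, "DD": 190}


@dataclass(frozen=True)
class LM19Label:
    """One of the 19 mosaic class names with its canonical integer code."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in LM19_CODES:
            raise ValueError(f"{self.name!r} is not a landscape-mosaic class name")

    @property
    def code(self) -> int:
        return LM19_CODES[self.name]

    def __str__(self) -> str:
        return self.name


# corner cells carry decile indices of the pure composition (10 in one axis)
_CORNER_INDICES = {"A": (10, 0, 0), "N": (0, 10, 0), "D": (0, 0, 10)}


@dataclass(frozen=True)
class LMCell:
    """One cell of the 103-class ternary chart.

    ``kind`` is ``corner``, ``up`` or ``down``.  For triangle cells the
    decile indices satisfy ``la + ln + ld == 9`` (upward) or ``8``
    (downward); a composition ``(a, n, d)`` lies in the cell when
    ``floor(10a) == la`` etc.  Corner cells store the pure composition's
    indices (one axis at 10).
    """

    kind: str
    la: int
    ln: int
    ld: int

    def __post_init__(self) -> None:
        idx = (self.la, self.ln, self.ld)
        if self.kind == "corner":
            if idx not in _CORNER_INDICES.values():
                raise ValueError(f"invalid corner indices {idx}")
        elif self.kind == "up":
            if sum(idx) != 9 or min(idx) < 0:
                raise ValueError(f"upward cell indices {idx} must be >=0 and sum to 9")
        elif self.kind == "down":
            if sum(idx) != 8 or min(idx) < 0:
                raise ValueError(f"downward cell indices {idx} must be >=0 and sum to 8")
        else:
            raise ValueError(f"unknown cell kind {self.kind!r}")

    @property
    def pole(self) -> str | None:
        """For corner cells, the pure base type ('A', 'N' or 'D')."""
        if self.kind != "corner":
            return None
        return {v: k for k, v in _CORNER_INDICES.items()}[(self.la, self.ln, self.ld)]

    @classmethod
    def corner(cls, pole: str) -> "LMCell":
        return cls("corner", *_CORNER_INDICES[pole])

    @classmethod
    def up(cls, la: int, ln: int, ld: int) -> "LMCell":
        return cls("up", la, ln, ld)

    @classmethod
    def down(cls, la: int, ln: int, ld: int) -> "LMCell":
        return cls("down", la, ln, ld)


def cell_centroid(cell: LMCell) -> TernaryComposition:
    """Barycenter of a chart cell (the representative evaluation point).

    Corner cells map to the unit vectors; an upward triangle with indices
    ``(i, j, k)`` has centroid ``((3i+1)/30, (3j+1)/30, (3k+1)/30)`` and a
    downward one ``((3i+2)/30, ...)`` — the mean of the three vertices.
    """
    if cell.kind == "corner":
        return TernaryComposition(
            float(cell.la == 10), float(cell.ln == 10), float(cell.ld == 10)
        )
    off = 1 if cell.kind == "up" else 2
    return TernaryComposition(
        (3 * cell.la + off) / 30, (3 * cell.ln + off) / 30, (3 * cell.ld + off) / 30
    )


def classify19(
    comp: TernaryComposition, thr: Thresholds19 = DEFAULT_THRESHOLDS
) -> LM19Label:
    """Assign the original 19-class mosaic label to a composition.

    A component contributes an upper-case letter when its proportion is in
    ``[dominance, 1)``, a lower-case letter in ``[presence, dominance)``,
    and no letter below presence.  A window containing a single class
    (proportion exactly 1) yields the doubled corner name AA/NN/DD.
    """
    upper = ""
    lowers: list[str] = []
    for letter, v in zip("and", comp.as_tuple()):
        if v == 1.0:
            return LM19Label((letter + letter).upper())
        if v >= thr.dominance:
            upper = letter.upper()
        elif v >= thr.presence:
            lowers.append(letter)
    name = upper + "".join(sorted(lowers))
    return LM19Label(name)


def classify103(comp: TernaryComposition) -> LMCell:
    """Assign a composition to its decile chart cell (the 103-class scheme).

    Corner cells require exact purity.  Otherwise the decile indices are the
    floors of ``10 * proportion``; they sum to 9 (upward cell) or 8
    (downward cell).  Compositions lying exactly on a decile grid
    intersection (floors summing to 10) are resolved by decrementing one
    index, which yields an upward cell; the 103 cells therefore partition
    the chart.  The decremented component is the largest one whose index is
    not a 19-class region boundary (the presence and dominance deciles, 1
    and 6), ties broken in the order d, a, n: such a component always
    exists (indices drawn from {0, 1, 6} sum to at most 8), the rule is
    deterministic, and it keeps every grid-intersection composition inside
    its own 19-class region, so the 103- and 19-class products stay
    consistent pixel by pixel.
    """
    a, n, d = comp.as_tuple()
    for pole, v in (("A", a), ("N", n), ("D", d)):
        if v == 1.0:
            return LMCell.corner(pole)
    la = min(int(math.floor(10 * a + _EPS_DECILE)), 9)
    ln = min(int(math.floor(10 * n + _EPS_DECILE)), 9)
    ld = min(int(math.floor(10 * d + _EPS_DECILE)), 9)
    s = la + ln + ld
    if s == 10:
        # eligibility: decrementing must not cross a 19-region boundary
        sa = la if la not in (0, 1, 6) else -1
        sn = ln if ln not in (0, 1, 6) else -1
        sd = ld if ld not in (0, 1, 6) else -1
        if sd >= sa and sd >= sn:
            ld -= 1
        elif sa >= sn:
            la -= 1
        else:
            ln -= 1
        s = 9
    if s == 9:
        return LMCell.up(la, ln, ld)
    if s == 8:
        return LMCell.down(la, ln, ld)
    raise ValueError(f"degenerate composition {comp}")  # pragma: no cover


def cell_to_19(
    cell: LMCell, thr: Thresholds19 = DEFAULT_THRESHOLDS
) -> LM19Label:
    """19-class label of a chart cell, evaluated at its centroid.

    Requires decile-aligned thresholds (as the defaults 0.1/0.6 are): then
    every cell lies entirely within one 19-class region, so the centroid's
    label holds for every interior point of the cell.
    """
    if not thr.is_decile():
        raise ValueError(
            "cell_to_19 requires decile-multiple thresholds; "
            f"got presence={thr.presence}, dominance={thr.dominance}"
        )
    return classify19(cell_centroid(cell), thr)


def enumerate_cells() -> list[LMCell]:
    """All 103 chart cells in canonical order.

    Corners first (NN, AA, DD — ascending code 170/180/190), then the 100
    triangles ordered by descending agriculture decile, then descending
    natural decile, upward before downward at equal indices.  The order is
    deterministic and defines the canonical triangle codes 1..100.
    """
    cells: list[LMCell] = [LMCell.corner("N"), LMCell.corner("A"), LMCell.corner("D")]
    for la in range(9, -1, -1):
        for ln in range(9 - la, -1, -1):
            cells.append(LMCell.up(la, ln, 9 - la - ln))
            if la + ln <= 8:
                cells.append(LMCell.down(la, ln, 8 - la - ln))
    return cells


@dataclass(frozen=True)
class CodeTable:
    """Bijection between the 103 chart cells and raster pixel codes.

    The corner anchors are fixed — NN→170, AA→180, DD→190 — matching the
    published pixel values; the 100 triangle codes default to 1..100 in
    canonical enumeration order but may be overridden (e.g. to match an
    external legend) via :meth:`from_csv`.
    """

    codes: dict[LMCell, int]
    provenance: str = "canonical"
    _by_code: dict[int, LMCell] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cells = enumerate_cells()
        if set(self.codes) != set(cells):
            raise ValueError("code table must cover exactly the 103 chart cells")
        values = list(self.codes.values())
        if len(set(values)) != 103:
            raise ValueError("code table must be a bijection (duplicate codes)")
        if any(not (1 <= c <= 255) for c in values):
            raise ValueError("codes must lie in [1, 255]")
        for pole, code in (("N", 170), ("A", 180), ("D", 190)):
            if self.codes[LMCell.corner(pole)] != code:
                raise ValueError(
                    f"corner {pole}{pole} must keep its fixed code {code}"
                )
        object.__setattr__(self, "_by_code", {v: k for k, v in self.codes.items()})

    @classmethod
    def canonical(cls) -> "CodeTable":
        codes: dict[LMCell, int] = {}
        nxt = 1
        for cell in enumerate_cells():
            if cell.kind == "corner":
                codes[cell] = CORNER_CODES[cell.pole * 2]
            else:
                codes[cell] = nxt
                nxt += 1
        return cls(codes, "canonical")

    def code_of(self, cell: LMCell) -> int:
        return self.codes[cell]

    def cell_of(self, code: int) -> LMCell:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"code {code} not present in code table") from None

    def __iter__(self) -> Iterator[LMCell]:
        return iter(enumerate_cells())

    # -- CSV interchange ---------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "la", "ln", "ld", "code"])
            for cell in enumerate_cells():
                w.writerow([cell.kind, cell.la, cell.ln, cell.ld, self.codes[cell]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "CodeTable":
        codes: dict[LMCell, int] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"kind", "la", "ln", "ld", "code"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"code table CSV must have columns {sorted(required)}")
            for row in reader:
                cell = LMCell(
                    row["kind"], int(row["la"]), int(row["ln"]), int(row["ld"])
                )
                if cell in codes:
                    raise ValueError(f"duplicate cell row for {cell}")
                codes[cell] = int(row["code"])
        return cls(codes, "user-supplied")


def random_compositions(
    n: int, rng, include_gridlines: bool = False
) -> Iterable[TernaryComposition]:
    """Uniform random compositions on the simplex (testing utility)."""
    import numpy as np

    x = rng.dirichlet(np.ones(3), size=n)
    for a, nn, d in x:
        d = 1.0 - a - nn  # exact closure
        yield TernaryComposition(float(a), float(nn), float(d))
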