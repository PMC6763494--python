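"""Discriminability indices and pixel-count measures for test pattern pairs.

The base discriminability index of a test pair is ``z_Z + h_H``: the number
of z-class pixels lit in the Z-like member plus the number of h-class pixels
lit in the H-like member, ranging 0-20 for a pair-A class map. Variants add
or subtract the ambiguous (zh), neutral (n) and cross-class ("inhibitory",
``h_Z + z_H``) lit counts. A "select" index restricts the count to the
salient cluster locations (8 z + 6 h by default, range 0-14).

When translocation adjustment is on, each member is first registered against
its own training reference (Z-like vs Z*, H-like vs H*) so that the counts
are taken in pattern-centred rather than matrix-centred coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .grids import (
    SALIENT_H_LOCATIONS,
    SALIENT_Z_LOCATIONS,
    PixelClassMap,
    PixelGrid,
    RegistrationResult,
    TrainingPair,
    location_name,
    register_to_reference,
)

#: Order and names of the columns of the TSV representation of breakdowns.
BREAKDOWN_COLUMNS = (
    "test_id", "phase", "session",
    "z_Z", "h_H", "z_H", "h_Z", "zh_lit", "n_lit", "richness",
    "index_base", "index_minus_inhib", "index_plus_zh", "index_plus_n",
    "index_select",
    "shift_Z_row", "shift_Z_col", "shift_H_row", "shift_H_col",
)

#: Index variant names accepted by correlation routines.
INDEX_VARIANTS = (
    "richness", "base", "minus_inhib", "plus_zh", "plus_n", "select",
)


@dataclasses.dataclass(frozen=True)
class TestCase:
    """One test session's pattern pair with its identifiers."""

    test_id: int
    grid_Zlike: PixelGrid
    grid_Hlike: PixelGrid
    phase: str = "I"
    session: int = 0
    repeat_of: Optional[int] = None
    translocated: bool = False

    def __post_init__(self):
        if self.phase not in ("I", "II", "III"):
            raise ValueError(f"phase must be I, II or III, got {self.phase!r}")

    @property
    def richness(self) -> int:
        """Total lit pixels across both members of the pair."""
        return self.grid_Zlike.lit_count() + self.grid_Hlike.lit_count()


TestCase.__test__ = False  # a domain object, not a pytest collectible


@dataclasses.dataclass(frozen=True)
class IndexBreakdown:
    """All pixel counts and index variants for one test pair."""

    test_id: int
    z_Z: int
    h_H: int
    z_H: int
    h_Z: int
    zh_lit: int  # lit zh pixels summed over both members
    n_lit: int  # lit n pixels summed over both members
    richness: int  # total lit pixels (raw grids, unadjusted)
    index_select: int
    shift_Z: tuple[int, int] = (0, 0)
    shift_H: tuple[int, int] = (0, 0)
    phase: str = "I"
    session: int = 0

    @property
    def index_base(self) -> int:
        return self.z_Z + self.h_H

    @property
    def index_minus_inhib(self) -> int:
        return self.index_base - (self.h_Z + self.z_H)

    @property
    def index_plus_zh(self) -> int:
        return self.index_base + self.zh_lit

    @property
    def index_plus_n(self) -> int:
        return self.index_base + self.n_lit

    def value(self, variant: str) -> int:
        """The index value for a named variant (see :data:`INDEX_VARIANTS`)."""
        if variant == "richness":
            return self.richness
        if variant == "base":
            return self.index_base
        if variant == "minus_inhib":
            return self.index_minus_inhib
        if variant == "plus_zh":
            return self.index_plus_zh
        if variant == "plus_n":
            return self.index_plus_n
        if variant == "select":
            return self.index_select
        raise ValueError(f"unknown index variant {variant!r}")


def _class_count(grid: PixelGrid, class_map: PixelClassMap, label: str) -> int:
    return int((grid.cells & class_map.mask(label)).sum())


def index_breakdown(
    case: TestCase,
    class_map: PixelClassMap,
    adjust_translocation: bool = False,
    max_shift: tuple[int, int] = (2, 2),
    select_Z: Sequence[str] = SALIENT_Z_LOCATIONS,
    select_H: Sequence[str] = SALIENT_H_LOCATIONS,
) -> IndexBreakdown:
    """Compute every pixel count and index variant for a test pair.

    With ``adjust_translocation``, each member is registered against its own
    training reference from ``class_map.pair`` before counting; the applied
    shifts are reported in ``shift_Z`` / ``shift_H``. Richness always refers
    to the raw (unshifted) grids, being a physical property of the display.
    """
    grid_z, grid_h = case.grid_Zlike, case.grid_Hlike
    shift_z = shift_h = (0, 0)
    if adjust_translocation:
        reg_z = register_to_reference(grid_z, class_map.pair.grid_Z, max_shift)
        reg_h = register_to_reference(grid_h, class_map.pair.grid_H, max_shift)
        grid_z, shift_z = reg_z.aligned, reg_z.shift
        grid_h, shift_h = reg_h.aligned, reg_h.shift

    return IndexBreakdown(
        test_id=case.test_id,
        z_Z=_class_count(grid_z, class_map, "z"),
        h_H=_class_count(grid_h, class_map, "h"),
        z_H=_class_count(grid_h, class_map, "z"),
        h_Z=_class_count(grid_z, class_map, "h"),
        zh_lit=_class_count(grid_z, class_map, "zh")
        + _class_count(grid_h, class_map, "zh"),
        n_lit=_class_count(grid_z, class_map, "n")
        + _class_count(grid_h, class_map, "n"),
        richness=case.richness,
        index_select=select_index(
            case, select_Z, select_H, class_map=class_map,
            grid_Zlike=grid_z, grid_Hlike=grid_h,
        ),
        shift_Z=shift_z,
        shift_H=shift_h,
        phase=case.phase,
        session=case.session,
    )


def select_index(
    case: TestCase,
    select_Z: Sequence[str] = SALIENT_Z_LOCATIONS,
    select_H: Sequence[str] = SALIENT_H_LOCATIONS,
    class_map: Optional[PixelClassMap] = None,
    grid_Zlike: Optional[PixelGrid] = None,
    grid_Hlike: Optional[PixelGrid] = None,
) -> int:
    """Count lit salient-set pixels: |lit(Z-like) ∩ select_Z| + |lit(H-like) ∩ select_H|.

    With the default 8-element z and 6-element h salient sets the range is
    0-14. When a class map is given, the select sets are validated to be
    subsets of the z (resp. h) classes. Pre-registered grids may be passed
    to count in pattern-centred coordinates.
    """
    if class_map is not None:
        z_locs = set(class_map.locations("z"))
        h_locs = set(class_map.locations("h"))
        bad_z = set(select_Z) - z_locs
        bad_h = set(select_H) - h_locs
        if bad_z:
            raise ValueError(f"select_Z contains non-z locations: {sorted(bad_z)}")
        if bad_h:
            raise ValueError(f"select_H contains non-h locations: {sorted(bad_h)}")
    gz = grid_Zlike if grid_Zlike is not None else case.grid_Zlike
    gh = grid_Hlike if grid_Hlike is not None else case.grid_Hlike
    n_z = sum(1 for loc in select_Z if gz.is_lit(loc))
    n_h = sum(1 for loc in select_H if gh.is_lit(loc))
    return n_z + n_h


def breakdown_table(
    cases: Iterable[TestCase],
    class_map: PixelClassMap,
    adjust_translocation: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """IndexBreakdowns for many cases as a DataFrame (stable TSV columns)."""
    rows = []
    for case in cases:
        b = index_breakdown(case, class_map, adjust_translocation, **kwargs)
        rows.append({
            "test_id": b.test_id, "phase": b.phase, "session": b.session,
            "z_Z": b.z_Z, "h_H": b.h_H, "z_H": b.z_H, "h_Z": b.h_Z,
            "zh_lit": b.zh_lit, "n_lit": b.n_lit, "richness": b.richness,
            "index_base": b.index_base,
            "index_minus_inhib": b.index_minus_inhib,
            "index_plus_zh": b.index_plus_zh,
            "index_plus_n": b.index_plus_n,
            "index_select": b.index_select,
            "shift_Z_row": b.shift_Z[0], "shift_Z_col": b.shift_Z[1],
            "shift_H_row": b.shift_H[0], "shift_H_col": b.shift_H[1],
        })
    return pd.DataFrame(rows, columns=list(BREAKDOWN_COLUMNS))


def pixel_presentation_frequencies(
    cases: Sequence[TestCase],
    class_map: Optional[PixelClassMap] = None,
) -> pd.DataFrame:
    """Per-location lit counts across the test suite, per pair side.

    Raw grids are used throughout (translocation adjustments deliberately
    play no part in this tally). Returns one row per location with columns
    ``row_label, col, label, count_Z_side, count_H_side``.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("pixel_presentation_frequencies requires at least one case")
    count_z = np.zeros((7, 5), dtype=int)
    count_h = np.zeros((7, 5), dtype=int)
    for case in cases:
        count_z += case.grid_Zlike.cells
        count_h += case.grid_Hlike.cells
    rows = []
    for r in range(7):
        for c in range(5):
            name = location_name(r + 1, c + 1)
            rows.append({
                "location": name,
                "row_label": name[:-1],
                "col": c + 1,
                "label": class_map.label(name) if class_map else "",
                "count_Z_side": int(count_z[r, c]),
                "count_H_side": int(count_h[r, c]),
            })
    return pd.DataFrame(rows)


def training_pair_as_case(pair: TrainingPair, test_id: int = 0) -> TestCase:
    """Present a training pair as its own test pair (Z* as Z-like, H* as H-like)."""
    return TestCase(test_id=test_id, grid_Zlike=pair.grid_Z, grid_Hlike=pair.grid_H)
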