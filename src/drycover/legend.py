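"""Seven-class dryland land-cover legend.

Forest is defined as land dominated by tree cover greater than 30%; the three
forest classes are split by leaf habit, with "mixed" denoting stands where
neither deciduous nor evergreen species dominate the canopy.
"""

from __future__ import annotations

MISSING = 0

DECIDUOUS_FOREST = 1
EVERGREEN_FOREST = 2
MIXED_FOREST = 3
WETLAND = 4
HERBACEOUS = 5
BARREN = 6
WATER = 7

CLASS_NAMES: dict[int, str] = {
    DECIDUOUS_FOREST: "deciduous_forest",
    EVERGREEN_FOREST: "evergreen_forest",
    MIXED_FOREST: "mixed_forest",
    WETLAND: "wetland",
    HERBACEOUS: "herbaceous",
    BARREN: "barren",
    WATER: "water",
}

CLASS_CODES: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: legend codes in fixed (tie-break) order
LEGEND: tuple[int, ...] = tuple(sorted(CLASS_NAMES))

#: the three forest classes whose coarse-pixel fractions are modelled
FOREST_CODES: tuple[int, int, int] = (DECIDUOUS_FOREST, EVERGREEN_FOREST, MIXED_FOREST)

FOREST_TARGETS: tuple[str, ...] = ("deciduous", "evergreen", "mixed", "overall")
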