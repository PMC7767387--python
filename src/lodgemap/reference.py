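"""Reference lodging-event statistics used as simulation defaults and screening inputs.

The package ships a reference scenario for mature-stage paddy rice hit by a
typhoon: class-conditional plot-mean values of ten dual-pol SAR parameters and
ten optical band reflectances, before and after the event, for lodged and
healthy rice.  These numbers drive the synthetic-scene generator defaults and
provide a desk-scale input table for the OSPL screening statistics.

Non-rice land-cover statistics (water, building, wood, bare soil) are not part
of the reference campaign; they are fixed, documented constants chosen for
physical plausibility and class separability (water dark in SAR and in all
optical bands, buildings bright in SAR, vegetation high in NIR).
"""

from __future__ import annotations

from dataclasses import dataclass

# Canonical parameter names; the SAR difference uses U+2212 minus throughout.
SAR_PARAMS = (
    "VV",
    "VH",
    "VV + VH",
    "VV − VH",
    "VH/VV",
    "Alpha",
    "Anisotropy",
    "Entropy",
    "Shannon Entropy",
    "Span",
)
OPTICAL_BANDS = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")


@dataclass(frozen=True)
class ParamStats:
    """Plot-averaged value of one parameter per class and epoch."""

    lodged_before: float
    lodged_after: float
    healthy_before: float
    healthy_after: float
    domain: str  # "sar" or "optical"

    @property
    def sigma_lodged(self) -> float:
        return abs(self.lodged_before - self.lodged_after)

    @property
    def sigma_healthy(self) -> float:
        return abs(self.healthy_before - self.healthy_after)


#: Reference plot-mean table: (lodged before, lodged after, healthy before,
#: healthy after).  SAR backscatter parameters are in dB, decomposition
#: parameters unitless, optical values in reflectance units.
REFERENCE_PLOT_MEANS: dict[str, ParamStats] = {
    "VV": ParamStats(-12.25, -11.10, -11.66, -12.27, "sar"),
    "VH": ParamStats(-17.13, -15.52, -16.91, -16.86, "sar"),
    "VV + VH": ParamStats(-29.37, -26.82, -28.56, -29.12, "sar"),
    "VV − VH": ParamStats(5.18, 4.43, 5.06, 4.59, "sar"),
    "VH/VV": ParamStats(1.41, 1.40, 1.46, 1.38, "sar"),
    "Alpha": ParamStats(0.83, 0.92, 0.85, 0.94, "sar"),
    "Anisotropy": ParamStats(0.49, 0.47, 0.51, 0.49, "sar"),
    "Entropy": ParamStats(0.81, 0.83, 0.79, 0.81, "sar"),
    "Shannon Entropy": ParamStats(0.48, 0.67, 0.53, 0.51, "sar"),
    "Span": ParamStats(-10.88, -9.63, -10.37, -10.86, "sar"),
    "B2": ParamStats(0.25, 0.67, 0.29, 0.53, "optical"),
    "B3": ParamStats(0.46, 0.81, 0.57, 0.72, "optical"),
    "B4": ParamStats(0.24, 0.66, 0.25, 0.61, "optical"),
    "B5": ParamStats(0.49, 0.84, 0.60, 0.77, "optical"),
    "B6": ParamStats(0.68, 0.93, 0.77, 0.85, "optical"),
    "B7": ParamStats(0.74, 0.93, 0.79, 0.85, "optical"),
    "B8": ParamStats(0.75, 0.93, 0.80, 0.85, "optical"),
    "B8A": ParamStats(0.76, 0.94, 0.81, 0.86, "optical"),
    "B11": ParamStats(0.47, 0.76, 0.55, 0.55, "optical"),
    "B12": ParamStats(0.38, 0.53, 0.44, 0.37, "optical"),
}

# ---------------------------------------------------------------------------
# Land-cover legend
# ---------------------------------------------------------------------------

LODGED_RICE = 0
HEALTHY_RICE = 1
WATER = 2
BUILDING = 3
WOOD = 4
BARE = 5

LEGEND: dict[int, str] = {
    LODGED_RICE: "lodged_rice",
    HEALTHY_RICE: "healthy_rice",
    WATER: "water",
    BUILDING: "building",
    WOOD: "wood",
    BARE: "bare",
}
CROP_CODES = (LODGED_RICE, HEALTHY_RICE)

#: Sentinel value for masked non-crop pixels in classification label maps.
NONCROP_LABEL = 255

# ---------------------------------------------------------------------------
# Simulation defaults
# ---------------------------------------------------------------------------

#: Default per-class mean backscatter (dB) by epoch.  Rice classes follow the
#: reference table above (VV and VH rows); the other classes are fixed
#: plausible constants with a small ±0.3 dB epoch drift so that change alone
#: does not mark a pixel as rice.
DEFAULT_SAR_MEANS_DB: dict[str, dict[str, dict[str, float]]] = {
    "lodged_rice": {
        "before": {"vv": -12.25, "vh": -17.13},
        "after": {"vv": -11.10, "vh": -15.52},
    },
    "healthy_rice": {
        "before": {"vv": -11.66, "vh": -16.91},
        "after": {"vv": -12.27, "vh": -16.86},
    },
    "water": {"before": {"vv": -22.0, "vh": -28.0}, "after": {"vv": -21.7, "vh": -27.8}},
    "building": {"before": {"vv": -4.0, "vh": -10.0}, "after": {"vv": -4.3, "vh": -10.2}},
    "wood": {"before": {"vv": -8.5, "vh": -13.5}, "after": {"vv": -8.7, "vh": -13.6}},
    "bare": {"before": {"vv": -14.5, "vh": -21.0}, "after": {"vv": -14.2, "vh": -20.8}},
}

_RICE_OPTICAL = {
    "lodged_rice": {
        "before": [REFERENCE_PLOT_MEANS[b].lodged_before for b in OPTICAL_BANDS],
        "after": [REFERENCE_PLOT_MEANS[b].lodged_after for b in OPTICAL_BANDS],
    },
    "healthy_rice": {
        "before": [REFERENCE_PLOT_MEANS[b].healthy_before for b in OPTICAL_BANDS],
        "after": [REFERENCE_PLOT_MEANS[b].healthy_after for b in OPTICAL_BANDS],
    },
}

#: Default per-class optical band means (reflectance units, band order B2..B12).
#: Rice classes reproduce the reference table, including the healthy-class
#: before/after drift attributable to illumination differences between the two
#: acquisitions, so the screening stage sees realistic confounding.
DEFAULT_OPTICAL_MEANS: dict[str, dict[str, list[float]]] = {
    **_RICE_OPTICAL,
    "water": {
        "before": [0.06, 0.07, 0.05, 0.05, 0.04, 0.04, 0.03, 0.03, 0.02, 0.02],
        "after": [0.07, 0.08, 0.06, 0.06, 0.05, 0.05, 0.04, 0.04, 0.02, 0.02],
    },
    "building": {
        "before": [0.30, 0.32, 0.34, 0.35, 0.36, 0.37, 0.38, 0.38, 0.40, 0.38],
        "after": [0.32, 0.34, 0.36, 0.37, 0.38, 0.39, 0.40, 0.40, 0.42, 0.40],
    },
    "wood": {
        "before": [0.08, 0.12, 0.09, 0.18, 0.35, 0.40, 0.42, 0.43, 0.25, 0.14],
        "after": [0.09, 0.13, 0.10, 0.19, 0.36, 0.41, 0.43, 0.44, 0.26, 0.15],
    },
    "bare": {
        "before": [0.16, 0.20, 0.24, 0.27, 0.30, 0.32, 0.33, 0.34, 0.38, 0.33],
        "after": [0.17, 0.21, 0.25, 0.28, 0.31, 0.33, 0.34, 0.35, 0.39, 0.34],
    },
}

#: Default scene composition: rice covers ~80% of the scene and the lodged
#: share of rice is ~35%, matching the reference scenario's land-cover mix.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "lodged_rice": 0.28,
    "healthy_rice": 0.52,
    "water": 0.05,
    "building": 0.05,
    "wood": 0.05,
    "bare": 0.05,
}


def reference_aggregate_rows() -> dict[str, tuple[float, float, float, float]]:
    """Return {parameter: (LBav, LAav, HBav, HAav)} for all 20 parameters."""
    return {
        name: (s.lodged_before, s.lodged_after, s.healthy_before, s.healthy_after)
        for name, s in REFERENCE_PLOT_MEANS.items()
    }
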