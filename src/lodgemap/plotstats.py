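"""Zonal reduction of feature rasters to the per-plot before/after table.

Plot inhomogeneity is eliminated by averaging each parameter over every
sample-plot polygon, giving one value per (plot, parameter, epoch).  The
resulting table is the input of the OSPL screening model: rows L1–L10 are
lodged plots, H1–H10 healthy plots; per-parameter aggregates LBav/LAav/
HBav/HAav are plot-set means and sigma_L/sigma_H their absolute before/after
differences.

Pixel membership uses the pixel-centre convention (a pixel belongs to a plot
iff its centre lies inside the polygon; boundary ties resolve to outside, the
shapely ``contains`` rule).  Quartiles use inclusive linear interpolation by
default; the rule is configurable and recorded on the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import GridTransform, RasterStack

CLASS_OF_PREFIX = {"L": "lodged", "H": "healthy"}


def zonal_mean(
    raster: np.ndarray, polygons: list[tuple[str, object]], transform: GridTransform
) -> dict[str, tuple[float, int]]:
    """Mean of ``raster`` over each polygon; returns {label: (mean, n_pixels)}.

    NaN pixels are excluded from the average.  A polygon covering zero pixel
    centres raises with the plot label in the message.
    """
    h, w = raster.shape
    out: dict[str, tuple[float, int]] = {}
    for label, poly in polygons:
        minx, miny, maxx, maxy = poly.bounds
        r0, c0 = transform.world_to_pixel(minx, maxy)
        r1, c1 = transform.world_to_pixel(maxx, miny)
        rr0 = max(int(np.floor(min(r0, r1))) - 1, 0)
        rr1 = min(int(np.ceil(max(r0, r1))) + 1, h - 1)
        cc0 = max(int(np.floor(min(c0, c1))) - 1, 0)
        cc1 = min(int(np.ceil(max(c0, c1))) + 1, w - 1)
        if rr0 > rr1 or cc0 > cc1:
            raise ValueError(f"plot {label!r} covers no pixel centres")
        rows, cols = np.mgrid[rr0 : rr1 + 1, cc0 : cc1 + 1]
        x, y = transform.pixel_center(rows.ravel(), cols.ravel())
        inside = shapely.contains_xy(poly, x, y)
        if not inside.any():
            raise ValueError(f"plot {label!r} covers no pixel centres")
        vals = raster[rows.ravel()[inside], cols.ravel()[inside]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"plot {label!r} has only undefined pixels")
        out[label] = (float(vals.mean()), int(vals.size))
    return out


@dataclass
class BeforeAfterPlotTable:
    """Per-plot, per-parameter values before/after the event.

    ``per_plot`` is a tidy frame (plot, class, parameter, before, after) or
    None when the table was built from published aggregates only, in which
    case only the four class means per parameter are available and screening
    steps that need per-plot values must flag insufficient data.
    """

    per_plot: pd.DataFrame | None
    aggregates_: pd.DataFrame  # index parameter; LBav LAav sigma_L HBav HAav sigma_H
    domains: dict[str, str]  # parameter -> "sar" | "optical"
    quantile_rule: str = "linear"
    meta: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.aggregates_.index)

    @property
    def has_per_plot(self) -> bool:
        return self.per_plot is not None

    def aggregates(self) -> pd.DataFrame:
        return self.aggregates_

    def plot_values(self, parameter: str, cls: str, epoch: str) -> np.ndarray:
        """Per-plot values for one parameter/class/epoch, ordered by plot label."""
        if self.per_plot is None:
            raise ValueError("table was built from aggregates only; no per-plot values")
        sel = self.per_plot[(self.per_plot["parameter"] == parameter) & (self.per_plot["class"] == cls)]
        return sel.sort_values("plot")[epoch].to_numpy(dtype=float)

    def after_order_stats(self) -> pd.DataFrame:
        """min / lower quartile / upper quartile / max of after-event plot values per class."""
        if self.per_plot is None:
            raise ValueError("order statistics require per-plot values")
        recs = []
        for param in self.parameters:
            for cls in ("lodged", "healthy"):
                v = self.plot_values(param, cls, "after")
                recs.append(
                    {
                        "parameter": param,
                        "class": cls,
                        "min": v.min(),
                        "q1": float(np.quantile(v, 0.25, method=self.quantile_rule)),
                        "q3": float(np.quantile(v, 0.75, method=self.quantile_rule)),
                        "max": v.max(),
                    }
                )
        return pd.DataFrame(recs)

    @classmethod
    def from_per_plot(
        cls, per_plot: pd.DataFrame, domains: dict[str, str], quantile_rule: str = "linear"
    ) -> "BeforeAfterPlotTable":
        need = {"plot", "class", "parameter", "before", "after"}
        if not need.issubset(per_plot.columns):
            raise ValueError(f"per-plot frame must have columns {sorted(need)}")
        rows = []
        for param, g in per_plot.groupby("parameter", sort=False):
            lod = g[g["class"] == "lodged"]
            hea = g[g["class"] == "healthy"]
            if lod.empty or hea.empty:
                raise ValueError(f"parameter {param!r} is missing a class")
            lbav, laav = lod["before"].mean(), lod["after"].mean()
            hbav, haav = hea["before"].mean(), hea["after"].mean()
            rows.append(
                {
                    "parameter": param,
                    "LBav": lbav,
                    "LAav": laav,
                    "sigma_L": abs(lbav - laav),
                    "HBav": hbav,
                    "HAav": haav,
                    "sigma_H": abs(hbav - haav),
                }
            )
        agg = pd.DataFrame(rows).set_index("parameter")
        return cls(per_plot=per_plot.reset_index(drop=True), aggregates_=agg, domains=dict(domains), quantile_rule=quantile_rule)

    @classmethod
    def from_aggregates(
        cls, rows: dict[str, tuple[float, float, float, float]], domains: dict[str, str]
    ) -> "BeforeAfterPlotTable":
        """Build an aggregate-only table from {param: (LBav, LAav, HBav, HAav)}."""
        agg = pd.DataFrame(
            [
                {
                    "parameter": p,
                    "LBav": lb,
                    "LAav": la,
                    "sigma_L": abs(lb - la),
                    "HBav": hb,
                    "HAav": ha,
                    "sigma_H": abs(hb - ha),
                }
                for p, (lb, la, hb, ha) in rows.items()
            ]
        ).set_index("parameter")
        return cls(per_plot=None, aggregates_=agg, domains=dict(domains))


def build_table(
    before: RasterStack,
    after: RasterStack,
    plots: list,
    domains: dict[str, str],
    quantile_rule: str = "linear",
) -> BeforeAfterPlotTable:
    """Reduce paired feature stacks over the sample plots to a screening table."""
    if before.names != after.names:
        raise ValueError(
            f"parameter names differ between epochs: {before.names} vs {after.names}"
        )
    polys = [(p.label, p.polygon) for p in plots]
    recs = []
    for param in before.names:
        mb = zonal_mean(before[param], polys, before.transform)
        ma = zonal_mean(after[param], polys, after.transform)
        for label, _ in polys:
            recs.append(
                {
                    "plot": label,
                    "class": CLASS_OF_PREFIX[label[0]],
                    "parameter": param,
                    "before": mb[label][0],
                    "after": ma[label][0],
                    "n_pixels": ma[label][1],
                }
            )
    table = BeforeAfterPlotTable.from_per_plot(pd.DataFrame(recs), domains, quantile_rule)
    table.meta["quantile_rule"] = quantile_rule
    table.meta["pixel_rule"] = "pixel-centre inside polygon (shapely contains)"
    return table
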