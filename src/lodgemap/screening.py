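"""OSPL screening: three-step selection of lodging-sensitive parameters.

A candidate parameter (SAR feature or optical band) passes:

step 1 — sensitivity: gamma = |LBav − LAav| / |LBav + LAav|
         − 1.5 |HBav − HAav| / |HBav + HAav| must be > 0, i.e. the relative
         before/after change of the lodged plots must clearly exceed that of
         the healthy plots.  The magnitude (absolute-value) convention is
         used for both numerators and denominators.

step 2 — consistency: over the ten lodged plots, eps_i = LA_i − LB_i must
         have the same sign almost everywhere; beta is the count of the
         majority sign (zeros excluded) and beta >= 9 is required.

step 3 — separability: after the event the two classes must separate in the
         order-statistic sense — with the higher-mean class's lower quartile
         above the lower-mean class's maximum and the lower-mean class's
         upper quartile below the higher-mean class's minimum.

Parameters passing all three form the OSPL set, partitioned into OSF (SAR)
and OSI (optical) by their domain tag.  On aggregate-only tables (no
per-plot values) steps 2 and 3 cannot be evaluated and are flagged as
insufficient data rather than guessed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plotstats import BeforeAfterPlotTable

log = logging.getLogger(__name__)

BETA_THRESHOLD = 9


def gamma_sensitivity(lbav: float, laav: float, hbav: float, haav: float) -> float:
    """Sensitivity statistic gamma (magnitude convention).

    Undefined (NaN, with a warning) when either class's before+after sum is
    zero.
    """
    den_l = abs(lbav + laav)
    den_h = abs(hbav + haav)
    if den_l == 0 or den_h == 0:
        warnings.warn("gamma undefined: zero before+after sum", stacklevel=2)
        return float("nan")
    return abs(lbav - laav) / den_l - 1.5 * abs(hbav - haav) / den_h


def epsilon_series(lb: np.ndarray, la: np.ndarray) -> np.ndarray:
    """Per-plot after − before differences eps_i = LA_i − LB_i."""
    lb = np.asarray(lb, dtype=float)
    la = np.asarray(la, dtype=float)
    if lb.shape != la.shape:
        raise ValueError("before/after vectors must be paired (equal length)")
    return la - lb


def beta_consistency(epsilon: np.ndarray) -> int:
    """Majority-sign count beta; exact zeros belong to neither sign.

    Returns 0 (with a warning) when every difference is exactly zero.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    if epsilon.size == 0:
        raise ValueError("epsilon must be non-empty")
    pos = int(np.count_nonzero(epsilon > 0))
    neg = int(np.count_nonzero(epsilon < 0))
    if pos == 0 and neg == 0:
        warnings.warn("beta undefined: all epsilon values are zero", stacklevel=2)
        return 0
    return max(pos, neg)


def quantile_separation(
    healthy_after: np.ndarray, lodged_after: np.ndarray, quantile_rule: str = "linear"
) -> bool:
    """Order-statistic separation of the after-event class samples.

    If the healthy mean is the higher one: healthy lower quartile > lodged
    maximum AND lodged upper quartile < healthy minimum; otherwise the
    mirrored condition.  Degenerate identical samples return False.
    """
    h = np.asarray(healthy_after, dtype=float)
    lo = np.asarray(lodged_after, dtype=float)
    if h.size < 4 or lo.size < 4:
        raise ValueError("quantile separation needs at least 4 plots per class")

    def q(v, p):
        return float(np.quantile(v, p, method=quantile_rule))

    if h.mean() > lo.mean():
        return bool(q(h, 0.25) > lo.max() and q(lo, 0.75) < h.min())
    if h.mean() < lo.mean():
        return bool(q(lo, 0.25) > h.max() and q(h, 0.75) < lo.min())
    return False


@dataclass
class ScreeningResult:
    """Per-parameter screening diagnostics."""

    parameter: str
    domain: str
    gamma: float
    epsilon: np.ndarray | None
    beta: int | None
    step1_pass: bool
    step2_pass: bool | None  # None: per-plot data unavailable
    step3_pass: bool | None
    insufficient_data: bool
    selected: bool


@dataclass
class ScreeningReport:
    results: list[ScreeningResult]
    beta_threshold: int = BETA_THRESHOLD
    meta: dict = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    "domain": r.domain,
                    "gamma": r.gamma,
                    "beta": r.beta,
                    "step1_pass": r.step1_pass,
                    "step2_pass": r.step2_pass,
                    "step3_pass": r.step3_pass,
                    "insufficient_data": r.insufficient_data,
                    "selected": r.selected,
                }
                for r in self.results
            ]
        ).set_index("parameter")

    def step1_set(self, domain: str | None = None) -> list[str]:
        return [r.parameter for r in self.results if r.step1_pass and (domain is None or r.domain == domain)]

    def selected_set(self, domain: str | None = None) -> list[str]:
        return [r.parameter for r in self.results if r.selected and (domain is None or r.domain == domain)]

    @property
    def osf(self) -> list[str]:
        """Selected SAR features."""
        return self.selected_set("sar")

    @property
    def osi(self) -> list[str]:
        """Selected optical indices."""
        return self.selected_set("optical")

    def to_dict(self) -> dict:
        return {
            "beta_threshold": self.beta_threshold,
            "osf": self.osf,
            "osi": self.osi,
            "step1_sar": self.step1_set("sar"),
            "step1_optical": self.step1_set("optical"),
            "parameters": self.frame.reset_index().replace({np.nan: None}).to_dict(orient="records"),
        }


def screen(table: BeforeAfterPlotTable, beta_threshold: int = BETA_THRESHOLD) -> ScreeningReport:
    """Apply the three screening steps to every parameter of the table."""
    agg = table.aggregates()
    results = []
    for param in table.parameters:
        row = agg.loc[param]
        domain = table.domains.get(param, "unknown")
        g = gamma_sensitivity(row["LBav"], row["LAav"], row["HBav"], row["HAav"])
        step1 = bool(np.isfinite(g) and g > 0)
        if table.has_per_plot:
            eps = epsilon_series(
                table.plot_values(param, "lodged", "before"),
                table.plot_values(param, "lodged", "after"),
            )
            beta = beta_consistency(eps)
            step2 = bool(beta >= beta_threshold)
            step3 = quantile_separation(
                table.plot_values(param, "healthy", "after"),
                table.plot_values(param, "lodged", "after"),
                table.quantile_rule,
            )
            insufficient = False
            selected = step1 and step2 and step3
        else:
            eps, beta, step2, step3 = None, None, None, None
            insufficient = True
            selected = False
            log.info("parameter %s: per-plot data unavailable, steps 2-3 skipped", param)
        results.append(
            ScreeningResult(
                parameter=param,
                domain=domain,
                gamma=g,
                epsilon=eps,
                beta=beta,
                step1_pass=step1,
                step2_pass=step2,
                step3_pass=step3,
                insufficient_data=insufficient,
                selected=selected,
            )
        )
    report = ScreeningReport(results, beta_threshold=beta_threshold)
    report.meta["quantile_rule"] = table.quantile_rule
    return report
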