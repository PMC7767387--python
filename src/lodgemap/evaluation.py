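"""Confusion-matrix accuracy assessment: PA, UA, OA and Kappa.

The contingency table is laid out with rows = classification category (CC)
and columns = ground truth (GT).  Producer's accuracy of a class is the
correctly classified count divided by its GT column total (recall);
user's accuracy divides by its CC row total (precision); overall accuracy is
the trace over the grand total; Kappa is the chance-corrected agreement
(po − pe)/(1 − pe) with pe from the row/column marginals.

Display rounding matches the conventional reporting style (accuracies to the
nearest percent, Kappa to two decimals); full precision is always retained
in the report object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def confusion(pred, truth, labels: list | None = None) -> pd.DataFrame:
    """Cross-tabulate predicted vs. true labels.

    Rows are the classification category (CC), columns the ground truth
    (GT).  ``labels`` fixes the class order (and includes absent classes);
    by default the sorted union of observed labels is used.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if labels is None:
        labels = sorted(set(pred) | set(truth))
    tab = pd.crosstab(pd.Series(pred, name="CC"), pd.Series(truth, name="GT"))
    tab = tab.reindex(index=labels, columns=labels, fill_value=0)
    return tab.astype(int)


@dataclass
class AccuracyReport:
    """Contingency table plus the accuracy metrics recomputable from it."""

    contingency: pd.DataFrame  # rows CC, cols GT
    pa: dict  # producer's accuracy per class (GT-column recall)
    ua: dict  # user's accuracy per class (CC-row precision)
    oa: float
    kappa: float
    undefined_classes: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        """Display-style rounding: percents to integers, Kappa to 2 d.p."""

        def pct(x):
            return None if x is None or not np.isfinite(x) else int(round(100 * x))

        return {
            "PA": {k: pct(v) for k, v in self.pa.items()},
            "UA": {k: pct(v) for k, v in self.ua.items()},
            "OA": pct(self.oa),
            "Kappa": round(self.kappa, 2),
        }

    def to_frame(self) -> pd.DataFrame:
        """Contingency table with PA/UA/OA/Kappa rows appended (display layout)."""
        tab = self.contingency.astype(object).copy()
        r = self.rounded()
        tab.loc["PA (%)"] = [r["PA"].get(c) for c in tab.columns]
        tab["UA (%)"] = [r["UA"].get(c) for c in self.contingency.index] + [None]
        tab.loc["OA (%)"] = [r["OA"]] + [None] * (tab.shape[1] - 1)
        tab.loc["Kappa"] = [round(self.kappa, 4)] + [None] * (tab.shape[1] - 1)
        return tab


def metrics(contingency) -> AccuracyReport:
    """Compute PA/UA/OA/Kappa from a CC-by-GT contingency table."""
    if isinstance(contingency, pd.DataFrame):
        tab = contingency
    else:
        arr = np.asarray(contingency)
        tab = pd.DataFrame(arr, index=range(arr.shape[0]), columns=range(arr.shape[1]))
    counts = tab.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("contingency counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    diag = np.diag(counts)
    row_tot = counts.sum(axis=1)  # CC totals
    col_tot = counts.sum(axis=0)  # GT totals

    undefined = []
    pa, ua = {}, {}
    for i, cls in enumerate(tab.columns):
        if col_tot[i] > 0:
            pa[cls] = diag[i] / col_tot[i]
        else:
            pa[cls] = float("nan")
            undefined.append(cls)
    for i, cls in enumerate(tab.index):
        if row_tot[i] > 0:
            ua[cls] = diag[i] / row_tot[i]
        else:
            ua[cls] = float("nan")
            if cls not in undefined:
                undefined.append(cls)

    po = diag.sum() / total
    pe = float(np.sum(row_tot * col_tot)) / total**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return AccuracyReport(
        contingency=tab.astype(int),
        pa=pa,
        ua=ua,
        oa=float(po),
        kappa=float(kappa),
        undefined_classes=undefined,
    )


def evaluate_labels(pred, truth, labels: list | None = None) -> AccuracyReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(pred, truth, labels))
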