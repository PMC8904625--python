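"""Accuracy/precision statistics between predicted and subjective refraction.

Differences are oriented ``predicted − subjective`` and analysed per
power-vector component (M, J0, J45):

* MBE — mean bias error (accuracy),
* MAE — mean absolute error,
* LOA95 — 95 % limits of agreement, ``2 × SD`` of the differences
  (sample SD, n−1 denominator; the Bland–Altman convention),
* agreement percentages within 0.25 D and 0.5 D (inclusive thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import PowerVector

__all__ = [
    "COMPONENTS",
    "PairedRefractions",
    "AgreementStats",
    "agreement_stats",
    "bland_altman_table",
    "error_distribution",
]

COMPONENTS = ("M", "J0", "J45")


@dataclass(frozen=True, eq=False)
class PairedRefractions:
    """Predicted and subjective refractions for a set of eyes (one eye each)."""

    ids: tuple
    predicted: tuple[PowerVector, ...]
    subjective: tuple[PowerVector, ...]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if not (len(self.predicted) == len(self.subjective) == n):
            raise ValueError("ids, predicted and subjective must have equal lengths")
        if n < 2:
            raise ValueError("at least 2 paired refractions are required")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_lists(
        cls,
        predicted: Sequence[PowerVector],
        subjective: Sequence[PowerVector],
        ids: Sequence | None = None,
    ) -> "PairedRefractions":
        if ids is None:
            ids = range(len(predicted))
        return cls(tuple(ids), tuple(predicted), tuple(subjective))

    def component(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        pred = np.array([getattr(p, name) for p in self.predicted])
        subj = np.array([getattr(s, name) for s in self.subjective])
        return pred, subj

    def differences(self) -> pd.DataFrame:
        """Per-eye ``predicted − subjective`` per component."""
        data = {"id": list(self.ids)}
        for comp in COMPONENTS:
            pred, subj = self.component(comp)
            data[comp] = pred - subj
        return pd.DataFrame(data)


@dataclass(frozen=True, eq=False)
class AgreementStats:
    """Per-component agreement statistics (rows M/J0/J45)."""

    table: pd.DataFrame  # index: component; columns: mae, mbe, loa95, pct_*
    n: int

    def __getitem__(self, component: str) -> pd.Series:
        return self.table.loc[component]

    def tidy(self) -> pd.DataFrame:
        """Long-form (component, statistic, value) table."""
        t = self.table.reset_index(names="component")
        return t.melt(id_vars="component", var_name="statistic", value_name="value")

    def __str__(self) -> str:
        return (
            f"Agreement vs subjective refraction (n = {self.n})\n"
            + self.table.to_string(float_format=lambda v: f"{v:8.3f}")
        )


def agreement_stats(pairs: PairedRefractions) -> AgreementStats:
    """Compute MBE/MAE/LOA95 and threshold agreement per component."""
    rows = {}
    for comp in COMPONENTS:
        pred, subj = pairs.component(comp)
        diff = pred - subj
        rows[comp] = {
            "mae": float(np.mean(np.abs(diff))),
            "mbe": float(np.mean(diff)),
            "loa95": float(2.0 * np.std(diff, ddof=1)),
            "pct_within_025": float(100.0 * np.mean(np.abs(diff) <= 0.25)),
            "pct_within_05": float(100.0 * np.mean(np.abs(diff) <= 0.5)),
        }
    table = pd.DataFrame(rows).T.loc[list(COMPONENTS)]
    return AgreementStats(table=table, n=len(pairs))


def bland_altman_table(pairs: PairedRefractions, component: str = "M") -> pd.DataFrame:
    """Bland–Altman coordinates: mean of methods vs difference, per eye.

    The returned frame carries the bias and limit lines in ``.attrs``
    (``bias``, ``loa_low``, ``loa_high``).
    """
    pred, subj = pairs.component(component)
    diff = pred - subj
    df = pd.DataFrame(
        {"id": list(pairs.ids), "mean": (pred + subj) / 2.0, "difference": diff}
    )
    bias = float(np.mean(diff))
    loa = float(2.0 * np.std(diff, ddof=1))
    df.attrs.update({"bias": bias, "loa_low": bias - loa, "loa_high": bias + loa,
                     "component": component})
    return df


def error_distribution(
    pairs_before: PairedRefractions,
    pairs_after: PairedRefractions,
    bin_width: float = 0.25,
) -> dict[str, pd.DataFrame]:
    """Histograms of prediction error before/after optimization, per component.

    Bins are aligned so that zero difference falls at the center of a bin.
    """
    if not bin_width > 0.0:
        raise ValueError("bin_width must be positive")
    if len(pairs_before) != len(pairs_after):
        raise ValueError("before/after must cover the same subjects")
    out = {}
    for comp in COMPONENTS:
        d_before = np.subtract(*pairs_before.component(comp))
        d_after = np.subtract(*pairs_after.component(comp))
        extent = max(np.abs(d_before).max(), np.abs(d_after).max(), bin_width / 2)
        k = int(np.ceil((extent - bin_width / 2) / bin_width + 1e-12))
        edges = (np.arange(-k, k + 2) - 0.5) * bin_width
        cb, _ = np.histogram(d_before, bins=edges)
        ca, _ = np.histogram(d_after, bins=edges)
        out[comp] = pd.DataFrame(
            {
                "bin_center": (edges[:-1] + edges[1:]) / 2.0,
                "count_before": cb,
                "count_after": ca,
            }
        )
    return out
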