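"""Marker positivity thresholds from labelled reference cells.

For each fluorescence marker a threshold separating negative from
positive cells is derived from reference cells of known status:

* if the two reference intensity ranges do not overlap, the threshold
  is the midpoint between the highest negative and the lowest positive
  intensity (zero training error by construction);
* otherwise both intensity distributions are smoothed with a Gaussian
  kernel density estimate (bandwidth by Silverman's rule of thumb) and
  the threshold minimises the overall classification error

      err(t) = pi_neg * P_neg(X > t) + pi_pos * P_pos(X <= t)

  under the two KDEs, with empirical class priors pi taken from the
  reference-set sizes.  Ties resolve to the smallest t.

False/true positive and negative rates are then computed empirically on
the reference cells at the chosen threshold; a cell is called positive
when its intensity is strictly greater than the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

logger = logging.getLogger("siascore")

__all__ = [
    "ThresholdResult",
    "silverman_bandwidth",
    "estimate_density",
    "determine_threshold",
    "apply_thresholds",
]

GRID_POINTS = 512


class DegenerateInputError(ValueError):
    """Raised when a sample carries too little variation for KDE."""


@dataclass(frozen=True)
class ThresholdResult:
    """A per-marker threshold with its training error rates."""

    marker: str
    threshold: float
    rule: str  # "midpoint" | "error-min"
    fpr: float
    tpr: float
    fnr: float
    tnr: float
    n_pos_ref: int
    n_neg_ref: int

    def __post_init__(self) -> None:
        assert abs(self.fpr + self.tnr - 1.0) < 1e-9
        assert abs(self.fnr + self.tpr - 1.0) < 1e-9

    @property
    def overall_error(self) -> float:
        n = self.n_pos_ref + self.n_neg_ref
        return (self.fnr * self.n_pos_ref + self.fpr * self.n_neg_ref) / n


def silverman_bandwidth(values: np.ndarray) -> float:
    """Rule-of-thumb KDE bandwidth: 0.9 * min(sd, IQR/1.349) * n^(-1/5).

    This is the classic automatic bandwidth of univariate density
    smoothing (the default of R's ``density``); it falls back to the
    standard deviation when the IQR degenerates to zero.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateInputError("sample has zero spread; cannot smooth")
    return 0.9 * spread * n ** (-0.2)


def estimate_density(values) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE of ``values`` on a 512-point grid.

    Returns ``(grid, density, bandwidth)`` where the grid spans
    ``[min - 3h, max + 3h]``.  The density integrates to 1 up to the
    Gaussian tail mass truncated beyond three bandwidths (< 1e-3 for
    any reasonably sized sample).
    """
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 2:
        raise DegenerateInputError("need at least 2 distinct intensity values")
    h = silverman_bandwidth(values)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, GRID_POINTS)
    z = (grid[:, None] - values[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return grid, density, h


def _kde_cdf(t: np.ndarray, values: np.ndarray, h: float) -> np.ndarray:
    """CDF of the Gaussian KDE at points ``t`` (exact mixture CDF)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return ndtr((t[:, None] - values[None, :]) / h).mean(axis=1)


def classification_error(t, pos_ref, neg_ref) -> np.ndarray:
    """err(t) under the two reference KDEs with empirical class priors."""
    pos = np.asarray(pos_ref, dtype=float)
    neg = np.asarray(neg_ref, dtype=float)
    h_pos = silverman_bandwidth(pos)
    h_neg = silverman_bandwidth(neg)
    n = pos.size + neg.size
    pi_pos, pi_neg = pos.size / n, neg.size / n
    return pi_neg * (1.0 - _kde_cdf(t, neg, h_neg)) + pi_pos * _kde_cdf(t, pos, h_pos)


def determine_threshold(pos_ref, neg_ref, marker: str = "") -> ThresholdResult:
    """Derive a positivity threshold from labelled reference intensities."""
    pos = np.asarray(pos_ref, dtype=float)
    neg = np.asarray(neg_ref, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both reference sets must be non-empty")

    if neg.max() < pos.min():
        threshold = 0.5 * (neg.max() + pos.min())
        rule = "midpoint"
    else:
        if np.array_equal(np.sort(pos), np.sort(neg)):
            logger.warning(
                "marker %s: positive and negative reference sets are identical; "
                "threshold is uninformative", marker or "<unnamed>",
            )
        grid_pos, _, _ = estimate_density(pos)
        grid_neg, _, _ = estimate_density(neg)
        candidates = np.union1d(grid_pos, grid_neg)
        err = classification_error(candidates, pos, neg)
        threshold = float(candidates[np.argmin(err)])  # first minimum = smallest t
        rule = "error-min"

    fpr = float((neg > threshold).mean())
    tpr = float((pos > threshold).mean())
    if tpr < 0.5:
        logger.warning(
            "marker %s: TPR %.3f < 0.5 at the chosen threshold; "
            "the marker may be inverted (positives dimmer than negatives)",
            marker or "<unnamed>", tpr,
        )
    return ThresholdResult(
        marker=marker, threshold=float(threshold), rule=rule,
        fpr=fpr, tpr=tpr, fnr=1.0 - tpr, tnr=1.0 - fpr,
        n_pos_ref=int(pos.size), n_neg_ref=int(neg.size),
    )


def thresholds_from_reference_table(refs: pd.DataFrame) -> dict[str, ThresholdResult]:
    """Thresholds for every marker in a reference table.

    ``refs`` needs columns ``marker``, ``intensity`` and ``label`` with
    labels in {"pos", "neg"}.  Each marker is processed independently.
    """
    results: dict[str, ThresholdResult] = {}
    for marker, grp in refs.groupby("marker"):
        pos = grp.loc[grp["label"] == "pos", "intensity"].to_numpy(float)
        neg = grp.loc[grp["label"] == "neg", "intensity"].to_numpy(float)
        results[marker] = determine_threshold(pos, neg, marker=str(marker))
    return results


def apply_thresholds(cells: pd.DataFrame, thresholds: dict[str, ThresholdResult],
                     config) -> pd.DataFrame:
    """Flag every cell positive/negative per marker of its panel.

    Adds one boolean column ``pos_<marker>`` per marker; a cell is
    positive when its intensity strictly exceeds the marker threshold.
    Idempotent: reapplying overwrites the same flags.
    """
    out = cells.copy()
    for panel_id in out["panel_id"].unique():
        markers = config.panels[panel_id]
        mask = out["panel_id"] == panel_id
        for m in markers:
            if m not in thresholds:
                raise KeyError(
                    f"no threshold configured for marker {m!r} (panel {panel_id!r})"
                )
            col = f"pos_{m}"
            if col not in out.columns:
                out[col] = False
            out.loc[mask, col] = (
                out.loc[mask, m].to_numpy(float) > thresholds[m].threshold
            )
    return out


def thresholds_to_frame(thresholds: dict[str, ThresholdResult]) -> pd.DataFrame:
    rows = [
        {
            "marker": r.marker, "threshold": r.threshold, "rule": r.rule,
            "FPR": r.fpr, "TPR": r.tpr, "FNR": r.fnr, "TNR": r.tnr,
            "n_pos_ref": r.n_pos_ref, "n_neg_ref": r.n_neg_ref,
        }
        for r in thresholds.values()
    ]
    return pd.DataFrame(rows)


def thresholds_from_frame(df: pd.DataFrame) -> dict[str, ThresholdResult]:
    return {
        row["marker"]: ThresholdResult(
            marker=row["marker"], threshold=float(row["threshold"]),
            rule=row["rule"], fpr=float(row["FPR"]), tpr=float(row["TPR"]),
            fnr=float(row["FNR"]), tnr=float(row["TNR"]),
            n_pos_ref=int(row["n_pos_ref"]), n_neg_ref=int(row["n_neg_ref"]),
        )
        for _, row in df.iterrows()
    }
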