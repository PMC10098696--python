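"""Univariate feature ranking against the binary stress label.

Two rankings are provided: a chi-square independence score per feature
(feature discretized into bins, 2×bins contingency table against the label,
score = −log p, threshold = the mean score over all features) and the
absolute Pearson correlation between feature and the 0/1 label with a fixed
0.10 cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS

__all__ = ["SelectionResult", "chi_square_rank", "pearson_rank", "contingency_chi2"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one ranking method: per-feature scores, threshold, survivors."""

    method: str
    scores: pd.Series
    threshold: float
    selected: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Serializable report: score and selected flag per feature, score-ordered."""
        df = pd.DataFrame({"score": self.scores.sort_values(ascending=False)})
        df["selected"] = [c in self.selected for c in df.index]
        df.attrs["method"] = self.method
        df.attrs["threshold"] = self.threshold
        return df


def contingency_chi2(observed: np.ndarray) -> tuple[float, int]:
    """Chi-square statistic Σ(O − E)²/E of a contingency table and its dof.

    Expected counts come from the marginal products; dof is
    (rows − 1)(cols − 1) over the columns actually populated.
    """
    obs = np.asarray(observed, dtype=float)
    col_ok = obs.sum(axis=0) > 0
    row_ok = obs.sum(axis=1) > 0
    obs = obs[np.ix_(row_ok, col_ok)]
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, dof


def _discretize(x: np.ndarray, n_bins: int, binning: str) -> np.ndarray:
    if binning == "width":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    elif binning == "quantile":
        edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    else:
        raise ValueError(f"unknown binning {binning!r}")
    # interior edges only; digitize pools the extremes into the end bins
    return np.digitize(x, edges[1:-1])


def chi_square_rank(
    table: pd.DataFrame,
    n_bins: int = 10,
    binning: str = "width",
    log_base: float = np.e,
    label_column: str = "label",
) -> SelectionResult:
    """Rank features by the chi-square independence score −log(p).

    Each feature is discretized into ``n_bins`` bins (equal-width by
    default; ``"quantile"`` makes the score invariant under monotone
    rescaling), crossed with the label into a 2×bins contingency table, and
    tested for independence; empty bins are pooled out and the degrees of
    freedom reduced accordingly. The score is −log(p) (computed through the
    log survival function, so perfect dependence stays finite), the
    threshold is the mean score, and features scoring strictly above it are
    selected.
    """
    y = table[label_column].to_numpy()
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    scores = {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            logger.warning("feature %s has a single distinct value; score 0", c)
            scores[c] = 0.0
            continue
        bins = _discretize(x, n_bins, binning)
        observed = pd.crosstab(y, bins).to_numpy()
        stat, dof = contingency_chi2(observed)
        if dof < 1:
            scores[c] = 0.0
            continue
        logp = stats.chi2.logsf(stat, dof)
        scores[c] = float(-logp / np.log(log_base))
    series = pd.Series(scores)
    threshold = float(series.mean())
    selected = tuple(
        series[series > threshold].sort_values(ascending=False).index
    )
    return SelectionResult("chi_square", series, threshold, selected)


def pearson_rank(
    table: pd.DataFrame,
    cutoff: float = 0.10,
    label_column: str = "label",
) -> SelectionResult:
    """Rank features by |Pearson r| against the 0/1 label; keep score ≥ cutoff.

    The sign is dropped — a feature anticorrelated with stress is as
    informative as a correlated one. Zero-variance features score 0.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    y = table[label_column].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("label must contain both classes")
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    scores = {}
    for c in cols:
        x = table[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            scores[c] = 0.0
            continue
        r = np.corrcoef(x, y)[0, 1]
        scores[c] = float(abs(r))
    series = pd.Series(scores)
    selected = tuple(series[series >= cutoff].sort_values(ascending=False).index)
    return SelectionResult("pearson", series, float(cutoff), selected)
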