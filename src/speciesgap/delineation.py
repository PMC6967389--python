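"""Population-level summaries over pairwise genome comparisons.

Three families of output:

* the ANI x alignment-fraction *landscape*: a 2-D Gaussian kernel
  density over all genome pairs, in which discrete sequence clusters
  appear as peaks separated by a depleted "species gap" around 90-95%
  ANI;
* *binned median curves* of a per-pair metric (dN/dS, hr, identical-gene
  fractions) against ANI, with percentile-bootstrap confidence bands;
* the *species-delineation threshold scan*: every identity threshold on
  a 80-100% grid (0.1 steps) is scored by how well "identity >= t"
  reproduces same-species pair labels, via recall, precision and F1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

PairKey = tuple[str, str]


def _key(g1: str, g2: str) -> PairKey:
    return (g1, g2) if g1 <= g2 else (g2, g1)


@dataclass
class PairLabelMatrix:
    """same-species booleans for every unordered genome pair."""

    genomes: list[str]
    same: dict[PairKey, bool]
    source: str  # "taxonomy" | "ani95"

    def __getitem__(self, pair: PairKey) -> bool:
        return self.same[_key(*pair)]

    def pairs(self) -> list[PairKey]:
        return sorted(self.same)


def pair_labels_from_taxonomy(labels: Mapping[str, str]) -> PairLabelMatrix:
    """Same-species pair labels from a genome -> species table."""
    genomes = sorted(labels)
    missing = [g for g in genomes if labels[g] in (None, "")]
    if missing:
        raise ValueError(f"genomes without a species label: {missing}")
    same = {_key(g1, g2): labels[g1] == labels[g2]
            for g1, g2 in itertools.combinations(genomes, 2)}
    return PairLabelMatrix(genomes=genomes, same=same, source="taxonomy")


def pair_labels_from_ani(pair_summaries: pd.DataFrame,
                         cutoff: float = 95.0) -> PairLabelMatrix:
    """Same-species labels from genome-wide ANI: same iff ANI >= cutoff.

    ``pair_summaries`` needs columns genome1, genome2, ani (ANI as a
    percentage).  Pairs with no alignment (missing ANI) are labeled
    different-species.  The boundary is closed: ANI exactly at the
    cutoff means same species.
    """
    same: dict[PairKey, bool] = {}
    genomes: set[str] = set()
    for row in pair_summaries.itertuples(index=False):
        genomes.update((row.genome1, row.genome2))
        ani = getattr(row, "ani", None)
        same[_key(row.genome1, row.genome2)] = (
            ani is not None and not pd.isna(ani) and ani >= cutoff)
    return PairLabelMatrix(genomes=sorted(genomes), same=same, source="ani95")


@dataclass(frozen=True)
class Scores:
    recall: float
    precision: float
    f1: float
    degenerate: bool = False  # any 0/0 encountered (scored as 0)


def precision_recall_f1(tp: int, fp: int, fn: int) -> Scores:
    """Pairwise classification scores.

    recall = tp / (tp + fn); precision = tp / (tp + fp);
    F1 = 2 * recall * precision / (recall + precision).
    Any 0/0 is scored 0 and flagged degenerate.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if recall + precision == 0:
        return Scores(recall, precision, 0.0, True)
    f1 = 2.0 * recall * precision / (recall + precision)
    return Scores(recall, precision, f1, degenerate)


@dataclass
class ThresholdScan:
    """Recall/precision/F1 across an identity-threshold grid."""

    thresholds: np.ndarray  # percent identity, ascending
    recall: np.ndarray
    precision: np.ndarray
    f1: np.ndarray
    optimal_threshold: float  # midpoint of the max-F1 plateau
    optimal_f1: float
    plateau_low: float
    plateau_high: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "recall": self.recall,
                             "precision": self.precision,
                             "f1": self.f1})


def scan_thresholds(identities: Mapping[PairKey, float],
                    labels: PairLabelMatrix,
                    lo: float = 80.0, hi: float = 100.0,
                    step: float = 0.1) -> ThresholdScan:
    """Scan identity thresholds for species delineation accuracy.

    ``identities`` maps unordered genome pairs to percent identity
    (0-100 scale); every labeled pair must be covered.  At each
    threshold t a pair is predicted same-species iff identity >= t.
    The optimal threshold is the midpoint of the plateau of thresholds
    attaining the maximum F1 (bounds reported alongside).

    Raises ValueError when the labels are single-class (F1 undefined as
    a delineation task).
    """
    pairs = labels.pairs()
    missing = [p for p in pairs if _key(*p) not in identities]
    if missing:
        raise ValueError(f"{len(missing)} labeled pairs lack an identity "
                         f"value, e.g. {missing[:3]}")
    y = np.array([labels[p] for p in pairs], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("labels are single-class; the scan is undefined")
    x = np.array([identities[_key(*p)] for p in pairs], dtype=float)

    n_steps = int(round((hi - lo) / step))
    grid = np.round(lo + step * np.arange(n_steps + 1), 6)
    pred = x[None, :] >= grid[:, None]  # (n_thresholds, n_pairs)
    tp = (pred & y[None, :]).sum(axis=1)
    fp = (pred & ~y[None, :]).sum(axis=1)
    fn = (~pred & y[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        denom = recall + precision
        f1 = np.where(denom > 0, 2.0 * recall * precision / np.maximum(denom, 1e-300), 0.0)
    best = f1.max()
    at_best = np.flatnonzero(f1 == best)
    plateau_low = float(grid[at_best[0]])
    plateau_high = float(grid[at_best[-1]])
    return ThresholdScan(thresholds=grid, recall=recall, precision=precision,
                         f1=f1,
                         optimal_threshold=(plateau_low + plateau_high) / 2.0,
                         optimal_f1=float(best),
                         plateau_low=plateau_low, plateau_high=plateau_high)


def identities_from_pair_summaries(pair_summaries: pd.DataFrame,
                                   column: str = "ani",
                                   percent: bool = True
                                   ) -> dict[PairKey, float]:
    """Pair -> percent-identity mapping from a pair-summary table.

    ``percent=False`` declares the column to be fractional (0-1) and
    rescales it to 0-100.  Pairs with missing values are mapped to 0
    (never same-species at any threshold on the grid).
    """
    out: dict[PairKey, float] = {}
    for row in pair_summaries.itertuples(index=False):
        v = getattr(row, column)
        if v is None or pd.isna(v):
            out[_key(row.genome1, row.genome2)] = 0.0
        else:
            out[_key(row.genome1, row.genome2)] = float(v) * (1.0 if percent else 100.0)
    return out


def identities_from_distance_matrix(dist: pd.DataFrame) -> dict[PairKey, float]:
    """Convert a square distance matrix (fractions) to percent identities:
    identity = 100 * (1 - distance)."""
    out: dict[PairKey, float] = {}
    for g1, g2 in itertools.combinations(dist.index, 2):
        out[_key(str(g1), str(g2))] = 100.0 * (1.0 - float(dist.loc[g1, g2]))
    return out


@dataclass
class LandscapeGrid:
    """Gaussian-KDE density over (ANI %, alignment fraction %)."""

    ani_grid: np.ndarray
    af_grid: np.ndarray
    density: np.ndarray  # shape (len(ani_grid), len(af_grid))
    bandwidth: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.density, index=self.ani_grid,
                            columns=self.af_grid)

    def integral(self) -> float:
        dx = self.ani_grid[1] - self.ani_grid[0]
        dy = self.af_grid[1] - self.af_grid[0]
        return float(self.density.sum() * dx * dy)


def ani_landscape(pair_summaries: pd.DataFrame, grid_size: int = 100,
                  bw_method: str | float = "scott",
                  pad: float = 2.0) -> LandscapeGrid:
    """2-D density of (ANI, alignment fraction) over genome pairs.

    Both axes are percentages; self-comparisons and no-alignment pairs
    are excluded.  The density is a Gaussian KDE (bandwidth by Scott's
    rule unless overridden) on a regular grid.  Per-axis padding beyond
    the data range is the larger of three kernel bandwidths and ``pad``
    percentage points (capped at the data range), so the grid always
    resolves the kernel even when one axis barely varies — as the
    alignment fraction does for closely related genomes.
    """
    df = pair_summaries
    df = df[df["genome1"] != df["genome2"]]
    df = df.dropna(subset=["ani", "alignment_fraction"])
    if len(df) < 2:
        raise ValueError("need >= 2 genome pairs with defined ANI")
    ani = np.asarray(df["ani"], dtype=float)
    af = np.asarray(df["alignment_fraction"], dtype=float)
    # fractions on a 0-1 scale are rescaled to percentages
    if ani.max() <= 1.0:
        ani = ani * 100.0
    if af.max() <= 1.0:
        af = af * 100.0
    # a constant axis would make the KDE covariance singular; spread it
    # by a negligible deterministic offset (different cycle per axis so
    # the two jitters are never collinear)
    idx = np.arange(len(ani))
    if ani.std() == 0.0:
        ani = ani + 1e-6 * np.where(idx % 2 == 0, 1.0, -1.0)
    if af.std() == 0.0:
        af = af + 1e-6 * (idx % 3 - 1.0)
    kde = gaussian_kde(np.vstack([ani, af]), bw_method=bw_method)

    def grid_for(values: np.ndarray) -> np.ndarray:
        h = kde.factor * values.std(ddof=1)
        extra = max(3.0 * h, min(pad, float(np.ptp(values))))
        return np.linspace(values.min() - extra, values.max() + extra,
                           grid_size)

    ani_grid = grid_for(ani)
    af_grid = grid_for(af)
    xx, yy = np.meshgrid(ani_grid, af_grid, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return LandscapeGrid(ani_grid=ani_grid, af_grid=af_grid, density=dens,
                         bandwidth=float(kde.factor))


@dataclass
class BinnedCurve:
    """Per-ANI-bin median of a metric with bootstrap confidence bands."""

    bin_edges: np.ndarray  # percent ANI
    median: np.ndarray  # NaN where masked
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray
    metric: str

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"bin_center": centers, "median": self.median,
                             "ci_low": self.ci_low, "ci_high": self.ci_high,
                             "n": self.n})


_METRIC_COLUMNS = {
    "dnds": lambda df: df["dnds"],
    "hr": lambda df: df["hr"],
    "identical_fraction_actual": lambda df: df["a"] / df["i"],
    "identical_fraction_expected": lambda df: df["e"] / df["i"],
}


def binned_median_curve(pair_summaries: pd.DataFrame, metric: str,
                        bin_width: float = 0.5, n_boot: int = 1000,
                        seed: int = 0, min_n: int = 3,
                        ci: float = 0.95) -> BinnedCurve:
    """Median of a per-pair metric in ANI bins, with bootstrap CIs.

    Pairs whose metric is undefined (missing dN/dS, hr of excluded
    pairs) are omitted from their bin; bins with fewer than ``min_n``
    defined values are masked (NaN).  The CI is a seeded percentile
    bootstrap of the median (``n_boot`` resamples).
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"choose from {sorted(_METRIC_COLUMNS)}")
    df = pair_summaries.dropna(subset=["ani"]).copy()
    ani = np.asarray(df["ani"], dtype=float)
    if len(ani) and ani.max() <= 1.0:
        ani = ani * 100.0
    if "excluded_flag" in df.columns and metric in (
            "hr", "identical_fraction_actual", "identical_fraction_expected"):
        keep = ~df["excluded_flag"].astype(bool).to_numpy()
        df, ani = df[keep], ani[keep]
    values = np.asarray(_METRIC_COLUMNS[metric](df), dtype=float)
    defined = np.isfinite(values)
    df, ani, values = df[defined], ani[defined], values[defined]

    lo = np.floor(ani.min() / bin_width) * bin_width if len(ani) else 0.0
    hi = np.ceil(ani.max() / bin_width) * bin_width if len(ani) else bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    med = np.full(n_bins, np.nan)
    ci_lo = np.full(n_bins, np.nan)
    ci_hi = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    which = np.clip(np.digitize(ani, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        vals = values[which == b]
        counts[b] = len(vals)
        if len(vals) < min_n:
            continue
        med[b] = np.median(vals)
        boots = np.median(
            rng.choice(vals, size=(n_boot, len(vals)), replace=True), axis=1)
        ci_lo[b] = np.quantile(boots, alpha)
        ci_hi[b] = np.quantile(boots, 1.0 - alpha)
    return BinnedCurve(bin_edges=edges, median=med, ci_low=ci_lo,
                       ci_high=ci_hi, n=counts, metric=metric)
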