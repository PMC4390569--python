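"""Broad-sense heritability via sequential variance decomposition.

For each trait measured on males of an inbred-line panel assayed in
experimental blocks, the analysis proceeds in two stages, mirroring the
classical two-column presentation (%B alongside H2):

1. Block partition - one-way fixed-effect ANOVA on block:
   %B = 100 * SS_block / SS_total, with F_B = MS_block / MS_within and its
   P value. Residuals (values minus block means) carry forward.

2. Line heritability - one-way random-effects ANOVA on line over the block
   residuals, method of moments (expected mean squares). With a lines,
   N males total and n_i males in line i, the unbalanced design coefficient
   is n0 = (N - sum(n_i^2)/N) / (a - 1), the between-line variance component
   is sigma2_L = (MS_line - MS_error) / n0, and broad-sense heritability is

       H2 = sigma2_L / (sigma2_L + sigma2_error).

   Estimates are NOT truncated at zero: sampling noise can and does make
   MS_line < MS_error under weak genetic signal, giving slightly negative
   H2 estimates, which are reported as-is.

Method of moments (not REML) is used deliberately so that negative
estimates remain visible; a REML fit would silently pin them to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .observations import arcsin_transform

__all__ = [
    "BlockPartition",
    "LineHeritability",
    "VarianceComponents",
    "VarianceComponentsResults",
    "block_partition",
    "heritability",
    "decompose_trait",
    "decompose_table",
    "bonferroni",
    "line_mean_correlation",
    "copulation_duration_means",
]


def _anova_oneway(values: np.ndarray, groups: np.ndarray):
    """SS/MS decomposition for a one-way layout.

    Returns (ss_between, ss_within, df_between, df_within, group_sizes).
    """
    grand = values.mean()
    levels, inverse = np.unique(groups, return_inverse=True)
    n_i = np.bincount(inverse).astype(float)
    sums = np.bincount(inverse, weights=values)
    means = sums / n_i
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[inverse]) ** 2))
    return ss_between, ss_within, len(levels) - 1, len(values) - len(levels), n_i


@dataclass
class BlockPartition:
    """Fixed-effect block stage: %B, F and P, plus block residuals."""

    pct_block: float
    F: float
    P: float
    residuals: np.ndarray
    df_block: int
    df_within: int


@dataclass
class LineHeritability:
    """Random-effect line stage: H2 and its F test."""

    H2: float
    F: float
    P: float
    sigma2_line: float
    sigma2_error: float
    n0: float
    df_line: int
    df_error: int


def block_partition(values, blocks) -> BlockPartition:
    """One-way fixed-effect ANOVA of a trait on experimental block.

    %B is the percentage of total sum of squares attributable to block;
    residuals are the values minus their block mean (grand mean removed
    with them, which is immaterial for the variance components that
    follow). A single block yields %B = 0 with an undefined (NaN) F.
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    if values.shape != blocks.shape:
        raise ValueError("values and blocks must align")
    levels, inverse = np.unique(blocks, return_inverse=True)
    if len(levels) < 2:
        warnings.warn("single block: %B set to 0, F undefined")
        return BlockPartition(0.0, np.nan, np.nan,
                              values - values.mean(), 0, len(values) - 1)
    ssb, ssw, dfb, dfw, _ = _anova_oneway(values, blocks)
    ss_total = ssb + ssw
    pct = 100.0 * ssb / ss_total if ss_total > 0 else 0.0
    msb = ssb / dfb
    msw = ssw / dfw if dfw > 0 else np.nan
    F = msb / msw if msw and msw > 0 else 0.0
    P = float(stats.f.sf(F, dfb, dfw)) if np.isfinite(F) else np.nan
    means = np.bincount(inverse, weights=values) / np.bincount(inverse)
    residuals = values - means[inverse]
    return BlockPartition(pct, float(F), P, residuals, dfb, dfw)


def heritability(residuals, lines) -> LineHeritability:
    """Random-effects one-way ANOVA on line; untruncated H2.

    Operates on block residuals. Requires >= 2 lines and at least one line
    with >= 2 males (else MS_error is undefined).
    """
    y = np.asarray(residuals, dtype=float)
    lines = np.asarray(lines)
    ssb, ssw, dfb, dfw, n_i = _anova_oneway(y, lines)
    if dfb < 1:
        raise ValueError("need at least 2 lines")
    if dfw < 1:
        raise ValueError("all lines are singletons: error variance undefined")
    ms_line = ssb / dfb
    ms_err = ssw / dfw
    N = float(len(y))
    n0 = (N - np.sum(n_i**2) / N) / dfb
    s2_line = (ms_line - ms_err) / n0
    s2_err = ms_err
    denom = s2_line + s2_err
    H2 = s2_line / denom if denom != 0 else 0.0
    if ms_err > 0:
        F = ms_line / ms_err
    else:
        F = np.inf if ms_line > 0 else np.nan
    P = float(stats.f.sf(F, dfb, dfw)) if np.isfinite(F) else (
        0.0 if F == np.inf else np.nan)
    return LineHeritability(float(H2), float(F), P, float(s2_line),
                            float(s2_err), float(n0), dfb, dfw)


class VarianceComponents:
    """Model: block-then-line variance decomposition of one trait.

    Parameters
    ----------
    values : per-male trait values
    lines, blocks : per-male labels
    arcsin : apply the arcsine-square-root transform first (for
        proportion-valued traits such as transition probabilities).

    ``fit()`` returns a :class:`VarianceComponentsResults`.
    """

    def __init__(self, values, lines, blocks, trait: str = "trait",
                 arcsin: bool = False):
        values = np.asarray(values, dtype=float)
        if arcsin:
            values = np.array([arcsin_transform(v) for v in values])
        self.values = values
        self.raw_mean = float(np.mean(np.asarray(values, dtype=float)))
        self.lines = np.asarray(lines)
        self.blocks = np.asarray(blocks)
        self.trait = trait

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trait: str,
                       line: str = "line", block: str = "block",
                       arcsin: bool = False) -> "VarianceComponents":
        return cls(df[trait].to_numpy(), df[line].to_numpy(),
                   df[block].to_numpy(), trait=trait, arcsin=arcsin)

    def fit(self) -> "VarianceComponentsResults":
        bp = block_partition(self.values, self.blocks)
        lh = heritability(bp.residuals, self.lines)
        return VarianceComponentsResults(self, bp, lh)


@dataclass
class VarianceComponentsResults:
    """One trait's Table-2/3-style row of variance components."""

    model: VarianceComponents
    block: BlockPartition
    line: LineHeritability

    @property
    def pct_block(self) -> float:
        return self.block.pct_block

    @property
    def H2(self) -> float:
        return self.line.H2

    @property
    def trait_mean(self) -> float:
        return self.model.raw_mean

    def line_means(self) -> pd.Series:
        """Per-line means of the block residuals (adjusted line means)."""
        df = pd.DataFrame({"line": self.model.lines,
                           "resid": self.block.residuals})
        return df.groupby("line")["resid"].mean()

    def as_row(self) -> dict:
        return {
            "trait": self.model.trait,
            "pct_block": self.pct_block,
            "F_B": self.block.F,
            "P_B": self.block.P,
            "H2_pct": 100.0 * self.H2,
            "F_L": self.line.F,
            "P_L": self.line.P,
            "mean": self.trait_mean,
        }

    def summary(self) -> str:
        r = self.as_row()
        lines = [
            f"Variance decomposition: {r['trait']}",
            "=" * 44,
            f"  %B (block)      {r['pct_block']:10.3f}",
            f"  F_B             {r['F_B']:10.3f}   P_B {r['P_B']:.4g}",
            f"  H2 (%)          {r['H2_pct']:10.3f}",
            f"  F_L             {r['F_L']:10.3f}   P_L {r['P_L']:.4g}",
            f"  trait mean      {r['mean']:10.4f}",
            f"  sigma2_L        {self.line.sigma2_line:10.5g}",
            f"  sigma2_e        {self.line.sigma2_error:10.5g}",
            f"  n0              {self.line.n0:10.3f}",
        ]
        return "\n".join(lines)


def decompose_trait(df: pd.DataFrame, trait: str, line: str = "line",
                    block: str = "block",
                    arcsin: bool = False) -> VarianceComponentsResults:
    """Convenience: fit a VarianceComponents model for one trait column."""
    return VarianceComponents.from_dataframe(
        df, trait, line=line, block=block, arcsin=arcsin
    ).fit()


def decompose_table(
    df: pd.DataFrame,
    traits: list[str],
    line: str = "line",
    block: str = "block",
    arcsin: bool = False,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Variance decomposition for many traits; one output row per trait.

    When ``n_tests`` is given, a ``sig`` column stars traits with
    P_L below the Bonferroni critical value alpha/n_tests.
    """
    rows = [decompose_trait(df, t, line=line, block=block,
                            arcsin=arcsin).as_row() for t in traits]
    out = pd.DataFrame(rows).set_index("trait")
    if n_tests is not None:
        crit = bonferroni(alpha, n_tests)
        out["sig"] = np.where(out["P_L"] < crit, "*", "")
    return out


def bonferroni(alpha: float, n_tests: int) -> float:
    """Bonferroni critical P value alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def line_mean_correlation(trait_a: pd.Series, trait_b: pd.Series):
    """Pearson correlation of two per-line trait means on shared lines.

    Returns (r, P, n) where P is the two-sided t-test P value.
    """
    shared = trait_a.index.intersection(trait_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared lines")
    r, p = stats.pearsonr(trait_a.loc[shared], trait_b.loc[shared])
    return float(r), float(p), len(shared)


def copulation_duration_means(
    events: pd.DataFrame,
    min_duration: float = 5.0,
    line: str = "line",
    duration: str = "duration",
) -> pd.DataFrame:
    """Per-line mean copulation duration after a minimum-duration filter.

    Copulations shorter than ``min_duration`` minutes (default 5) are
    discarded as likely pseudo-copulations before averaging. Lines left
    with no surviving events are dropped with a warning. Returns a frame
    indexed by line with columns mean and n.
    """
    if (events[duration] < 0).any():
        raise ValueError("durations must be nonnegative")
    kept = events[events[duration] >= min_duration]
    empty = set(events[line]) - set(kept[line])
    if empty:
        warnings.warn(
            f"{len(empty)} line(s) with no copulations >= "
            f"{min_duration} min excluded: {sorted(empty)}"
        )
    g = kept.groupby(line)[duration]
    return pd.DataFrame({"mean": g.mean(), "n": g.size()})
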