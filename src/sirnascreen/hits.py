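"""Replicate aggregation, one-sided testing against siNC, and hit calling.

A gene is a hit in a screen when its mean normalized log2 fold change falls
below a readout-specific threshold AND a one-sided two-sample Student t-test
against the siNC wells of the gene's own plate is significant in the decrease
direction. Default thresholds: p < 0.01 with log2fc < -1 for cell and sphere
counts and log2fc < -0.6 for total viability; an all-readouts-at-minus-1
preset is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .simulate import NEGATIVE_CONTROL, POSITIVE_CONTROL

__all__ = [
    "HitThresholds",
    "pooled_t_pvalue",
    "one_sided_t_test",
    "call_hits",
    "hit_rate",
    "percentage",
    "spearman_correlation",
    "common_hits",
]

CONTROL_LABELS = (NEGATIVE_CONTROL, POSITIVE_CONTROL)


@dataclass(frozen=True)
class HitThresholds:
    """Fold-change and significance cutoffs for hit calling.

    ``fc_thresholds`` are on the log2 scale and must be negative (hits are
    decreases); ``p_threshold`` applies to the one-sided decrease test.
    """

    p_threshold: float = 0.01
    fc_thresholds: dict[str, float] = field(
        default_factory=lambda: {"count2d": -1.0, "sphere3d": -1.0, "viability2d": -0.6}
    )

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if any(v >= 0 for v in self.fc_thresholds.values()):
            raise ConfigError("fold-change thresholds must be negative (log2 scale)")

    @classmethod
    def twofold_all(cls) -> "HitThresholds":
        """>2-fold decrease (log2fc < -1) for every readout."""
        return cls(fc_thresholds={"count2d": -1.0, "sphere3d": -1.0, "viability2d": -1.0})

    def fc_threshold(self, readout: str) -> float:
        try:
            return self.fc_thresholds[readout]
        except KeyError:
            raise ConfigError(f"no fold-change threshold configured for readout {readout!r}")


def pooled_t_pvalue(
    sample: np.ndarray,
    control: np.ndarray,
    alternative: str = "less",
    welch: bool = False,
) -> float:
    """One-sided two-sample t-test p-value (sample vs control).

    Pooled-variance Student t by default; Welch optional. ``alternative``
    "less" tests for a decrease (lower tail), "greater" for an increase.
    Degenerate zero-variance groups resolve by mean comparison (equal means
    give p = 0.5). Fewer than 2 values in either group yields NaN with a
    warning.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"alternative must be 'less' or 'greater', got {alternative!r}")
    x = np.asarray(sample, dtype=float)
    y = np.asarray(control, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        warnings.warn(f"t-test needs >= 2 values per group (got {n1} vs {n2})", stacklevel=2)
        return float("nan")
    diff = x.mean() - y.mean()
    if welch:
        v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1)) if se > 0 else n1 + n2 - 2
    else:
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    if se == 0:
        t = 0.0 if diff == 0 else np.copysign(np.inf, diff)
    else:
        t = diff / se
    return float(stats.t.cdf(t, df) if alternative == "less" else stats.t.sf(t, df))


#: Alias matching the operation's name in the analysis workflow.
one_sided_t_test = pooled_t_pvalue


def _pooled_t_pvalues_vectorized(
    means: np.ndarray,
    variances: np.ndarray,
    sizes: np.ndarray,
    control: np.ndarray,
    welch: bool = False,
    alternative: str = "less",
) -> np.ndarray:
    """Lower-tail t p-values for many genes against one control pool.

    Same conventions as :func:`pooled_t_pvalue`; NaN where a gene has < 2
    replicates.
    """
    n2 = control.size
    cmean = control.mean()
    cvar = control.var(ddof=1) if n2 >= 2 else np.nan
    valid = (sizes >= 2) & (n2 >= 2)
    diff = means - cmean
    var1 = np.where(valid, variances, np.nan)
    n1 = sizes.astype(float)
    if welch:
        v1, v2 = var1 / n1, cvar / n2
        se = np.sqrt(v1 + v2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        df = np.where(se > 0, df, n1 + n2 - 2)
    else:
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * cvar) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where((se == 0) & (diff == 0), 0.0, t)
        t = np.where((se == 0) & (diff != 0), np.sign(diff) * np.inf, t)
    p = stats.t.cdf(t, df) if alternative == "less" else stats.t.sf(t, df)
    return np.where(valid, p, np.nan)


def call_hits(
    norm: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    welch: bool = False,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Aggregate replicates per gene and flag hits, per (cell_line, readout).

    The control pool for each gene's test is the pooled siNC log2fc values of
    the gene's own plate (all replicates). Returns a result table sorted by
    log2fc_mean ascending within each screen. With ``bh_correct`` the
    Benjamini-Hochberg adjusted p-value is used for flagging (and reported in
    ``p_adjusted``).
    """
    thresholds = thresholds or HitThresholds()
    results = []
    for (line, readout), screen in norm.groupby(["cell_line", "readout"], sort=False):
        fc_cut = thresholds.fc_threshold(readout)
        tables = []
        for plate, group in screen.groupby("plate", sort=False):
            ctrl = group.loc[group["gene_id"] == NEGATIVE_CONTROL, "log2fc"].to_numpy()
            genes = group[~group["gene_id"].isin(CONTROL_LABELS)]
            agg = genes.groupby("gene_id", sort=False)["log2fc"].agg(
                log2fc_mean="mean", log2fc_sd=lambda v: v.std(ddof=1), n_replicates="size"
            )
            n1 = agg["n_replicates"].to_numpy(dtype=float)
            n2 = float(ctrl.size)
            if (n1 < 2).any() or n2 < 2:
                warnings.warn(
                    f"{line}/{readout}, plate {plate}: groups with < 2 replicates "
                    "yield no p-value",
                    stacklevel=2,
                )
            p = _pooled_t_pvalues_vectorized(
                agg["log2fc_mean"].to_numpy(),
                agg["log2fc_sd"].to_numpy() ** 2,
                n1,
                ctrl,
                welch=welch,
            )
            agg = agg.reset_index()
            agg.insert(0, "cell_line", line)
            agg.insert(1, "readout", readout)
            agg["n_replicates"] = agg["n_replicates"].astype(int)
            agg["p_value"] = p
            tables.append(agg)
        table = pd.concat(tables, ignore_index=True)
        pvals = table["p_value"]
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            mask = pvals.notna()
            adjusted = pvals.copy()
            if mask.any():
                adjusted[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
            table["p_adjusted"] = adjusted
            pvals = adjusted
        table["hit_flag"] = (pvals < thresholds.p_threshold) & (
            table["log2fc_mean"] < fc_cut
        )
        table = table.sort_values("log2fc_mean", kind="mergesort", ignore_index=True)
        results.append(table)
    return pd.concat(results, ignore_index=True)


def percentage(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


def hit_rate(n_hits: int, n_library: int, decimals: int = 2) -> float:
    """Hit rate as a percentage of the library, rounded half-up."""
    if not 0 <= n_hits <= n_library:
        raise ValueError(f"n_hits must be in [0, n_library], got {n_hits}/{n_library}")
    return percentage(n_hits, n_library, decimals=decimals)


def spearman_correlation(screen_a: pd.Series, screen_b: pd.Series) -> float:
    """Spearman rank correlation over genes present in both screens.

    Ties receive average ranks. Returns NaN when fewer than 3 genes are
    shared.
    """
    a = pd.Series(screen_a).dropna()
    b = pd.Series(screen_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        warnings.warn(f"only {len(shared)} shared genes; Spearman undefined", stacklevel=2)
        return float("nan")
    return float(stats.spearmanr(a.loc[shared], b.loc[shared]).statistic)


def _hit_set(hits: pd.DataFrame | set) -> set:
    if isinstance(hits, pd.DataFrame):
        return set(hits.loc[hits["hit_flag"], "gene_id"])
    return set(hits)


def common_hits(hits_a: pd.DataFrame | set, hits_b: pd.DataFrame | set) -> tuple[set, int]:
    """Genes flagged as hits in both screens, with their count."""
    shared = _hit_set(hits_a) & _hit_set(hits_b)
    return shared, len(shared)
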