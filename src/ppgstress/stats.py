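"""Mass-univariate nonparametric screening with family-wise correction.

Every feature cell (feature x filtering status x derivative order) is
compared between the rest condition and each exercise stage with the
two-sided Wilcoxon-Mann-Whitney rank-sum test; the per-cell summary is the
arithmetic mean of the three p-values. Family-wise error is controlled with
the Holm-Bonferroni step-down procedure, which is uniformly at least as
powerful as plain Bonferroni at the same level.

The Mann-Whitney p-value uses exact enumeration when the combined sample
size is at most 12 and there are no ties, and the tie-corrected normal
approximation with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .features import FEATURES, STATUSES

__all__ = ["mann_whitney_p", "holm_bonferroni", "screen_features",
           "ScreeningResult", "EXACT_MAX_N"]

#: Combined-sample-size cutover from exact enumeration to the normal
#: approximation.
EXACT_MAX_N = 12

STAGE_PAIRS = (("BE", "E1"), ("BE", "E2"), ("BE", "E3"))


def mann_whitney_p(x, y, *, paired: bool = False) -> float:
    """Two-sided rank-test p-value for two samples.

    The default is the unpaired Wilcoxon-Mann-Whitney rank-sum test;
    ``paired=True`` runs the Wilcoxon signed-rank test on subject-matched
    pairs instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples contain non-finite values")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        if np.all(d == 0):
            return 1.0
        return float(sstats.wilcoxon(x, y, alternative="two-sided").pvalue)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                            use_continuity=True).pvalue
    return float(min(1.0, p))


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down correction.

    Returns
    -------
    reject : bool ndarray
        Rejection flags at family-wise level ``alpha``.
    p_adjusted : ndarray
        Step-down adjusted p-values (monotone, capped at 1).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.asarray([], dtype=bool), np.asarray([])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


@dataclass
class ScreeningResult:
    """Per-cell p-value grid with Holm flags.

    ``table`` has one row per (feature, status, order) with columns
    ``p1``/``p2``/``p3`` (rest vs each stage), ``p_mean``, per-stage
    ``sig1``/``sig2``/``sig3`` (uncorrected p <= alpha),
    ``holm1``/``holm2``/``holm3`` (significant after correction) and
    ``best_in_block`` marking the minimum-p_mean order of each
    (feature, status) block.
    """

    table: pd.DataFrame
    alpha: float
    family_size: int

    def to_wide_csv(self, path: str | Path) -> None:
        """Write a wide per-order grid (rows = orders, blocks = feature x status)."""
        wide = self.table.pivot_table(
            index="order", columns=["feature", "status"],
            values=["p1", "p2", "p3", "p_mean"], sort=False)
        wide.to_csv(path)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def screen_features(table: pd.DataFrame, *, alpha: float = 0.05,
                    family: str | int = "all",
                    paired: bool = False) -> ScreeningResult:
    """Screen every feature cell across conditions.

    Parameters
    ----------
    table : DataFrame
        Tidy feature table (``subject_id``, ``condition``, ``feature``,
        ``status``, ``order``, ``value``).
    alpha : float
        Family-wise significance level.
    family : "all" or int
        Multiplicity family for Holm. ``"all"`` corrects across every test
        computed in the run (2 x 2 x 21 orders x 3 comparisons = 252 for
        the full grid); an integer restricts the family to derivative
        orders >= 1 until the requested count is reached (240 excludes
        order 0).
    paired : bool
        Use the Wilcoxon signed-rank test on subject-matched pairs.
    """
    conditions = set(table["condition"].unique())
    if "BE" not in conditions:
        raise ValueError("feature table is missing the BE condition")
    stages = [b for _, b in STAGE_PAIRS if b in conditions]
    if not stages:
        raise ValueError("feature table has no exercise condition (E1/E2/E3)")

    pivot = table.pivot_table(index=["feature", "status", "order"],
                              columns=["condition", "subject_id"],
                              values="value", sort=False)
    rows = []
    for key, row in pivot.iterrows():
        feature, status, order = key
        be = row["BE"].to_numpy()
        ps = {}
        for stage in stages:
            stress = row[stage].to_numpy()
            ps[stage] = mann_whitney_p(be, stress, paired=paired)
        entry = {"feature": feature, "status": status, "order": order}
        for i, (_, stage) in enumerate(STAGE_PAIRS, start=1):
            entry[f"p{i}"] = ps.get(stage, np.nan)
        entry["p_mean"] = float(np.mean(list(ps.values())))
        rows.append(entry)
    out = pd.DataFrame(rows)

    # multiplicity family
    pcols = [f"p{i}" for i, (_, stage) in enumerate(STAGE_PAIRS, start=1)
             if stage in stages]
    long = out.melt(id_vars=["feature", "status", "order"], value_vars=pcols,
                    var_name="comparison", value_name="p").dropna(subset=["p"])
    if family == "all":
        in_family = np.ones(len(long), dtype=bool)
    else:
        m = int(family)
        mask_order = (long["order"] >= 1).to_numpy()
        if mask_order.sum() != m:
            raise ValueError(
                f"requested family size {m} does not match the "
                f"{int(mask_order.sum())} order>=1 tests computed")
        in_family = mask_order
    reject = np.zeros(len(long), dtype=bool)
    if in_family.any():
        rej, _ = holm_bonferroni(long.loc[in_family, "p"].to_numpy(), alpha)
        reject[np.flatnonzero(in_family)] = rej
    long["holm"] = reject
    long["sig"] = long["p"] <= alpha

    for i, pcol in enumerate(pcols, start=1):
        sub = long[long["comparison"] == pcol].set_index(
            ["feature", "status", "order"])
        out[f"sig{i}"] = sub["sig"].reindex(
            out.set_index(["feature", "status", "order"]).index).to_numpy()
        out[f"holm{i}"] = sub["holm"].reindex(
            out.set_index(["feature", "status", "order"]).index).to_numpy()

    # flag the lowest mean-p order within each feature x status block
    out["best_in_block"] = False
    for (feature, status), grp in out.groupby(["feature", "status"], sort=False):
        best = grp["p_mean"].idxmin()
        out.loc[best, "best_in_block"] = True

    return ScreeningResult(table=out, alpha=alpha,
                           family_size=int(in_family.sum()))
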