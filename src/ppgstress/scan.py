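"""Derivative-order scan: the model object orchestrating the full analysis.

:class:`HeatStressScan` is built from a :class:`~ppgstress.cohort.CohortDataset`
and ``fit()`` runs the whole study at desk scale:

1. extract the energy/entropy grid over derivative orders 0..20 for the
   unfiltered and band-passed signal of every recording;
2. compute per-recording HRV (peak detection + RMSSD);
3. screen every cell with Mann-Whitney + Holm-Bonferroni;
4. LOOCV-benchmark every cell with the four classifiers, per comparison
   (rest vs each exercise stage), giving the OA grid;
5. locate the optimal cell per feature block and globally;
6. evaluate the combined two-dimensional QDA detector: the filtered
   seventh-derivative entropy together with RMSSD (both the fixed cell and
   the data-selected optimal cell are reported).

The returned :class:`ScanResults` carries all intermediate tables, a
``summary()`` text report and CSV writers.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import (CLASSIFIER_NAMES, ClassifierReport, evaluate_feature,
                       overall_accuracy)
from .cohort import CohortDataset, STRESS_CONDITIONS
from .features import compute_feature_table
from .hrv import compute_hrv_table
from .preprocess import FilterSpec
from .stats import ScreeningResult, screen_features

__all__ = ["HeatStressScan", "ScanResults", "run_scan", "run_combined"]

#: The fixed combined-detector cell: entropy of the filtered 7th derivative.
DEFAULT_COMBINED_CELL = ("entropy", "filtered", 7)


@dataclass
class ScanResults:
    """Fitted results of a :class:`HeatStressScan`."""

    feature_table: pd.DataFrame
    hrv_table: pd.DataFrame
    screening: ScreeningResult
    oa_grid: pd.DataFrame
    optimal_cells: pd.DataFrame
    combined: dict
    config: dict = field(default_factory=dict)

    # ------------------------------------------------------------- accessors

    @property
    def optimal_cell(self) -> tuple[str, str, int]:
        """Globally best (feature, status, order) by mean OA."""
        row = self.optimal_cells.loc[self.optimal_cells["oa_mean"].idxmax()]
        return (row["feature"], row["status"], int(row["order"]))

    @property
    def optimal_oa(self) -> float:
        return float(self.optimal_cells["oa_mean"].max())

    def oa_of(self, feature: str, status: str, order: int) -> float:
        g = self.oa_grid
        sel = g[(g["feature"] == feature) & (g["status"] == status)
                & (g["order"] == order)]
        if sel.empty:
            raise KeyError((feature, status, order))
        return float(sel["OA"].mean())

    # --------------------------------------------------------------- output

    def summary(self) -> str:
        lines = []
        med = self.hrv_table.groupby("condition", sort=False).median(numeric_only=True)
        lines.append("Derivative-order heat-stress scan")
        lines.append("=" * 50)
        n_sub = self.feature_table["subject_id"].nunique()
        lines.append(f"Cohort: {n_sub} subjects, conditions "
                     f"{list(self.hrv_table['condition'].unique())}")
        lines.append("")
        lines.append("Cohort-median HRV per condition:")
        for cond, row in med.iterrows():
            lines.append(f"  {cond}:  HR {row['mean_hr_bpm']:6.1f} bpm   "
                         f"RMSSD {row['rmssd_ms']:6.1f} ms")
        lines.append("")
        lines.append(f"Screening: {self.screening.family_size} tests in the "
                     f"Holm family (alpha={self.screening.alpha})")
        nrej = int(self.screening.table[[c for c in self.screening.table
                                         if c.startswith("holm")]].to_numpy().sum())
        lines.append(f"  tests significant after Holm correction: {nrej}")
        lines.append("")
        lines.append("Optimal cell per feature block (mean OA over comparisons):")
        for _, row in self.optimal_cells.iterrows():
            lines.append(f"  {row['feature']:8s} {row['status']:10s} "
                         f"order {int(row['order']):2d}   OA {row['oa_mean']:5.1f}%")
        f, s, o = self.optimal_cell
        lines.append(f"Global optimum: {f}/{s} order {o}  (OA {self.optimal_oa:.1f}%)")
        lines.append("")
        cmb = self.combined
        lines.append(f"Combined QDA detector ({cmb['cell']} + RMSSD):")
        for comp, rep in cmb["reports"].items():
            r = rep.table.loc["qda"]
            lines.append(f"  BE vs {comp}:  SE {r['SE']:5.1f}%  PP {r['PP']:5.1f}%  "
                         f"F1 {r['F1']:5.1f}%")
        lines.append(f"  mean F1 combined: {cmb['mean_f1']:.1f}%  | "
                     f"entropy alone: {cmb['mean_f1_feature_only']:.1f}%  | "
                     f"RMSSD alone: {cmb['mean_f1_rmssd_only']:.1f}%")
        if cmb["n_excluded"]:
            lines.append(f"  recordings excluded (no valid RMSSD): {cmb['n_excluded']}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write table2.csv (p grid), table3.csv (OA grid), combined.csv and
        a manifest.json with the run configuration."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.screening.to_csv(outdir / "table2.csv")
        wide = self.oa_grid.pivot_table(index="order",
                                        columns=["feature", "status", "comparison"],
                                        values="OA", sort=False)
        wide.to_csv(outdir / "table3.csv")
        rows = []
        for comp, rep in self.combined["reports"].items():
            t = rep.table.reset_index()
            t.insert(0, "comparison", comp)
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(outdir / "combined.csv", index=False)
        self.hrv_table.to_csv(outdir / "hrv.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.config, fh, indent=2, default=str)


class HeatStressScan:
    """Model object for the whole-recording derivative-order analysis.

    Parameters
    ----------
    dataset : CohortDataset
        Paired rest / heat-stress recordings.
    filter_spec : FilterSpec, optional
        Band-pass used both for the "filtered" feature branch and for peak
        detection (default 0.5--7 Hz order-2 Butterworth, causal).
    max_order : int
        Highest derivative order scanned (default 20).
    alpha : float
        Family-wise level of the Holm-corrected screening.
    family : "all" or int
        Multiplicity family for Holm (see :func:`ppgstress.stats.screen_features`).
    classifiers : sequence of str
        Classifier subset for the OA grid.
    combined_cell : (feature, status, order)
        Cell paired with RMSSD in the combined QDA detector.
    """

    def __init__(self, dataset: CohortDataset, *,
                 filter_spec: FilterSpec | None = None,
                 max_order: int = 20,
                 alpha: float = 0.05,
                 family: str | int = "all",
                 classifiers: Sequence[str] = CLASSIFIER_NAMES,
                 combined_cell: tuple[str, str, int] = DEFAULT_COMBINED_CELL):
        if not dataset.by_condition("BE"):
            raise ValueError("dataset has no BE (rest) recordings")
        if not any(dataset.by_condition(c) for c in STRESS_CONDITIONS):
            raise ValueError("dataset has no exercise-stage recordings")
        self.dataset = dataset
        self.filter_spec = filter_spec or FilterSpec()
        self.max_order = max_order
        self.alpha = alpha
        self.family = family
        self.classifiers = tuple(classifiers)
        feat, status, order = combined_cell
        # clamp to the scanned range so shallow scans still report a detector
        self.combined_cell = (feat, status, min(order, max_order))

    # ------------------------------------------------------------------ fit

    def fit(self, verbose: bool = False) -> ScanResults:
        t0 = time.time()
        stages = [c for c in STRESS_CONDITIONS if self.dataset.by_condition(c)]

        features = compute_feature_table(self.dataset,
                                         filter_spec=self.filter_spec,
                                         max_order=self.max_order)
        if verbose:
            print(f"[scan] features        {time.time() - t0:6.1f}s", flush=True)
        hrv = compute_hrv_table(self.dataset, filter_spec=self.filter_spec)
        screening = screen_features(features, alpha=self.alpha, family=self.family)
        if verbose:
            print(f"[scan] screening       {time.time() - t0:6.1f}s", flush=True)

        oa_grid = self._oa_grid(features, stages)
        if verbose:
            print(f"[scan] OA grid         {time.time() - t0:6.1f}s", flush=True)

        optimal = (oa_grid.groupby(["feature", "status", "order"], sort=False)
                   ["OA"].mean().reset_index().rename(columns={"OA": "oa_mean"}))
        optimal = (optimal.sort_values("oa_mean", ascending=False)
                   .groupby(["feature", "status"], sort=False).head(1)
                   .reset_index(drop=True))

        combined = self._combined(features, hrv, stages)
        if verbose:
            print(f"[scan] combined        {time.time() - t0:6.1f}s", flush=True)

        config = {"filter": {"low": self.filter_spec.low,
                             "high": self.filter_spec.high,
                             "order": self.filter_spec.order,
                             "mode": self.filter_spec.mode},
                  "max_order": self.max_order, "alpha": self.alpha,
                  "family": self.family, "classifiers": list(self.classifiers),
                  "combined_cell": list(self.combined_cell),
                  "cohort": self.dataset.config}
        return ScanResults(feature_table=features, hrv_table=hrv,
                           screening=screening, oa_grid=oa_grid,
                           optimal_cells=optimal, combined=combined,
                           config=config)

    # ------------------------------------------------------------- internals

    def _oa_grid(self, features: pd.DataFrame, stages: list[str]) -> pd.DataFrame:
        pivot = features.pivot_table(index=["feature", "status", "order"],
                                     columns=["condition", "subject_id"],
                                     values="value", sort=False)
        rows = []
        for key, row in pivot.iterrows():
            feature, status, order = key
            be = row["BE"].to_numpy()
            for stage in stages:
                stress = row[stage].to_numpy()
                X = np.concatenate([be, stress])
                y = np.array(["before"] * len(be) + ["after"] * len(stress),
                             dtype=object)
                rep = evaluate_feature(X, y, self.classifiers)
                entry = {"feature": feature, "status": status, "order": order,
                         "comparison": stage}
                for name in self.classifiers:
                    entry[f"F1_{name}"] = rep.table.loc[name, "F1"]
                entry["OA"] = rep.oa
                rows.append(entry)
        return pd.DataFrame(rows)

    def _combined(self, features: pd.DataFrame, hrv: pd.DataFrame,
                  stages: list[str]) -> dict:
        feat, status, order = self.combined_cell
        cell = features[(features["feature"] == feat)
                        & (features["status"] == status)
                        & (features["order"] == order)]
        merged = cell.merge(hrv[["subject_id", "condition", "rmssd_ms"]],
                            on=["subject_id", "condition"])
        n_total = len(merged)
        valid = merged.dropna(subset=["rmssd_ms"])
        n_excluded = n_total - len(valid)
        if n_excluded > 0.2 * n_total:
            raise RuntimeError(
                f"{n_excluded}/{n_total} recordings lack a valid RMSSD; "
                "cohort too noisy for the combined detector")

        reports, rep_feat, rep_rmssd = {}, {}, {}
        for stage in stages:
            sub = valid[valid["condition"].isin(["BE", stage])]
            y = np.where(sub["condition"] == "BE", "before", "after").astype(object)
            X2 = sub[["value", "rmssd_ms"]].to_numpy()
            reports[stage] = evaluate_feature(X2, y, ["qda"])
            rep_feat[stage] = evaluate_feature(sub[["value"]].to_numpy(), y, ["qda"])
            rep_rmssd[stage] = evaluate_feature(sub[["rmssd_ms"]].to_numpy(), y, ["qda"])

        def _mean_f1(reps: dict) -> float:
            return overall_accuracy([r.table.loc["qda", "F1"] for r in reps.values()])

        return {"cell": self.combined_cell,
                "reports": reports,
                "mean_f1": _mean_f1(reports),
                "mean_f1_feature_only": _mean_f1(rep_feat),
                "mean_f1_rmssd_only": _mean_f1(rep_rmssd),
                "n_excluded": n_excluded}


def run_scan(dataset: CohortDataset, **kwargs) -> ScanResults:
    """Functional wrapper: build a :class:`HeatStressScan` and fit it."""
    return HeatStressScan(dataset, **kwargs).fit()


def run_combined(dataset: CohortDataset, **kwargs) -> dict:
    """Evaluate only the combined (feature + RMSSD) QDA detector."""
    model = HeatStressScan(dataset, **kwargs)
    stages = [c for c in STRESS_CONDITIONS if dataset.by_condition(c)]
    features = compute_feature_table(dataset, filter_spec=model.filter_spec,
                                     max_order=max(model.combined_cell[2],
                                                   model.max_order))
    hrv = compute_hrv_table(dataset, filter_spec=model.filter_spec)
    return model._combined(features, hrv, stages)
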