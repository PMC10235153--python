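"""Decision-tree classification of tonotopic expression patterns.

:class:`PatternAnalysis` is the model object: it is built from an aggregated
measurements DataFrame (one relative intensity per section x ROI, as produced
by :func:`ishpattern.quantify.aggregate_measurements`) and an
:class:`~ishpattern.stats.AnalysisParams`.  ``fit()`` runs the decision tree:

1. Unpaired t-test of rostral (per-section mean of RM, RL) against caudal
   (mean of CM, CL).  Not significant -> **homogeneous**, stop.  Significant
   -> **differential**, direction from the sign of the mean difference.
2. On the differential branch, test MM vs MC and MC vs ML on the middle
   plane.  Both significant with the same sign -> **gradient**; MM vs MC
   significant and MC vs ML not -> **selective**; anything else (including
   two significant tests of opposite sign, which is not a monotone change)
   stays plain **differential**.

The result object carries the pattern call, the underlying test results, a
``summary()`` table and a bar-chart ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .patterns import CATEGORIES, DIRECTIONS, ML_DIRECTIONS
from .stats import AnalysisParams, TestResult, build_groups, ttest_unpaired

__all__ = ["PatternCall", "PatternAnalysis", "PatternResults", "classify_pattern"]


@dataclass(frozen=True)
class PatternCall:
    """Decision-tree output with its evidence.

    ``evidence`` maps comparison names to :class:`TestResult`; the middle-plane
    entries are absent when the tree stopped at the homogeneous branch (the
    tree does not run them).
    """

    category: str
    direction: str
    medial_lateral_direction: str
    evidence: Mapping[str, TestResult]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.medial_lateral_direction not in ML_DIRECTIONS:
            raise ValueError(
                f"invalid medial_lateral_direction {self.medial_lateral_direction!r}"
            )


def _holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


class PatternAnalysis:
    """Model: classify one gene's spatial expression pattern from ROI intensities.

    Parameters
    ----------
    data
        Aggregated measurements with columns
        ``gene, section_id, plane, roi_name, value`` (one row per
        section x ROI; ``value`` is the replicate-averaged relative intensity).
    params
        Testing parameters; defaults to :class:`AnalysisParams()`.
    """

    def __init__(self, data: pd.DataFrame, params: AnalysisParams | None = None):
        required = {"section_id", "plane", "roi_name", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns: {sorted(missing)}")
        self.data = data
        self.params = params if params is not None else AnalysisParams()
        genes = sorted(set(data["gene"])) if "gene" in data.columns else []
        if len(genes) > 1:
            raise ValueError(
                f"data contains multiple genes {genes}; fit one model per gene"
            )
        self.gene = genes[0] if genes else ""

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, params: AnalysisParams | None = None
    ) -> "PatternAnalysis":
        return cls(data, params)

    @classmethod
    def from_measurements(
        cls, records: pd.DataFrame, params: AnalysisParams | None = None
    ) -> "PatternAnalysis":
        """Build from per-replicate records, aggregating replicates first."""
        from .quantify import aggregate_measurements

        return cls(aggregate_measurements(records), params)

    def fit(self) -> "PatternResults":
        """Run the decision tree and return the results object."""
        p = self.params
        rostral, caudal = build_groups(self.data, "rostral_vs_caudal")
        step1 = ttest_unpaired(rostral, caudal, p, label_a="rostral", label_b="caudal")
        evidence: dict[str, TestResult] = {"rostral_vs_caudal": step1}

        middle_tests: dict[str, TestResult] = {}
        if step1.significant or p.holm:
            for comparison in ("MM_vs_MC", "MC_vs_ML"):
                a, b = build_groups(self.data, comparison)
                la, lb = comparison.split("_vs_")
                middle_tests[comparison] = ttest_unpaired(a, b, p, label_a=la, label_b=lb)

        if p.holm:
            tests = {"rostral_vs_caudal": step1, **middle_tests}
            names = list(tests)
            adjusted = _holm_adjust([tests[n].p_value for n in names])
            for name, adj in zip(names, adjusted):
                t = tests[name]
                tests[name] = TestResult(
                    t.group_a, t.group_b, t.n_a, t.n_b, t.mean_a, t.mean_b,
                    t.t_statistic, t.degrees_of_freedom, adj, bool(adj < p.alpha),
                )
            step1 = tests["rostral_vs_caudal"]
            middle_tests = {k: tests[k] for k in middle_tests}
            evidence["rostral_vs_caudal"] = step1

        if not step1.significant:
            call = PatternCall("homogeneous", "none", "none", evidence)
            return PatternResults(self, call)

        evidence.update(middle_tests)
        direction = "rostral_high" if step1.mean_diff > 0 else "caudal_high"
        mm_mc = middle_tests["MM_vs_MC"]
        mc_ml = middle_tests["MC_vs_ML"]

        if (
            mm_mc.significant
            and mc_ml.significant
            and np.sign(mm_mc.mean_diff) == np.sign(mc_ml.mean_diff)
        ):
            ml_dir = "medial_high" if mm_mc.mean_diff > 0 else "lateral_high"
            call = PatternCall("gradient", direction, ml_dir, evidence)
        elif mm_mc.significant and not mc_ml.significant:
            ml_dir = "medial_high" if mm_mc.mean_diff > 0 else "lateral_high"
            call = PatternCall("selective", direction, ml_dir, evidence)
        else:
            call = PatternCall("differential", direction, "none", evidence)
        return PatternResults(self, call)


class PatternResults:
    """Fitted decision tree: the pattern call plus its test evidence."""

    def __init__(self, model: PatternAnalysis, call: PatternCall):
        self.model = model
        self.call = call

    @property
    def category(self) -> str:
        return self.call.category

    @property
    def direction(self) -> str:
        return self.call.direction

    @property
    def medial_lateral_direction(self) -> str:
        return self.call.medial_lateral_direction

    @property
    def tests(self) -> Mapping[str, TestResult]:
        return self.call.evidence

    def to_frame(self) -> pd.DataFrame:
        """One row per comparison, with the call attached to every row."""
        rows = []
        for name, t in self.call.evidence.items():
            rows.append(
                {
                    "gene": self.model.gene,
                    "comparison": name,
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "n_a": t.n_a,
                    "n_b": t.n_b,
                    "mean_a": t.mean_a,
                    "mean_b": t.mean_b,
                    "mean_diff": t.mean_diff,
                    "t_statistic": t.t_statistic,
                    "degrees_of_freedom": t.degrees_of_freedom,
                    "p_value": t.p_value,
                    "significant": t.significant,
                    "category": self.call.category,
                    "direction": self.call.direction,
                    "medial_lateral_direction": self.call.medial_lateral_direction,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the call and its evidence."""
        p = self.model.params
        lines = [
            "Tonotopic expression pattern analysis",
            "=" * 53,
            f"Gene:                 {self.model.gene or '(unnamed)'}",
            f"Test:                 unpaired t ({p.test_variant}), two-sided, "
            f"alpha = {p.alpha:g}",
            f"Normalization:        {p.normalization}",
            "-" * 53,
            f"Pattern:              {self.call.category}",
            f"Rostro-caudal:        {self.call.direction}",
            f"Medial-lateral:       {self.call.medial_lateral_direction}",
            "-" * 53,
        ]
        for name, t in self.call.evidence.items():
            lines.append(f"{name}:")
            lines.append(f"  {t}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of group means with SEM, star-annotated per comparison."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        agg = self.model.data
        groups: list[tuple[str, np.ndarray]] = []
        rostral, caudal = build_groups(agg, "rostral_vs_caudal")
        groups += [("rostral\n(RM+RL)/2", rostral), ("caudal\n(CM+CL)/2", caudal)]
        for roi in ("MM", "MC", "ML"):
            vals = agg.loc[
                (agg["plane"] == "middle") & (agg["roi_name"] == roi), "value"
            ].to_numpy()
            groups.append((roi, vals))
        xs = np.arange(len(groups))
        means = [g.mean() for _, g in groups]
        sems = [g.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0 for _, g in groups]
        ax.bar(xs, means, yerr=sems, capsize=4, color="#6688bb")
        ax.set_xticks(xs)
        ax.set_xticklabels([n for n, _ in groups])
        ax.set_ylabel("relative intensity")
        title = f"{self.model.gene}: {self.call.category}"
        if self.call.direction != "none":
            title += f" ({self.call.direction})"
        ax.set_title(title)
        return ax


def classify_pattern(records: pd.DataFrame, params: AnalysisParams | None = None) -> PatternCall:
    """Classify aggregated measurements; functional wrapper around the model.

    ``records`` may be per-replicate (a ``replicate`` column present, in which
    case replicates are averaged first) or already aggregated.
    """
    if "replicate" in records.columns:
        model = PatternAnalysis.from_measurements(records, params)
    else:
        model = PatternAnalysis(records, params)
    return model.fit().call
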