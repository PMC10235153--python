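"""Unpaired two-sample t-tests and the group constructions used for pattern calling.

Two comparisons drive the classification: rostral vs caudal (per-section
averages of the two rostral and the two caudal ROIs) and the middle-plane
pairwise comparisons MM vs MC and MC vs ML.  Tests are two-sided unpaired t
(Student pooled-variance by default, Welch optional) with strict p < alpha
significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnalysisParams",
    "TestResult",
    "ttest_unpaired",
    "build_groups",
    "COMPARISONS",
]

COMPARISONS = ("rostral_vs_caudal", "MM_vs_MC", "MC_vs_ML")


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the measurement + testing pipeline.

    Parameters
    ----------
    alpha
        Significance level; p-values strictly below it are significant.
    test_variant
        ``"student"`` (pooled variance, df = n_a + n_b - 2) or ``"welch"``.
    tails
        Only ``"two-sided"`` is supported.
    normalization
        ``"ratio"`` (ROI mean / reference mean) or ``"subtract"``.
    jitter_px
        Maximum replicate re-placement offset in pixels.
    n_replicates
        Replicate measurements per ROI, 2-4.
    n_mc
        Default Monte-Carlo repetition count for calibration utilities.
    holm
        Apply a Holm correction across the three tests of one gene.  Off by
        default: the study design runs the three tests uncorrected.
    """

    alpha: float = 0.05
    test_variant: str = "student"
    tails: str = "two-sided"
    normalization: str = "ratio"
    jitter_px: int = 2
    n_replicates: int = 3
    n_mc: int = 200
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.test_variant not in ("student", "welch"):
            raise ValueError(f"test_variant must be 'student' or 'welch', got {self.test_variant!r}")
        if self.tails != "two-sided":
            raise ValueError("only two-sided tests are supported")
        if self.normalization not in ("ratio", "subtract"):
            raise ValueError(f"normalization must be 'ratio' or 'subtract', got {self.normalization!r}")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if not 2 <= self.n_replicates <= 4:
            raise ValueError(f"n_replicates must be in [2, 4], got {self.n_replicates}")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """One unpaired two-sample comparison."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool

    @property
    def mean_diff(self) -> float:
        return self.mean_a - self.mean_b

    def __str__(self) -> str:  # compact one-line report
        star = "*" if self.significant else "ns"
        return (
            f"{self.group_a} (n={self.n_a}, mean={self.mean_a:.4f}) vs "
            f"{self.group_b} (n={self.n_b}, mean={self.mean_b:.4f}): "
            f"t={self.t_statistic:.4f}, df={self.degrees_of_freedom:.4g}, "
            f"p={self.p_value:.4g} [{star}]"
        )


def ttest_unpaired(
    a,
    b,
    params: AnalysisParams | None = None,
    *,
    label_a: str = "a",
    label_b: str = "b",
) -> TestResult:
    """Two-sided unpaired t-test between two samples of relative intensities.

    Student's pooled-variance variant is the default; Welch is selected via
    ``params.test_variant``.  Two identical constant samples are not an error:
    they yield t = 0, p = 1 by convention (no evidence of a difference).
    """
    if params is None:
        params = AnalysisParams()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need n >= 2 in both groups, got n_a={a.size}, n_b={b.size}")

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            t, p = 0.0, 1.0
            df = float(a.size + b.size - 2)
        else:
            raise ValueError(
                "both samples are constant with different values; the t statistic "
                "is undefined (zero variance in both groups)"
            )
    else:
        res = sps.ttest_ind(a, b, equal_var=(params.test_variant == "student"))
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)

    return TestResult(
        group_a=label_a,
        group_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significant=bool(p < params.alpha),
    )


def _section_values(agg: pd.DataFrame, plane: str, roi: str) -> pd.Series:
    sub = agg[(agg["plane"] == plane) & (agg["roi_name"] == roi)]
    return sub.set_index("section_id")["value"]


def build_groups(agg: pd.DataFrame, comparison: str) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the two samples of one named comparison.

    ``rostral_vs_caudal``: one value per rostral section (mean of its RM and
    RL relative intensities) against one value per caudal section (mean of CM
    and CL).  ``MM_vs_MC`` / ``MC_vs_ML``: one value per middle section per ROI.
    """
    if comparison == "rostral_vs_caudal":
        pairs = (("rostral", ("RM", "RL")), ("caudal", ("CM", "CL")))
        samples = []
        for plane, rois in pairs:
            per_roi = {}
            for roi in rois:
                vals = _section_values(agg, plane, roi)
                if vals.empty:
                    raise ValueError(f"no {roi} measurements on any {plane} section")
                per_roi[roi] = vals
            frame = pd.DataFrame(per_roi)
            if frame.isna().any().any():
                bad = frame[frame.isna().any(axis=1)]
                sec = bad.index[0]
                roi = frame.columns[bad.iloc[0].isna()][0]
                raise ValueError(f"section {sec!r} is missing ROI {roi!r}")
            samples.append(frame.mean(axis=1).to_numpy())
        return samples[0], samples[1]

    if comparison in ("MM_vs_MC", "MC_vs_ML"):
        roi_a, roi_b = comparison.split("_vs_")
        out = []
        for roi in (roi_a, roi_b):
            vals = _section_values(agg, "middle", roi)
            if vals.empty:
                raise ValueError(f"no {roi} measurements on any middle section")
            out.append(vals.sort_index())
        a, b = out
        missing_a = set(b.index) - set(a.index)
        missing_b = set(a.index) - set(b.index)
        if missing_a or missing_b:
            sec, roi = (
                (sorted(missing_a)[0], roi_a) if missing_a else (sorted(missing_b)[0], roi_b)
            )
            raise ValueError(f"section {sec!r} is missing ROI {roi!r}")
        return a.to_numpy(), b.to_numpy()

    raise ValueError(f"unknown comparison {comparison!r}; expected one of {COMPARISONS}")
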