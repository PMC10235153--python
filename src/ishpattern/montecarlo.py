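"""Monte-Carlo calibration and pattern-recovery harnesses.

These utilities repeatedly run the full pipeline (generate -> measure ->
classify) on fresh seeded synthetic datasets to (a) calibrate the type-I
error of the homogeneous/differential decision at step 1 of the tree and
(b) estimate how reliably each preset's generating pattern is recovered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .model import PatternCall, classify_pattern
from .patterns import CATEGORIES, pattern_from_levels
from .quantify import measure_dataset
from .stats import AnalysisParams
from .synthetic import PRESETS, SyntheticConfig, generate_dataset, make_preset

__all__ = [
    "run_pipeline_once",
    "expected_call",
    "estimate_type1_error",
    "Type1Estimate",
    "pattern_recovery_matrix",
    "preset_recovery_rate",
]


def run_pipeline_once(config: SyntheticConfig, params: AnalysisParams) -> PatternCall:
    """Generate one dataset, measure it and classify; fully seeded by the config."""
    ds = generate_dataset(config)
    # measurement jitter gets its own substream, decoupled from rendering
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 997)))
    records = measure_dataset(ds.images, ds.roi_table, params, rng)
    return classify_pattern(records, params)


def expected_call(preset: str) -> tuple[str, str]:
    """(category, rostro-caudal direction) implied by a preset's level table."""
    category, direction, _ = pattern_from_levels(dict(PRESETS[preset]))
    return category, direction


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31)


@dataclass(frozen=True)
class Type1Estimate:
    """Estimated false-positive proportion with a Wilson 95% interval."""

    proportion: float
    ci_low: float
    ci_high: float
    n_mc: int
    n_false_positive: int


def estimate_type1_error(
    null_config: SyntheticConfig,
    params: AnalysisParams | None = None,
    n_mc: int | None = None,
    seed: int = 0,
) -> Type1Estimate:
    """Fraction of homogeneous datasets called non-homogeneous at step 1.

    Each repetition generates a fresh dataset from ``null_config`` (with a
    derived per-repetition seed), runs the full measurement pipeline, and
    counts a false positive whenever the classifier leaves the homogeneous
    branch.  Under a nominal alpha this fraction should sit near alpha.
    """
    if params is None:
        params = AnalysisParams()
    if n_mc is None:
        n_mc = params.n_mc
    category, _, _ = pattern_from_levels(dict(null_config.roi_levels))
    if category != "homogeneous":
        raise ValueError(
            f"null_config generates a {category!r} pattern; type-I calibration "
            "requires a homogeneous configuration"
        )
    if n_mc < 100:
        warnings.warn(
            f"n_mc={n_mc} gives a wide binomial interval; use >= 100 repetitions",
            stacklevel=2,
        )
    hits = 0
    for child in _spawn_seeds(seed, n_mc):
        call = run_pipeline_once(replace(null_config, seed=int(child)), params)
        hits += call.category != "homogeneous"
    lo, hi = proportion_confint(hits, n_mc, alpha=0.05, method="wilson")
    return Type1Estimate(hits / n_mc, float(lo), float(hi), n_mc, hits)


def pattern_recovery_matrix(
    presets: Sequence[str],
    params: AnalysisParams | None = None,
    n_mc: int = 200,
    seed: int = 0,
    **config_overrides,
) -> pd.DataFrame:
    """Counts of called categories per preset (rows sum to ``n_mc``).

    Rows are presets (each row's generating pattern is its level table's
    noiseless classification); columns are the four callable categories.
    """
    if params is None:
        params = AnalysisParams()
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    counts = pd.DataFrame(
        0, index=list(presets), columns=list(CATEGORIES), dtype=int
    )
    for p_idx, preset in enumerate(presets):
        for child in _spawn_seeds(seed + 7919 * p_idx, n_mc):
            config = make_preset(preset, seed=int(child), **config_overrides)
            call = run_pipeline_once(config, params)
            counts.loc[preset, call.category] += 1
    counts.index.name = "preset"
    return counts


def preset_recovery_rate(
    preset: str,
    params: AnalysisParams | None = None,
    n_mc: int = 200,
    seed: int = 0,
    **config_overrides,
) -> float:
    """Fraction of runs recovering the preset's category AND direction."""
    if params is None:
        params = AnalysisParams()
    want_category, want_direction = expected_call(preset)
    hits = 0
    for child in _spawn_seeds(seed, n_mc):
        config = make_preset(preset, seed=int(child), **config_overrides)
        call = run_pipeline_once(config, params)
        hits += call.category == want_category and call.direction == want_direction
    return hits / n_mc
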