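"""Control-vs-metastasis group comparison: mean ± SEM, two-sample
t-test, percent change.

The unit of replication is one 3D measurement (one Z-stack), matching a
design with several measurements per group (e.g., six control and five
metastasis stacks over n = 5 animals per group) — not one animal, and not
one pixel.  For each compartment (upper = endothelium, lower = media,
all = entire measured volume) and each measure (I_lipid, I_protein,
ratio) the two conditions are compared with a two-sided two-sample
t-test; a difference is significant when p < α (default 0.05).  Welch's
variant is the default (robust to unequal variance at n ≈ 5–6);
Student's pooled-variance variant is available by flag.  No
multiple-testing correction is applied across the nine comparisons by
default; a Bonferroni flag is provided.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError

__all__ = ["summarize", "t_test", "compare_conditions", "MEASURES", "COMPARTMENTS"]

log = logging.getLogger(__name__)

MEASURES = ("I_lipid", "I_protein", "ratio")
COMPARTMENTS = ("upper", "lower", "all")


def summarize(values: Sequence[float] | np.ndarray) -> tuple[float, float | None, int]:
    """Arithmetic mean, SEM, and n of one group of measurements.

    SEM is the n−1 sample standard deviation divided by √n; it is
    undefined (returned as ``None``) for a single measurement.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ConfigError("summarize needs at least one value")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None, 1
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem, int(arr.size)


def t_test(
    group_a: Sequence[float] | np.ndarray,
    group_b: Sequence[float] | np.ndarray,
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    Degenerate zero-variance inputs follow the conventions: both groups
    constant with equal means → (0, 1); constant with unequal means →
    (±inf, 0), logged as degenerate.
    """
    if variant not in ("welch", "student"):
        raise ConfigError(f"unknown t-test variant {variant!r}; valid: welch, student")
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("t_test needs at least 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        log.warning(
            "t_test: zero variance in both groups with unequal means; p -> 0 convention"
        )
        return math.copysign(math.inf, b.mean() - a.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(t), float(p)


def compare_conditions(
    control: pd.DataFrame,
    metastasis: pd.DataFrame,
    alpha: float = 0.05,
    variant: str = "welch",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-compartment, per-measure comparison of two condition tables.

    Each input is a per-measurement compartment table (one row per stack ×
    compartment, columns ``stack_id, compartment, I_lipid, I_protein,
    ratio`` as produced by the depth profiler).  Returns nine rows
    (3 compartments × 3 measures) with group means, SEMs, n, t, p,
    percent change 100 × (mean_met − mean_ctrl)/mean_ctrl, and the
    significance verdict at α.
    """
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    d_ctrl = control.attrs.get("dialect")
    d_met = metastasis.attrs.get("dialect")
    if d_ctrl is not None and d_met is not None and d_ctrl != d_met:
        raise ConfigError(
            f"dialect mismatch between conditions: control={d_ctrl!r}, metastasis={d_met!r}"
        )
    for name, table in (("control", control), ("metastasis", metastasis)):
        missing = {"compartment", *MEASURES} - set(table.columns)
        if missing:
            raise DataError(f"{name} table is missing columns {sorted(missing)}")
        if table.groupby("compartment").size().min() < 2 or len(table) == 0:
            raise ConfigError(f"{name} condition needs >= 2 measurements per compartment")

    n_tests = len(COMPARTMENTS) * len(MEASURES)
    rows = []
    for comp in COMPARTMENTS:
        a_rows = control[control["compartment"] == comp]
        b_rows = metastasis[metastasis["compartment"] == comp]
        if a_rows.empty or b_rows.empty:
            raise DataError(f"compartment {comp!r} missing from one condition table")
        for measure in MEASURES:
            a = a_rows[measure].to_numpy(dtype=float)
            b = b_rows[measure].to_numpy(dtype=float)
            mean_a, sem_a, n_a = summarize(a)
            mean_b, sem_b, n_b = summarize(b)
            t, p = t_test(a, b, variant=variant)
            p_eff = min(1.0, p * n_tests) if bonferroni else p
            pct = 100.0 * (mean_b - mean_a) / mean_a if mean_a != 0 else math.nan
            rows.append(
                {
                    "compartment": comp,
                    "measure": measure,
                    "mean_control": mean_a,
                    "sem_control": sem_a,
                    "n_control": n_a,
                    "mean_metastasis": mean_b,
                    "sem_metastasis": sem_b,
                    "n_metastasis": n_b,
                    "t_statistic": t,
                    "p_value": p_eff,
                    "percent_change": pct,
                    "significant": bool(p_eff < alpha),
                }
            )
    result = pd.DataFrame(rows)
    result.attrs["alpha"] = alpha
    result.attrs["variant"] = variant
    result.attrs["bonferroni"] = bonferroni
    return result
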