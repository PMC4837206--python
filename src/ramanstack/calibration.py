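"""Simulation harnesses: batched phantom measurement, planted-effect
recovery, and null-hypothesis calibration of the group comparison.

These helpers run the exact same generator and per-spectrum preprocessing
as the stack-at-a-time pipeline, but batch the preprocessing across many
small phantom stacks so that large replicate counts (e.g., a 10,000-rep
type-I error simulation) stay cheap.  ``batch_compartment_measures``
agrees exactly with ``preprocess_stack`` + ``profile_stack`` run per
stack, which is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as sps

from .errors import ConfigError
from .phantom import PhantomConfig, generate_stack
from .preprocess import PreprocessConfig, baseline_correct_batch, despike_batch, vector_normalize_batch
from .profile import (
    DEFAULT_N_UPPER,
    DEFAULT_SIGNAL_FRACTION_THRESHOLD,
    _integrate,
    dialect_windows,
)

__all__ = [
    "derive_seeds",
    "batch_compartment_measures",
    "null_type_i_error",
    "recover_percent_changes",
]


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds (< 2^31) from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return (state & 0x7FFFFFFF).astype(np.int64)


def _compartment_means(values: np.ndarray, labels: list[str]) -> dict[str, float]:
    upper = [k for k, lab in enumerate(labels) if lab == "upper"]
    lower = [k for k, lab in enumerate(labels) if lab == "lower"]
    retained = upper + lower
    return {
        "upper": float(values[upper].mean()),
        "lower": float(values[lower].mean()),
        "all": float(values[retained].mean()),
    }


def batch_compartment_measures(
    config: PhantomConfig,
    condition: str,
    seeds: np.ndarray,
    preprocess: PreprocessConfig | None = None,
    n_upper: int = DEFAULT_N_UPPER,
    signal_fraction_threshold: float = DEFAULT_SIGNAL_FRACTION_THRESHOLD,
    chunk: int = 256,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-stack compartment measures for many phantom seeds.

    Generates one phantom stack per entry of ``seeds``, preprocesses all
    pixel spectra in batches, and returns
    ``result[measure][compartment]`` → array over stacks, where measure ∈
    {I_lipid, I_protein, ratio} and compartment ∈ {upper, lower, all}.
    """
    if preprocess is None:
        preprocess = PreprocessConfig(dialect=config.dialect)
    windows = dialect_windows(config.dialect)
    axis = None
    out: dict[str, dict[str, list[float]]] = {
        m: {c: [] for c in ("upper", "lower", "all")}
        for m in ("I_lipid", "I_protein", "ratio")
    }
    seeds = np.asarray(seeds)
    for start in range(0, seeds.size, chunk):
        batch_seeds = seeds[start : start + chunk]
        stacks = []
        for s in batch_seeds:
            cfg = replace(config, seed=int(s), record_clean=False)
            stack, _ = generate_stack(cfg, condition)
            stacks.append(stack)
        axis = stacks[0].axis
        n_planes = stacks[0].n_planes
        h, w = stacks[0].planes[0].shape
        n_px = h * w
        data = np.stack([s.data() for s in stacks])  # (S, P, H, W, C)
        flat = data.reshape(-1, axis.size)
        flat, _ = despike_batch(
            flat,
            threshold=preprocess.despike_threshold,
            window=preprocess.despike_window,
            rel_floor=preprocess.despike_rel_floor,
        )
        flat, _ = baseline_correct_batch(flat, axis, method=preprocess.baseline_method)
        flat, _ = vector_normalize_batch(flat, axis, preprocess.normalization_region)
        # average spectrum per (stack, plane), then integrate both windows
        avg = flat.reshape(len(stacks), n_planes, n_px, axis.size).mean(axis=2)
        lo_l, hi_l = windows["lipid_CH"].window
        lo_p, hi_p = windows["protein_phe"].window
        i_lipid = _integrate(axis, avg, lo_l, hi_l)  # (S, P)
        i_protein = _integrate(axis, avg, lo_p, hi_p)
        ratio = i_lipid / i_protein

        for s_idx, stack in enumerate(stacks):
            totals = stack.plane_totals()
            z0 = int(np.argmax(totals))
            cutoff = signal_fraction_threshold * totals[z0]
            labels = ["excluded" if t < cutoff else "lower" for t in totals]
            retained = [k for k, lab in enumerate(labels) if lab != "excluded"]
            if n_upper >= len(retained):
                raise ConfigError(
                    f"n_upper={n_upper} must be less than retained planes ({len(retained)})"
                )
            for k in retained[-n_upper:]:
                labels[k] = "upper"
            for name, values in (
                ("I_lipid", i_lipid[s_idx]),
                ("I_protein", i_protein[s_idx]),
                ("ratio", ratio[s_idx]),
            ):
                means = _compartment_means(values, labels)
                for comp, v in means.items():
                    out[name][comp].append(v)
    return {
        m: {c: np.asarray(v) for c, v in comps.items()} for m, comps in out.items()
    }


def null_pvalues(
    config: PhantomConfig,
    n_control: int = 6,
    n_metastasis: int = 5,
    n_reps: int = 10_000,
    seed: int = 0,
    measure: str = "I_protein",
    compartment: str = "upper",
) -> dict[str, np.ndarray]:
    """Two-sample p-values under a null phantom simulation.

    Every measurement of every replicate is a control phantom (no planted
    effect); each replicate splits its measurements into pseudo-groups of
    ``n_control`` and ``n_metastasis`` stacks mirroring the study design
    and applies the two-sided t-test.  Returns the p-value array per test
    variant ("student", "welch") over ``n_reps`` replicates.  Under this
    design both groups share one variance, so the Student variant is the
    exactly calibrated reference; Welch is expected to be slightly
    conservative at these group sizes.
    """
    per_rep = n_control + n_metastasis
    seeds = derive_seeds(seed, n_reps * per_rep)
    measures = batch_compartment_measures(config, "control", seeds)
    values = measures[measure][compartment].reshape(n_reps, per_rep)
    a = values[:, :n_control]
    b = values[:, n_control:]
    out = {}
    for variant, equal_var in (("student", True), ("welch", False)):
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=equal_var)
        out[variant] = p
    return out


def null_type_i_error(
    config: PhantomConfig,
    n_control: int = 6,
    n_metastasis: int = 5,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    variant: str = "student",
) -> float:
    """Empirical type-I error (rejection rate at ``alpha``) under the null
    phantom simulation of :func:`null_pvalues`."""
    p = null_pvalues(config, n_control, n_metastasis, n_reps, seed)[variant]
    return float(np.mean(p < alpha))


def recover_percent_changes(
    config: PhantomConfig,
    n_pairs: int = 50,
    seed: int = 0,
    measure: str = "I_protein",
) -> dict[str, float]:
    """Mean estimated percent change per compartment over phantom pairs.

    Each pair is one control and one metastasis phantom sharing nothing
    but the configuration; the percent change is computed per pair as
    100 × (metastasis − control)/control of the compartment measure, then
    averaged over pairs.
    """
    seeds = derive_seeds(seed, 2 * n_pairs)
    ctrl = batch_compartment_measures(config, "control", seeds[:n_pairs])
    met = batch_compartment_measures(config, "metastasis", seeds[n_pairs:])
    out = {}
    for comp in ("upper", "lower", "all"):
        a = ctrl[measure][comp]
        b = met[measure][comp]
        out[comp] = float(np.mean(100.0 * (b - a) / a))
    return out
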