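"""Ensemble diagnostics against remote-sensing references.

Covers carbon-use efficiency (NPP/GPP), the down-regulated-NPP scenario
in which annual relative NPP increments are damped relative to GPP's,
multimodel bias statistics against a reference value, and
variance-explained diagnostics (squared Pearson correlation with a
seeded permutation p-value across models, or averaged across per-model
spatial fields).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ModelMember


def carbon_use_efficiency(member: ModelMember) -> pd.Series:
    """Year-indexed NPP/GPP ratio (dimensionless)."""
    gpp = member.data["gpp"]
    if (gpp <= 0).any():
        raise ValueError("GPP must be positive in every year")
    return member.data["npp"] / gpp


def downregulate_npp(
    gpp: pd.Series, npp_initial: float, damping: float = 0.5
) -> pd.Series:
    """Damped NPP trajectory tracking a fraction of GPP's relative growth.

    Each year the relative increment of the adjusted NPP is ``damping``
    times the concurrent relative increment of GPP:

        NPP'(t) = NPP'(t-1) * (1 + damping * (GPP(t)/GPP(t-1) - 1))

    anchored at ``npp_initial``. damping=1 keeps carbon-use efficiency
    constant; damping=0 freezes NPP. Year-over-year increments (rather
    than increments relative to a fixed baseline) keep the trajectory
    independent of how the window is split.
    """
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must be in [0, 1]")
    g = gpp.to_numpy(dtype=float)
    if np.any(g <= 0):
        raise ValueError("GPP must be positive")
    out = np.empty_like(g)
    out[0] = npp_initial
    for t in range(1, len(g)):
        out[t] = out[t - 1] * (1.0 + damping * (g[t] / g[t - 1] - 1.0))
    return pd.Series(out, index=gpp.index)


def ensemble_bias_stats(values, reference: float) -> dict:
    """Multimodel mean +/- sd (n-1) and percent bias against a reference."""
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 models for ensemble statistics")
    if reference == 0:
        raise ValueError("zero reference value")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return {
        "mean": mean,
        "sd": sd,
        "per_model": values,
        "reference": reference,
        "bias_percent": 100.0 * (mean - reference) / reference,
    }


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic ** 2)


def variance_explained(
    x,
    y,
    mode: str = "cross_model",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Squared Pearson correlation diagnostics.

    mode="cross_model": ``x`` and ``y`` are per-model scalars (e.g.
    vegetation-carbon change vs cumulative NBP); returns R^2 with a
    seeded permutation p-value (fraction of shuffles with R^2 at least
    as large).

    mode="within_model_spatial": ``x`` and ``y`` are sequences of
    per-cell arrays, one pair per model; returns the across-model mean
    and sd of per-model spatial R^2.
    """
    if mode == "cross_model":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3 or len(x) != len(y):
            raise ValueError("need >= 3 paired values")
        r2 = _r_squared(x, y)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            if _r_squared(x, rng.permutation(y)) >= r2 - 1e-15:
                count += 1
        # add-one correction keeps the permutation p-value off exact zero
        p = (count + 1) / (n_permutations + 1)
        return {"r2": r2, "p_value": p, "n": len(x), "mode": mode}
    if mode == "within_model_spatial":
        if len(x) != len(y) or len(x) == 0:
            raise ValueError("need one cell-array pair per model")
        r2s = np.array(
            [_r_squared(np.asarray(xi, float), np.asarray(yi, float)) for xi, yi in zip(x, y)]
        )
        return {
            "r2_mean": float(r2s.mean()),
            "r2_sd": float(r2s.std(ddof=1)) if len(r2s) > 1 else 0.0,
            "per_model_r2": r2s,
            "mode": mode,
        }
    raise ValueError(f"unknown mode {mode!r}")
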