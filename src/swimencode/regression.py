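"""Per-neuron encoding models and episode-level regressions.

The encoding model explains a neuron's ΔF/F as a linear combination of the
four motor regressors (iTBA, iTBA-rise, iTBF, iTBF-rise), fit by ordinary
least squares; a coefficient is significant when it is positive and its
circular-shift permutation p-value is below 0.05.  Also: maximum ΔF/F
against the natural log of the episode oscillation count, and plain Pearson
correlations of traces with regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .regressors import RegressorSet

__all__ = [
    "RegressionResult",
    "OscillationFit",
    "fit_encoding_model",
    "permutation_significance",
    "fit_log_oscillations",
    "pearson_correlate",
]


@dataclass
class RegressionResult:
    roi_id: int
    alphas: np.ndarray  # [alpha0 (intercept), alpha1..alpha4]
    r2: float
    p_perm: np.ndarray | None = None  # per slope coefficient (alpha1..alpha4)
    significant: np.ndarray | None = None
    n_permutations: int = 0
    seed: int | None = None
    coef_names: list[str] = field(
        default_factory=lambda: ["intercept", "itba", "itba_rise", "itbf", "itbf_rise"]
    )


@dataclass
class OscillationFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_episodes: int


def _design(regressor_set: RegressorSet | np.ndarray) -> np.ndarray:
    x = (
        regressor_set.design_matrix()
        if isinstance(regressor_set, RegressorSet)
        else np.asarray(regressor_set, dtype=float)
    )
    return np.column_stack([np.ones(x.shape[0]), x])


def fit_encoding_model(
    dff: np.ndarray,
    regressor_set: RegressorSet | np.ndarray,
    mask: np.ndarray | None = None,
    roi_id: int = 0,
) -> RegressionResult:
    """OLS fit of ΔF/F(t) = α0 + Σ αi·xi(t).

    ``mask`` marks artifact frames to drop from the fit.  Raises on a
    rank-deficient design, naming the most collinear regressor pair.
    """
    dff = np.asarray(dff, dtype=float)
    x = _design(regressor_set)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        x, dff = x[keep], dff[keep]
    n, p = x.shape
    if n < 5 * p:
        raise ValueError("need at least 5x more frames than parameters")
    if np.linalg.matrix_rank(x) < p:
        c = np.corrcoef(x[:, 1:].T)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        raise ValueError(f"rank-deficient design: regressors x{i + 1} and x{j + 1} are collinear")
    alphas, _, _, _ = np.linalg.lstsq(x, dff, rcond=None)
    resid = dff - x @ alphas
    tss = float(np.sum((dff - dff.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    return RegressionResult(roi_id=roi_id, alphas=alphas, r2=r2)


def permutation_significance(
    dff: np.ndarray,
    regressor_set: RegressorSet | np.ndarray,
    fit: RegressionResult,
    n_perm: int = 999,
    seed: int | None = None,
    tau_s: float = 1.5,
    rate_hz: float = 10.0,
    alpha_level: float = 0.05,
    mask: np.ndarray | None = None,
) -> RegressionResult:
    """One-sided circular-shift permutation test on the slope coefficients.

    The null preserves the autocorrelation of ΔF/F: the trace is circularly
    shifted by offsets drawn uniformly from [10·τ, T − 10·τ] (in frames) and
    refit; per coefficient, p = (1 + #{null αi ≥ observed αi}) / (1 + n_perm)
    and significance requires αi > 0 and p < ``alpha_level``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    dff = np.asarray(dff, dtype=float)
    x = _design(regressor_set)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        x, dff = x[keep], dff[keep]
    t = dff.size
    lo = int(np.ceil(10 * tau_s * rate_hz))
    hi = t - lo
    if hi <= lo:
        raise ValueError("trace shorter than 20*tau")
    rng = np.random.default_rng(seed)
    shifts = rng.integers(lo, hi, size=n_perm)
    pinv = np.linalg.pinv(x)
    observed = fit.alphas[1:]
    # null coefficients for all shifts at once: pinv @ shifted dff
    shifted = np.stack([np.roll(dff, int(s)) for s in shifts])  # (n_perm, T)
    null = shifted @ pinv.T  # (n_perm, p+1)
    exceed = (null[:, 1:] >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    fit.p_perm = p
    fit.significant = (observed > 0) & (p < alpha_level)
    fit.n_permutations = n_perm
    fit.seed = seed
    return fit


def fit_log_oscillations(
    max_dff: np.ndarray,
    n_oscillations: np.ndarray,
) -> OscillationFit:
    """Simple regression of episode max ΔF/F on ln(number of oscillations).

    The log transform tames the right-skewed oscillation-count distribution.
    """
    max_dff = np.asarray(max_dff, dtype=float)
    n_osc = np.asarray(n_oscillations, dtype=float)
    if max_dff.size < 3:
        raise ValueError("need at least 3 episodes")
    if np.any(n_osc < 1):
        raise ValueError("all oscillation counts must be >= 1")
    ln = np.log(n_osc)
    if np.ptp(ln) == 0:
        raise ValueError("zero variance in ln(n_oscillations)")
    res = stats.linregress(ln, max_dff)
    return OscillationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_episodes=int(max_dff.size),
    )


def pearson_correlate(
    traces: np.ndarray,
    regressor: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pearson r between each ROI trace (rows) and one regressor.

    Zero-variance traces yield NaN (undefined-marker) for downstream
    exclusion.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    regressor = np.asarray(regressor, dtype=float)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        traces, regressor = traces[:, keep], regressor[keep]
    if traces.shape[1] < 10:
        raise ValueError("need at least 10 frames")
    tz = traces - traces.mean(axis=1, keepdims=True)
    rz = regressor - regressor.mean()
    denom = np.sqrt((tz**2).sum(axis=1) * (rz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (tz @ rz) / denom
    r[denom == 0] = np.nan
    return r
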