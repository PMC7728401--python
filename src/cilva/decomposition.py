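"""Post-fit analyses: evoked/spontaneous trace components, variance
decomposition, drive ratios, private variability, factor contribution
indices, tuning curves, shuffle nulls and factor cross-correlograms.

The fitted model splits each neuron's reconstruction into a stimulus-locked
(evoked) and a latent-factor (spontaneous) component,

    f_evoked_n = alpha_n (k * w_n^T s) + beta_n,
    f_spont_n  = alpha_n (k * b_n^T x) + beta_n,

each carrying the baseline so that both align with the raw trace.  Their
sample variances and covariance satisfy the exact identity
var[f_hat] = var_e + var_s + 2 cov_es (the shared baseline cancels), and the
drive ratio d_n = (var_e - var_s) / (var_e + var_s) in [-1, 1] summarizes
whether a neuron is stimulus- or spontaneously dominated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    CilvaModel,
    FluorescenceMatrix,
    StimulusDesign,
    convolve_causal,
    reconstruct,
)

__all__ = [
    "Decomposition",
    "decompose",
    "decompose_traces",
    "variance_components",
    "drive_ratio",
    "corrected_variance_and_private",
    "factor_contribution_index",
    "averaged_tuning_curve",
    "model_tuning_curve",
    "shuffle_null",
    "factor_cross_correlogram",
]

# Neurons whose fit correlation is this close to zero are excluded from
# contribution indices (the index divides by corr(f, f_hat)).
_CORR_FLOOR = 1e-6


@dataclass
class Decomposition:
    """Per-neuron trace components and summary statistics of a fitted model."""

    f_evoked: np.ndarray
    f_spont: np.ndarray
    residual: np.ndarray
    var_evoked: np.ndarray
    var_spont: np.ndarray
    cov_es: np.ndarray
    drive_ratio: np.ndarray       # NaN where both variance components vanish
    var_corrected: np.ndarray
    private_var: np.ndarray
    private_negative: np.ndarray  # flag: noise estimate exceeded the shortfall
    contribution_index: np.ndarray


def decompose_traces(
    model: CilvaModel, S: StimulusDesign, F: FluorescenceMatrix | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Split the reconstruction into evoked and spontaneous trace components.

    Both components include the baseline beta_n, so
    f_evoked + f_spont - beta_n = f_hat.  The residual F - f_hat is returned
    when the raw traces are supplied.
    """
    k = model.kernel
    ev_int = model.W @ S.matrix
    f_evoked = model.alpha[:, None] * convolve_causal(k, ev_int) + model.beta[:, None]
    if model.n_factors:
        sp_int = model.B @ model.X
        f_spont = model.alpha[:, None] * convolve_causal(k, sp_int) + model.beta[:, None]
    else:
        f_spont = np.tile(model.beta[:, None], (1, S.n_frames))
    residual = None
    if F is not None:
        residual = F.values - (f_evoked + f_spont - model.beta[:, None])
    return f_evoked, f_spont, residual


def variance_components(
    f_evoked: np.ndarray, f_spont: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-neuron sample variances and covariance of the two components."""
    if f_evoked.shape[1] < 2:
        raise ValueError("need at least 2 frames for sample variances")
    ec = f_evoked - f_evoked.mean(axis=1, keepdims=True)
    sc = f_spont - f_spont.mean(axis=1, keepdims=True)
    T = f_evoked.shape[1]
    var_e = np.sum(ec**2, axis=1) / T
    var_s = np.sum(sc**2, axis=1) / T
    cov_es = np.sum(ec * sc, axis=1) / T
    return var_e, var_s, cov_es


def drive_ratio(var_e: np.ndarray, var_s: np.ndarray) -> np.ndarray:
    """d = (var_e - var_s) / (var_e + var_s), NaN where both vanish."""
    denom = var_e + var_s
    out = np.full_like(denom, np.nan, dtype=float)
    ok = denom > 0
    out[ok] = (var_e[ok] - var_s[ok]) / denom[ok]
    return out


def corrected_variance_and_private(
    F: FluorescenceMatrix, f_hat: np.ndarray, sigma2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-corrected raw variance and the private-variability upper bound.

    var_corrected = var[f_n] - sigma_n^2;  private = var_corrected - var[f_hat_n].
    Negative values are reported as-is — they diagnose noise-estimate error.
    """
    T = F.n_frames
    var_raw = F.values.var(axis=1)
    var_corrected = var_raw - np.asarray(sigma2)
    var_hat = f_hat.var(axis=1)
    return var_corrected, var_corrected - var_hat


def factor_contribution_index(
    F: FluorescenceMatrix, model: CilvaModel, S: StimulusDesign
) -> np.ndarray:
    """Mean proportional drop in fit correlation when one factor is deleted.

    index_l = 1 - mean_n corr(f_n, f_hat^(-l)_n) / corr(f_n, f_hat_n), where
    f_hat^(-l) is rebuilt with factor l's activity row and coupling column
    removed.  Neurons with |corr(f, f_hat)| below 1e-6 are excluded.
    """
    L = model.n_factors
    if L == 0:
        return np.zeros(0)
    f_hat = reconstruct(model, S)
    base_corr = _rowwise_corr(F.values, f_hat)
    keep = np.abs(base_corr) > _CORR_FLOOR
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} neuron(s) with near-zero fit correlation "
            "from contribution indices"
        )
    idx = np.empty(L)
    for l in range(L):
        sub = model.copy()
        sub.B = np.delete(sub.B, l, axis=1)
        sub.X = np.delete(sub.X, l, axis=0)
        corr_l = _rowwise_corr(F.values, reconstruct(sub, S))
        idx[l] = 1.0 - np.mean(corr_l[keep] / base_corr[keep])
    return idx


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = np.sum(Ac * Bc, axis=1)
    den = np.sqrt(np.sum(Ac**2, axis=1) * np.sum(Bc**2, axis=1))
    out = np.full(A.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def decompose(
    F: FluorescenceMatrix,
    model: CilvaModel,
    S: StimulusDesign,
    sigma2: np.ndarray | None = None,
) -> Decomposition:
    """Full post-fit decomposition with variance components and indices."""
    sigma2 = model.sigma2 if sigma2 is None else np.asarray(sigma2)
    f_evoked, f_spont, residual = decompose_traces(model, S, F)
    var_e, var_s, cov_es = variance_components(f_evoked, f_spont)
    d = drive_ratio(var_e, var_s)
    f_hat = f_evoked + f_spont - model.beta[:, None]
    var_corr, priv = corrected_variance_and_private(F, f_hat, sigma2)
    ci = factor_contribution_index(F, model, S)
    return Decomposition(
        f_evoked=f_evoked, f_spont=f_spont, residual=residual,
        var_evoked=var_e, var_spont=var_s, cov_es=cov_es, drive_ratio=d,
        var_corrected=var_corr, private_var=priv,
        private_negative=priv < 0, contribution_index=ci,
    )


def averaged_tuning_curve(
    F: FluorescenceMatrix, onsets: list[tuple[int, int]], n_stimuli: int
) -> np.ndarray:
    """Averaging-based tuning curves: mean dF/F over post-onset frames 4-7.

    ``onsets`` is a list of (frame, stimulus index) pairs.  For each
    presentation the mean of frames onset+4 .. onset+7 inclusive (four
    frames, counting post-onset frames 1-based) is taken, then averaged over
    presentations of the same stimulus.  Presentations whose window runs past
    the end of the recording are dropped with a warning; a stimulus left with
    no usable presentation gets a NaN column.
    """
    N, T = F.values.shape
    sums = np.zeros((N, n_stimuli))
    counts = np.zeros(n_stimuli)
    dropped = 0
    for frame, stim in onsets:
        if frame + 7 >= T:
            dropped += 1
            continue
        window = F.values[:, frame + 4 : frame + 8]
        sums[:, stim] += window.mean(axis=1)
        counts[stim] += 1
    if dropped:
        warnings.warn(f"dropped {dropped} onset(s) within 7 frames of the recording end")
    out = np.full((N, n_stimuli), np.nan)
    ok = counts > 0
    out[:, ok] = sums[:, ok] / counts[ok]
    if not ok.all():
        warnings.warn("stimuli with no usable presentation flagged as NaN columns")
    return out


def model_tuning_curve(model: CilvaModel) -> np.ndarray:
    """Model-based tuning curves k_max * alpha_n * w_n, on the scale of the
    calcium-transient amplitude evoked by each stimulus (comparable with the
    averaging-based curves despite the identifiability rescaling)."""
    return model.kernel.peak * model.alpha[:, None] * model.W


def onsets_from_design(S: StimulusDesign) -> list[tuple[int, int]]:
    """Extract (frame, stimulus) onset pairs from a binary design matrix."""
    frames, stims = np.nonzero(S.matrix.T)
    return list(zip(frames.tolist(), stims.tolist()))


def shuffle_null(
    trace_set: np.ndarray,
    n_shuffles: int,
    statistic,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Null distribution of a statistic under random cyclic trace shifts.

    Each shuffle cyclically permutes every row of ``trace_set`` by an
    independent uniform random offset (preserving each trace's temporal
    structure and its exact moments), then recomputes
    ``statistic(shuffled)``.  Returns the null values and their 95th
    percentile.  Deterministic given the seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be at least 1")
    rng = np.random.default_rng(seed)
    traces = np.atleast_2d(np.asarray(trace_set, dtype=float))
    Q, T = traces.shape
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        offsets = rng.integers(0, T, size=Q)
        shuffled = np.stack([np.roll(row, off) for row, off in zip(traces, offsets)])
        null[i] = statistic(shuffled)
    return null, float(np.percentile(null, 95))


def factor_cross_correlogram(X: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized cross-correlograms between latent factor time series.

    Returns an L x L x (2 max_lag + 1) array of the Pearson-normalized
    cross-correlation of mean-centered factors at lags -max_lag..max_lag;
    the diagonal at lag 0 equals 1.  Zero-variance factors yield NaN rows
    with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    L, T = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(Xc**2, axis=1))
    if np.any(norms == 0):
        warnings.warn("zero-variance factor(s): cross-correlogram rows are NaN")
    lags = np.arange(-max_lag, max_lag + 1)
    out = np.full((L, L, len(lags)), np.nan)
    for i in range(L):
        for j in range(L):
            if norms[i] == 0 or norms[j] == 0:
                continue
            full = np.correlate(Xc[j], Xc[i], mode="full")  # index T-1+lag: sum_t x_i(t) x_j(t+lag)
            sel = full[T - 1 + lags[0] : T + lags[-1]]
            out[i, j] = sel / (norms[i] * norms[j])
    return out
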