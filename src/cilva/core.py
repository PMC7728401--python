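"""Generative model for calcium-imaging fluorescence traces.

A neuron's observed fluorescence is modelled as an affine transform of its
calcium concentration plus i.i.d. Gaussian imaging noise,

    f_n(t) = alpha_n * c_n(t) + beta_n + eps_n(t),    eps_n(t) ~ N(0, sigma_n^2),

where the calcium concentration is the causal convolution of a
difference-of-exponentials indicator kernel with a non-negative intensity

    c_n(t) = sum_{tau<=t} k(t - tau) * lambda_n(tau),
    k(t)   = exp(-t / tau_d) - exp(-t / tau_r),
    lambda_n(t) = w_n . s(t) + b_n . x(t).

``s(t)`` is a binary 1-of-K stimulus indicator, ``w_n`` the neuron's stimulus
filter, ``x(t)`` the activity of L shared latent factors with an exponential
sparsity prior of mean ``gamma``, and ``b_n`` the neuron's factor couplings.
All parameters and latents are constrained non-negative.

This module houses the kernel, the convolution, the intensity and
reconstruction maps, the penalized log-joint density and its analytic
gradients.  Inference lives in :mod:`cilva.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "FluorescenceMatrix",
    "StimulusDesign",
    "CalciumKernel",
    "CilvaModel",
    "make_kernel",
    "convolve_causal",
    "intensity",
    "reconstruct",
    "log_joint",
    "gradients",
]

# Kernels shorter than this are convolved directly; longer ones via FFT.
_DIRECT_CONV_MAX_LEN = 64


@dataclass
class FluorescenceMatrix:
    """Observed dF/F traces, neurons as rows.

    Parameters
    ----------
    values : ndarray of shape (N, T)
        dF/F traces. Negative entries are permitted (imaging noise).
    fs : float
        Imaging rate in Hz.
    neuron_ids : sequence of str, optional
        Labels carried through to output tables.
    """

    values: np.ndarray
    fs: float
    neuron_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite fluorescence entry at (row {bad[0]}, col {bad[1]})"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("need at least 1 neuron and 2 frames")
        if not self.fs > 0:
            raise ValueError("imaging rate fs must be positive")
        if self.neuron_ids is not None and len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length does not match row count")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class StimulusDesign:
    """Binary K x T stimulus design matrix under a 1-of-K encoding.

    With ``shift_count > 0`` the design additionally contains time-shifted
    copies of each stimulus row (to model temporally extended responses), in
    which case more than one entry per column may be active.
    """

    matrix: np.ndarray
    stim_labels: list[str] | None = None
    shift_count: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        uniq = np.unique(self.matrix)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("stimulus design entries must be binary 0/1")
        if self.shift_count == 0 and np.any(self.matrix.sum(axis=0) > 1):
            raise ValueError("1-of-K design: at most one active stimulus per frame")
        if self.stim_labels is not None and len(self.stim_labels) != self.matrix.shape[0]:
            raise ValueError("stim_labels length does not match design rows")

    @property
    def n_stimuli(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def with_shifted_copies(self, shift_count: int) -> "StimulusDesign":
        """Expand K rows to K*(shift_count+1) rows shifted by 0..shift_count frames."""
        if shift_count < 0:
            raise ValueError("shift_count must be non-negative")
        K, T = self.matrix.shape
        rows = []
        labels = []
        for i in range(K):
            for s in range(shift_count + 1):
                row = np.zeros(T)
                row[s:] = self.matrix[i, : T - s] if s else self.matrix[i]
                rows.append(row)
                base = self.stim_labels[i] if self.stim_labels else str(i)
                labels.append(f"{base}+{s}" if s else base)
        return StimulusDesign(np.array(rows), stim_labels=labels, shift_count=shift_count)


@dataclass
class CalciumKernel:
    """Discretized difference-of-exponentials calcium impulse response.

    ``values[t] = exp(-t/tau_d) - exp(-t/tau_r)`` at integer frames, unnormalized,
    truncated where the tail falls below ``truncation_tol`` of the peak.
    Time constants are in frames.
    """

    tau_r: float
    tau_d: float
    values: np.ndarray
    truncation_tol: float = 1e-6

    @property
    def peak(self) -> float:
        return float(self.values.max())

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CilvaModel:
    """Full parameter set plus latent factor matrix.

    ``alpha`` (N,) scale, ``beta`` (N,) baseline, ``W`` (N, K) stimulus
    filters, ``B`` (N, L) factor couplings, ``X`` (L, T) factor activity,
    ``sigma2`` (N,) imaging-noise variances, ``gamma`` the exponential prior
    mean on latent activity.
    """

    alpha: np.ndarray
    beta: np.ndarray
    W: np.ndarray
    B: np.ndarray
    X: np.ndarray
    sigma2: np.ndarray
    gamma: float
    kernel: CalciumKernel
    fit_history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.B = np.asarray(self.B, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.B.ndim != 2:
            raise ValueError("B must be N x L and X must be L x T (use shape (N, 0) / (0, T) for L = 0)")
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        N = len(self.alpha)
        L = self.X.shape[0]
        if self.W.shape[0] != N or self.B.shape != (N, L) or len(self.beta) != N:
            raise ValueError("model dimensions are mutually inconsistent")
        for name, arr in (("alpha", self.alpha), ("beta", self.beta),
                          ("W", self.W), ("B", self.B), ("X", self.X)):
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be strictly positive")

    @property
    def n_neurons(self) -> int:
        return len(self.alpha)

    @property
    def n_factors(self) -> int:
        return self.X.shape[0]

    @property
    def n_frames(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "CilvaModel":
        return replace(
            self,
            alpha=self.alpha.copy(), beta=self.beta.copy(), W=self.W.copy(),
            B=self.B.copy(), X=self.X.copy(), sigma2=self.sigma2.copy(),
            fit_history=list(self.fit_history),
        )


def make_kernel(
    tau_r: float,
    tau_d: float,
    max_len: int = 10_000,
    truncation_tol: float = 1e-6,
) -> CalciumKernel:
    """Build the difference-of-exponentials kernel k(t) = e^{-t/tau_d} - e^{-t/tau_r}.

    Time constants are in frames and must satisfy ``0 < tau_r < tau_d`` so the
    kernel rises from ``k(0) = 0`` to a single peak and decays. The tail is
    truncated at the first post-peak frame where ``k(t)`` falls below
    ``truncation_tol`` times the peak (or at ``max_len`` frames).
    """
    if tau_r <= 0 or tau_d <= 0:
        raise ValueError("time constants must be positive")
    if tau_r >= tau_d:
        raise ValueError(f"require tau_r < tau_d, got tau_r={tau_r}, tau_d={tau_d}")
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    t = np.arange(max_len, dtype=float)
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    peak_idx = int(np.argmax(k))
    below = np.nonzero(k[peak_idx:] < truncation_tol * k[peak_idx])[0]
    if below.size:
        k = k[: peak_idx + below[0]]
    return CalciumKernel(tau_r=tau_r, tau_d=tau_d, values=k, truncation_tol=truncation_tol)


def kernel_from_rates(tau_r_s: float, tau_d_s: float, fs: float, **kw) -> CalciumKernel:
    """Convenience constructor taking time constants in seconds."""
    return make_kernel(tau_r_s * fs, tau_d_s * fs, **kw)


def default_kernel(fs: float, **kw) -> CalciumKernel:
    """GCaMP6s nuclear-indicator defaults: tau_r = 5.68/fs s, tau_d = 11.5/fs s,
    i.e. 5.68 and 11.5 frames at any imaging rate."""
    return make_kernel(5.68, 11.5, **kw)


def convolve_causal(kernel: CalciumKernel, intensity_rows: np.ndarray) -> np.ndarray:
    """Row-wise causal convolution with the calcium kernel, truncated to T frames.

    Output frame t depends only on intensity at frames <= t.  Direct
    convolution for short kernels, FFT-based above a length threshold.
    """
    arr = np.atleast_2d(np.asarray(intensity_rows, dtype=float))
    T = arr.shape[1]
    k = kernel.values
    if len(k) <= _DIRECT_CONV_MAX_LEN:
        out = np.empty_like(arr)
        for i, row in enumerate(arr):
            out[i] = np.convolve(row, k)[:T]
    else:
        out = fftconvolve(arr, k[None, :], axes=1)[:, :T]
    if intensity_rows.ndim == 1:
        return out[0]
    return out


def intensity(W: np.ndarray, S: StimulusDesign | np.ndarray, B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Neural intensity lambda_n(t) = w_n . s(t) + b_n . x(t), an N x T matrix."""
    Smat = S.matrix if isinstance(S, StimulusDesign) else np.atleast_2d(S)
    lam = W @ Smat
    if B.size and X.size:
        lam = lam + B @ X
    return lam


def reconstruct(model: CilvaModel, S: StimulusDesign) -> np.ndarray:
    """Model reconstruction f_hat_n = alpha_n (k * lambda_n) + beta_n."""
    lam = intensity(model.W, S, model.B, model.X)
    c = convolve_causal(model.kernel, lam)
    return model.alpha[:, None] * c + model.beta[:, None]


def _residuals(F: FluorescenceMatrix, model: CilvaModel, S: StimulusDesign) -> np.ndarray:
    return F.values - reconstruct(model, S)


def log_joint(F: FluorescenceMatrix, model: CilvaModel, S: StimulusDesign) -> float:
    """Penalized log-joint density ln p(f, x | theta, gamma).

    Gaussian log-likelihood of the residuals plus the exponential-prior log
    density of the latent factors.  The prior normalizer (-ln gamma per latent
    entry) is included so values are comparable across gamma during model
    selection; the Gaussian normalizers are likewise included.
    """
    E = _residuals(F, model, S)
    T = F.n_frames
    gauss = -0.5 * np.sum(E**2 / model.sigma2[:, None]) \
        - 0.5 * T * np.sum(np.log(2 * np.pi * model.sigma2))
    L = model.n_factors
    prior = -np.sum(model.X) / model.gamma - L * T * np.log(model.gamma)
    return float(gauss + prior)


def gradients(
    F: FluorescenceMatrix, model: CilvaModel, S: StimulusDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the penalized log-joint.

    Returns ``(g_alpha, g_beta, g_W, g_B, g_X)``.  With E_n(t) the residual
    and C_n = k * lambda_n:

        d/d beta_n  = (1/sigma_n^2) sum_t E_n(t)
        d/d alpha_n = (1/sigma_n^2) sum_t E_n(t) C_n(t)
        d/d w_ni    = (alpha_n/sigma_n^2) sum_t E_n(t) (k*s_i)(t)
        d/d b_nl    = (alpha_n/sigma_n^2) sum_t E_n(t) (k*x_l)(t)
        d/d x_l(tau)= sum_n (alpha_n/sigma_n^2) b_nl sum_{t>=tau} E_n(t) k(t-tau) - 1/gamma
    """
    k = model.kernel
    Smat = S.matrix
    CS = convolve_causal(k, Smat)
    CX = convolve_causal(k, model.X) if model.n_factors else np.zeros_like(model.X)
    C = model.W @ CS + (model.B @ CX if model.n_factors else 0.0)
    E = F.values - model.alpha[:, None] * C - model.beta[:, None]

    inv_s2 = 1.0 / model.sigma2
    scale = (model.alpha * inv_s2)[:, None]
    g_beta = inv_s2 * E.sum(axis=1)
    g_alpha = inv_s2 * np.sum(E * C, axis=1)
    g_W = (scale * E) @ CS.T
    if model.n_factors:
        g_B = (scale * E) @ CX.T
        g_X = model.B.T @ _correlate_with_kernel(scale * E, k) - 1.0 / model.gamma
    else:
        g_B = np.zeros_like(model.B)
        g_X = np.zeros_like(model.X)
    return g_alpha, g_beta, g_W, g_B, g_X


def _correlate_with_kernel(E: np.ndarray, kernel: CalciumKernel) -> np.ndarray:
    """Row-wise cross-correlation r(tau) = sum_{u>=0} k(u) E(tau + u)."""
    k = kernel.values
    Lk = len(k)
    full = fftconvolve(E, k[::-1][None, :], axes=1)
    return full[:, Lk - 1 : Lk - 1 + E.shape[1]]
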