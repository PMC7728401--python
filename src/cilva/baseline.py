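"""Two-stage residual-NMF decomposition, the comparison method.

Stage one regresses each trace onto kernel-convolved stimulus regressors by
non-negative least squares (NNLS), defining the evoked component.  Stage two
rectifies the residuals and factorizes them with rank-L non-negative matrix
factorization (NMF); the projection of the latent time courses back onto
each neuron is its spontaneous component.

Because the NMF stage knows nothing about calcium dynamics, its spontaneous
components need not look like calcium transients.  The
`calcium_basis_projection` diagnostic re-expresses a component in a basis of
shifted kernel impulse responses: a large normalized residual flags
atypical, non-calcium-like structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from sklearn.decomposition import NMF

from .core import CalciumKernel, FluorescenceMatrix, StimulusDesign, convolve_causal

__all__ = [
    "ResidualNmfResult",
    "build_stimulus_regressors",
    "nnls_evoked",
    "rectified_residuals",
    "nmf_spont",
    "calcium_basis_projection",
    "residual_nmf",
]


@dataclass
class ResidualNmfResult:
    """Output of the NNLS + residual-NMF pipeline."""

    beta_stim: np.ndarray  # N x K NNLS coefficients
    evoked: np.ndarray     # N x T
    residuals: np.ndarray  # N x T, rectified
    W_nmf: np.ndarray      # N x L
    H_nmf: np.ndarray      # L x T
    spont: np.ndarray      # N x T


def build_stimulus_regressors(S: StimulusDesign, kernel: CalciumKernel) -> np.ndarray:
    """Phi: row i is the kernel-convolved binary time series of stimulus i."""
    return convolve_causal(kernel, S.matrix)


def nnls_evoked(F: FluorescenceMatrix, Phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron NNLS of traces onto the stimulus regressors.

    Returns the N x K coefficient matrix and the evoked reconstruction
    beta^T Phi.  Near-collinear regressors trigger a warning but the NNLS
    solution remains well defined.
    """
    if np.any(np.linalg.norm(Phi, axis=1) == 0):
        raise ValueError("Phi contains an all-zero regressor row; prune it first")
    gram = np.corrcoef(Phi)
    off = np.abs(gram - np.eye(len(gram)))
    if off.size and off.max() > 0.999:
        warnings.warn("near-collinear stimulus regressors; NNLS coefficients may trade off")
    A = Phi.T
    beta = np.stack([nnls(A, f)[0] for f in F.values])
    return beta, beta @ Phi


def rectified_residuals(F: FluorescenceMatrix, evoked: np.ndarray) -> np.ndarray:
    """Elementwise max(0, F - evoked)."""
    if F.values.shape != evoked.shape:
        raise ValueError("shape mismatch between traces and evoked component")
    return np.maximum(0.0, F.values - evoked)


def nmf_spont(
    E: np.ndarray, L: int, seed: int = 0, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-L NMF of the rectified residuals, minimizing squared error.

    Deterministic non-negative double-SVD initialization (seeded fallback for
    ties), so identical inputs and seed reproduce the factorization exactly.
    Returns (W, H, spont = W @ H).
    """
    N, T = E.shape
    if not 1 <= L <= min(N, T):
        raise ValueError(f"L must be in [1, min(N, T)] = [1, {min(N, T)}]")
    if np.any(E < 0):
        raise ValueError("NMF input must be non-negative")
    if not E.any():
        W = np.zeros((N, L))
        H = np.zeros((L, T))
        return W, H, W @ H
    nmf = NMF(n_components=L, init="nndsvda", random_state=seed, max_iter=max_iter, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at tight max_iter
        W = nmf.fit_transform(E)
    H = nmf.components_
    return W, H, W @ H


def residual_nmf(
    F: FluorescenceMatrix,
    S: StimulusDesign,
    kernel: CalciumKernel,
    L: int,
    seed: int = 0,
    max_iter: int = 500,
) -> ResidualNmfResult:
    """Run the full NNLS + residual-NMF pipeline."""
    Phi = build_stimulus_regressors(S, kernel)
    keep = np.linalg.norm(Phi, axis=1) > 0
    beta = np.zeros((F.n_neurons, S.n_stimuli))
    beta[:, keep], evoked = nnls_evoked(F, Phi[keep])
    E = rectified_residuals(F, evoked)
    W, H, spont = nmf_spont(E, L, seed=seed, max_iter=max_iter)
    return ResidualNmfResult(
        beta_stim=beta, evoked=evoked, residuals=E, W_nmf=W, H_nmf=H, spont=spont
    )


def calcium_basis_projection(
    spont_trace: np.ndarray, kernel: CalciumKernel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Express a spontaneous component in a basis of shifted calcium impulses.

    The basis has one column per frame: psi_t is the kernel response to a
    unit impulse at frame t.  NNLS coefficients re-express the trace; the
    deviation metric ||trace - reconstruction|| / ||trace|| quantifies how
    far the component departs from calcium-transient structure (approx. 0
    for a genuine transient, large for e.g. square pulses).

    Returns (coefficients, reconstruction, deviation).
    """
    y = np.asarray(spont_trace, dtype=float).ravel()
    T = len(y)
    k = kernel.values
    # Psi[t] = kernel placed at frame t, truncated to T: banded lower-triangular design
    Psi = np.zeros((T, T))
    for t in range(T):
        m = min(len(k), T - t)
        Psi[t, t : t + m] = k[:m]
    coef, _ = nnls(Psi.T, y)
    recon = coef @ Psi
    ynorm = np.linalg.norm(y)
    deviation = float(np.linalg.norm(y - recon) / ynorm) if ynorm > 0 else 0.0
    return coef, recon, deviation
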