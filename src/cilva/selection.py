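"""Hyperparameter selection: sparsity gamma by held-out grid search, factor
count L by the elbow of the correlation-vs-L curve.

The recording's final ``test_seconds`` are held out.  For each candidate
(L, gamma) and random restart, the model is fit on the training segment;
fresh latents are then inferred on the test segment at the fitted parameters
and the held-out penalized log-joint ln p(f_test | x_test, theta) +
ln p(x_test | gamma) scored.  The configuration maximizing the held-out
score wins, and training latents are re-inferred under the winning
parameters.

L itself is user-guided: `correlation_vs_L` traces mean train/test fit
correlation against the factor count, and the elbow (the L beyond which the
mean correlation stops improving substantially) is the recommended choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CilvaModel, FluorescenceMatrix, StimulusDesign, log_joint, reconstruct
from .inference import FitConfig, fit, infer_latents
from .noise import estimate_noise_variance

__all__ = [
    "SelectionReport",
    "split_train_test",
    "select_hyperparams",
    "correlation_vs_L",
]


@dataclass
class SelectionReport:
    """Grid-search record and the winning configuration."""

    gamma_grid: np.ndarray
    entries: list[dict] = field(default_factory=list)  # one per (L, gamma, restart)
    chosen: dict | None = None
    model: CilvaModel | None = None

    def to_dict(self) -> dict:
        return {
            "gamma_grid": [float(g) for g in self.gamma_grid],
            "entries": self.entries,
            "chosen": self.chosen,
        }


def split_train_test(
    F: FluorescenceMatrix,
    S: StimulusDesign,
    test_seconds: float,
) -> tuple[FluorescenceMatrix, FluorescenceMatrix, StimulusDesign, StimulusDesign]:
    """Hold out the final contiguous ``round(test_seconds * fs)`` frames.

    The stimulus design is split identically.  A zero-length test segment is
    permitted (selection then falls back to the training objective, with a
    warning at scoring time).
    """
    T = F.n_frames
    n_test = int(round(test_seconds * F.fs))
    if n_test >= T:
        raise ValueError(f"test segment of {n_test} frames covers the whole recording (T={T})")
    n_train = T - n_test
    F_train = FluorescenceMatrix(F.values[:, :n_train], fs=F.fs, neuron_ids=F.neuron_ids)
    S_train = StimulusDesign(S.matrix[:, :n_train], stim_labels=S.stim_labels,
                             shift_count=S.shift_count)
    if n_test == 0:
        return F_train, None, S_train, None
    F_test = FluorescenceMatrix(F.values[:, n_train:], fs=F.fs, neuron_ids=F.neuron_ids)
    S_test = StimulusDesign(S.matrix[:, n_train:], stim_labels=S.stim_labels,
                            shift_count=S.shift_count)
    return F_train, F_test, S_train, S_test


def _held_out_score(model: CilvaModel, F_test: FluorescenceMatrix, S_test: StimulusDesign) -> float:
    """ln p(f_test | x_test, theta) p(x_test | gamma) at freshly inferred latents."""
    X_test = infer_latents(F_test, model, S_test)
    scored = model.copy()
    scored.X = X_test
    return log_joint(F_test, scored, S_test)


def select_hyperparams(
    F: FluorescenceMatrix,
    S: StimulusDesign,
    kernel,
    L_list: list[int],
    delta_gamma: float = 0.2,
    d: int = 10,
    i_max: int = 5,
    test_seconds: float = 300.0,
    seed: int = 0,
    max_alternations: int = 100,
) -> SelectionReport:
    """Grid search gamma over {delta_gamma, 2*delta_gamma, ..., d*delta_gamma}
    with ``i_max`` restarts per configuration, scored on held-out data.

    Restart i uses seed ``seed + i``.  Noise variances are estimated once on
    the training segment and shared across all configurations.
    """
    gamma_grid = delta_gamma * np.arange(1, d + 1)
    F_train, F_test, S_train, S_test = split_train_test(F, S, test_seconds)
    if F_test is None:
        warnings.warn("empty test segment: selection falls back to the training objective")
    sigma2 = estimate_noise_variance(F_train).sigma2
    report = SelectionReport(gamma_grid=gamma_grid)
    best = None
    for L in L_list:
        for gamma in gamma_grid:
            for i in range(i_max):
                cfg = FitConfig(L=L, gamma=float(gamma), seed=seed + i, restarts=1,
                                max_alternations=max_alternations)
                model = fit(F_train, S_train, kernel, cfg, sigma2=sigma2)
                train_obj = model.fit_history[-1]
                if F_test is not None:
                    score = _held_out_score(model, F_test, S_test)
                else:
                    score = train_obj
                entry = {
                    "L": L, "gamma": float(gamma), "restart": i,
                    "train_objective": float(train_obj),
                    "held_out_objective": float(score),
                }
                report.entries.append(entry)
                if best is None or score > best[0]:
                    best = (score, entry, model)
    score, entry, model = best
    # re-infer training latents under the winning (theta, gamma)
    model.X = infer_latents(F_train, model, S_train)
    report.chosen = dict(entry)
    report.model = model
    assert report.chosen["held_out_objective"] >= max(
        e["held_out_objective"] for e in report.entries
    ) - 1e-12
    return report


def mean_fit_correlation(F: FluorescenceMatrix, model: CilvaModel, S: StimulusDesign) -> float:
    """Mean over neurons of the Pearson correlation between trace and
    reconstruction; constant traces are excluded with a warning."""
    f_hat = reconstruct(model, S)
    return float(np.mean(_per_neuron_corr(F.values, f_hat)))


def _per_neuron_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    out = []
    for a, b in zip(A, B):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            warnings.warn("constant trace excluded from correlation summary")
            continue
        out.append(np.corrcoef(a, b)[0, 1])
    return np.asarray(out)


def correlation_vs_L(
    F: FluorescenceMatrix,
    S: StimulusDesign,
    kernel,
    L_list: list[int],
    config: FitConfig | None = None,
    test_seconds: float = 0.0,
) -> dict:
    """Mean train/test fit correlation as a function of the factor count.

    Test reconstructions use latents inferred on the test segment at the
    fitted parameters.  Returns ``{"L": [...], "train": [...], "test": [...]}``
    (test entries are None when no data is held out).
    """
    config = config or FitConfig()
    F_train, F_test, S_train, S_test = split_train_test(F, S, test_seconds)
    sigma2 = estimate_noise_variance(F_train).sigma2
    curve = {"L": list(L_list), "train": [], "test": []}
    for L in L_list:
        cfg = FitConfig(L=L, gamma=config.gamma, seed=config.seed,
                        restarts=config.restarts,
                        max_alternations=config.max_alternations,
                        inner_tol=config.inner_tol)
        model = fit(F_train, S_train, kernel, cfg, sigma2=sigma2)
        curve["train"].append(mean_fit_correlation(F_train, model, S_train))
        if F_test is not None:
            test_model = model.copy()
            test_model.X = infer_latents(F_test, model, S_test)
            curve["test"].append(mean_fit_correlation(F_test, test_model, S_test))
        else:
            curve["test"].append(None)
    return curve
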