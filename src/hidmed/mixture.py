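"""Step 2: two-component Gaussian mixture fitted by EM.

The estimated effect vectors a* and c* are each modelled as a mixture of a
near-zero-mean "noise" Gaussian (regression error around the zero point
mass) and a shifted "effect" Gaussian.  EM is run several times from
jittered starts and the run whose effect-component mean is the median
across runs is returned, which guards against occasional convergence to a
degenerate optimum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateFitError

VAR_FLOOR = 1e-10


@dataclass
class GmmFit:
    """Parameters of a fitted two-component Gaussian mixture.

    Components keep the order they were fitted in; ``noise_index`` says
    which one plays the noise role (the other is the effect component).
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    noise_index: int = 0
    responsibilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive")
        if self.noise_index not in (0, 1):
            raise ValueError("noise_index must be 0 or 1")

    @property
    def effect_index(self) -> int:
        return 1 - self.noise_index

    @property
    def mu_noise(self) -> float:
        return float(self.means[self.noise_index])

    @property
    def mu_effect(self) -> float:
        return float(self.means[self.effect_index])

    @property
    def var_noise(self) -> float:
        return float(self.variances[self.noise_index])

    @property
    def var_effect(self) -> float:
        return float(self.variances[self.effect_index])

    @property
    def w_noise(self) -> float:
        return float(self.weights[self.noise_index])

    @property
    def w_effect(self) -> float:
        return float(self.weights[self.effect_index])

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {"weights": self.weights.tolist(), "means": self.means.tolist(),
             "variances": self.variances.tolist(), "loglik": self.loglik,
             "n_iterations": self.n_iterations, "converged": self.converged,
             "noise_index": self.noise_index}
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=1))
        return d

    @classmethod
    def from_json(cls, path: str | Path) -> "GmmFit":
        return cls(**json.loads(Path(path).read_text()))


def _log_norm_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _loglik_and_resp(x, weights, means, variances):
    logp = np.stack([np.log(weights[k]) + _log_norm_pdf(x, means[k], variances[k])
                     for k in range(2)], axis=1)
    m = logp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
    resp = np.exp(logp - lse[:, None])
    return float(lse.sum()), resp


def em_fit_once(x, init_lambda: float = 0.5, init_means=None, init_vars=None,
                tol: float = 1e-8, max_iter: int = 1000,
                seed=None) -> GmmFit:
    """One EM run.

    E-step: posterior component responsibilities; M-step: weighted weight /
    mean / variance updates.  Stops when the relative change in the
    observed-data log-likelihood drops below ``tol``.  When ``init_means``
    is None they are set to data quantiles — fixed (25%, 75%) without a
    seed, or at uniformly drawn quantile levels with one (the per-run
    jitter used by :func:`em_fit_multi`).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations to fit the mixture")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if init_means is None:
        if seed is None:
            qs = np.array([0.25, 0.75])
        else:
            rng = seed if isinstance(seed, np.random.Generator) \
                else np.random.default_rng(seed)
            qs = np.sort(rng.uniform(0.05, 0.95, size=2))
        init_means = np.quantile(x, qs)
    if init_vars is None:
        v = float(np.var(x))
        init_vars = (v, v)

    weights = np.array([init_lambda, 1.0 - init_lambda], dtype=float)
    means = np.asarray(init_means, dtype=float).copy()
    variances = np.maximum(np.asarray(init_vars, dtype=float), VAR_FLOOR).copy()

    loglik, resp = _loglik_and_resp(x, weights, means, variances)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        if (variances < VAR_FLOOR).any():
            raise DegenerateFitError(
                f"component variance collapsed below {VAR_FLOOR:g}")
        new_loglik, resp = _loglik_and_resp(x, weights, means, variances)
        if abs(new_loglik - loglik) < tol * (abs(loglik) + 1e-300):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    fit = GmmFit(weights=weights, means=means, variances=variances,
                 loglik=loglik, n_iterations=it, converged=converged,
                 responsibilities=resp)
    return label_components(fit)


def _two_means_cut(s: np.ndarray) -> int:
    """Exact 1-D 2-means: index cutting sorted data into the two blocks
    minimizing total within-block sum of squares."""
    n = s.size
    c1 = np.cumsum(s)
    c2 = np.cumsum(s * s)
    k = np.arange(1, n)
    ss_left = c2[:-1] - c1[:-1] ** 2 / k
    ss_right = (c2[-1] - c2[:-1]) - (c1[-1] - c1[:-1]) ** 2 / (n - k)
    return int(np.argmin(ss_left + ss_right)) + 1


def _partition_init(s: np.ndarray, cut: int):
    lo, hi = s[:cut], s[cut:]
    return ((lo.mean(), hi.mean()),
            (max(lo.var(), VAR_FLOOR), max(hi.var(), VAR_FLOOR)))


def _em_one_run(x, s, rng, n_init: int, **em_opts) -> GmmFit:
    """One 'run' = a small multi-start EM: the exact 2-means partition plus
    ``n_init - 1`` random quantile-cut partitions, keeping the best
    log-likelihood.  The effect vectors fitted here have a tight near-zero
    noise cluster next to a broad effect cluster; partition starts with a
    matching small-variance component are the reliable way into that basin.
    """
    n = s.size
    cuts = [_two_means_cut(s)]
    lo_cut, hi_cut = max(2, n // 20), n - max(2, n // 20)
    for _ in range(n_init - 1):
        cuts.append(int(rng.integers(lo_cut, max(lo_cut + 1, hi_cut))))
    best: GmmFit | None = None
    for cut in cuts:
        means, variances = _partition_init(s, cut)
        try:
            fit = em_fit_once(x, init_means=means, init_vars=variances,
                              **em_opts)
        except DegenerateFitError:
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise DegenerateFitError("all EM starts collapsed")
    return best


def em_fit_multi(x, n_runs: int = 15, seed=None, n_init: int = 6,
                 component_medians: bool = False, **em_opts) -> GmmFit:
    """Multi-run EM with median selection.

    Each run is a small multi-start EM (see :func:`_em_one_run`); across
    runs the one whose effect-component mean is the median of the effect
    means is returned (for even counts, the lower-middle order statistic),
    so the result is one coherent parameter set.  With
    ``component_medians`` the weights, means and variances are instead the
    component-wise medians across runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    x = np.asarray(x, dtype=float)
    s = np.sort(x)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    fits: list[GmmFit] = []
    for _ in range(n_runs):
        try:
            fits.append(_em_one_run(x, s, rng, n_init, **em_opts))
        except DegenerateFitError:
            continue
    if not fits:
        raise DegenerateFitError("all EM runs collapsed")
    effect_means = np.array([f.mu_effect for f in fits])
    pick = int(np.argsort(effect_means, kind="stable")[(len(fits) - 1) // 2])
    if not component_medians:
        return fits[pick]
    ref = fits[pick]
    noise = ref.noise_index
    eff = 1 - noise
    params = {}
    for attr in ("weights", "means", "variances"):
        vals = np.array([[getattr(f, attr)[f.noise_index],
                          getattr(f, attr)[f.effect_index]] for f in fits])
        out = np.empty(2)
        out[noise], out[eff] = np.median(vals, axis=0)
        params[attr] = out
    params["weights"] /= params["weights"].sum()
    return GmmFit(loglik=ref.loglik, n_iterations=ref.n_iterations,
                  converged=ref.converged, noise_index=noise, **params)


def label_components(fit: GmmFit) -> GmmFit:
    """Label the component with smaller |mean| as noise; on a tie the
    smaller-variance component is the noise."""
    am = np.abs(fit.means)
    if am[0] != am[1]:
        noise = int(np.argmin(am))
    else:
        noise = int(np.argmin(fit.variances))
    return dataclasses.replace(fit, noise_index=noise)


def flip_labels(fit: GmmFit) -> GmmFit:
    """Swap the noise/effect roles; parameters unchanged."""
    return dataclasses.replace(fit, noise_index=1 - fit.noise_index)


def plot_fit(fit: GmmFit, x, ax=None, bins: int = 40):
    """Histogram of the effect values with the fitted component densities."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    ax.hist(x, bins=bins, density=True, color="0.8", edgecolor="0.5")
    grid = np.linspace(x.min(), x.max(), 400)
    for k, style in ((fit.noise_index, "C0--"), (fit.effect_index, "C3-")):
        pdf = fit.weights[k] * stats.norm.pdf(grid, fit.means[k],
                                              np.sqrt(fit.variances[k]))
        label = "noise" if k == fit.noise_index else "effect"
        ax.plot(grid, pdf, style, label=label)
    ax.axvline(fit.mu_effect, color="red", lw=1)
    ax.legend()
    return ax
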