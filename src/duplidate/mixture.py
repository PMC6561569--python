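"""Lognormal mixture fits of corrected-4dTv age distributions.

Paralogue divergences accumulated in bursts (whole-genome duplications)
appear as components of a lognormal mixture: a Gaussian mixture is fitted
by EM on ln(4dTv), the component count is chosen by BIC, and the "modes"
reported are the local maxima of the mixture density on the original
scale (the mode of one lognormal component is exp(mu - sigma^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from duplidate.config import PipelineConfig

VARIANCE_FLOOR = 1e-6  # log-space; below this the fit is a degenerate spike


class MixtureError(ValueError):
    pass


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray      # (k,)
    means: np.ndarray        # (k,) log-space mu
    sigmas: np.ndarray       # (k,) log-space sigma
    bic: float
    bic_by_k: dict[int, float]
    seed: int
    grid: np.ndarray
    density: np.ndarray
    maxima: list[float]

    @property
    def component_modes(self) -> np.ndarray:
        """Original-scale mode of each lognormal component, exp(mu - sigma^2)."""
        return np.exp(self.means - self.sigmas**2)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for w, mu, sig in zip(self.weights, self.means, self.sigmas):
            out += w * stats.lognorm.pdf(x, s=sig, scale=np.exp(mu))
        return out


def fit_lognormal_mixture(
    values,
    k_candidates=(1, 2, 3, 4),
    seed: int = 0,
    n_init: int = 10,
    grid_min: float = 0.01,
    grid_max: float = 1.5,
    grid_step: float = 0.005,
) -> MixtureFit:
    """Fit lognormal mixtures (Gaussian EM in log space) for each k and
    keep the minimum-BIC fit; deterministic given (values, seed).

    Values must be strictly positive (saturated/undefined distances are
    excluded upstream) and n must be at least 10 per candidate component.
    """
    x = np.asarray(list(values), dtype=float)
    bad = np.where(~(x > 0))[0]
    if bad.size:
        raise MixtureError(
            f"{bad.size} non-positive value(s) at indices {bad[:5].tolist()}..."
        )
    kmax = max(k_candidates)
    if x.size < 10 * kmax:
        raise MixtureError(f"need >= {10 * kmax} values for k up to {kmax}, got {x.size}")
    logx = np.log(x).reshape(-1, 1)
    if np.var(logx) < VARIANCE_FLOOR:
        raise MixtureError("degenerate input: log-space variance below the variance floor")
    bic_by_k: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in sorted(k_candidates):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=VARIANCE_FLOOR,
            max_iter=500,
        ).fit(logx)
        bic_by_k[k] = float(gm.bic(logx))
        fits[k] = gm
    best_k = min(sorted(bic_by_k), key=lambda k: bic_by_k[k])
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    fit = MixtureFit(
        k=best_k,
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sigmas=np.sqrt(gm.covariances_.reshape(best_k)[order]),
        bic=bic_by_k[best_k],
        bic_by_k=bic_by_k,
        seed=seed,
        grid=np.array([]),
        density=np.array([]),
        maxima=[],
    )
    fit.grid = np.arange(grid_min, grid_max + grid_step / 2, grid_step)
    fit.density = fit.pdf(fit.grid)
    fit.maxima = density_local_maxima(fit, grid_min, grid_max, grid_step)
    return fit


def density_local_maxima(
    fit: MixtureFit,
    grid_min: float = 0.01,
    grid_max: float = 1.5,
    step: float = 0.005,
) -> list[float]:
    """Grid points where the mixture density exceeds both neighbours;
    plateaus contribute their midpoint.  Sorted ascending."""
    grid = np.arange(grid_min, grid_max + step / 2, step)
    dens = fit.pdf(grid)
    maxima: list[float] = []
    i = 1
    n = len(grid)
    while i < n - 1:
        if dens[i] > dens[i - 1]:
            j = i
            while j + 1 < n and dens[j + 1] == dens[j]:
                j += 1
            if j < n - 1 and dens[j] > dens[j + 1]:
                maxima.append(float((grid[i] + grid[j]) / 2))
            i = j + 1
        else:
            i += 1
    return sorted(maxima)


def histogram_4dtv(values, config: PipelineConfig) -> dict:
    """Fixed-width half-open bins over [hist_min, hist_max); out-of-range
    values land in the underflow/overflow counters."""
    x = np.asarray(list(values), dtype=float)
    edges = np.arange(
        config.hist_min,
        config.hist_max + config.hist_width / 2,
        config.hist_width,
    )
    counts = np.zeros(len(edges) - 1, dtype=int)
    under = over = 0
    for v in x:
        if v < config.hist_min:
            under += 1
        elif v >= config.hist_max:
            over += 1
        else:
            counts[min(int((v - config.hist_min) / config.hist_width), len(counts) - 1)] += 1
    return {
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "underflow": under,
        "overflow": over,
    }


def plot_density(fit: MixtureFit, values, path, config: PipelineConfig) -> None:
    """Histogram with the fitted mixture density on top (both normalized)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.asarray(list(values), dtype=float)
    ax.hist(x, bins=np.arange(config.hist_min, config.hist_max, config.hist_width),
            density=True, alpha=0.5, color="steelblue", label="corrected 4dTv")
    ax.plot(fit.grid, fit.density, color="firebrick", label=f"mixture (k={fit.k})")
    for m in fit.maxima:
        ax.axvline(m, color="grey", linestyle=":")
    ax.set_xlabel("corrected 4dTv")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
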