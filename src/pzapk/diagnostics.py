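"""Internal validation: goodness-of-fit residuals, prediction-corrected
visual predictive check (pcVPC) and nonparametric bootstrap.

* Residuals: PRED (population, eta=0), IPRED (at the empirical-Bayes eta),
  IWRES = (obs - IPRED)/sigma for the additive error model, and CWRES from
  the FOCE linearisation (whitened residual against the population-level
  FOCE mean).
* pcVPC: each observation (and each simulated replicate of the design) is
  scaled by the ratio of its time-bin's median population prediction to its
  own population prediction, removing dose/covariate heterogeneity before
  percentile comparison.
* Bootstrap: subjects resampled with replacement, model refitted per
  replicate; medians and percentile intervals over converged replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SubjectRecord
from .model import PopPKModel, PopPKResults
from .modelspec import ModelSpec

__all__ = [
    "ResidualTable",
    "VpcResult",
    "BootstrapResult",
    "compute_residuals",
    "pc_vpc",
    "bootstrap",
    "plot_vpc",
    "plot_gof",
]

logger = logging.getLogger(__name__)


def compute_residuals(results: PopPKResults) -> pd.DataFrame:
    """Per-observation residual table (PRED, IPRED, RES, IWRES, CWRES)."""
    eng = results.model.engine
    ps = results.params
    eta = results.ebes.to_numpy()

    pred = eng.predict(ps, None)
    ipred = eng.predict(ps, eta)
    sigma = ps.sigma
    res = eng.y - pred
    iwres = (eng.y - ipred) / sigma

    # CWRES: whitened FOCE residual, V = J Omega J' + sigma^2 I at eta_hat
    f, J = eng._fj(ps, eta)
    mean_foce = f - np.einsum("oa,oa->o", J, eta[eng.isub])
    cwres = np.empty(eng.n_obs)
    om2 = ps.omega**2
    for i in range(eng.n_sub):
        sl = slice(eng.starts[i], eng.starts[i + 1])
        Ji = J[sl]
        V = Ji @ np.diag(om2) @ Ji.T + sigma**2 * np.eye(sl.stop - sl.start)
        L = np.linalg.cholesky(V)
        cwres[sl] = np.linalg.solve(L, eng.y[sl] - mean_foce[sl])

    ids = np.array([s.id for s in results.model.subjects])
    return pd.DataFrame(
        {
            "id": ids[eng.isub],
            "time": eng.t,
            "obs": eng.y,
            "pred": pred,
            "ipred": ipred,
            "res": res,
            "iwres": iwres,
            "cwres": cwres,
        }
    )


@dataclass
class VpcResult:
    """Prediction-corrected VPC summary."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame  # rows bins, columns p5/p50/p95 of pc-observations
    simulated_median: pd.DataFrame  # median across simulations of each percentile
    simulated_ci_low: pd.DataFrame  # 2.5th across simulations
    simulated_ci_high: pd.DataFrame  # 97.5th across simulations
    n_simulations: int
    percentiles: tuple[float, ...]

    def coverage(self) -> pd.Series:
        """Fraction of bins whose observed percentile lies inside the
        simulated percentile's CI, per percentile."""
        inside = (self.observed >= self.simulated_ci_low) & (self.observed <= self.simulated_ci_high)
        return inside.mean(axis=0)


def pc_vpc(
    results: PopPKResults,
    n_sim: int = 1000,
    n_bins: int = 8,
    seed: int = 0,
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Observations and ``n_sim`` simulated replicates of the exact design are
    corrected by ``bin-median PRED / own PRED`` and summarised as percentile
    bands; the spread of each percentile across replicates gives its 95% CI.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1 (spec: >= 100 for reporting)")
    eng = results.model.engine
    ps = results.params
    rng = np.random.default_rng(seed)

    pred = eng.predict(ps, None)
    t = eng.t
    edges = np.unique(np.quantile(t, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        logger.info("merged empty/duplicate VPC bins: %d -> %d", n_bins, len(edges) - 1)
    n_bins = len(edges) - 1
    which = np.clip(np.digitize(t, edges[1:-1], right=True), 0, n_bins - 1)

    bin_median_pred = np.array([np.median(pred[which == b]) for b in range(n_bins)])
    corr = bin_median_pred[which] / np.maximum(pred, 1e-12)
    pc_obs = eng.y * corr

    cols = [f"p{int(p)}" for p in percentiles]
    obs_pct = pd.DataFrame(
        [np.percentile(pc_obs[which == b], percentiles) for b in range(n_bins)],
        columns=cols,
    )

    sim_pct = np.empty((n_sim, n_bins, len(percentiles)))
    chunk = 200
    for s0 in range(0, n_sim, chunk):
        s1 = min(s0 + chunk, n_sim)
        m = s1 - s0
        eta = rng.normal(0.0, 1.0, size=(m, eng.n_sub, 3)) * ps.omega
        for j in range(m):
            f = eng.predict(ps, eta[j])
            ysim = np.maximum(f + rng.normal(0.0, ps.sigma, size=eng.n_obs), 0.0)
            pc_sim = ysim * corr
            for b in range(n_bins):
                sim_pct[s0 + j, b] = np.percentile(pc_sim[which == b], percentiles)

    mid = 0.5 * (edges[:-1] + edges[1:])
    return VpcResult(
        bin_edges=edges,
        bin_mid=mid,
        observed=obs_pct,
        simulated_median=pd.DataFrame(np.median(sim_pct, axis=0), columns=cols),
        simulated_ci_low=pd.DataFrame(np.percentile(sim_pct, 2.5, axis=0), columns=cols),
        simulated_ci_high=pd.DataFrame(np.percentile(sim_pct, 97.5, axis=0), columns=cols),
        n_simulations=n_sim,
        percentiles=percentiles,
    )


@dataclass
class BootstrapResult:
    """Nonparametric bootstrap summary over converged replicates."""

    table: pd.DataFrame  # index parameters, columns median / ci_low / ci_high
    samples: pd.DataFrame  # one row per converged replicate
    n_resamples: int
    convergence_fraction: float


def bootstrap(
    subjects: Sequence[SubjectRecord],
    spec: ModelSpec,
    n_resamples: int = 1000,
    seed: int = 0,
    start=None,
    maxiter: int = 200,
) -> BootstrapResult:
    """Resample subjects with replacement to the original n and refit.

    Non-converging replicates are dropped and counted; medians and the
    2.5-97.5 percentile interval are computed over the rest.  Bit-identical
    resample indices under a fixed seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    subjects = list(subjects)
    n = len(subjects)
    rng = np.random.default_rng(seed)
    rows = []
    n_converged = 0
    for rep in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        sample = [subjects[i] for i in idx]
        try:
            fit = PopPKModel(sample, spec=spec).fit(start=start, compute_se=False, maxiter=maxiter)
        except Exception as exc:  # noqa: BLE001 - replicate failure is data, not fatal
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            continue
        if fit.converged:
            n_converged += 1
            rows.append(fit.estimates)
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    samples = pd.DataFrame(rows).reset_index(drop=True)
    table = pd.DataFrame(
        {
            "median": samples.median(),
            "ci_low": samples.quantile(0.025),
            "ci_high": samples.quantile(0.975),
        }
    )
    return BootstrapResult(
        table=table,
        samples=samples,
        n_resamples=n_resamples,
        convergence_fraction=n_converged / n_resamples,
    )


# ---------------------------------------------------------------------------
# Plots (PNG/SVG files; numeric content is available from the result objects)
# ---------------------------------------------------------------------------


def plot_vpc(vpc: VpcResult, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for i, col in enumerate(vpc.observed.columns):
        ax.fill_between(vpc.bin_mid, vpc.simulated_ci_low[col], vpc.simulated_ci_high[col],
                        alpha=0.25)
        ax.plot(vpc.bin_mid, vpc.simulated_median[col], "--", lw=1)
        ax.plot(vpc.bin_mid, vpc.observed[col], "o-", lw=1.5, label=col)
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (ug/mL)")
    ax.legend(title="percentile")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gof(residuals: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    axes[0, 0].plot(residuals["pred"], residuals["obs"], "ko", ms=3, alpha=0.5)
    _identity(axes[0, 0])
    axes[0, 0].set_xlabel("PRED")
    axes[0, 0].set_ylabel("observed")
    axes[0, 1].plot(residuals["ipred"], residuals["obs"], "ko", ms=3, alpha=0.5)
    _identity(axes[0, 1])
    axes[0, 1].set_xlabel("IPRED")
    axes[0, 1].set_ylabel("observed")
    axes[1, 0].plot(residuals["pred"], residuals["cwres"], "ko", ms=3, alpha=0.5)
    axes[1, 0].axhline(0, color="r", lw=1)
    axes[1, 0].set_xlabel("PRED")
    axes[1, 0].set_ylabel("CWRES")
    axes[1, 1].plot(residuals["ipred"], residuals["iwres"], "ko", ms=3, alpha=0.5)
    axes[1, 1].axhline(0, color="r", lw=1)
    axes[1, 1].set_xlabel("IPRED")
    axes[1, 1].set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _identity(ax) -> None:
    lims = [min(ax.get_xlim()[0], ax.get_ylim()[0]), max(ax.get_xlim()[1], ax.get_ylim()[1])]
    ax.plot(lims, lims, "r-", lw=1)
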