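"""Model evaluation: goodness-of-fit quantities, visual predictive check
and nonparametric bootstrap.

Goodness of fit reports, per observation, the population prediction PRED
(random effect at zero), the individual prediction IPRED (at the
empirical Bayes mode), individual weighted residuals
iWRES = (DV - IPRED) / sd(residual at IPRED), and population weighted
residuals from the first-order approximation of the marginal covariance
(classic WRES, linearized at eta = 0) alongside the conditional variant
CWRES (linearized at the empirical Bayes mode) since plain "weighted
residuals" is ambiguous.

The bootstrap resamples subjects with replacement, refits each replicate,
and summarizes each parameter by its bootstrap median, 5th-95th
percentile interval and the bias statistic
(median - estimate) / estimate * 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import LikelihoodEngine
from .data import EventDataset
from .popmodel import EstimationResult, fit

__all__ = [
    "GofTable",
    "VpcResult",
    "BootstrapSummary",
    "gof",
    "vpc",
    "bootstrap",
    "bootstrap_bias",
    "plot_gof",
    "plot_vpc",
]


@dataclass
class GofTable:
    """Per-observation diagnostics; ``table`` columns: subject, time, dv,
    pred, ipred, iwres, wres, cwres, flagged (zero residual sd)."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class VpcResult:
    """Visual-predictive-check summary.

    ``bins``: per time-bin observed 5/50/95 percentiles with the matching
    simulated percentile medians and 90% envelopes (5th-95th across
    replicates).
    """

    bin_edges: np.ndarray
    bins: pd.DataFrame
    n_replicates: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class BootstrapSummary:
    """Per-parameter bootstrap summary: estimate, median, 90% interval
    (5th-95th percentile), bias %; bookkeeping of failed replicates."""

    table: pd.DataFrame
    n_resamples: int
    n_failed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return self.n_resamples - self.n_failed


def bootstrap_bias(estimate: float, median: float) -> float:
    """Bias % = (median - estimate) / estimate * 100; exact, unrounded."""
    if estimate == 0:
        raise ZeroDivisionError("bias is undefined for a zero estimate")
    return (median - estimate) / estimate * 100.0


def _eta_gradient(eng: LikelihoodEngine, x, eta, delta=1e-5):
    """dg/deta per observation by central differences; (S, J)."""
    gp, _ = eng.predictions(x, np.asarray(eta) + delta)
    gm, _ = eng.predictions(x, np.asarray(eta) - delta)
    return (gp - gm) / (2.0 * delta)


def gof(result: EstimationResult, data: EventDataset) -> GofTable:
    """Goodness-of-fit table for a successful fit.

    WRES uses the first-order marginal covariance
    ``omega^2 G G' + diag(Var(y|PRED))`` linearized at eta = 0; CWRES uses
    the same construction linearized at the empirical Bayes mode.  Rows
    with zero residual sd are flagged rather than dropped.
    """
    model = result.model.as_sd_convention()
    eng = LikelihoodEngine(data, model)
    x = eng.pack(model)
    zeros = np.zeros(eng.n_sub)
    etas = np.asarray(result.etas, dtype=float)
    if etas.shape != (eng.n_sub,):
        raise ValueError("result.etas length does not match the dataset")

    pred, mask = eng.predictions(x, zeros)
    ipred, _ = eng.predictions(x, etas)
    g0_grad = _eta_gradient(eng, x, zeros)
    gc_grad = _eta_gradient(eng, x, etas)

    omega = model.omega_sd
    rows = []
    for i, s in enumerate(eng.subjects):
        m = mask[i]
        y = eng.y[i, m]
        p0 = pred[i, m]
        pc = ipred[i, m]
        sd_i = eng.residual_sd(x, pc)
        flagged = sd_i <= 0
        iwres = np.where(flagged, np.nan, (y - pc) / np.where(flagged, 1.0, sd_i))

        def _wres(center, grad, mean_shift):
            G = grad[i, m]
            cov = omega**2 * np.outer(G, G) + np.diag(
                np.maximum(eng.residual_sd(x, center) ** 2, 1e-300)
            )
            L = np.linalg.cholesky(cov)
            return np.linalg.solve(L, y - mean_shift)

        wres = _wres(p0, g0_grad, p0)
        cwres = _wres(pc, gc_grad, pc - gc_grad[i, m] * etas[i])
        times = [o.time for o in s.observations]
        for j in range(m.sum()):
            rows.append(
                {
                    "subject": s.id,
                    "time": times[j],
                    "dv": y[j],
                    "pred": p0[j],
                    "ipred": pc[j],
                    "iwres": iwres[j],
                    "wres": wres[j],
                    "cwres": cwres[j],
                    "flagged": bool(flagged[j]),
                }
            )
    return GofTable(table=pd.DataFrame(rows))


def _simulate_observations(eng: LikelihoodEngine, model, x, rng):
    """One replicate dataset on the original design: new eta and eps draws."""
    eta = rng.normal(0.0, model.omega_sd, size=eng.n_sub)
    g, mask = eng.predictions(x, eta)
    eps1 = rng.normal(0.0, model.sigma_prop_sd, size=g.shape)
    eps2 = rng.normal(0.0, model.sigma_add_sd, size=g.shape)
    y = g * (1.0 + eps1) + eps2
    return np.maximum(y, 0.0), mask


def vpc(
    result: EstimationResult,
    data: EventDataset,
    n_replicates: int = 500,
    n_bins: int = 6,
    seed: int = 0,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VpcResult:
    """Visual predictive check: observed vs simulated percentiles per
    equal-count time bin, with 90% envelopes across replicates.

    Fully reproducible under a fixed seed; fewer than 50 replicates is
    recorded as a warning.
    """
    warnings = []
    if n_replicates < 50:
        warnings.append(f"n_replicates={n_replicates} < 50: envelopes unreliable")
    model = result.model.as_sd_convention()
    eng = LikelihoodEngine(data, model)
    x = eng.pack(model)
    rng = np.random.default_rng(seed)

    times = np.concatenate(
        [[o.time for o in s.observations] for s in eng.subjects]
    ).astype(float)
    y_obs = eng.y[eng.mask]
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(times, qs))  # duplicates collapse (few distinct times)
    n_bins = max(len(edges) - 1, 1)
    edges[0] -= 1e-9  # make first bin left-inclusive
    which = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, n_bins - 1)

    def _percentiles(values):
        return [
            [np.percentile(values[which == b], p) for p in percentiles]
            for b in range(n_bins)
        ]

    obs_pct = np.asarray(_percentiles(y_obs))  # (bins, 3)
    sim_pct = np.empty((n_replicates, n_bins, len(percentiles)))
    for r in range(n_replicates):
        y_sim, mask = _simulate_observations(eng, model, x, rng)
        sim_pct[r] = np.asarray(_percentiles(y_sim[mask]))

    rows = []
    for b in range(n_bins):
        row = {
            "bin": b,
            "t_lo": edges[b],
            "t_hi": edges[b + 1],
            "n_obs": int((which == b).sum()),
        }
        for k, p in enumerate(percentiles):
            tag = f"p{p:g}"
            row[f"obs_{tag}"] = obs_pct[b, k]
            row[f"sim_{tag}"] = np.median(sim_pct[:, b, k])
            row[f"sim_{tag}_lo"] = np.percentile(sim_pct[:, b, k], 5)
            row[f"sim_{tag}_hi"] = np.percentile(sim_pct[:, b, k], 95)
        rows.append(row)
    return VpcResult(
        bin_edges=edges, bins=pd.DataFrame(rows), n_replicates=n_replicates,
        warnings=warnings,
    )


def bootstrap(
    result: EstimationResult,
    data: EventDataset,
    n_resamples: int = 1000,
    seed: int = 0,
    restart_from: EstimationResult | None = None,
    compute_se: bool = False,
    maxiter: int = 2000,
) -> BootstrapSummary:
    """Nonparametric bootstrap: resample subjects with replacement
    (n = original subject count), refit each replicate starting from the
    final estimates (or ``restart_from``'s model for a robustness run),
    and summarize parameters by median, 5th-95th interval and bias %.

    Failed replicate fits are excluded and counted; a failure fraction
    above 10% raises a warning in the summary.
    """
    rng = np.random.default_rng(seed)
    model = result.model.as_sd_convention()
    start = (restart_from.model if restart_from else model).as_sd_convention()
    n = len(data.subjects)

    eng = LikelihoodEngine(data, model)
    names = eng.parameter_names()
    est = dict(zip(names, _param_values(model)))

    draws: list[dict] = []
    n_failed = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        sub = data.subset(idx)
        try:
            # warm-started replicate fits: a single simplex pass suffices
            r = fit(start, sub, method=result.method, compute_se=False,
                    maxiter=maxiter, restarts=0)
            if not np.isfinite(r.ofv):
                raise RuntimeError("non-finite OFV")
        except Exception:
            n_failed += 1
            continue
        draws.append(dict(zip(names, _param_values(r.model))))

    warnings = []
    if n_resamples and n_failed / n_resamples > 0.10:
        warnings.append(
            f"{n_failed}/{n_resamples} replicate fits failed (> 10%)"
        )
    rows = []
    frame = pd.DataFrame(draws)
    for name in names:
        if name == "theta_ka" and model.ka_fixed:
            continue
        vals = frame[name].to_numpy() if name in frame else np.array([])
        med = float(np.median(vals)) if vals.size else np.nan
        rows.append(
            {
                "parameter": name,
                "estimate": est[name],
                "median": med,
                "ci90_lo": float(np.percentile(vals, 5)) if vals.size else np.nan,
                "ci90_hi": float(np.percentile(vals, 95)) if vals.size else np.nan,
                "bias_pct": bootstrap_bias(est[name], med) if vals.size else np.nan,
            }
        )
    return BootstrapSummary(
        table=pd.DataFrame(rows), n_resamples=n_resamples, n_failed=n_failed,
        warnings=warnings,
    )


def _param_values(model):
    vals = [model.theta_cl, model.theta_v]
    if not model.ka_fixed:
        vals.append(model.theta_ka)
    m = model.as_sd_convention()
    vals += [m.omega_cl, m.sigma_prop, m.sigma_add]
    vals += [e.coefficient for e in model.covariate_effects]
    return vals


# ---------------------------------------------------------------------------
# plotting (standard image files; thin wrappers over matplotlib)
# ---------------------------------------------------------------------------


def plot_gof(gof_table: GofTable, path: str) -> None:
    """Six-panel goodness-of-fit figure (DV vs PRED/IPRED, |iWRES|, WRES
    vs time, QQ, residual density) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy import stats

    t = gof_table.table
    fig, axes = plt.subplots(2, 3, figsize=(13, 8))
    lim = [0, max(t.dv.max(), t.pred.max(), t.ipred.max()) * 1.05]

    for ax, xcol, name in ((axes[0, 0], "pred", "PRED"), (axes[0, 1], "ipred", "IPRED")):
        ax.plot(t[xcol], t.dv, "o", ms=3, alpha=0.6)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set(xlabel=f"{name} (ng/mL)", ylabel="DV (ng/mL)", xlim=lim, ylim=lim)
    axes[0, 2].plot(t.ipred, t.iwres.abs(), "o", ms=3, alpha=0.6)
    axes[0, 2].set(xlabel="IPRED (ng/mL)", ylabel="|iWRES|")
    axes[1, 0].plot(t.time, t.wres, "o", ms=3, alpha=0.6)
    axes[1, 0].axhline(0, color="k", ls="--", lw=1)
    axes[1, 0].set(xlabel="time (h)", ylabel="WRES")
    stats.probplot(t.wres.dropna(), dist="norm", plot=axes[1, 1])
    axes[1, 1].set_title("")
    axes[1, 1].set(xlabel="normal quantiles", ylabel="WRES quantiles")
    axes[1, 2].hist(t.wres.dropna(), bins=30, density=True, alpha=0.7)
    grid = np.linspace(t.wres.min(), t.wres.max(), 200)
    axes[1, 2].plot(grid, stats.norm.pdf(grid), "k--", lw=1)
    axes[1, 2].set(xlabel="WRES", ylabel="density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_vpc(vpc_result: VpcResult, path: str) -> None:
    """Observed percentiles against simulated envelopes per time bin."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    b = vpc_result.bins
    mid = 0.5 * (b.t_lo + b.t_hi)
    fig, ax = plt.subplots(figsize=(7, 5))
    for tag, color in (("p5", "tab:blue"), ("p50", "tab:red"), ("p95", "tab:blue")):
        ax.fill_between(
            mid, b[f"sim_{tag}_lo"], b[f"sim_{tag}_hi"], alpha=0.25, color=color
        )
        ax.plot(mid, b[f"obs_{tag}"], "o-", color=color, label=f"observed {tag}")
    ax.set(xlabel="time (h)", ylabel="concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
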