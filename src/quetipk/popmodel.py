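"""Population PK model: fixed effects, random effects, residual error,
allometric weight scaling, covariate submodels, marginal likelihood,
estimation and stepwise covariate selection.

Model structure
---------------
Individual clearance and volume follow

    CL/F_i = TV(CL) * (W_i / 70)^0.75 * prod(covariate terms) * exp(eta_i)
    V/F_i  = TV(V)  * (W_i / 70)^1    * prod(covariate terms)

with a single log-normal inter-individual random effect eta_i ~ N(0, omega^2)
on CL/F and the absorption rate constant ka fixed (1.46/h by default).
Observed concentrations follow the combined residual model

    y_ij = g_ij * (1 + eps1_ij) + eps2_ij,
    Var(y|g) = g^2 * sigma1^2 + sigma2^2

The marginal likelihood integrates the single eta dimension per subject,
either exactly by adaptive Gauss-Hermite quadrature or approximately by
the Laplace/first-order-conditional (FOCE) correction at the empirical
Bayes mode.  The objective function value (OFV) is -2 log L including the
Gaussian constants; a NONMEM-style value with n*log(2*pi) dropped is also
reported.  Model selection uses OFV differences, which are convention-free.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .core_pk import StructuralParams
from .data import DoseEvent, EventDataset, Observation, SubjectRecord

__all__ = [
    "AllometricRule",
    "CovariateEffect",
    "PopulationModel",
    "EstimationResult",
    "SelectionTrace",
    "MissingCovariateError",
    "EstimationFailureError",
    "individual_params",
    "params_at",
    "residual_variance",
    "subject_marginal_ofv_quad",
    "foce_ofv",
    "quad_ofv",
    "fit",
    "initial_model",
    "covariate_stepwise",
    "make_candidates",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

# stepwise objective-function thresholds: chi-square(1) at p < 0.05 / p < 0.01;
# inclusion requires a drop strictly greater than 3.84, retention in the
# backward step requires removal to raise the OFV strictly more than 6.63
FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63


class MissingCovariateError(KeyError):
    """A model covariate effect references a covariate a subject lacks."""


class EstimationFailureError(RuntimeError):
    """The marginal likelihood could not be evaluated."""


@dataclass(frozen=True)
class AllometricRule:
    """Fixed power-law body-weight scaling relative to a reference weight.

    Defaults are the standard theory-based exponents: 0.75 for clearance,
    1 for volume, at a 70-kg reference.
    """

    reference_weight: float = 70.0
    exponent_cl: float = 0.75
    exponent_v: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_weight <= 0:
            raise ValueError("reference_weight must be positive")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate submodel term on CL/F or V/F.

    form "power" (continuous covariates): multiplier ``(S_i / center)^Z``
    with ``center`` the population median of the covariate.
    form "linear" (0/1 categorical flags): multiplier ``1 + Z * S_i``,
    which must remain positive over the data.
    ``coefficient=None`` marks Z as to-be-estimated (a selection candidate).
    """

    target: Literal["cl", "v"]
    covariate: str
    form: Literal["power", "linear"]
    coefficient: float | None = None
    center: float | None = None

    def __post_init__(self) -> None:
        if self.target not in ("cl", "v"):
            raise ValueError(f"target must be 'cl' or 'v', got {self.target!r}")
        if self.form not in ("power", "linear"):
            raise ValueError(f"form must be 'power' or 'linear', got {self.form!r}")
        if self.form == "power" and self.center is not None and self.center <= 0:
            raise ValueError("power-form center must be positive")

    def multiplier(self, value: float, coefficient: float | None = None) -> float:
        z = self.coefficient if coefficient is None else coefficient
        if z is None:
            raise ValueError(f"coefficient of {self.label} is not set")
        if self.form == "power":
            if value <= 0:
                raise ValueError(
                    f"power-form covariate {self.covariate!r} needs positive values"
                )
            if self.center is None:
                raise ValueError(f"center of {self.label} is not set")
            return (value / self.center) ** z
        m = 1.0 + z * value
        if m <= 0:
            raise ValueError(f"{self.label}: 1 + Z*S = {m} is not positive")
        return m

    @property
    def label(self) -> str:
        return f"{self.covariate}->{self.target}({self.form})"


@dataclass
class PopulationModel:
    """The estimand: typical values, variability parameters, allometry
    and covariate effects.

    ``scale_convention`` states whether ``omega_cl``, ``sigma_prop`` and
    ``sigma_add`` are standard deviations ("sd", default) or variances
    ("variance"); it is recorded in every serialized result.
    """

    theta_cl: float
    theta_v: float
    theta_ka: float = 1.46
    ka_fixed: bool = True
    omega_cl: float = 0.0
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    allometry: AllometricRule = field(default_factory=AllometricRule)
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    scale_convention: Literal["sd", "variance"] = "sd"

    def __post_init__(self) -> None:
        if self.theta_cl <= 0 or self.theta_v <= 0 or self.theta_ka <= 0:
            raise ValueError("typical values must be strictly positive")
        if min(self.omega_cl, self.sigma_prop, self.sigma_add) < 0:
            raise ValueError("variability parameters must be non-negative")
        if self.scale_convention not in ("sd", "variance"):
            raise ValueError(f"unknown scale_convention {self.scale_convention!r}")

    # -- convention-free accessors (always standard deviations) ------------
    def _sd(self, value: float) -> float:
        return value if self.scale_convention == "sd" else math.sqrt(value)

    @property
    def omega_sd(self) -> float:
        return self._sd(self.omega_cl)

    @property
    def sigma_prop_sd(self) -> float:
        return self._sd(self.sigma_prop)

    @property
    def sigma_add_sd(self) -> float:
        return self._sd(self.sigma_add)

    def as_sd_convention(self) -> "PopulationModel":
        if self.scale_convention == "sd":
            return copy.deepcopy(self)
        return replace(
            copy.deepcopy(self),
            omega_cl=self.omega_sd,
            sigma_prop=self.sigma_prop_sd,
            sigma_add=self.sigma_add_sd,
            scale_convention="sd",
        )

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        m = copy.deepcopy(self)
        m.covariate_effects = list(m.covariate_effects) + [effect]
        return m

    def without_effect(self, label: str) -> "PopulationModel":
        m = copy.deepcopy(self)
        m.covariate_effects = [e for e in m.covariate_effects if e.label != label]
        return m

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta_cl": self.theta_cl,
            "theta_v": self.theta_v,
            "theta_ka": self.theta_ka,
            "ka_fixed": self.ka_fixed,
            "omega_cl": self.omega_cl,
            "sigma_prop": self.sigma_prop,
            "sigma_add": self.sigma_add,
            "scale_convention": self.scale_convention,
            "allometry": {
                "reference_weight": self.allometry.reference_weight,
                "exponent_cl": self.allometry.exponent_cl,
                "exponent_v": self.allometry.exponent_v,
            },
            "covariate_effects": [
                {
                    "target": e.target,
                    "covariate": e.covariate,
                    "form": e.form,
                    "coefficient": e.coefficient,
                    "center": e.center,
                }
                for e in self.covariate_effects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            theta_cl=d["theta_cl"],
            theta_v=d["theta_v"],
            theta_ka=d["theta_ka"],
            ka_fixed=d["ka_fixed"],
            omega_cl=d["omega_cl"],
            sigma_prop=d["sigma_prop"],
            sigma_add=d["sigma_add"],
            scale_convention=d["scale_convention"],
            allometry=AllometricRule(**d["allometry"]),
            covariate_effects=[CovariateEffect(**e) for e in d["covariate_effects"]],
        )


def params_at(
    model: PopulationModel,
    weight: float,
    covariates: dict[str, float] | None = None,
    eta: float = 0.0,
) -> StructuralParams:
    """Individual structural parameters at a body weight and covariate set.

    Applies the allometric rule, all covariate-effect multipliers, and the
    log-normal random effect ``exp(eta)`` on CL/F (no IIV on V/F or ka).
    """
    covariates = covariates or {}
    allo = model.allometry
    rel = weight / allo.reference_weight
    cl = model.theta_cl * rel**allo.exponent_cl
    v = model.theta_v * rel**allo.exponent_v
    for e in model.covariate_effects:
        if e.covariate == "weight":
            value = weight
        elif e.covariate in covariates:
            value = covariates[e.covariate]
        else:
            raise MissingCovariateError(f"missing covariate {e.covariate!r}")
        m = e.multiplier(value)
        if e.target == "cl":
            cl *= m
        else:
            v *= m
    cl *= math.exp(eta)
    return StructuralParams(cl=cl, v=v, ka=model.theta_ka)


def individual_params(
    model: PopulationModel, subject: SubjectRecord, eta: float = 0.0
) -> StructuralParams:
    """Structural parameters of one subject at random effect ``eta``."""
    return params_at(model, subject.weight, dict(subject.covariates), eta)


def residual_variance(model: PopulationModel, g) -> float | np.ndarray:
    """Residual variance Var(y | g) = g^2 sigma1^2 + sigma2^2, (ng/mL)^2.

    ``sigma1``/``sigma2`` are taken on the standard-deviation scale after
    applying the model's ``scale_convention``.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("predicted concentration must be non-negative")
    out = g**2 * model.sigma_prop_sd**2 + model.sigma_add_sd**2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Likelihood, estimation, selection (vectorized engine lives in _engine)
# ---------------------------------------------------------------------------

from ._engine import LikelihoodEngine  # noqa: E402  (engine needs the types above)


def subject_marginal_ofv_quad(
    model: PopulationModel, subject: SubjectRecord, order: int = 21
) -> float:
    """-2 log marginal likelihood of one subject by adaptive Gauss-Hermite
    quadrature over the single eta dimension (order configurable, default 21)."""
    if subject.n_obs < 1:
        raise EstimationFailureError(f"subject {subject.id} has no observations")
    eng = LikelihoodEngine(EventDataset((subject,)), model)
    out = eng.ofv(eng.pack(model), method="quad", order=order)
    if not np.isfinite(out):
        raise EstimationFailureError(
            f"non-finite marginal likelihood for subject {subject.id}"
        )
    return float(out)


def quad_ofv(model: PopulationModel, data: EventDataset, order: int = 21) -> float:
    """Population OFV (-2 log L, constants included) by adaptive quadrature."""
    eng = LikelihoodEngine(data, model)
    return float(eng.ofv(eng.pack(model), method="quad", order=order))


def foce_ofv(model: PopulationModel, data: EventDataset) -> float:
    """Population OFV by the FOCE/Laplace approximation at the empirical
    Bayes mode, residual variance evaluated at the conditional prediction."""
    eng = LikelihoodEngine(data, model)
    return float(eng.ofv(eng.pack(model), method="foce"))


@dataclass
class EstimationResult:
    """Output of :func:`fit`: estimates, uncertainty, OFV and random effects."""

    model: PopulationModel
    ofv: float
    ofv_nonmem: float
    se_percent: dict[str, float]
    etas: np.ndarray
    convergence: dict
    method: str

    @property
    def success(self) -> bool:
        return bool(self.convergence.get("success", False))

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "ofv": self.ofv,
            "ofv_nonmem": self.ofv_nonmem,
            "se_percent": dict(self.se_percent),
            "etas": [float(x) for x in np.asarray(self.etas)],
            "convergence": {
                k: (bool(v) if isinstance(v, (bool, np.bool_)) else v)
                for k, v in self.convergence.items()
            },
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EstimationResult":
        return cls(
            model=PopulationModel.from_dict(d["model"]),
            ofv=d["ofv"],
            ofv_nonmem=d["ofv_nonmem"],
            se_percent=dict(d["se_percent"]),
            etas=np.asarray(d["etas"], dtype=float),
            convergence=dict(d["convergence"]),
            method=d["method"],
        )


def initial_model(
    data: EventDataset,
    half_life_h: float = 7.0,
    omega0: float = 0.3,
    sigma_prop0: float = 0.3,
    sigma_add0: float = 10.0,
    theta_ka: float = 1.46,
) -> PopulationModel:
    """Heuristic starting model: CL from mean dose rate over mean observed
    concentration, V from CL/ke with ke from a nominal 7-h half-life.
    All defaults documented and overridable."""
    rates, concs = [], []
    for s in data.estimation_subjects():
        for e in s.doses:
            if e.interval and (e.ss or e.n_doses > 1):
                rates.append(e.amount / e.interval)
        concs.extend(o.value for o in s.observations)
    if not rates:  # single-dose designs: spread each dose over 24 h
        rates = [
            sum(e.amount for e in s.doses) / 24.0 for s in data.estimation_subjects()
        ]
    mean_rate = float(np.mean(rates))  # mg/h
    mean_conc = max(float(np.mean(concs)), 1e-6) / 1000.0  # ng/mL -> mg/L
    cl0 = max(mean_rate / mean_conc, 1e-3)
    ke0 = math.log(2.0) / half_life_h
    return PopulationModel(
        theta_cl=cl0,
        theta_v=cl0 / ke0,
        theta_ka=theta_ka,
        omega_cl=omega0,
        sigma_prop=sigma_prop0,
        sigma_add=sigma_add0,
    )


def _parameter_box(eng: "LikelihoodEngine", model0: PopulationModel):
    """Optimization box on the transformed scale (log for positive
    parameters, raw for covariate coefficients); generous but finite."""
    per_name = {
        "theta_cl": (-3.0, 10.0),
        "theta_v": (0.0, 12.0),
        "theta_ka": (-4.0, 4.0),
        "omega_cl": (-7.0, 3.0),
        "sigma_prop": (-7.0, 2.0),
        "sigma_add": (-7.0, 8.0),
    }
    lo, hi = [], []
    for name in eng.parameter_names():
        b = per_name.get(name, (-20.0, 20.0))
        lo.append(b[0])
        hi.append(b[1])
    return np.asarray(lo), np.asarray(hi)


def fit(
    model0: PopulationModel,
    data: EventDataset,
    method: Literal["quad", "foce"] = "quad",
    order: int = 21,
    compute_se: bool = True,
    maxiter: int = 4000,
    restarts: int = 1,
) -> EstimationResult:
    """Maximum-likelihood fit of (TV(CL), TV(V), omega, sigma1, sigma2) and
    any free covariate coefficients; ka honored as fixed when flagged.

    Positivity is enforced by optimizing log-transformed parameters with a
    Nelder-Mead simplex; relative standard errors come from the inverse
    finite-difference Hessian of OFV/2 (delta method on the log scale).
    Non-convergence yields a result carrying failure status, the partial
    values and the optimizer trace rather than an exception.
    """
    from scipy.optimize import minimize

    model0 = model0.as_sd_convention()
    eng = LikelihoodEngine(data, model0)
    x0 = eng.pack(model0)

    # soft box on the transformed scale: keeps the simplex from chasing
    # degenerate ridges (e.g. sigma_add -> 0 is reached at the wall instead
    # of log sigma -> -inf, which destroys the simplex geometry)
    lo, hi = _parameter_box(eng, model0)
    x0 = np.clip(x0, lo, hi)

    def objective(x: np.ndarray) -> float:
        xc = np.clip(x, lo, hi)
        val = eng.ofv(xc, method=method, order=order)
        if not np.isfinite(val):
            return 1e12
        return float(val) + 1e3 * float(np.sum((x - xc) ** 2))

    def run_nm(start: np.ndarray):
        # explicit initial simplex: Nelder-Mead's default perturbation
        # collapses at zero coordinates (fresh covariate coefficients)
        simplex = np.vstack([start] + [start + 0.15 * e for e in np.eye(len(start))])
        return minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "maxfev": maxiter,
                "xatol": 1e-4,
                "fatol": 1e-5,
                "adaptive": True,
                "initial_simplex": simplex,
            },
        )

    res = run_nm(x0)
    if restarts:
        for _ in range(restarts):  # fresh simplex guards against early collapse
            res2 = run_nm(np.clip(res.x, lo, hi))
            improved = res2.fun < res.fun - 0.01
            res = res2 if res2.fun < res.fun else res
            if not improved:
                break
    x_hat = np.clip(res.x, lo, hi)
    model = eng.unpack(x_hat, model0)
    etas = eng.eb_etas(x_hat)
    ofv = float(eng.ofv(x_hat, method=method, order=order))
    se = eng.standard_errors(x_hat, method=method, order=order) if compute_se else {}
    return EstimationResult(
        model=model,
        ofv=ofv,
        ofv_nonmem=ofv - data.n_obs * math.log(2.0 * math.pi),
        se_percent=se,
        etas=etas,
        convergence={
            "success": bool(res.success),
            "iterations": int(res.nit),
            "n_eval": int(res.nfev),
            "message": str(res.message),
        },
        method=method,
    )


# ---------------------------------------------------------------------------
# Stepwise covariate modeling
# ---------------------------------------------------------------------------


@dataclass
class SelectionTrace:
    """Audit trail of stepwise selection: every tested (candidate, dOFV)."""

    records: list[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.records.append(kw)

    def to_list(self) -> list[dict]:
        return [dict(r) for r in self.records]


def make_candidates(
    data: EventDataset,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
    targets: Sequence[str] = ("cl", "v"),
) -> list[CovariateEffect]:
    """Build selection candidates: continuous covariates in power form
    centered at the dataset median (computed once and frozen), categorical
    0/1 flags in linear-shift form; each covariate x target pair is a
    separate candidate."""
    cands: list[CovariateEffect] = []
    for name in continuous:
        med = float(np.median(data.covariate_values(name)))
        for t in targets:
            cands.append(
                CovariateEffect(target=t, covariate=name, form="power", center=med)
            )
    for name in categorical:
        for t in targets:
            cands.append(CovariateEffect(target=t, covariate=name, form="linear"))
    return cands


def covariate_stepwise(
    base: PopulationModel,
    data: EventDataset,
    candidates: Sequence[CovariateEffect],
    method: Literal["quad", "foce"] = "quad",
    fitter: Callable[..., EstimationResult] | None = None,
) -> tuple[PopulationModel, SelectionTrace]:
    """Forward inclusion / backward elimination on OFV differences.

    Forward: every remaining candidate is added singly to the current model
    and refitted; the candidate with the largest OFV drop strictly greater
    than 3.84 (chi-square(1), p < 0.05) enters; ties resolve by candidate
    list order; repeat until no candidate qualifies.  Backward: each
    included effect is removed singly and retained only if its removal
    raises the OFV strictly more than 6.63 (p < 0.01).  The base model's
    allometric weight rule is structural and never a candidate.  A candidate
    whose fit fails is skipped and logged, never silently dropped.
    """
    do_fit = fitter or (
        lambda m, d: fit(m, d, method=method, compute_se=False)
    )
    trace = SelectionTrace()

    current = do_fit(base, data)
    trace.add(step="base", ofv=current.ofv, labels=[e.label for e in base.covariate_effects])

    remaining = list(candidates)
    step = 0
    while remaining:
        step += 1
        tested: list[tuple[float, int, EstimationResult]] = []
        for i, cand in enumerate(remaining):
            trial_model = current.model.with_effect(
                replace(cand, coefficient=0.0 if cand.coefficient is None else cand.coefficient)
            )
            try:
                trial = do_fit(trial_model, data)
                if not np.isfinite(trial.ofv):
                    raise EstimationFailureError("non-finite OFV")
            except Exception as exc:  # candidate failure: logged, skipped
                trace.add(
                    step=f"forward-{step}", candidate=cand.label, delta_ofv=None,
                    error=str(exc),
                )
                continue
            d_ofv = current.ofv - trial.ofv
            trace.add(step=f"forward-{step}", candidate=cand.label, delta_ofv=d_ofv)
            tested.append((d_ofv, i, trial))
        qualifying = [t for t in tested if t[0] > FORWARD_THRESHOLD]
        if not qualifying:
            break
        # largest drop wins; ties resolve to the earliest candidate in list order
        best = max(qualifying, key=lambda t: (t[0], -t[1]))
        chosen = remaining.pop(best[1])
        current = best[2]
        trace.add(step=f"forward-{step}", selected=chosen.label, ofv=current.ofv)

    # backward elimination
    changed = True
    sweep = 0
    while changed and current.model.covariate_effects:
        changed = False
        sweep += 1
        for eff in list(current.model.covariate_effects):
            if eff.label not in {c.label for c in candidates}:
                continue  # structural effects present in the base model stay
            reduced_model = current.model.without_effect(eff.label)
            try:
                reduced = do_fit(reduced_model, data)
            except Exception as exc:
                trace.add(step=f"backward-{sweep}", candidate=eff.label, error=str(exc))
                continue
            rise = reduced.ofv - current.ofv
            keep = rise > BACKWARD_THRESHOLD
            trace.add(
                step=f"backward-{sweep}", candidate=eff.label, delta_ofv=rise,
                retained=keep,
            )
            if not keep:
                current = reduced
                changed = True
                break
    return current.model, trace
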