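"""Virtual study cohorts with the statistical structure of the study
population: a 99-patient therapeutic-drug-monitoring cohort of adults
with bipolar affective disorder on oral quetiapine.

Continuous demographics and laboratory covariates are drawn from normal
distributions truncated at the published ranges; binary co-medication
flags are independent Bernoulli draws at the published frequencies (only
marginal frequencies are available, so between-drug correlation is not
emulated).  Concentrations are generated through the population model
(allometric scaling, log-normal inter-individual variability on CL/F)
plus combined proportional + additive residual error, under a
trough-dominated sparse sampling design (1-3 steady-state troughs per
subject) unless an explicit rich design is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .data import DoseEvent, EventDataset, Observation, SubjectRecord
from .popmodel import PopulationModel, individual_params
from .core_pk import _conc_kernel

__all__ = ["CohortSpec", "CohortSample", "SpecError", "sample_cohort", "default_paper_spec"]


class SpecError(ValueError):
    """A cohort specification is infeasible (e.g. mean outside its bounds)."""


#: continuous covariate name -> (mean, sd, min, max); study Table-1 moments
CONTINUOUS_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "age": (39.05, 12.79, 17.05, 69.47),
    "albumin": (41.80, 3.49, 33.60, 50.40),
    "globulin": (27.31, 3.99, 18.90, 41.30),
    "alt": (29.01, 31.81, 7.00, 308.00),
    "ast": (23.89, 18.66, 11.00, 212.00),
    "creatinine": (68.11, 17.88, 32.00, 150.00),
    "urea": (4.50, 1.76, 1.99, 12.49),
    "total_protein": (69.12, 5.60, 56.80, 84.90),
    "total_cholesterol": (4.62, 1.01, 2.45, 7.53),
    "triglyceride": (2.28, 1.12, 0.70, 5.74),
    "direct_bilirubin": (2.74, 1.45, 0.50, 10.30),
    "total_bilirubin": (8.51, 4.08, 3.20, 34.80),
    "hematocrit": (41.73, 4.29, 31.00, 54.00),
    "hemoglobin": (137.12, 15.73, 101.00, 185.00),
    "mch": (30.52, 1.58, 25.90, 34.30),
    "mchc": (328.24, 9.32, 302.00, 356.00),
}

WEIGHT_SPEC = (73.75, 13.85, 43.00, 119.00)

#: co-medication flag -> users out of 99 (study Table-2 marginal counts)
COMEDICATION_COUNTS: dict[str, int] = {
    "alprazolam": 6,
    "amlodipine": 5,
    "aripiprazole": 32,
    "aspirin": 7,
    "atorvastatin": 8,
    "clonazepam": 4,
    "clozapine": 3,
    "docusate": 3,
    "irbesartan_hctz": 3,
    "lithium_sr": 7,
    "lithium": 5,
    "lorazepam": 4,
    "metformin": 7,
    "metoprolol": 55,
    "nifedipine": 61,
    "omeprazole": 13,
    "propranolol": 2,
    "risperidone": 4,
    "silymarin": 17,
    "valproate_sr": 3,
    "valproate": 3,
    "trihexyphenidyl": 4,
    "zopiclone": 3,
}

#: published final-model parameters used as the generating truth
FINAL_MODEL = PopulationModel(
    theta_cl=76.1,
    theta_v=530.0,
    theta_ka=1.46,
    ka_fixed=True,
    omega_cl=0.285,
    sigma_prop=0.312,
    sigma_add=23.896,
    scale_convention="sd",
)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one virtual cohort.

    ``sampling_times=None`` selects the sparse trough design: each subject
    contributes ``n_obs`` steady-state troughs (uniform in
    ``n_obs_range``) at successive dosing times ``k * interval``.  A tuple
    of times (h after a steady-state dose) selects a rich design instead.
    """

    n_subjects: int = 99
    n_male: int = 66
    weight: tuple[float, float, float, float] = WEIGHT_SPEC
    continuous: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(CONTINUOUS_COVARIATES)
    )
    comedication_freq: dict[str, float] = field(
        default_factory=lambda: {k: v / 99.0 for k, v in COMEDICATION_COUNTS.items()}
    )
    daily_doses: tuple[float, ...] = (200.0, 300.0, 400.0, 600.0, 800.0)
    interval: float = 12.0
    n_obs_range: tuple[int, int] = (1, 3)
    trough_fraction: float = 0.6
    min_sample_offset: float = 1.0
    sampling_times: tuple[float, ...] | None = None
    true_model: PopulationModel = field(default_factory=lambda: replace(FINAL_MODEL))

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")
        if not 0 <= self.n_male <= self.n_subjects:
            raise SpecError("n_male must lie within [0, n_subjects]")
        for name, (mean, sd, lo, hi) in {"weight": self.weight, **self.continuous}.items():
            if not (lo <= mean <= hi):
                raise SpecError(f"{name}: mean {mean} outside bounds [{lo}, {hi}]")
            if sd <= 0:
                raise SpecError(f"{name}: sd must be positive")
        for name, f in self.comedication_freq.items():
            if not 0.0 <= f <= 1.0:
                raise SpecError(f"{name}: frequency {f} outside [0, 1]")

    def resized(self, n_subjects: int) -> "CohortSpec":
        """The same spec at a different cohort size, keeping the sex ratio."""
        n_male = round(self.n_male * n_subjects / self.n_subjects)
        return replace(self, n_subjects=n_subjects, n_male=n_male)


@dataclass(frozen=True)
class CohortSample:
    """A generated cohort together with its generating truth."""

    dataset: EventDataset
    etas: np.ndarray  # true per-subject random effects
    model: PopulationModel  # generating model


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(spec: CohortSpec, seed: int | np.random.Generator) -> CohortSample:
    """Draw one virtual cohort; a fixed seed gives an identical dataset.

    Concentrations are the model-predicted values at each subject's true
    random effect with one combined residual draw per observation
    (proportional + additive); the rare draw that lands non-positive is
    redrawn, since measured trough concentrations are positive.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model = spec.true_model.as_sd_convention()
    n = spec.n_subjects

    weights = _truncated_normal(rng, *spec.weight, size=n)
    continuous = {
        name: _truncated_normal(rng, *params, size=n)
        for name, params in spec.continuous.items()
    }
    flags = {
        name: (rng.random(n) < f).astype(float)
        for name, f in spec.comedication_freq.items()
    }
    male = np.zeros(n)
    male[rng.permutation(n)[: spec.n_male]] = 1.0

    etas = rng.normal(0.0, model.omega_sd, size=n)
    daily = rng.choice(spec.daily_doses, size=n)

    subjects = []
    for i in range(n):
        cov = {name: float(vals[i]) for name, vals in continuous.items()}
        cov.update({name: float(vals[i]) for name, vals in flags.items()})
        cov["gender"] = float(male[i])
        dose_amt = daily[i] * spec.interval / 24.0
        dose = DoseEvent(time=0.0, amount=dose_amt, interval=spec.interval, ss=True)
        if spec.sampling_times is None:
            # trough-dominated sparse design: each sample is the pre-dose
            # trough with probability trough_fraction, otherwise drawn
            # uniformly within the dosing interval (real-world TDM draw
            # times scatter around the nominal trough)
            n_obs = int(rng.integers(spec.n_obs_range[0], spec.n_obs_range[1] + 1))
            times = []
            for k in range(n_obs):
                if rng.random() < spec.trough_fraction:
                    times.append(spec.interval * (k + 1))
                else:
                    times.append(
                        spec.interval * k
                        + rng.uniform(spec.min_sample_offset, spec.interval)
                    )
        else:
            times = sorted(spec.sampling_times)

        subj_tmp = SubjectRecord(
            id=f"S{i + 1:03d}", weight=float(weights[i]), doses=(dose,),
            observations=(), covariates=cov,
        )
        p = individual_params(model, subj_tmp, eta=float(etas[i]))
        t = np.asarray(times, dtype=float)
        g = _conc_kernel(
            p.cl, p.v, p.ka, dose_amt, np.mod(t, spec.interval), spec.interval, np.inf
        )
        y = np.full(len(t), -1.0)
        for _ in range(100):  # redraw residuals for non-positive observations
            bad = y <= 0.0
            if not bad.any():
                break
            eps1 = rng.normal(0.0, model.sigma_prop_sd, size=bad.sum())
            eps2 = rng.normal(0.0, model.sigma_add_sd, size=bad.sum())
            y[bad] = g[bad] * (1.0 + eps1) + eps2
        y = np.maximum(y, 1e-6)

        obs = tuple(Observation(time=float(ti), value=float(yi)) for ti, yi in zip(t, y))
        subjects.append(
            SubjectRecord(
                id=subj_tmp.id, weight=subj_tmp.weight, doses=(dose,),
                observations=obs, covariates=cov,
            )
        )
    return CohortSample(dataset=EventDataset(tuple(subjects)), etas=etas, model=model)


def default_paper_spec() -> CohortSpec:
    """The study-cohort spec: n=99, 66 men / 33 women, published covariate
    moments and co-medication frequencies, published final-model parameters
    as the generating truth, sparse trough-dominated sampling (1-3 samples
    per subject at steady state) under twice-daily dosing."""
    return CohortSpec()


def rich_design_spec(
    n_subjects: int = 200,
    times: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0),
) -> CohortSpec:
    """A rich post-dose sampling variant used for identifiability checks."""
    return replace(default_paper_spec().resized(n_subjects), sampling_times=times)
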