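"""Population estimation with censored-data (M3) likelihood.

The estimation scheme is an iterative-two-stage / EM hybrid: an inner step
computes per-subject MAP (empirical-Bayes) random effects under the
current population model, and an outer step updates typical values,
random-effect variances and residual errors.  Records below the assay
limit of quantification contribute through the normal CDF (the M3
method) instead of being discarded.  Structural parameters are estimated
on the log scale (positivity) and the release fractions on the logit
scale (boundedness).

The objective function value (OFV) reported is -2 times the joint
penalized log-likelihood (data likelihood at the random-effect modes plus
the log-normal prior, including its normalising constant); only OFV
*differences* between nested fits are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fast, model
from .design import StudyDesign, build_monkey_study
from .model import DoseEvent
from .params import (
    IIV_PARAMETERS,
    AdcParameters,
    DarDistribution,
    MmaeParameters,
    PopulationParameters,
    default_dar_distribution,
)
from .simulate import ANALYTE_CODES, predict_mmae_linear, simulate_individual

__all__ = [
    "ModelVariant",
    "VariantModel",
    "build_variant",
    "FitSettings",
    "FitResult",
    "observation_loglik",
    "fit_individual",
    "fit_population",
    "fisher_standard_errors",
    "compare_models",
    "compare_nonnested",
]

FIT_RTOL = 1e-8
FIT_ATOL = 1e-10

#: Structural parameters on the estimation scale, with their transform.
_LOGIT_PARAMS = ("fmp", "fmd")
_ADC_FIELDS = (
    "emax",
    "km",
    "vc",
    "cld",
    "vp",
    "weibull_lambda",
    "weibull_kappa",
    "fmp",
    "fmd",
)
_MMAE_FIELDS = ("clm", "vm", "clmd", "vmp")


# ---------------------------------------------------------------------------
# model variants


@dataclass(frozen=True)
class ModelVariant:
    """Structural-model alternatives explored during model development.

    ``proteolysis``: ``mm_only`` (saturable only, the final model),
    ``linear_plus_mm`` (adds a linear proteolytic clearance ``clp``) or
    ``dar_dependent`` (power-of-DAR multiplier ``gamma`` on the capacity).
    ``deconjugation_site``: ``central`` or ``central_and_peripheral``.
    ``deconjugation_rate``: ``weibull`` or ``constant`` (one shared rate
    ``k_dec`` for every DAR species).
    """

    proteolysis: str = "mm_only"
    deconjugation_site: str = "central"
    deconjugation_rate: str = "weibull"

    def __post_init__(self) -> None:
        allowed = {
            "proteolysis": ("mm_only", "linear_plus_mm", "dar_dependent"),
            "deconjugation_site": ("central", "central_and_peripheral"),
            "deconjugation_rate": ("weibull", "constant"),
        }
        for attr, opts in allowed.items():
            if getattr(self, attr) not in opts:
                raise ValueError(f"{attr} must be one of {opts}, got {getattr(self, attr)!r}")

    def extra_parameter_names(self) -> tuple:
        names = []
        if self.proteolysis == "linear_plus_mm":
            names.append("clp")
        elif self.proteolysis == "dar_dependent":
            names.append("gamma")
        if self.deconjugation_rate == "constant":
            names.append("k_dec")
        return tuple(names)

    def default_extra(self) -> dict:
        return {
            name: {"clp": 1e-4, "gamma": 0.0, "k_dec": 0.05}[name]
            for name in self.extra_parameter_names()
        }


class VariantModel:
    """Derivative/observation functions realising a :class:`ModelVariant`."""

    #: reference DAR scale for the power multiplier, chosen so gamma = 0
    #: reproduces the shared-capacity model for every species
    _DAR_REF = 4.0

    def __init__(self, variant: ModelVariant):
        self.variant = variant

    def kvec(self, adc: AdcParameters, extra: dict) -> np.ndarray:
        if self.variant.deconjugation_rate == "constant":
            k = np.full(model.N_DAR, float(extra["k_dec"]))
            k[0] = 0.0
            return k
        return model.deconjugation_rates(adc)

    def emax_by_dar(self, adc: AdcParameters, extra: dict) -> np.ndarray | None:
        if self.variant.proteolysis == "dar_dependent":
            n = np.arange(model.N_DAR, dtype=float)
            return adc.emax * ((n + 1.0) / (self._DAR_REF + 1.0)) ** float(extra["gamma"])
        return None

    def pack(self, adc: AdcParameters, mmae: MmaeParameters, extra: dict | None = None) -> np.ndarray:
        extra = extra if extra is not None else self.variant.default_extra()
        return _fast.pack_params(
            adc,
            mmae,
            self.kvec(adc, extra),
            clp=float(extra.get("clp", 0.0)),
            peripheral_deconjugation=(
                self.variant.deconjugation_site == "central_and_peripheral"
            ),
            emax_by_dar=self.emax_by_dar(adc, extra),
        )

    def derivatives(self, state, t, adc, mmae, extra: dict | None = None) -> np.ndarray:
        return np.asarray(_fast.rhs(np.asarray(state, float), t, self.pack(adc, mmae, extra)))

    def observe(self, state, adc, mmae):
        return model.observe(state, adc, mmae)


def build_variant(variant: ModelVariant) -> VariantModel:
    """Return model functions implementing ``variant``."""
    return VariantModel(variant)


# ---------------------------------------------------------------------------
# likelihood


def observation_loglik(value, pred, sigma, lloq=None, censored=False) -> float:
    """Log-likelihood of one record under the proportional error model.

    Non-censored: normal density of ``value`` with mean ``pred`` and SD
    ``sigma * pred``.  Censored: ``log Phi((lloq - pred) / (sigma * pred))``
    — the probability of falling below the quantification limit.
    """
    if pred <= 0 or not np.isfinite(pred):
        raise ValueError("model prediction must be positive")
    sd = sigma * pred
    if censored:
        if lloq is None:
            raise ValueError("censored record requires an LLOQ")
        return float(stats.norm.logcdf((lloq - pred) / sd))
    return float(stats.norm.logpdf(value, loc=pred, scale=sd))


def _vector_loglik(pred, dv, bloq, lloq, sigma):
    """Vectorised record log-likelihood; tolerant of zero predictions."""
    pred = np.asarray(pred, float)
    ll = np.zeros(pred.size)
    sd = sigma * np.maximum(pred, 1e-300)
    cens = bloq.astype(bool)
    zero = pred <= 0.0
    # censored, positive prediction
    m = cens & ~zero
    if m.any():
        ll[m] = stats.norm.logcdf((lloq[m] - pred[m]) / sd[m])
    # censored, zero prediction: below the limit with certainty
    # non-censored records
    m = ~cens
    if m.any():
        ok = m & ~zero
        ll[ok] = stats.norm.logpdf(dv[ok], loc=pred[ok], scale=sd[ok])
        bad = m & zero
        ll[bad] = -1e10  # a positive observation is incompatible with pred = 0
    return ll


# ---------------------------------------------------------------------------
# dataset preprocessing


@dataclass
class SubjectData:
    subj: int
    arm: str
    regimen: list
    grid: np.ndarray  # unique observation times
    analytes: dict  # code -> dict(time_idx, dv, bloq, lloq)
    mmae_only: bool
    n_obs: int


def _resolve_regimen(grp: pd.DataFrame, design: StudyDesign | None, regimens: dict | None):
    subj = int(grp["SUBJ"].iloc[0])
    if regimens is not None and subj in regimens:
        return regimens[subj]
    arm_name = grp["ARM"].iloc[0]
    if design is not None:
        try:
            return design.arm(arm_name).regimen()
        except KeyError:
            pass
    # fall back to a single dose at t = 0 described by the dataset columns
    return [
        DoseEvent(
            time=0.0,
            compound=str(grp["CMPD"].iloc[0]),
            dose_level=float(grp["DOSE_MGKG"].iloc[0]),
            body_weight=float(grp["BW_KG"].iloc[0]),
        )
    ]


def prepare_subjects(
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
    regimens: dict | None = None,
) -> list:
    """Group the long-format dataset into per-subject fitting units."""
    subjects = []
    for subj, grp in dataset.groupby("SUBJ", sort=True):
        grid = np.unique(grp["TIME_H"].to_numpy(float))
        pos = {t: i for i, t in enumerate(grid)}
        analytes = {}
        for code, sub in grp.groupby("ANALYTE", sort=True):
            analytes[code] = {
                "time_idx": np.array([pos[t] for t in sub["TIME_H"]], dtype=int),
                "dv": sub["DV"].to_numpy(float),
                "bloq": sub["BLOQ"].to_numpy(int),
                "lloq": sub["LLOQ"].to_numpy(float),
            }
        regimen = _resolve_regimen(grp, design, regimens)
        subjects.append(
            SubjectData(
                subj=int(subj),
                arm=str(grp["ARM"].iloc[0]),
                regimen=regimen,
                grid=grid,
                analytes=analytes,
                mmae_only=all(d.compound == "mmae" for d in regimen),
                n_obs=len(grp),
            )
        )
    return subjects


def _predict_subject(
    sub: SubjectData,
    adc: AdcParameters,
    mm: MmaeParameters,
    dist: DarDistribution,
    vmodel: VariantModel,
    extra: dict,
) -> dict:
    """Analyte predictions aligned to the subject's records."""
    if sub.mmae_only:
        conc = predict_mmae_linear(sub.regimen, mm, sub.grid)
        series = {"MMAE": conc}
    else:
        profile = simulate_individual(
            sub.regimen,
            adc,
            mm,
            sub.grid,
            dist=dist,
            rtol=FIT_RTOL,
            atol=FIT_ATOL,
            kernel_params=vmodel.pack(adc, mm, extra),
        )
        an = profile.analytes
        series = {code: an[name] for code, name in ANALYTE_CODES.items()}
    return {
        code: series[code][rec["time_idx"]]
        for code, rec in sub.analytes.items()
    }


def _subject_data_loglik(sub: SubjectData, preds: dict, sigma: dict) -> float:
    total = 0.0
    for code, rec in sub.analytes.items():
        total += _vector_loglik(
            preds[code], rec["dv"], rec["bloq"], rec["lloq"], sigma[ANALYTE_CODES[code]]
        ).sum()
    return float(total)


# ---------------------------------------------------------------------------
# settings / result containers


@dataclass
class FitSettings:
    """Tuning knobs of the population fit.

    The defaults favour robustness within a desk-scale compute budget;
    ``outer_max`` caps the ITS sweeps, ``inner_maxfun`` the per-subject
    MAP evaluations and ``struct_maxfun`` the structural-search
    evaluations per sweep.
    """

    outer_max: int = 8
    inner_maxfun: int = 60
    struct_maxfun: int = 120
    # pooled (eta = 0) structural search before EM.  Off by default: the
    # pooled objective is biased under inter-individual variability and can
    # strand the conjugate-block parameters in a spurious basin; the
    # blockwise sweeps provide enough throughput without it.
    warmup_maxfun: int = 0
    ofv_tol: float = 0.01
    param_tol: float = 1e-3
    omega_floor: float = 1e-6
    fd_eps: float = 1e-4
    estimate_sigma: bool = True
    curvature_omega: bool = True  # add the posterior variance to the omega update
    fix: tuple = ()  # structural parameter names held at their initial value
    mc_samples: int = 0  # >0 switches the E-step summary to importance sampling
    seed: int = 0  # seed for the Monte-Carlo E-step draws


@dataclass
class FitResult:
    """Outcome of a population fit."""

    population: PopulationParameters
    extra: dict
    eta: pd.DataFrame  # subjects x IIV_PARAMETERS, MAP random effects
    ofv: float
    bic: float
    n_obs: int
    n_params: int
    trace: list
    converged: bool
    variant: ModelVariant = field(default_factory=ModelVariant)
    inner_converged: bool = True

    @property
    def theta(self) -> dict:
        out = {f: getattr(self.population.adc, f) for f in _ADC_FIELDS}
        out.update({f: getattr(self.population.mmae, f) for f in _MMAE_FIELDS})
        out.update(self.extra)
        return out


# ---------------------------------------------------------------------------
# transforms


def _to_unconstrained(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        value = min(max(value, 1e-12), 1 - 1e-12)
        return float(np.log(value / (1.0 - value)))
    if name == "gamma":
        return float(value)
    return float(np.log(value))


def _from_unconstrained(name: str, z: float) -> float:
    if name in _LOGIT_PARAMS:
        return float(1.0 / (1.0 + np.exp(-z)))
    if name == "gamma":
        return float(z)
    return float(np.exp(z))


def _set_structural(pop: PopulationParameters, extra: dict, names, values) -> tuple:
    adc_kw, mm_kw = {}, {}
    extra = dict(extra)
    for name, v in zip(names, values):
        if name in _ADC_FIELDS:
            adc_kw[name] = v
        elif name in _MMAE_FIELDS:
            mm_kw[name] = v
        else:
            extra[name] = v
    pop = pop.replace(
        adc=pop.adc.replace(**adc_kw) if adc_kw else pop.adc,
        mmae=pop.mmae.replace(**mm_kw) if mm_kw else pop.mmae,
    )
    return pop, extra


# ---------------------------------------------------------------------------
# inner (subject-level) estimation


def _active_eta_indices(sub: SubjectData, omega: np.ndarray) -> np.ndarray:
    idx = [j for j, w in enumerate(omega) if w > 0]
    if sub.mmae_only:
        informative = {IIV_PARAMETERS.index("clm"), IIV_PARAMETERS.index("vmp")}
        idx = [j for j in idx if j in informative]
    return np.array(idx, dtype=int)


def _map_eta(
    sub: SubjectData,
    pop: PopulationParameters,
    extra: dict,
    dist: DarDistribution,
    vmodel: VariantModel,
    omega: np.ndarray,
    eta0: np.ndarray,
    settings: FitSettings,
):
    """MAP random effects for one subject; returns (eta, loglik, converged)."""
    active = _active_eta_indices(sub, omega)
    eta = np.zeros(len(IIV_PARAMETERS))

    def objective(z):
        eta_full = eta.copy()
        eta_full[active] = z
        adc_i, mm_i = pop.individual(eta_full)
        try:
            preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra)
        except RuntimeError:
            return 1e10
        ll = _subject_data_loglik(sub, preds, pop.sigma)
        prior = -0.5 * np.sum(z**2 / omega[active])
        return -(ll + prior)

    if active.size == 0:
        adc_i, mm_i = pop.individual(eta)
        preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra)
        return eta, _subject_data_loglik(sub, preds, pop.sigma), True

    z0 = eta0[active]
    res = optimize.minimize(
        objective,
        z0,
        method="L-BFGS-B",
        options={
            "maxfun": settings.inner_maxfun,
            "eps": settings.fd_eps,
            "ftol": 1e-8,
        },
    )
    f0 = objective(z0)
    if res.fun <= f0:
        z_best, f_best = res.x, res.fun
    else:  # optimizer wandered off; keep the warm start
        z_best, f_best = z0, f0
    eta[active] = z_best
    prior = -0.5 * np.sum(z_best**2 / omega[active])
    return eta, float(-f_best - prior), bool(res.success or res.fun <= f0)


def _posterior_variance(
    sub: SubjectData,
    pop: PopulationParameters,
    extra: dict,
    dist: DarDistribution,
    vmodel: VariantModel,
    omega: np.ndarray,
    eta: np.ndarray,
) -> np.ndarray:
    """Diagonal posterior variance of eta (second-difference Laplace).

    For random effects the subject's data do not inform, the posterior
    equals the prior, so the prior variance is returned there.  Used by
    the curvature-corrected omega update E[eta^2 | y] ~ eta_hat^2 + var.
    """
    var = omega.copy()
    active = _active_eta_indices(sub, omega)

    def neg_logpost(e):
        adc_i, mm_i = pop.individual(e)
        try:
            preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra)
        except RuntimeError:
            return 1e10
        ll = _subject_data_loglik(sub, preds, pop.sigma)
        return -(ll - 0.5 * np.sum(e[active] ** 2 / omega[active]))

    f0 = neg_logpost(eta)
    for j in active:
        h = min(max(0.1 * np.sqrt(omega[j]), 0.01), 0.3)
        ep = eta.copy()
        ep[j] += h
        em = eta.copy()
        em[j] -= h
        curv = (neg_logpost(ep) + neg_logpost(em) - 2.0 * f0) / h**2
        if curv > 1.0 / omega[j]:  # posterior tighter than the prior
            var[j] = min(1.0 / curv, omega[j])
        # else: keep the prior variance (data essentially uninformative)
    return var


def _importance_moments(
    sub: SubjectData,
    pop: PopulationParameters,
    extra: dict,
    dist: DarDistribution,
    vmodel: VariantModel,
    omega: np.ndarray,
    eta_mode: np.ndarray,
    var_mode: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
):
    """Monte-Carlo E-step: importance sampling around the MAP mode.

    Draws from N(eta_hat, posterior-variance diagonal), weights by the
    exact posterior, and returns the weighted first and second moments
    of the subject's random effects.
    """
    active = _active_eta_indices(sub, omega)
    mean = eta_mode.copy()
    second = eta_mode**2
    second[~np.isin(np.arange(len(eta_mode)), active)] = 0.0
    # uninformed effects keep prior moments
    for j in range(len(eta_mode)):
        if j not in active and omega[j] > 0:
            second[j] = omega[j]
    if active.size == 0 or n_samples <= 0:
        return mean, second
    sd_prop = np.sqrt(np.maximum(var_mode[active], 1e-10))
    draws = eta_mode[active] + sd_prop * rng.standard_normal((n_samples, active.size))
    logw = np.empty(n_samples)
    for s in range(n_samples):
        e = eta_mode.copy()
        e[active] = draws[s]
        adc_i, mm_i = pop.individual(e)
        try:
            preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra)
            ll = _subject_data_loglik(sub, preds, pop.sigma)
        except RuntimeError:
            ll = -1e10
        log_prior = -0.5 * np.sum(draws[s] ** 2 / omega[active])
        log_prop = -0.5 * np.sum(((draws[s] - eta_mode[active]) / sd_prop) ** 2)
        logw[s] = ll + log_prior - log_prop
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean[active] = w @ draws
    second[active] = w @ draws**2
    return mean, second


def fit_individual(
    subject_data,
    pop: PopulationParameters,
    variant: ModelVariant | None = None,
    extra: dict | None = None,
    dist: DarDistribution | None = None,
    design: StudyDesign | None = None,
    regimens: dict | None = None,
    settings: FitSettings | None = None,
) -> tuple:
    """MAP random-effect estimate for a single subject.

    ``subject_data`` is the long-format record table of one subject.
    Returns ``(eta_hat, converged)`` with ``eta_hat`` in
    :data:`IIV_PARAMETERS` order.  Subjects whose data carry no
    information on a random effect get the prior mode (zero) there.
    """
    if subject_data["SUBJ"].nunique() != 1:
        raise ValueError("fit_individual expects records of exactly one subject")
    if not (subject_data["BLOQ"] == 0).any() and len(subject_data) == 0:
        raise ValueError("subject has no records")
    variant = variant or ModelVariant()
    vmodel = build_variant(variant)
    extra = extra if extra is not None else variant.default_extra()
    dist = dist or default_dar_distribution()
    settings = settings or FitSettings()
    if design is None and regimens is None:
        design = build_monkey_study()
    sub = prepare_subjects(subject_data, design=design, regimens=regimens)[0]
    omega = pop.omega_vector()
    eta, _, ok = _map_eta(
        sub, pop, extra, dist, vmodel, omega, np.zeros(len(IIV_PARAMETERS)), settings
    )
    return eta, ok


# ---------------------------------------------------------------------------
# population fit


def _total_joint_ofv(etas, omega, data_ll_total):
    """-2 x (data loglik at modes + log-normal prior with its constant)."""
    prior = 0.0
    act = omega > 0
    if act.any():
        w = omega[act]
        prior -= 0.5 * etas.shape[0] * np.sum(np.log(2.0 * np.pi * w))
        prior -= 0.5 * np.sum(etas[:, act] ** 2 / w)
    return -2.0 * (data_ll_total + prior)


def fit_population(
    dataset: pd.DataFrame,
    pop_init: PopulationParameters,
    variant: ModelVariant | None = None,
    settings: FitSettings | None = None,
    design: StudyDesign | None = None,
    regimens: dict | None = None,
    dist: DarDistribution | None = None,
    verbose: bool = False,
) -> FitResult:
    """ITS/EM-style population fit with M3 censoring handling.

    Alternates per-subject MAP estimation of the random effects with
    updates of the typical values (recentring for parameters carrying
    variability, a bounded quasi-Newton search for the shared structural
    parameters), the random-effect variances and the residual errors.
    Stops when the OFV change and the maximum relative parameter change
    fall below tolerance, or at the iteration cap.
    """
    if dataset["SUBJ"].nunique() < 2:
        raise ValueError("population fitting requires at least 2 subjects")
    variant = variant or ModelVariant()
    vmodel = build_variant(variant)
    settings = settings or FitSettings()
    dist = dist or default_dar_distribution()
    if design is None and regimens is None:
        design = build_monkey_study()

    subjects = prepare_subjects(dataset, design=design, regimens=regimens)
    n_sub = len(subjects)
    pop = pop_init
    extra = {**variant.default_extra()}
    omega = pop.omega_vector()
    etas = np.zeros((n_sub, len(IIV_PARAMETERS)))

    struct_names = [
        n
        for n in (*_ADC_FIELDS, *_MMAE_FIELDS, *variant.extra_parameter_names())
        if n not in settings.fix
    ]
    # coordinate blocks exploiting the design's identifiability structure:
    # the free-MMAE disposition is pinned down by the IV-MMAE arms (whose
    # predictions are closed-form and cheap), everything else by the
    # conjugate-dosed arms (whose likelihood does not depend on which
    # subjects carry only MMAE doses)
    mmae_block = [n for n in struct_names if n in _MMAE_FIELDS]
    adc_block = [n for n in struct_names if n not in _MMAE_FIELDS]
    idx_mmae_only = [i for i, s in enumerate(subjects) if s.mmae_only]
    idx_adc = [i for i, s in enumerate(subjects) if not s.mmae_only]

    def data_loglik(pop_z, extra_z, etas, subset):
        total = 0.0
        for i in subset:
            adc_i, mm_i = pop_z.individual(etas[i])
            try:
                preds = _predict_subject(subjects[i], adc_i, mm_i, dist, vmodel, extra_z)
            except RuntimeError:
                return -1e10
            total += _subject_data_loglik(subjects[i], preds, pop_z.sigma)
        return total

    def block_search(pop, extra, etas, names, subset, maxfun):
        """Quasi-Newton search of one transformed-parameter block."""
        if not names or not subset or maxfun <= 0:
            return pop, extra
        current = {
            **{f: getattr(pop.adc, f) for f in _ADC_FIELDS},
            **{f: getattr(pop.mmae, f) for f in _MMAE_FIELDS},
            **extra,
        }
        z0 = np.array([_to_unconstrained(n, current[n]) for n in names])

        def neg(z):
            vals = [_from_unconstrained(n, zi) for n, zi in zip(names, z)]
            try:
                pop_z, extra_z = _set_structural(pop, extra, names, vals)
            except ValueError:
                return 1e10
            return -data_loglik(pop_z, extra_z, etas, subset)

        res = optimize.minimize(
            neg,
            z0,
            method="L-BFGS-B",
            options={"maxfun": maxfun, "eps": settings.fd_eps, "ftol": 1e-10},
        )
        z_best = res.x if res.fun <= neg(z0) else z0
        vals = [_from_unconstrained(n, zi) for n, zi in zip(names, z_best)]
        return _set_structural(pop, extra, names, vals)

    def struct_search(pop, extra, etas, maxfun):
        """Blockwise structural update, guarded to never lower the total."""
        if not idx_mmae_only or not idx_adc:
            return block_search(
                pop, extra, etas, struct_names, list(range(n_sub)), maxfun
            )
        # MMAE-disposition block: closed-form predictions, generous budget.
        # The conjugate arms also depend (weakly) on these parameters, so
        # accept the block only if the total likelihood improves.
        before = data_loglik(pop, extra, etas, range(n_sub))
        pop_m, extra_m = block_search(
            pop, extra, etas, mmae_block, idx_mmae_only, max(400, maxfun)
        )
        after = data_loglik(pop_m, extra_m, etas, range(n_sub))
        if after >= before:
            pop, extra = pop_m, extra_m
        # conjugate/release block: exact coordinate maximisation (the
        # MMAE-only subjects' likelihood does not involve these parameters)
        return block_search(pop, extra, etas, adc_block, idx_adc, maxfun)

    # pooled warm-up: bring the shared structural parameters close before
    # estimating any random effects
    if struct_names and settings.warmup_maxfun > 0:
        pop, extra = struct_search(pop, extra, etas, settings.warmup_maxfun)

    trace: list = []
    converged = False
    inner_ok = True
    prev_vec = None

    for it in range(settings.outer_max):
        # E-step surrogate: subject-level MAP random effects (+ curvature,
        # optionally sharpened by importance sampling around the mode)
        data_ll = 0.0
        post_var = np.tile(omega, (n_sub, 1))
        eta_second = np.zeros_like(etas)
        for i, sub in enumerate(subjects):
            etas[i], ll_i, ok = _map_eta(
                sub, pop, extra, dist, vmodel, omega, etas[i], settings
            )
            data_ll += ll_i
            inner_ok = inner_ok and ok
            if settings.curvature_omega or settings.mc_samples > 0:
                post_var[i] = _posterior_variance(
                    sub, pop, extra, dist, vmodel, omega, etas[i]
                )
            if settings.mc_samples > 0:
                rng = np.random.default_rng(
                    np.random.SeedSequence([settings.seed, it, i])
                )
                etas[i], eta_second[i] = _importance_moments(
                    sub, pop, extra, dist, vmodel, omega,
                    etas[i], post_var[i], settings.mc_samples, rng,
                )

        # M-step 1: recentre the typical values of parameters with IIV
        shift = etas.mean(axis=0)
        act = omega > 0
        shift[~act] = 0.0
        adc_kw, mm_kw = {}, {}
        for j, name in enumerate(IIV_PARAMETERS):
            if not act[j]:
                continue
            mult = float(np.exp(shift[j]))
            if name in _ADC_FIELDS:
                adc_kw[name] = getattr(pop.adc, name) * mult
            else:
                mm_kw[name] = getattr(pop.mmae, name) * mult
        if adc_kw or mm_kw:
            pop = pop.replace(
                adc=pop.adc.replace(**adc_kw) if adc_kw else pop.adc,
                mmae=pop.mmae.replace(**mm_kw) if mm_kw else pop.mmae,
            )
            etas[:, act] -= shift[act]
            if settings.mc_samples > 0:
                # recentre the second moments: E[(eta-m)^2] = E[eta^2] - 2m*mu + m^2
                eta_second[:, act] -= 2.0 * shift[act] * etas[:, act] + shift[act] ** 2

        # M-step 2: random-effect variances.  The curvature-corrected
        # update E[eta^2|y] ~ eta_hat^2 + posterior variance avoids the
        # shrinkage collapse of the plain mode-based update.
        new_omega_sq = dict(pop.omega_sq)
        for j, name in enumerate(IIV_PARAMETERS):
            if not act[j]:
                continue
            if settings.mc_samples > 0:
                v = float(np.mean(eta_second[:, j]))
            elif settings.curvature_omega:
                v = float(np.mean(etas[:, j] ** 2 + post_var[:, j]))
            else:
                v = float(np.mean(etas[:, j] ** 2))
            if v < settings.omega_floor:
                warnings.warn(f"omega^2 for {name} floored at {settings.omega_floor}")
                v = settings.omega_floor
            new_omega_sq[name] = v
        pop = pop.replace(omega_sq=new_omega_sq)
        omega = pop.omega_vector()

        # cache predictions at the current individual estimates
        cached = []
        for i, sub in enumerate(subjects):
            adc_i, mm_i = pop.individual(etas[i])
            cached.append(_predict_subject(sub, adc_i, mm_i, dist, vmodel, extra))

        # M-step 3: residual errors, one bounded 1-D search per analyte
        if settings.estimate_sigma:
            sigma = dict(pop.sigma)
            for code, name in ANALYTE_CODES.items():
                preds, dvs, bloqs, lloqs = [], [], [], []
                for sub, pr in zip(subjects, cached):
                    if code in sub.analytes:
                        rec = sub.analytes[code]
                        preds.append(pr[code])
                        dvs.append(rec["dv"])
                        bloqs.append(rec["bloq"])
                        lloqs.append(rec["lloq"])
                if not preds:
                    continue
                p_ = np.concatenate(preds)
                d_ = np.concatenate(dvs)
                b_ = np.concatenate(bloqs)
                l_ = np.concatenate(lloqs)

                def neg(logsig):
                    return -_vector_loglik(p_, d_, b_, l_, float(np.exp(logsig))).sum()

                r = optimize.minimize_scalar(
                    neg, bounds=(np.log(1e-3), np.log(3.0)), method="bounded"
                )
                if r.fun <= neg(np.log(sigma[name])):
                    sigma[name] = float(np.exp(r.x))
            pop = pop.replace(sigma=sigma)

        # M-step 4: shared structural parameters at fixed random effects
        if struct_names and settings.struct_maxfun > 0:
            pop, extra = struct_search(pop, extra, etas, settings.struct_maxfun)

        # objective and convergence check
        data_ll = 0.0
        for i, sub in enumerate(subjects):
            adc_i, mm_i = pop.individual(etas[i])
            preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra)
            data_ll += _subject_data_loglik(sub, preds, pop.sigma)
        ofv = _total_joint_ofv(etas, omega, data_ll)
        trace.append(ofv)
        if verbose:
            print(f"iteration {it + 1}: OFV = {ofv:.3f}", flush=True)

        vec = np.array(
            [getattr(pop.adc, f) for f in _ADC_FIELDS]
            + [getattr(pop.mmae, f) for f in _MMAE_FIELDS]
            + [extra[n] for n in variant.extra_parameter_names()]
            + [pop.omega_sq.get(p, 0.0) for p in IIV_PARAMETERS]
            + [pop.sigma[a] for a in sorted(pop.sigma)]
        )
        if prev_vec is not None and len(trace) >= 2:
            dofv = abs(trace[-2] - trace[-1])
            rel = np.max(np.abs(vec - prev_vec) / np.maximum(np.abs(prev_vec), 1e-12))
            if dofv < settings.ofv_tol and rel < settings.param_tol:
                converged = True
                prev_vec = vec
                break
        prev_vec = vec

    n_obs = len(dataset)
    n_params = (
        len(struct_names)
        + int(np.sum(omega > 0)) * 2  # typical value + variance per IIV parameter
        + (len(pop.sigma) if settings.estimate_sigma else 0)
    )
    bic = float(trace[-1] + n_params * np.log(n_obs))
    eta_df = pd.DataFrame(etas, columns=list(IIV_PARAMETERS))
    eta_df.insert(0, "SUBJ", [s.subj for s in subjects])
    return FitResult(
        population=pop,
        extra=extra,
        eta=eta_df,
        ofv=float(trace[-1]),
        bic=bic,
        n_obs=n_obs,
        n_params=n_params,
        trace=trace,
        converged=converged,
        variant=variant,
        inner_converged=inner_ok,
    )


# ---------------------------------------------------------------------------
# standard errors


def fisher_standard_errors(
    fit: FitResult,
    dataset: pd.DataFrame,
    names: tuple | None = None,
    design: StudyDesign | None = None,
    regimens: dict | None = None,
    dist: DarDistribution | None = None,
    step: float = 1e-3,
) -> dict:
    """Approximate %RSE of structural typical values at the fit optimum.

    Numerical Fisher information: the Hessian of the data log-likelihood
    with respect to the transformed (log/logit) structural parameters,
    computed by central differences with the random effects held at their
    MAP modes, then inverted.  For log-scale parameters the SD on the log
    scale is reported directly as %CV; logit-scale parameters use the
    delta method.  This conditions on the random-effect modes (a Laplace-
    style approximation), so the values are indicative precision, not an
    exact marginal-likelihood curvature.
    """
    dist = dist or default_dar_distribution()
    if design is None and regimens is None:
        design = build_monkey_study()
    vmodel = build_variant(fit.variant)
    subjects = prepare_subjects(dataset, design=design, regimens=regimens)
    eta_by_subj = {
        int(r["SUBJ"]): np.array([r[p] for p in IIV_PARAMETERS])
        for _, r in fit.eta.iterrows()
    }
    etas = [eta_by_subj.get(s.subj, np.zeros(len(IIV_PARAMETERS))) for s in subjects]
    pop, extra = fit.population, fit.extra
    if names is None:
        names = (*_ADC_FIELDS, *_MMAE_FIELDS, *fit.variant.extra_parameter_names())
    names = tuple(names)
    current = fit.theta
    z0 = np.array([_to_unconstrained(n, current[n]) for n in names])

    def loglik(z):
        vals = [_from_unconstrained(n, zi) for n, zi in zip(names, z)]
        pop_z, extra_z = _set_structural(pop, extra, names, vals)
        total = 0.0
        for sub, eta in zip(subjects, etas):
            adc_i, mm_i = pop_z.individual(eta)
            preds = _predict_subject(sub, adc_i, mm_i, dist, vmodel, extra_z)
            total += _subject_data_loglik(sub, preds, pop_z.sigma)
        return total

    p = len(names)
    H = np.zeros((p, p))
    f0 = loglik(z0)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        zi = z0.copy()
        zi[i] += step
        fp[i] = loglik(zi)
        zi[i] -= 2 * step
        fm[i] = loglik(zi)
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            zz = z0.copy()
            zz[i] += step
            zz[j] += step
            fpp = loglik(zz)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + f0
            ) / step**2
    info = -H
    try:
        cov = np.linalg.inv(info)
        se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # singular information: report NaN
        se_t = np.full(p, np.nan)
    out = {}
    for k, name in enumerate(names):
        theta = current[name]
        if name in _LOGIT_PARAMS:
            se_nat = se_t[k] * theta * (1.0 - theta)
            rse = 100.0 * se_nat / theta if theta > 0 else np.nan
        elif name == "gamma":
            rse = np.nan if theta == 0 else 100.0 * se_t[k] / abs(theta)
        else:
            rse = 100.0 * se_t[k]  # log-scale SD ~ CV
        out[name] = {"estimate": float(theta), "rse_percent": float(rse)}
    return out


# ---------------------------------------------------------------------------
# model comparison


def compare_models(fit_full: FitResult, fit_reduced: FitResult, df: int | None = None) -> dict:
    """Likelihood-ratio test of nested fits; returns dOFV, df and p-value."""
    if df is None:
        df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("the full model must have at least as many parameters")
    dofv = fit_reduced.ofv - fit_full.ofv
    if dofv < 0:
        warnings.warn(
            "reduced model has a lower OFV than the full model; "
            "likely an approximation artifact of the EM scheme"
        )
    p = 1.0 if df == 0 else float(stats.chi2.sf(max(dofv, 0.0), df))
    return {"delta_ofv": float(dofv), "df": int(df), "p_value": p}


def compare_nonnested(fit_a: FitResult, fit_b: FitResult) -> float:
    """Schwarz-criterion comparison: BIC(a) - BIC(b); negative favours a."""
    return float(fit_a.bic - fit_b.bic)
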