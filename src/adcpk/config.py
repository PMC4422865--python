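"""Structured (YAML) configuration for parameters, designs and settings.

Parameter keys use the conventional population-PK symbols (Emax, Km, Vc,
CLd, Vp, lambda, kappa, K, Fmp, Fmd, CLm, Vm, CLmd, Vmp); the ``iiv``
section holds random-effect variances (omega^2) under the same symbols and
``sigma`` the proportional residual-error SD per analyte.  The optional
``iiv_scale: sd`` switch reinterprets the ``iiv`` entries as standard
deviations instead of variances.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .estimate import FitSettings
from .params import (
    AdcParameters,
    DarDistribution,
    MmaeParameters,
    PopulationParameters,
)

__all__ = [
    "SYMBOL_TO_FIELD",
    "FIELD_TO_SYMBOL",
    "load_config",
    "save_config",
    "population_from_config",
    "population_to_config",
    "dar_distribution_from_config",
    "design_from_config",
    "design_to_config",
    "fit_settings_from_config",
]

SYMBOL_TO_FIELD = {
    "Emax": "emax",
    "Km": "km",
    "Vc": "vc",
    "CLd": "cld",
    "Vp": "vp",
    "lambda": "weibull_lambda",
    "kappa": "weibull_kappa",
    "K": "k_ref",
    "Fmp": "fmp",
    "Fmd": "fmd",
    "CLm": "clm",
    "Vm": "vm",
    "CLmd": "clmd",
    "Vmp": "vmp",
}
FIELD_TO_SYMBOL = {v: k for k, v in SYMBOL_TO_FIELD.items()}

_ADC_FIELDS = {
    "emax", "km", "vc", "cld", "vp",
    "weibull_lambda", "weibull_kappa", "k_ref", "fmp", "fmd",
}
_MMAE_FIELDS = {"clm", "vm", "clmd", "vmp"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def population_from_config(cfg: dict) -> PopulationParameters:
    """Build population parameters from a config mapping (defaults fill gaps)."""
    params = cfg.get("parameters", {}) or {}
    adc_kw, mm_kw = {}, {}
    for symbol, value in params.items():
        if symbol not in SYMBOL_TO_FIELD:
            raise ValueError(f"unknown parameter symbol {symbol!r}")
        f = SYMBOL_TO_FIELD[symbol]
        (adc_kw if f in _ADC_FIELDS else mm_kw)[f] = float(value)
    if "dar_mapping" in cfg:
        adc_kw["dar_mapping"] = str(cfg["dar_mapping"])
    iiv = cfg.get("iiv", {}) or {}
    omega_sq = {}
    as_sd = str(cfg.get("iiv_scale", "variance")).lower() in ("sd", "stdev")
    for symbol, value in iiv.items():
        if symbol not in SYMBOL_TO_FIELD:
            raise ValueError(f"unknown parameter symbol {symbol!r} in iiv")
        omega_sq[SYMBOL_TO_FIELD[symbol]] = float(value) ** 2 if as_sd else float(value)
    sigma = {str(k).lower(): float(v) for k, v in (cfg.get("sigma", {}) or {}).items()}
    kwargs = {}
    if omega_sq:
        kwargs["omega_sq"] = omega_sq
    if sigma:
        kwargs["sigma"] = sigma
    return PopulationParameters(
        adc=AdcParameters(**adc_kw), mmae=MmaeParameters(**mm_kw), **kwargs
    )


def population_to_config(pop: PopulationParameters) -> dict:
    params = {}
    for f in sorted(_ADC_FIELDS - {"dar_mapping"}):
        params[FIELD_TO_SYMBOL[f]] = float(getattr(pop.adc, f))
    for f in sorted(_MMAE_FIELDS):
        params[FIELD_TO_SYMBOL[f]] = float(getattr(pop.mmae, f))
    return {
        "parameters": params,
        "iiv": {FIELD_TO_SYMBOL[k]: float(v) for k, v in pop.omega_sq.items()},
        "iiv_scale": "variance",
        "sigma": {k: float(v) for k, v in pop.sigma.items()},
        "dar_mapping": pop.adc.dar_mapping,
    }


def dar_distribution_from_config(cfg: dict) -> DarDistribution | None:
    spec = cfg.get("dar_distribution")
    if spec is None:
        return None
    return DarDistribution.from_percent({int(k): float(v) for k, v in spec.items()})


def design_from_config(cfg: dict):
    """Build a :class:`~adcpk.design.StudyDesign` from a config mapping.

    Expects a ``design:`` section with an ``arms`` list; each arm has
    ``name``, ``compound``, ``dose_mgkg``, ``n_subjects``, ``dose_times``
    (hours) and ``schedule`` (analyte code -> sampling times), plus an
    optional ``body_weight_kg``.
    """
    from .design import Arm, StudyDesign
    from .params import DEFAULT_BODY_WEIGHT_KG

    section = cfg.get("design")
    if section is None:
        raise ValueError("config has no 'design' section")
    arms = [
        Arm(
            name=str(a["name"]),
            compound=str(a["compound"]),
            dose_level=float(a["dose_mgkg"]),
            n_subjects=int(a["n_subjects"]),
            dose_times=[float(t) for t in a["dose_times"]],
            schedule={str(k): [float(t) for t in v] for k, v in a["schedule"].items()},
            body_weight=float(a.get("body_weight_kg", DEFAULT_BODY_WEIGHT_KG)),
        )
        for a in section["arms"]
    ]
    design = StudyDesign(arms=arms)
    if "lloq" in section:
        design.lloq = {str(k): float(v) for k, v in section["lloq"].items()}
    return design


def design_to_config(design) -> dict:
    return {
        "design": {
            "arms": [
                {
                    "name": a.name,
                    "compound": a.compound,
                    "dose_mgkg": float(a.dose_level),
                    "n_subjects": int(a.n_subjects),
                    "dose_times": [float(t) for t in a.dose_times],
                    "schedule": {k: [float(t) for t in v] for k, v in a.schedule.items()},
                    "body_weight_kg": float(a.body_weight),
                }
                for a in design.arms
            ],
            "lloq": {k: float(v) for k, v in design.lloq.items()},
        }
    }


def fit_settings_from_config(cfg: dict) -> FitSettings:
    section = cfg.get("estimation", {}) or {}
    valid = set(asdict(FitSettings()))
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown estimation settings: {sorted(unknown)}")
    if "fix" in section:
        section["fix"] = tuple(section["fix"])
    return FitSettings(**section)
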