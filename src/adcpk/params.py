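"""Parameter containers for the multi-analyte ADC pharmacokinetic model.

The model tracks nine drug-to-antibody-ratio (DAR) species of an MMAE
antibody-drug conjugate in a two-compartment disposition system, coupled to
a two-compartment model of unconjugated MMAE.  Conjugate is lost by
saturable (Michaelis-Menten) proteolytic degradation and by sequential
DAR(n) -> DAR(n-1) deconjugation whose rate constant follows a Weibull
density in DAR.  All amounts are in nmol (antibody-nmol for conjugate
species, MMAE-nmol for the free toxin), volumes in litres, time in hours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MW_ANTIBODY",
    "MW_MMAE",
    "DEFAULT_BODY_WEIGHT_KG",
    "N_DAR",
    "AdcParameters",
    "MmaeParameters",
    "DarDistribution",
    "PopulationParameters",
    "IIV_PARAMETERS",
    "DEFAULT_DAR_FRACTIONS",
    "default_adc_parameters",
    "default_mmae_parameters",
    "default_dar_distribution",
    "default_population_parameters",
]

#: Molecular weight of the conjugate antibody (g/mol).
MW_ANTIBODY = 145239.0
#: Molecular weight of monomethyl auristatin E (g/mol).
MW_MMAE = 718.0
#: Typical cynomolgus monkey body weight (kg).
DEFAULT_BODY_WEIGHT_KG = 2.5
#: DAR species 0..8 inclusive.
N_DAR = 9


def _require_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass
class AdcParameters:
    """Structural parameters of conjugate disposition and catabolism.

    Attributes
    ----------
    emax : float
        Maximal proteolytic elimination rate per DAR species (nmol/h).
    km : float
        Conjugate concentration at half-maximal proteolysis (nmol/L).
    vc, vp : float
        Central and peripheral volumes of the conjugate (L).
    cld : float
        Conjugate distributional clearance (L/h).
    weibull_lambda, weibull_kappa : float
        Scale and shape of the Weibull law mapping DAR to the
        per-site deconjugation rate constant (dimensionless).
    k_ref : float
        Deconjugation scaling constant (1/h); fixed at 1 by convention.
    fmp, fmd : float
        Fractions of proteolysis- and deconjugation-released MMAE that
        appear as measurable unconjugated MMAE in the central circulation.
    dar_mapping : str
        How DAR n maps onto the Weibull abscissa x; one of ``"8-n"``
        (default), ``"9-n"`` or ``"n"``.  Provided for sensitivity
        analysis of the DAR-to-rate relationship.
    """

    emax: float = 0.0407
    km: float = 0.959
    vc: float = 0.0996
    cld: float = 0.00197
    vp: float = 0.183
    weibull_lambda: float = 1.51
    weibull_kappa: float = 1.10
    k_ref: float = 1.0
    fmp: float = 0.783
    fmd: float = 0.0242
    dar_mapping: str = "8-n"

    def __post_init__(self) -> None:
        for name in ("emax", "km", "vc", "cld", "vp", "weibull_lambda", "weibull_kappa"):
            _require_positive(name, getattr(self, name))
        if not np.isfinite(self.k_ref) or self.k_ref < 0:
            raise ValueError(f"k_ref must be >= 0, got {self.k_ref!r}")
        for name in ("fmp", "fmd"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.dar_mapping not in ("8-n", "9-n", "n"):
            raise ValueError(f"unknown dar_mapping {self.dar_mapping!r}")

    def replace(self, **kwargs) -> "AdcParameters":
        return replace(self, **kwargs)


@dataclass
class MmaeParameters:
    """Two-compartment linear disposition of unconjugated MMAE.

    ``clm`` is systemic clearance (L/h), ``vm`` the central volume (L),
    ``clmd`` the distributional clearance (L/h) and ``vmp`` the peripheral
    volume (L).
    """

    clm: float = 2.27
    vm: float = 1.00
    clmd: float = 23.0
    vmp: float = 88.4

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_positive(f.name, getattr(self, f.name))

    def replace(self, **kwargs) -> "MmaeParameters":
        return replace(self, **kwargs)


#: DAR-species molar percentages of the dosing solution as measured by
#: hydrophobic-interaction chromatography; species 3, 5 and 7 are absent.
DEFAULT_DAR_FRACTIONS = {0: 5.235, 1: 0.61, 2: 30.51, 4: 48.35, 6: 12.755, 8: 2.545}


class DarDistribution:
    """Molar fractions of antibody carrying n = 0..8 conjugated MMAE.

    Fractions must be non-negative; if they do not sum to one they are
    renormalised (with a warning) when ``renormalize=True``, otherwise an
    unnormalised vector is rejected.
    """

    def __init__(self, fractions, *, renormalize: bool = True, atol: float = 1e-9):
        arr = np.asarray(fractions, dtype=float)
        if arr.shape != (N_DAR,):
            raise ValueError(f"expected {N_DAR} fractions, got shape {arr.shape}")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("DAR fractions must be finite and non-negative")
        total = arr.sum()
        if total <= 0:
            raise ValueError("DAR fractions sum to zero")
        if abs(total - 1.0) > atol:
            if not renormalize:
                raise ValueError(
                    f"DAR fractions sum to {total:.6g}, not 1; pass renormalize=True"
                )
            warnings.warn(
                f"renormalising DAR fractions (sum was {total:.6g})",
                stacklevel=2,
            )
            arr = arr / total
        self.fraction = arr

    @classmethod
    def from_percent(cls, percent_by_dar: dict) -> "DarDistribution":
        arr = np.zeros(N_DAR)
        for n, pct in percent_by_dar.items():
            if not 0 <= int(n) < N_DAR:
                raise ValueError(f"DAR index {n} outside 0..{N_DAR - 1}")
            arr[int(n)] = pct / 100.0
        return cls(arr)

    def mean_dar(self) -> float:
        """Average drug-to-antibody ratio, sum_n n * fraction[n]."""
        return float(np.arange(N_DAR) @ self.fraction)

    def __eq__(self, other) -> bool:
        return isinstance(other, DarDistribution) and np.array_equal(
            self.fraction, other.fraction
        )

    def __repr__(self) -> str:
        return f"DarDistribution({self.fraction.tolist()})"


#: Names of parameters that carry log-normal inter-individual variability,
#: in canonical order.  The remaining structural parameters are shared by
#: all subjects.
IIV_PARAMETERS = ("emax", "vc", "vp", "fmd", "clm", "vmp")

_DEFAULT_OMEGA_SQ = {
    "emax": 0.0945,
    "vc": 0.0118,
    "vp": 0.230,
    "fmd": 1.78,
    "clm": 0.333,
    "vmp": 0.0670,
}

_DEFAULT_SIGMA = {"acmmae": 0.257, "tab": 0.194, "mmae": 0.327}


@dataclass
class PopulationParameters:
    """Typical structural values plus the statistical model.

    ``omega_sq`` maps parameter name -> variance of the log-normal random
    effect (only the six parameters in :data:`IIV_PARAMETERS` may carry
    variability).  ``sigma`` maps analyte -> proportional residual-error
    standard deviation on the reporting scale.
    """

    adc: AdcParameters = field(default_factory=AdcParameters)
    mmae: MmaeParameters = field(default_factory=MmaeParameters)
    omega_sq: dict = field(default_factory=lambda: dict(_DEFAULT_OMEGA_SQ))
    sigma: dict = field(default_factory=lambda: dict(_DEFAULT_SIGMA))

    def __post_init__(self) -> None:
        for name, var in self.omega_sq.items():
            if name not in IIV_PARAMETERS:
                raise ValueError(
                    f"random effect on {name!r} not supported; allowed: {IIV_PARAMETERS}"
                )
            if var < 0:
                raise ValueError(f"omega_sq[{name!r}] must be >= 0")
        for analyte, s in self.sigma.items():
            if analyte not in ("tab", "acmmae", "mmae"):
                raise ValueError(f"unknown analyte {analyte!r} in sigma")
            if s <= 0:
                raise ValueError(f"sigma[{analyte!r}] must be > 0")

    def omega_vector(self) -> np.ndarray:
        """Variances in :data:`IIV_PARAMETERS` order (zero where absent)."""
        return np.array([self.omega_sq.get(p, 0.0) for p in IIV_PARAMETERS])

    def individual(self, eta: np.ndarray) -> tuple[AdcParameters, MmaeParameters]:
        """Apply log-normal random effects ``eta`` (IIV_PARAMETERS order)."""
        eta = np.asarray(eta, dtype=float)
        if eta.shape != (len(IIV_PARAMETERS),):
            raise ValueError(f"eta must have shape ({len(IIV_PARAMETERS)},)")
        mult = {p: float(np.exp(e)) for p, e in zip(IIV_PARAMETERS, eta)}
        adc = self.adc.replace(
            emax=self.adc.emax * mult["emax"],
            vc=self.adc.vc * mult["vc"],
            vp=self.adc.vp * mult["vp"],
            fmd=min(1.0, self.adc.fmd * mult["fmd"]),
        )
        mm = self.mmae.replace(
            clm=self.mmae.clm * mult["clm"],
            vmp=self.mmae.vmp * mult["vmp"],
        )
        return adc, mm

    def replace(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


def default_adc_parameters() -> AdcParameters:
    """Final-model typical values for the conjugate."""
    return AdcParameters()


def default_mmae_parameters() -> MmaeParameters:
    """Final-model typical values for unconjugated MMAE."""
    return MmaeParameters()


def default_dar_distribution() -> DarDistribution:
    """Initial DAR distribution of the dosing solution (mean DAR ~3.5)."""
    with warnings.catch_warnings():
        # measured percentages sum to 100.005; renormalisation is intended
        warnings.simplefilter("ignore")
        return DarDistribution.from_percent(DEFAULT_DAR_FRACTIONS)


def default_population_parameters() -> PopulationParameters:
    """Typical values, IIV variances and residual errors of the final model."""
    return PopulationParameters()
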