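"""Structural model: ODE right-hand side, release fluxes and helpers.

State vector layout (22 states, all amounts in nmol):

====================  =======================================================
index                 meaning
====================  =======================================================
``0..8``              central conjugate amount per DAR species (antibody-nmol)
``9..17``             peripheral conjugate amount per DAR species
``18``                central unconjugated MMAE
``19``                peripheral unconjugated MMAE
``20``                cumulative MMAE released by proteolytic degradation
``21``                cumulative MMAE released by deconjugation
====================  =======================================================

Proteolysis and deconjugation act on central-compartment conjugate only.
Proteolysis of the DAR-n species releases n MMAE molecules per antibody;
deconjugation of DAR n moves the antibody to DAR n-1 and releases one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    MW_ANTIBODY,
    MW_MMAE,
    N_DAR,
    AdcParameters,
    DarDistribution,
    MmaeParameters,
)

__all__ = [
    "N_STATES",
    "IDX_XC",
    "IDX_XP",
    "IDX_XMC",
    "IDX_XMP",
    "IDX_AMP",
    "IDX_AMD",
    "DoseEvent",
    "AnalyteTriple",
    "deconjugation_rate",
    "deconjugation_rates",
    "mm_flux",
    "release_fluxes",
    "derivatives",
    "jacobian",
    "initial_state",
    "apply_dose",
    "observe",
    "observe_trajectory",
    "mean_dar",
    "two_compartment_halflives",
    "deconjugation_curve",
    "vc_per_kg",
    "tab_nm_to_ug_ml",
]

N_STATES = 22
IDX_XC = slice(0, 9)
IDX_XP = slice(9, 18)
IDX_XMC = 18
IDX_XMP = 19
IDX_AMP = 20
IDX_AMD = 21

_DAR = np.arange(N_DAR, dtype=float)


@dataclass(frozen=True)
class DoseEvent:
    """An instantaneous IV bolus of conjugate or unconjugated MMAE.

    ``amount`` is derived from the mg/kg dose level, the body weight and
    the compound's molecular weight, in nmol of antibody (conjugate) or
    nmol of MMAE.
    """

    time: float
    compound: str  # "conjugate" | "mmae"
    dose_level: float  # mg/kg
    body_weight: float  # kg

    def __post_init__(self) -> None:
        if self.compound not in ("conjugate", "mmae"):
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.dose_level < 0 or self.body_weight <= 0:
            raise ValueError("dose_level must be >= 0 and body_weight > 0")

    @property
    def amount(self) -> float:
        """Dose in nmol: dose_mg / MW * 1e6."""
        mw = MW_ANTIBODY if self.compound == "conjugate" else MW_MMAE
        dose_mg = self.dose_level * self.body_weight
        return dose_mg * 1e6 / mw  # mg -> nmol


@dataclass(frozen=True)
class AnalyteTriple:
    """The three measured analytes on their reporting scales.

    ``tab`` is total antibody in ug/mL, ``acmmae`` the antibody-conjugated
    MMAE in nM (DAR-weighted molar conjugate concentration) and ``mmae``
    unconjugated MMAE in nM.
    """

    tab: float
    acmmae: float
    mmae: float


def _weibull_x(n, mapping: str):
    n = np.asarray(n, dtype=float)
    if mapping == "8-n":
        return 8.0 - n
    if mapping == "9-n":
        return 9.0 - n
    if mapping == "n":
        return n
    raise ValueError(f"unknown dar_mapping {mapping!r}")


def deconjugation_rate(n: int, p: AdcParameters) -> float:
    """Per-site deconjugation rate constant K_ADCn (1/h) for DAR n.

    The rate follows a Weibull density in the transformed DAR
    ``x`` (default ``x = 8 - n``)::

        K_ADCn = K * (kappa/lambda) * (x/lambda)**(kappa-1) * exp(-(x/lambda)**kappa)

    With shape kappa > 1 the density vanishes at x = 0, so the default
    mapping gives an exactly zero rate for DAR 8.
    """
    if not (1 <= n <= 8):
        raise ValueError(f"DAR n must be in 1..8, got {n}")
    return float(deconjugation_rates(p)[n])


def deconjugation_rates(p: AdcParameters) -> np.ndarray:
    """Vector of K_ADCn for n = 0..8 (entry 0 is zero: nothing to shed)."""
    x = _weibull_x(_DAR, p.dar_mapping)
    lam, kap = p.weibull_lambda, p.weibull_kappa
    z = x / lam
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = (kap / lam) * z ** (kap - 1.0) * np.exp(-(z**kap))
    # at the Weibull origin the density is 0 for shape > 1, kappa/lambda at
    # shape = 1, and unbounded below 1 -- an infinite rate constant is
    # unphysical, so the origin rate is clamped to zero there as well
    origin = (kap / lam) if kap == 1.0 else 0.0
    dens = np.where(z > 0, dens, np.where(z == 0, origin, 0.0))
    rates = p.k_ref * dens
    rates[0] = 0.0  # DAR0 has no drug to deconjugate
    return rates


def mm_flux(x, p: AdcParameters):
    """Michaelis-Menten proteolytic elimination rate (nmol/h).

    ``emax * x / (km * vc + x)``; saturates at ``emax`` and is applied to
    each DAR species independently.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("conjugate amount must be >= 0")
    out = p.emax * x / (p.km * p.vc + x)
    return float(out) if out.ndim == 0 else out


def release_fluxes(xc: np.ndarray, adc: AdcParameters, kvec=None):
    """Instantaneous MMAE release (nmol MMAE/h) by pathway.

    Returns ``(amp, amd)``: total release via proteolytic degradation
    (each degraded DAR-n antibody frees its n drugs) and via
    deconjugation (one drug per event).
    """
    if kvec is None:
        kvec = deconjugation_rates(adc)
    prot = adc.emax * xc / (adc.km * adc.vc + xc)
    amp = float(_DAR @ prot)
    amd = float(_DAR @ (kvec * xc))
    return amp, amd


def derivatives(
    state: np.ndarray,
    t: float,
    adc: AdcParameters,
    mmae: MmaeParameters,
    kvec: np.ndarray | None = None,
) -> np.ndarray:
    """Time derivative of the 22-state system (pure function of state)."""
    if kvec is None:
        kvec = deconjugation_rates(adc)
    y = np.asarray(state, dtype=float)
    xc = y[IDX_XC]
    xp = y[IDX_XP]
    dy = np.empty(N_STATES)

    prot = adc.emax * xc / (adc.km * adc.vc + xc)
    decon = _DAR * kvec * xc  # species-level deconjugation flux

    dxc = -(adc.cld / adc.vc) * xc + (adc.cld / adc.vp) * xp - prot - decon
    dxc[:-1] += decon[1:]  # DAR n+1 -> n feeds the next species down
    dy[IDX_XC] = dxc
    dy[IDX_XP] = (adc.cld / adc.vc) * xc - (adc.cld / adc.vp) * xp

    amp = _DAR @ prot
    amd = decon.sum()
    xmc, xmp = y[IDX_XMC], y[IDX_XMP]
    dy[IDX_XMC] = (
        adc.fmp * amp
        + adc.fmd * amd
        - (mmae.clm / mmae.vm + mmae.clmd / mmae.vm) * xmc
        + (mmae.clmd / mmae.vmp) * xmp
    )
    dy[IDX_XMP] = (mmae.clmd / mmae.vm) * xmc - (mmae.clmd / mmae.vmp) * xmp
    dy[IDX_AMP] = amp
    dy[IDX_AMD] = amd
    return dy


def jacobian(
    state: np.ndarray,
    t: float,
    adc: AdcParameters,
    mmae: MmaeParameters,
    kvec: np.ndarray | None = None,
) -> np.ndarray:
    """Analytic Jacobian of :func:`derivatives`; speeds up stiff solvers."""
    if kvec is None:
        kvec = deconjugation_rates(adc)
    y = np.asarray(state, dtype=float)
    xc = y[IDX_XC]
    J = np.zeros((N_STATES, N_STATES))

    kmvc = adc.km * adc.vc
    dprot = adc.emax * kmvc / (kmvc + xc) ** 2  # d(mm_flux)/dx
    sk = _DAR * kvec  # species-level deconjugation rate constants

    for n in range(N_DAR):
        J[n, n] = -(adc.cld / adc.vc) - dprot[n] - sk[n]
        J[n, 9 + n] = adc.cld / adc.vp
        if n < 8:
            J[n, n + 1] += sk[n + 1]
        J[9 + n, n] = adc.cld / adc.vc
        J[9 + n, 9 + n] = -(adc.cld / adc.vp)

    J[IDX_XMC, :9] = adc.fmp * _DAR * dprot + adc.fmd * sk
    J[IDX_XMC, IDX_XMC] = -(mmae.clm / mmae.vm + mmae.clmd / mmae.vm)
    J[IDX_XMC, IDX_XMP] = mmae.clmd / mmae.vmp
    J[IDX_XMP, IDX_XMC] = mmae.clmd / mmae.vm
    J[IDX_XMP, IDX_XMP] = -(mmae.clmd / mmae.vmp)
    J[IDX_AMP, :9] = _DAR * dprot
    J[IDX_AMD, :9] = sk
    return J


def initial_state(dose: DoseEvent, dist: DarDistribution | None = None) -> np.ndarray:
    """State immediately after an IV bolus into a drug-free animal."""
    y = np.zeros(N_STATES)
    return apply_dose(y, dose, dist)


def apply_dose(
    state: np.ndarray, dose: DoseEvent, dist: DarDistribution | None = None
) -> np.ndarray:
    """Add a bolus to ``state`` (conjugate split over DAR species)."""
    y = np.array(state, dtype=float)
    if dose.compound == "conjugate":
        if dist is None:
            raise ValueError("conjugate dose requires a DarDistribution")
        y[IDX_XC] += dose.amount * dist.fraction
    else:
        y[IDX_XMC] += dose.amount
    return y


def tab_nm_to_ug_ml(conc_nm: float) -> float:
    """Convert antibody concentration from nmol/L to ug/mL."""
    return conc_nm * MW_ANTIBODY * 1e-6


def observe(
    state: np.ndarray, adc: AdcParameters, mmae: MmaeParameters
) -> AnalyteTriple:
    """Map the state to the three assayed analytes.

    Total antibody sums every DAR species (including DAR 0) in the central
    compartment; acMMAE is the DAR-weighted sum, i.e. the molar
    concentration of conjugated drug; unconjugated MMAE is the free toxin
    in its own central compartment.
    """
    y = np.asarray(state, dtype=float)
    xc = y[IDX_XC]
    tab_nm = xc.sum() / adc.vc
    acmmae = float(_DAR @ xc) / adc.vc
    free = y[IDX_XMC] / mmae.vm
    return AnalyteTriple(tab=tab_nm_to_ug_ml(tab_nm), acmmae=acmmae, mmae=free)


def observe_trajectory(
    states: np.ndarray, adc: AdcParameters, mmae: MmaeParameters
) -> dict:
    """Vectorised :func:`observe` over a (n_times, 22) state array."""
    Y = np.atleast_2d(np.asarray(states, dtype=float))
    xc = Y[:, IDX_XC]
    tab_nm = xc.sum(axis=1) / adc.vc
    return {
        "tab": tab_nm_to_ug_ml(tab_nm),
        "acmmae": xc @ _DAR / adc.vc,
        "mmae": Y[:, IDX_XMC] / mmae.vm,
    }


def mean_dar(dist: DarDistribution) -> float:
    """Average drug-to-antibody ratio of a distribution."""
    return dist.mean_dar()


def two_compartment_halflives(
    cl: float, v: float, cld: float, vp: float
) -> tuple[float, float]:
    """Distribution and elimination half-lives of a two-compartment model.

    The micro rate constants are k10 = cl/v, k12 = cld/v, k21 = cld/vp; the
    hybrid rate constants alpha >= beta are the roots of
    ``s**2 - (k10+k12+k21)*s + k10*k21``.  Returns ``(ln2/alpha, ln2/beta)``
    in the time unit of the clearances.
    """
    for name, val in (("cl", cl), ("v", v), ("cld", cld), ("vp", vp)):
        if not np.isfinite(val) or val <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {val!r}")
    k10 = cl / v
    k12 = cld / v
    k21 = cld / vp
    s = k10 + k12 + k21
    disc = np.sqrt(s * s - 4.0 * k10 * k21)
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ln2 = np.log(2.0)
    return float(ln2 / alpha), float(ln2 / beta)


def deconjugation_curve(p: AdcParameters):
    """Tabulate K_ADCn and the species-level rate n*K_ADCn for n = 1..8.

    Returns a list of dicts with keys ``dar``, ``k_adc`` (per-site rate
    constant, 1/h) and ``species_rate`` (n * K_ADCn, 1/h).
    """
    kvec = deconjugation_rates(p)
    return [
        {"dar": n, "k_adc": float(kvec[n]), "species_rate": float(n * kvec[n])}
        for n in range(1, N_DAR)
    ]


def vc_per_kg(vc_litres: float, body_weight_kg: float) -> float:
    """Central volume scaled to body weight, in mL/kg."""
    if vc_litres <= 0 or body_weight_kg <= 0:
        raise ValueError("vc and body weight must be > 0")
    return vc_litres * 1000.0 / body_weight_kg
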