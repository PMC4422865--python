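"""Numba-accelerated right-hand side and Jacobian.

Mirrors :func:`adcpk.model.derivatives` / :func:`adcpk.model.jacobian`
(same math, loop form instead of vector form) for use inside the ODE
solver's inner loop, generalised to cover the structural model variants:
a per-DAR proteolysis capacity, an optional additional linear proteolytic
clearance, and optional deconjugation in the peripheral compartment.
With the defaults (equal capacities, zero linear clearance, central-only
deconjugation) the kernel reduces bit-for-bit to the final model.
If numba is unavailable the pure-Python fallback is used transparently.
"""

from __future__ import annotations

import numpy as np

from .params import AdcParameters, MmaeParameters

try:  # pragma: no cover - exercised implicitly by the equivalence test
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# packed parameter vector layout for the jitted kernels
# [0] km*vc      [1] cld/vc   [2] cld/vp   [3] fmp   [4] fmd
# [5] clm/vm     [6] clmd/vm  [7] clmd/vmp
# [8] clp/vc (additional linear proteolytic clearance rate constant)
# [9] peripheral-deconjugation flag (0 or 1)
# [10:19] emax_n for n = 0..8 (nmol/h)   [19:28] K_ADCn for n = 0..8 (1/h)
N_PACKED = 28


def pack_params(
    adc: AdcParameters,
    mmae: MmaeParameters,
    kvec: np.ndarray,
    *,
    clp: float = 0.0,
    peripheral_deconjugation: bool = False,
    emax_by_dar: np.ndarray | None = None,
) -> np.ndarray:
    c = np.empty(N_PACKED)
    c[0] = adc.km * adc.vc
    c[1] = adc.cld / adc.vc
    c[2] = adc.cld / adc.vp
    c[3] = adc.fmp
    c[4] = adc.fmd
    c[5] = mmae.clm / mmae.vm
    c[6] = mmae.clmd / mmae.vm
    c[7] = mmae.clmd / mmae.vmp
    c[8] = clp / adc.vc
    c[9] = 1.0 if peripheral_deconjugation else 0.0
    c[10:19] = adc.emax if emax_by_dar is None else emax_by_dar
    c[19:28] = kvec
    return c


@njit(cache=False)
def rhs(y, t, c):  # noqa: ARG001 - odeint signature
    dy = np.zeros(22)
    amp = 0.0
    amd = 0.0
    for n in range(9):
        xc = y[n]
        xp = y[9 + n]
        prot = c[10 + n] * xc / (c[0] + xc) + c[8] * xc
        decon = n * c[19 + n] * xc
        dy[n] += -c[1] * xc + c[2] * xp - prot - decon
        if n > 0:
            dy[n - 1] += decon
        dy[9 + n] += c[1] * xc - c[2] * xp
        if c[9] > 0.0:
            decon_p = n * c[19 + n] * xp
            dy[9 + n] -= decon_p
            if n > 0:
                dy[9 + n - 1] += decon_p
            amd += decon_p
        amp += n * prot
        amd += decon
    xmc = y[18]
    xmp = y[19]
    dy[18] = c[3] * amp + c[4] * amd - (c[5] + c[6]) * xmc + c[7] * xmp
    dy[19] = c[6] * xmc - c[7] * xmp
    dy[20] = amp
    dy[21] = amd
    return dy


@njit(cache=False)
def jac(y, t, c):  # noqa: ARG001 - odeint signature
    J = np.zeros((22, 22))
    for n in range(9):
        xc = y[n]
        dprot = c[10 + n] * c[0] / (c[0] + xc) ** 2 + c[8]
        sk = n * c[19 + n]
        J[n, n] = -c[1] - dprot - sk
        J[n, 9 + n] = c[2]
        if n < 8:
            J[n, n + 1] += (n + 1) * c[20 + n]
        J[9 + n, n] = c[1]
        J[9 + n, 9 + n] = -c[2]
        if c[9] > 0.0:
            J[9 + n, 9 + n] -= sk
            if n < 8:
                J[9 + n, 9 + n + 1] += (n + 1) * c[20 + n]
            J[18, 9 + n] += c[4] * sk
            J[21, 9 + n] += sk
        J[18, n] = c[3] * n * dprot + c[4] * sk
        J[20, n] = n * dprot
        J[21, n] = sk
    J[18, 18] = -(c[5] + c[6])
    J[18, 19] = c[7]
    J[19, 18] = c[6]
    J[19, 19] = -c[7]
    return J
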