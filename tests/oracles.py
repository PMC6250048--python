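"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the range oracle
integrates the Bethe stopping power numerically, and the WEPL oracle is a
fixed-step midpoint rasterization of the geometry.
"""

from __future__ import annotations

import numpy as np

from protonct.phantom import compensator_contains, rsp_at

# Bethe stopping-power constants for liquid water
_K = 0.307075          # MeV cm^2 / mol
_Z_OVER_A = 0.5551     # water
_I_EV = 75.0           # mean excitation energy, eV
_ME_C2 = 0.5109989     # MeV
_MP_C2 = 938.272       # MeV


def bethe_stopping_power_water(energy_mev: float) -> float:
    """Electronic mass stopping power of water, MeV cm^2/g."""
    e_tot = energy_mev + _MP_C2
    gamma = e_tot / _MP_C2
    beta2 = 1.0 - 1.0 / gamma**2
    i_mev = _I_EV * 1e-6
    arg = 2.0 * _ME_C2 * beta2 * gamma**2 / i_mev
    return _K * _Z_OVER_A / beta2 * (np.log(arg) - beta2)


def bethe_water_range(energy_mev: float, e_min: float = 1.0, n: int = 4000) -> float:
    """CSDA range in water (mm) by trapezoidal integration of 1/S."""
    energies = np.linspace(e_min, energy_mev, n)
    inv_s = 1.0 / np.array([bethe_stopping_power_water(e) for e in energies])
    range_cm = np.trapezoid(inv_s, energies)  # density 1 g/cm^3
    return 10.0 * range_cm


def brute_force_wepl(entry, exit, phantom=None, compensator=None,
                     step: float = 0.01) -> float:
    """Midpoint-rule WEPL along a straight segment at 0.01 mm steps."""
    entry = np.asarray(entry, float)
    exit = np.asarray(exit, float)
    seg = exit - entry
    length = np.linalg.norm(seg)
    d = seg / length
    n = int(np.ceil(length / step))
    t = (np.arange(n) + 0.5) * (length / n)
    pts = entry + t[:, None] * d
    total = 0.0
    if phantom is not None:
        total += float(np.sum(rsp_at(pts, phantom))) * (length / n)
    if compensator is not None:
        inside = compensator_contains(pts, compensator)
        total += compensator.material.rsp * float(np.sum(inside)) * (length / n)
    return total


def enumerate_triples(m0, m60, m120, tolerance):
    """All strip-measurement triples passing the x-u-v consistency test
    (the brute-force candidate set, before exclusive assignment)."""
    out = []
    for i, a in enumerate(m0):
        for j, b in enumerate(m60):
            for k, c in enumerate(m120):
                if abs(a - b + c) <= tolerance:
                    out.append((i, j, k, a, (b - 0.5 * a) / (np.sqrt(3) / 2)))
    return out
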