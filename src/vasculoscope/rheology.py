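"""Empirical microvascular blood rheology.

Three diameter-dependent effects dominate blood flow in microvessels and
are captured here by the standard empirical closed forms fitted to in-vivo
microvascular data:

* the **Fahraeus effect** — the tube (resident) hematocrit H_T is lower
  than the discharge (flowing) hematocrit H_D because red cells travel
  faster than plasma in narrow tubes;
* the **Fahraeus–Lindqvist effect** — apparent viscosity depends strongly
  and non-monotonically on vessel diameter, with an additional wall-layer
  penalty in vivo captured by the (D/(D−1.1))² term;
* **plasma skimming / phase separation** — at diverging bifurcations red
  cells partition unequally between daughters, following a logit law in
  the fractional blood flow.

All coefficient sets live in :class:`RheologyParams` so alternates can be
swapped.  Diameters in µm, viscosities in cP, hematocrits as fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RheologyParams",
    "apparent_viscosity",
    "fahraeus_tube_hematocrit",
    "phase_separation",
]


@dataclass(frozen=True)
class RheologyParams:
    """Coefficients of the empirical rheology laws.

    Defaults are the standard in-vivo coefficient set.  ``visc_*`` enter the
    in-vivo apparent viscosity law, ``fahraeus_*`` the tube-hematocrit law,
    and ``ps_*`` the bifurcation phase-separation law (all scaled by
    (1−H_D)/D_f with D_f the feeder diameter in µm).
    """

    plasma_viscosity: float = 1.0  # cP
    # relative apparent viscosity at H_D = 0.45: mu45 = a*exp(b*D) + c + d*exp(e*D^f)
    visc_a: float = 6.0
    visc_b: float = -0.085
    visc_c: float = 3.2
    visc_d: float = -2.44
    visc_e: float = -0.06
    visc_f: float = 0.645
    # shape exponent C of the hematocrit dependence
    visc_wall_offset: float = 1.1  # µm, effective wall-layer reduction of lumen
    # Fahraeus law: H_T/H_D = H_D + (1-H_D)*(1 + f1*exp(f2*D) + f3*exp(f4*D))
    fahraeus_f1: float = 1.7
    fahraeus_f2: float = -0.415
    fahraeus_f3: float = -0.6
    fahraeus_f4: float = -0.011
    # phase separation: A, B, X0 prefactors
    ps_a: float = -13.29
    ps_b: float = 6.98
    ps_x0: float = 0.964

    def mu45(self, d):
        """Relative apparent viscosity at H_D = 0.45, diameter d in µm."""
        d = np.asarray(d, dtype=float)
        return self.visc_a * np.exp(self.visc_b * d) + self.visc_c + self.visc_d * np.exp(
            self.visc_e * d**self.visc_f
        )

    def shape_exponent(self, d):
        """Exponent C controlling the curvature of μ(H_D)."""
        d = np.asarray(d, dtype=float)
        dampen = 1.0 / (1.0 + 1e-11 * d**12)
        return (0.8 + np.exp(-0.075 * d)) * (-1.0 + dampen) + dampen


def apparent_viscosity(diameter, hd, params: RheologyParams = RheologyParams()):
    """In-vivo apparent blood viscosity, cP.

    Evaluates the empirical in-vivo viscosity law

    .. math::

       \\mu = \\mu_p \\Big[1 + (\\mu^*_{45} - 1)
              \\frac{(1-H_D)^C - 1}{(1-0.45)^C - 1}
              \\Big(\\frac{D}{D-1.1}\\Big)^2\\Big]
              \\Big(\\frac{D}{D-1.1}\\Big)^2

    Strictly increasing in H_D at fixed diameter; at H_D = 0 it reduces to
    plasma viscosity times the wall-layer factor (D/(D−1.1))².

    Parameters
    ----------
    diameter : array_like, µm (> wall offset, 1.1 µm)
    hd : array_like, discharge hematocrit in [0, 1)
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hd, dtype=float)
    if np.any(d <= params.visc_wall_offset):
        raise ValueError(f"diameter must exceed {params.visc_wall_offset} µm")
    if np.any((h < 0) | (h >= 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1)")
    wall = (d / (d - params.visc_wall_offset)) ** 2
    c = params.shape_exponent(d)
    hterm = ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)
    mu_rel = (1.0 + (params.mu45(d) - 1.0) * hterm * wall) * wall
    out = params.plasma_viscosity * mu_rel
    return out if out.shape else float(out)


def fahraeus_tube_hematocrit(diameter, hd, params: RheologyParams = RheologyParams()):
    """Tube hematocrit H_T from discharge hematocrit via the Fahraeus law.

    H_T/H_D = H_D + (1−H_D)(1 + 1.7 e^{−0.415 D} − 0.6 e^{−0.011 D});
    H_T ≤ H_D for physiologic diameters and H_T → H_D in large tubes.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hd, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1]")
    ratio = h + (1.0 - h) * (
        1.0
        + params.fahraeus_f1 * np.exp(params.fahraeus_f2 * d)
        + params.fahraeus_f3 * np.exp(params.fahraeus_f4 * d)
    )
    out = np.minimum(ratio, 1.0) * h  # clamp: law exceeds 1 only below ~2.6 µm
    return out if out.shape else float(out)


def _logit(x):
    return np.log(x / (1.0 - x))


def phase_separation(
    frac_flow_alpha: float,
    d_feeder: float,
    d_alpha: float,
    d_beta: float,
    hd_feeder: float,
    params: RheologyParams = RheologyParams(),
) -> float:
    """Fraction of red-cell flux entering daughter α at a diverging bifurcation.

    Empirical logit law: with FQ_B the fractional blood flow into α,

        FQ_E = 0                         for FQ_B ≤ X0
        logit FQ_E = A + B logit[(FQ_B − X0)/(1 − 2 X0)]   for X0 < FQ_B < 1−X0
        FQ_E = 1                         for FQ_B ≥ 1 − X0

    A = −13.29 [(D_α²−D_β²)/(D_α²+D_β²)] (1−H_D)/D_f,
    B = 1 + 6.98 (1−H_D)/D_f,  X0 = 0.964 (1−H_D)/D_f  (diameters in µm).
    The complementary daughter receives 1 − FQ_E, so red-cell flux is
    conserved exactly.
    """
    if not (0.0 <= frac_flow_alpha <= 1.0):
        raise ValueError("fractional flow must lie in [0, 1]")
    scale = (1.0 - hd_feeder) / d_feeder
    x0 = min(params.ps_x0 * scale, 0.4999)
    if frac_flow_alpha <= x0:
        return 0.0
    if frac_flow_alpha >= 1.0 - x0:
        return 1.0
    ratio2 = (d_alpha**2 - d_beta**2) / (d_alpha**2 + d_beta**2)
    a = params.ps_a * ratio2 * scale
    b = 1.0 + params.ps_b * scale
    logit_inner = _logit((frac_flow_alpha - x0) / (1.0 - 2.0 * x0))
    z = a + b * logit_inner
    return float(1.0 / (1.0 + np.exp(-z)))
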