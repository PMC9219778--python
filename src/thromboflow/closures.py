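"""Algebraic closures of the continuum thrombosis-risk model.

Everything in this module is pure and grid-free: scalar shear stress,
threshold (gating) functions, shear-dependent diffusivities, clot-amplified
viscosity and the clot momentum-sink coefficient.  All functions accept
scalars or numpy arrays and broadcast.

Units
-----
SI throughout, with one documented exception: coagulation-factor (CFs) and
thrombotic-clot (TCs) concentrations are carried in a fixed internal unit of
nmol/L (= 1e-6 mol/m^3).  Their thresholds (``CF0 = 10``, ``TC0 = 200``) are
expressed in that unit.  Every place the model consumes CFs or TCs it does so
through a ratio against its threshold, so the choice of unit cancels; only the
release coefficient ``k_CFs`` (mol per platelet) needs an explicit conversion,
which is :data:`CONC_UNIT`.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import InvalidInputError

__all__ = [
    "CONC_UNIT",
    "ModelParameters",
    "Thresholds",
    "scalar_shear_stress",
    "threshold_factor",
    "platelet_diffusivity",
    "cf_effective_diffusivity",
    "thrombus_viscosity",
    "momentum_sink",
]

#: mol/m^3 per internal concentration unit (1 nmol/L).
CONC_UNIT = 1.0e-6


class ModelParameters(BaseModel):
    """Rate constants, diffusivities and fluid properties of the model.

    Defaults are the published coefficient set for human blood in a
    rotary blood pump; see docs/methods.md for provenance and units.

    Attributes
    ----------
    D_RT : float
        Self-diffusivity of blood carried by the residence-time tracer, m^2/s.
    k1 : float
        Shear-driven platelet activation rate, 1/s.
    k2 : float
        Coagulation-factor-driven activation rate, 1/s.
    k_CFs : float
        Amount of coagulation factors released per activated platelet, mol.
    D_pt : float
        Baseline (Brownian) platelet diffusivity, m^2/s.
    alpha : float
        Shear-enhanced platelet diffusivity coefficient, m^2.
    D_c : float
        Coagulation-factor base diffusivity, m^2/s.
    k_TCs : float
        Clot source coefficient, internal concentration units (nmol/L) per
        second.
    k_M : float
        Momentum-sink (Brinkman) coefficient, kg/(m^3 s).
    mu0 : float
        Plasma viscosity, Pa s.
    rho : float
        Blood density, kg/m^3.
    k_ceff : float
        Magnitude of the low-shear wall coagulation-factor flux,
        (nmol/L) m/s.  No published value exists; the default keeps the wall
        source small next to the bulk release term.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    D_RT: float = 1.14e-11
    k1: float = 0.3
    k2: float = 0.1
    k_CFs: float = 3.0e-17
    D_pt: float = 1.6e-13
    alpha: float = 7.0e-13
    D_c: float = 1.0e-8
    k_TCs: float = 2.0e-2
    k_M: float = 1.0e7
    mu0: float = 0.0035
    rho: float = 1055.0
    k_ceff: float = 1.0e-6

    @model_validator(mode="after")
    def _check_positive(self) -> "ModelParameters":
        for name, value in self.__dict__.items():
            if name == "k_ceff":
                if value < 0:
                    raise ValueError(f"{name} must be >= 0, got {value}")
            elif not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        return self


class Thresholds(BaseModel):
    """Reaction thresholds and the common reaction-cutoff fraction.

    A transported quantity only drives its reaction once it exceeds
    ``cutoff_fraction`` times its threshold; above the cutoff the drive is the
    plain ratio value/threshold (see :func:`threshold_factor`).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    RT0: float = 1.0  # s
    NPSS0: float = 35.0  # Pa
    gamma0: float = 100.0  # 1/s
    CF0: float = 10.0  # nmol/L
    TC0: float = 200.0  # nmol/L
    cutoff_fraction: float = 0.4

    @model_validator(mode="after")
    def _check(self) -> "Thresholds":
        for name in ("RT0", "NPSS0", "gamma0", "CF0", "TC0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.cutoff_fraction < 1.0:
            raise ValueError("cutoff_fraction must lie in [0, 1)")
        return self


def scalar_shear_stress(grad_v, mu):
    """Scalar shear stress (SSS) of a velocity-gradient tensor.

    The viscous stress tensor is symmetrized,
    ``sigma_ij = mu * (dv_i/dx_j + dv_j/dx_i)``, and collapsed to the scalar
    invariant

        sigma = sqrt( 1/6 * sum_{i<j} (sigma_ii - sigma_jj)^2
                      + sum_{i<j} sigma_ij^2 )

    which is ``sqrt(J2)`` of the stress deviator: frame-invariant, zero for
    rigid motion, and equal to ``mu * gamma_dot`` in simple shear (so a shear
    rate of 10 000 1/s at mu = 3.5 mPa s maps to exactly 35 Pa).

    Parameters
    ----------
    grad_v : array_like, shape (..., 2, 2) or (..., 3, 3)
        Velocity-gradient tensor(s) ``grad_v[..., i, j] = dv_i/dx_j`` in 1/s.
        2x2 input is treated as planar flow (zero third row/column).
    mu : float or array_like
        Dynamic viscosity, Pa s; broadcasts against the leading axes.

    Returns
    -------
    ndarray or float
        SSS in Pa, same leading shape as ``grad_v``.
    """
    g = np.asarray(grad_v, dtype=float)
    if g.shape[-2:] not in ((2, 2), (3, 3)):
        raise InvalidInputError(
            f"grad_v must have trailing shape (2, 2) or (3, 3), got {g.shape}"
        )
    if not np.all(np.isfinite(g)):
        raise InvalidInputError("grad_v contains non-finite entries")
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(mu_arr <= 0) or not np.all(np.isfinite(mu_arr)):
        raise InvalidInputError("mu must be finite and > 0")
    if g.shape[-1] == 2:
        pad = np.zeros(g.shape[:-2] + (3, 3), dtype=float)
        pad[..., :2, :2] = g
        g = pad
    sig = mu_arr[..., None, None] * (g + np.swapaxes(g, -1, -2))
    d01 = sig[..., 0, 0] - sig[..., 1, 1]
    d02 = sig[..., 0, 0] - sig[..., 2, 2]
    d12 = sig[..., 1, 1] - sig[..., 2, 2]
    off = sig[..., 0, 1] ** 2 + sig[..., 0, 2] ** 2 + sig[..., 1, 2] ** 2
    out = np.sqrt((d01**2 + d02**2 + d12**2) / 6.0 + off)
    return out if out.ndim else float(out)


def threshold_factor(value, threshold, cutoff_fraction=0.4):
    """Threshold gating function phi = value/threshold with a hard cutoff.

    Returns ``value / threshold`` where ``value >= cutoff_fraction *
    threshold`` and 0 below: reactions driven by a quantity well under its
    threshold are treated as completely stopped.

    Parameters are broadcastable arrays; ``value`` must be >= 0 and
    ``threshold`` > 0.
    """
    v = np.asarray(value, dtype=float)
    th = np.asarray(threshold, dtype=float)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise InvalidInputError("value must be finite and >= 0")
    if np.any(th <= 0):
        raise InvalidInputError("threshold must be > 0")
    phi = np.where(v >= cutoff_fraction * th, v / th, 0.0)
    return phi if phi.ndim else float(phi)


def platelet_diffusivity(npss, mu, params: ModelParameters):
    """Shear-enhanced platelet diffusivity ``D_p = D_pt + alpha * NPSS / mu``.

    ``NPSS / mu`` recovers the shear rate, so the enhancement is
    ``alpha * gamma_dot``; monotone nondecreasing in the shear stress.
    Units: m^2/s.
    """
    npss_arr = np.asarray(npss, dtype=float)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(npss_arr < 0):
        raise InvalidInputError("npss must be >= 0")
    if np.any(mu_arr <= 0):
        raise InvalidInputError("mu must be > 0")
    out = params.D_pt + params.alpha * npss_arr / mu_arr
    return out if out.ndim else float(out)


def cf_effective_diffusivity(gamma, thresholds: Thresholds, params: ModelParameters):
    """Effective coagulation-factor diffusivity ``D_ceff = D_c * phi_gamma``.

    The base diffusivity is gated by the shear rate against ``gamma0``:
    in near-stagnant flow the factors do not disperse.
    """
    phi = threshold_factor(gamma, thresholds.gamma0, thresholds.cutoff_fraction)
    out = params.D_c * np.asarray(phi, dtype=float)
    return out if out.ndim else float(out)


def thrombus_viscosity(phi_tc, mu0):
    """Clot-amplified effective viscosity ``mu = mu0 * (1 + 100 * phi_TC)``."""
    phi = np.asarray(phi_tc, dtype=float)
    if np.any(phi < 0):
        raise InvalidInputError("phi_tc must be >= 0")
    out = mu0 * (1.0 + 100.0 * phi)
    return out if out.ndim else float(out)


def momentum_sink(phi_tc, velocity, k_M):
    """Brinkman momentum sink ``f = -k_M * phi_TC * v`` (force density).

    A velocity-proportional resistive body force modelling the obstruction of
    flow by a growing clot: zero where no clot drive exists, always
    anti-parallel to the local velocity.  Units: N/m^3 given k_M in
    kg/(m^3 s) and v in m/s.
    """
    phi = np.asarray(phi_tc, dtype=float)
    if np.any(phi < 0):
        raise InvalidInputError("phi_tc must be >= 0")
    v = np.asarray(velocity, dtype=float)
    out = -k_M * phi[..., None] * v if v.ndim > phi.ndim else -k_M * phi * v
    return out
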