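"""Baseline BOLD biophysics: susceptibility model of the resting signal.

The BOLD fractional signal change is modelled with the standard power-law
(Davis-type) form

    dS/S0 = M * (1 - (CMRO2/CMRO2|0)^beta * (CBV/CBV0) * (CBF/CBF0)^-beta)

where M is the susceptibility scaling factor set by the baseline deoxy-Hb
content, echo time and field strength. The off-resonance frequency shift of
blood relative to tissue is

    delta_omega = gamma * (4/3) * pi * dchi0 * Hct * OEF * B0

(with gamma the gyromagnetic ratio, dchi0 the susceptibility difference
between fully oxy- and deoxygenated blood). When the arterial inflow is not
fully saturated (SaO2 < 1), the baseline deoxy-Hb density gains an inflow
contribution: the deoxygenated fraction of venous haemoglobin is
SaO2*OEF + (1 - SaO2), which makes the baseline BOLD signal a monotone
increasing function of SaO2. Only zeros, signs, ratios and linearity of these
expressions are relied on downstream; M carries an arbitrary-units scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhysioParams",
    "off_resonance_shift",
    "bold_susceptibility_factor",
    "bold_fraction",
    "sao2_bold_shift",
]


@dataclass(frozen=True)
class PhysioParams:
    """Physiological and acquisition parameters of the baseline BOLD model.

    Defaults are standard physiological values at 3 T: OEF 45%, tissue blood
    volume fraction 3%, hematocrit 40%, TE 30 ms.
    """

    OEF: float = 0.45          # oxygen extraction fraction
    Hct: float = 0.40          # hematocrit (volume fraction)
    CBV0: float = 0.03         # baseline tissue blood volume fraction
    TE: float = 0.030          # echo time, s
    B0: float = 3.0            # field strength, T
    gamma: float = 42.58       # gyromagnetic ratio, MHz/T
    delta_chi0: float = 0.264e-6  # susceptibility difference oxy vs deoxy blood (SI)
    beta_exp: float = 1.5      # power-law exponent beta
    SaO2: float = 1.0          # arterial (inflow) oxygen saturation
    kappa: float = 1.0         # arbitrary-units scale absorbed into M

    def __post_init__(self) -> None:
        for name in ("OEF", "Hct", "CBV0", "SaO2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("TE", "B0", "gamma", "delta_chi0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _gamma_rad_per_s_t(p: PhysioParams) -> float:
    """Gyromagnetic ratio converted from MHz/T to rad/s/T."""
    return 2.0 * np.pi * p.gamma * 1e6


def _deoxy_fraction(p: PhysioParams, sao2: float | np.ndarray | None = None):
    """Deoxygenated fraction of venous haemoglobin, including inflow deoxy-Hb."""
    s = p.SaO2 if sao2 is None else np.asarray(sao2, dtype=float)
    return s * p.OEF + (1.0 - s)


def off_resonance_shift(p: PhysioParams) -> float:
    """Blood/tissue off-resonance shift delta_omega in rad/s.

    Assumes fully saturated inflow (OEF is then the only deoxy-Hb source).
    """
    return _gamma_rad_per_s_t(p) * (4.0 / 3.0) * np.pi * p.delta_chi0 * p.Hct * p.OEF * p.B0


def _off_resonance_shift_sao2(p: PhysioParams, sao2=None):
    """Off-resonance shift with the (1 - SaO2) inflow contribution included."""
    return (
        _gamma_rad_per_s_t(p)
        * (4.0 / 3.0)
        * np.pi
        * p.delta_chi0
        * p.Hct
        * _deoxy_fraction(p, sao2)
        * p.B0
    )


def bold_susceptibility_factor(p: PhysioParams, sao2=None):
    """M, the scaling factor of the BOLD susceptibility effect (arbitrary units).

    M = kappa * TE * CBV0 * delta_omega_base^beta, with the baseline deoxy-Hb
    density (and hence delta_omega_base) carrying the inflow contribution when
    SaO2 < 1.
    """
    return p.kappa * p.TE * p.CBV0 * _off_resonance_shift_sao2(p, sao2) ** p.beta_exp


def bold_fraction(
    p: PhysioParams,
    cmro2_ratio: float | np.ndarray = 1.0,
    cbf_ratio: float | np.ndarray = 1.0,
    cbv_ratio: float | np.ndarray = 1.0,
):
    """Fractional BOLD signal change dS/S0 for given physiological ratios.

    All ratios are relative to baseline; at baseline (all 1) the change is
    exactly zero, and for cbf_ratio -> inf (others 1) the limit is M.
    """
    cmro2_ratio = np.asarray(cmro2_ratio, dtype=float)
    cbf_ratio = np.asarray(cbf_ratio, dtype=float)
    cbv_ratio = np.asarray(cbv_ratio, dtype=float)
    if np.any(cmro2_ratio <= 0) or np.any(cbf_ratio <= 0) or np.any(cbv_ratio <= 0):
        raise ValueError("physiological ratios must be positive")
    M = bold_susceptibility_factor(p)
    val = M * (1.0 - cmro2_ratio**p.beta_exp * cbv_ratio * cbf_ratio ** (-p.beta_exp))
    return float(val) if val.ndim == 0 else val


def sao2_bold_shift(p: PhysioParams, sao2: float | np.ndarray):
    """Baseline BOLD signal offset vs the fully saturated (SaO2 = 1) state.

    dS/S0(SaO2) = -TE * [R2'(SaO2) - R2'(1)], with R2' = kappa*CBV0*dw^beta.
    Monotone decreasing as SaO2 falls: desaturated inflow adds deoxy-Hb.
    """
    sao2 = np.asarray(sao2, dtype=float)
    if np.any(sao2 < 0) or np.any(sao2 > 1):
        raise ValueError("SaO2 must lie in [0, 1]")
    r2p = p.kappa * p.CBV0 * _off_resonance_shift_sao2(p, sao2) ** p.beta_exp
    r2p0 = p.kappa * p.CBV0 * _off_resonance_shift_sao2(p, 1.0) ** p.beta_exp
    val = -p.TE * (r2p - r2p0)
    return float(val) if val.ndim == 0 else val
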