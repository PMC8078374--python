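"""Optical forward model for two-wavelength pulse oximetry.

Pulse oximetry exploits the fact that oxygenated (HbO2) and deoxygenated
(Hb) hemoglobin absorb red and infrared light very differently: around
660 nm Hb absorbs several times more strongly than HbO2, while around
940 nm the ordering reverses.  Under a Beer-Lambert description of the
pulsatile light path, the effective extinction seen by each LED channel is
the saturation-weighted mixture of the two species' extinctions, so the
ratio of the red to infrared pulsatile modulations (the "ratio of ratios"
R) is a monotone, nearly linear function of arterial saturation.

This module holds the extinction constants, the saturation arithmetic and
the closed-form modulation ratio used as an oracle by the synthesizer and
the DSP estimator tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

#: Channel indices used consistently across the package.
RED, INFRARED, GREEN = 0, 1, 2

_CHANNEL_NAMES = ("red", "infrared", "green")


@dataclass(frozen=True)
class OpticalConstants:
    """Per-wavelength molar extinction coefficients of Hb and HbO2.

    Units are L·mmol⁻¹·cm⁻¹; channel order is (red, infrared, green).
    """

    wavelengths_nm: tuple[float, float, float]
    eps_hb: tuple[float, float, float]
    eps_hbo2: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.wavelengths_nm) != 3 or len(self.eps_hb) != 3 or len(self.eps_hbo2) != 3:
            raise ValueError("expected exactly three channels (red, infrared, green)")
        if any(e <= 0 for e in self.eps_hb) or any(e <= 0 for e in self.eps_hbo2):
            raise ValueError("extinction coefficients must be strictly positive")
        # Spectral shape that makes the modulation ratio informative:
        # Hb dominates in the red, HbO2 dominates in the infrared.
        if not self.eps_hb[RED] > self.eps_hbo2[RED]:
            raise ValueError("red channel must have eps_hb > eps_hbo2")
        if not self.eps_hbo2[INFRARED] > self.eps_hb[INFRARED]:
            raise ValueError("infrared channel must have eps_hbo2 > eps_hb")

    @classmethod
    def default(cls) -> "OpticalConstants":
        """Load the packaged default extinction table."""
        with resources.files("wristox.data").joinpath("optical_defaults.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        return cls(
            wavelengths_nm=tuple(raw["wavelengths_nm"]),
            eps_hb=tuple(raw["eps_hb"]),
            eps_hbo2=tuple(raw["eps_hbo2"]),
        )


def functional_saturation(hbo2_conc, hb_conc):
    """Functional arterial oxygen saturation [HbO2]/([HbO2]+[Hb]).

    Carboxy- and methemoglobin are neglected.  Accepts scalars or arrays;
    both concentrations must be non-negative and not simultaneously zero.
    """
    hbo2 = np.asarray(hbo2_conc, dtype=float)
    hb = np.asarray(hb_conc, dtype=float)
    if np.any(hbo2 < 0) or np.any(hb < 0):
        raise ValueError("hemoglobin concentrations must be non-negative")
    total = hbo2 + hb
    if np.any(total == 0):
        raise ValueError("saturation undefined: total hemoglobin is zero")
    out = hbo2 / total
    return float(out) if out.ndim == 0 else out


def pulsatile_absorbance(s, constants: OpticalConstants, channel: int):
    """Effective extinction of pulsatile arterial blood at saturation ``s``.

    Beer-Lambert mixture rule: eps_eff = s·eps_HbO2 + (1−s)·eps_Hb at the
    channel's wavelength.  ``s`` is a fraction in [0, 1]; scalar or array.
    """
    if channel not in (RED, INFRARED, GREEN):
        raise ValueError(f"unknown wavelength index {channel!r}")
    s_arr = np.asarray(s, dtype=float)
    tol = 1e-9  # tolerate float round-off at the endpoints
    if np.any(s_arr < -tol) or np.any(s_arr > 1 + tol):
        raise ValueError("saturation must lie in [0, 1]")
    s_arr = np.clip(s_arr, 0.0, 1.0)
    out = s_arr * constants.eps_hbo2[channel] + (1.0 - s_arr) * constants.eps_hb[channel]
    return float(out) if out.ndim == 0 else out


def analytic_modulation_ratio(s, constants: OpticalConstants):
    """Closed-form ratio of red to infrared pulsatile extinctions.

    This is the noiseless modulation ratio R(s) the forward model bakes
    into synthesized PPG, and the oracle the DSP path is checked against.
    Strictly decreasing in s given the spectral-shape invariants.
    """
    num = pulsatile_absorbance(s, constants, RED)
    den = pulsatile_absorbance(s, constants, INFRARED)
    return num / den


def channel_name(channel: int) -> str:
    return _CHANNEL_NAMES[channel]
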