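"""Acquisition and physiological parameters for WEPCAST MRI modeling.

All times are in milliseconds, CBF in mL/100 g/min. The time origin is
t = 0 at the start of the pCASL labeling train; the image is acquired at
``t_acq = tau + pld``. Background-suppression (bs) inversion pulses are
specified by their instants relative to labeling start and are modeled as
instantaneous sign flips of longitudinal magnetization with a per-pulse
efficiency.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Tuple

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Sex",
    "AcquisitionProtocol",
    "PhysioParams",
    "default_t1_blood",
    "arterial_transit_from_venous",
]

#: Sex-specific venous blood T1 defaults at 3 T, ms.
T1_BLOOD_FEMALE = 1742.0
T1_BLOOD_MALE = 1667.0

#: Default example bs schedule (ms after labeling start) for the default
#: tau=4 s / PLD=3 s protocol. Mid-sequence inversions create the transient
#: tissue/blood T1 contrast that makes the control signal sensitive to the
#: venous transit time; without bs pulses the control signal is identically
#: at equilibrium and the two-parameter inversion is singular.
DEFAULT_BS_TIMES: Tuple[float, float] = (1600.0, 2900.0)


class Sex(str, Enum):
    male = "male"
    female = "female"


def default_t1_blood(sex: "Sex | str") -> float:
    """Sex-specific default venous blood T1 in ms (female 1742, male 1667)."""
    sex = Sex(sex)
    return T1_BLOOD_FEMALE if sex is Sex.female else T1_BLOOD_MALE


def arterial_transit_from_venous(delta_v: float, att_ratio: float = 0.555) -> float:
    """Arterial transit time from venous transit time, delta_a = ratio * delta_v.

    The model ties the labeling-plane-to-capillary transit time to the
    capillary-to-vein transit time through a fixed ratio (default 0.555,
    from literature values delta_a = 1901 ms and delta_v = 3423 ms).
    """
    if not (delta_v >= 0):
        raise ValueError(f"delta_v must be >= 0, got {delta_v}")
    if att_ratio < 0:
        raise ValueError(f"att_ratio must be >= 0, got {att_ratio}")
    return att_ratio * delta_v


class AcquisitionProtocol(BaseModel):
    """Timing of the WEPCAST acquisition.

    Parameters
    ----------
    tau:
        Labeling duration, ms (> 0).
    pld:
        Post-labeling delay, ms (>= 0). Acquisition occurs at tau + pld.
    bs_times:
        Background-suppression inversion instants, ms after labeling start;
        strictly increasing, each inside (0, tau + pld).
    bs_efficiency:
        Per-pulse inversion efficiency in [0, 1]; 1 is an ideal adiabatic
        inversion.
    m0_tr:
        Repetition time of the M0 normalization scan, ms.
    """

    model_config = ConfigDict(frozen=True)

    tau: float = 4000.0
    pld: float = 3000.0
    bs_times: Tuple[float, ...] = DEFAULT_BS_TIMES
    bs_efficiency: float = 1.0
    m0_tr: float = 10000.0

    @property
    def t_acq(self) -> float:
        """Acquisition time, ms, with origin at labeling start (= tau + pld)."""
        return self.tau + self.pld

    @field_validator("tau")
    @classmethod
    def _tau_pos(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("tau must be > 0")
        return v

    @field_validator("pld")
    @classmethod
    def _pld_nonneg(cls, v: float) -> float:
        if not v >= 0:
            raise ValueError("pld must be >= 0")
        return v

    @field_validator("bs_efficiency")
    @classmethod
    def _eff_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("bs_efficiency must be in [0, 1]")
        return v

    @field_validator("m0_tr")
    @classmethod
    def _m0tr_pos(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("m0_tr must be > 0")
        return v

    @model_validator(mode="after")
    def _bs_inside_window(self) -> "AcquisitionProtocol":
        t_acq = self.tau + self.pld
        prev = 0.0
        for u in self.bs_times:
            if not (0.0 < u < t_acq):
                raise ValueError(
                    f"bs time {u} ms outside the open window (0, {t_acq}) ms"
                )
            if u <= prev:
                raise ValueError("bs_times must be strictly increasing")
            prev = u
        return self


class PhysioParams(BaseModel):
    """Physiological parameters of the venous-signal model.

    Parameters
    ----------
    t1_blood:
        Venous blood T1, ms (sex defaults 1742 female / 1667 male).
    t1_tissue:
        Tissue T1, ms (default 1056).
    lam:
        Blood-brain partition coefficient, mL/g (default 0.9). Equilibrium
        tissue magnetization is lam when venous blood equilibrium is 1.
    alpha:
        pCASL labeling (inversion) efficiency in [0, 1] (default 0.86).
    f:
        Global cerebral blood flow, mL/100 g/min.
    sigma_vtt:
        Standard deviation of the venous-transit-time distribution, ms
        (default 1161.7).
    att_ratio:
        Fixed ratio delta_a / delta_v (default 0.555).
    """

    model_config = ConfigDict(frozen=True)

    t1_blood: float = T1_BLOOD_FEMALE
    t1_tissue: float = 1056.0
    lam: float = 0.9
    alpha: float = 0.86
    f: float = 55.0
    sigma_vtt: float = 1161.7
    att_ratio: float = 0.555

    @field_validator("t1_blood", "t1_tissue", "lam", "f", "sigma_vtt", "att_ratio")
    @classmethod
    def _strictly_positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("physiological parameters must be strictly positive")
        return v

    @field_validator("alpha")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        return v


def load_config(path) -> "tuple[PhysioParams, AcquisitionProtocol]":
    """Read (physio, protocol) from a JSON file with keys 'physio'/'protocol'."""
    with open(path) as fh:
        raw = json.load(fh)
    physio = PhysioParams(**raw.get("physio", {}))
    protocol = AcquisitionProtocol(**raw.get("protocol", {}))
    return physio, protocol
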