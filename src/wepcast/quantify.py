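"""Physiological quantification: Renkin-Crone permeability and global CBF."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PermeabilityResult", "renkin_crone_ps", "global_cbf", "BRAIN_DENSITY_G_PER_ML"]

#: Brain tissue density used to convert brain volume (mL) to mass (100 g).
BRAIN_DENSITY_G_PER_ML = 1.06


@dataclass(frozen=True)
class PermeabilityResult:
    """Water extraction fraction with its derived permeability."""

    e_hat: float
    f: float  # CBF, mL/100 g/min
    ps: float  # permeability-surface-area product, mL/100 g/min
    vtt_hat: float  # venous transit time, ms


def renkin_crone_ps(e: float, f: float) -> float:
    """Permeability-surface-area product PS = -ln(1 - E) * f.

    Single-capillary Renkin-Crone exchange: the extraction fraction of a
    freely diffusing tracer at flow ``f`` is E = 1 - exp(-PS/f). E must lie
    in [0, 1) (E -> 1 implies infinite permeability) and f must be positive;
    units of PS follow f (mL/100 g/min).
    """
    if not 0.0 <= e < 1.0:
        raise ValueError(f"E must lie in [0, 1), got {e}")
    if not f > 0:
        raise ValueError(f"f must be > 0, got {f}")
    return -math.log(1.0 - e) * f


def global_cbf(total_flow: float, brain_volume: float, density: float = BRAIN_DENSITY_G_PER_ML) -> float:
    """Global CBF in mL/100 g/min from total arterial inflow and brain volume.

    ``total_flow`` is the summed flow of the four feeding arteries in mL/min
    (phase-contrast measurement); ``brain_volume`` is whole-brain volume in
    mL; ``density`` converts volume to mass (g/mL).
    """
    for name, v in (("total_flow", total_flow), ("brain_volume", brain_volume), ("density", density)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    return total_flow / (brain_volume * density) * 100.0
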