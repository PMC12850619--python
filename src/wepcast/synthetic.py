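"""Synthetic WEPCAST inputs for testing and Monte-Carlo experiments.

Generators emulate the statistical structure of the in-vivo acquisitions:
ROI tables along the superior sagittal sinus with a venous transit time that
increases from anterior to posterior and a spatially constant extraction
fraction; cohorts of subjects with inter-individual spread in E, transit
time, CBF and blood T1; and noisy Look-Locker saturation-recovery series.
All generators are pure functions of (parameters, seed).

The emulated M0 channel is the M0 *scan* signal, i.e. the equilibrium
venous signal attenuated by the finite repetition time of the normalization
scan, M0_meas = M0 * (1 - exp(-TR_M0 / T1b)); the estimation module's
saturation-recovery correction then recovers the true M0.

Noise is additive Gaussian on the ROI-mean magnitude signals (the
complex-difference ROI means are effectively Gaussian at the SNR of
interest); a Rician option is available for low-SNR regimes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blood_t1 as bt1
from .kinetics import signal_pair
from .protocol import AcquisitionProtocol, PhysioParams

__all__ = [
    "RoiSignalTable",
    "SubjectRecord",
    "generate_roi_table",
    "generate_cohort",
    "generate_satrec",
]

#: Default anterior->posterior transit-time profile span across 8 ROIs, ms
#: (illustrative of the qualitative in-vivo range, not a measured value).
DEFAULT_VTT_PROFILE = (3000.0, 3600.0)


@dataclass
class RoiSignalTable:
    """Per-ROI control/label/M0 signals along the SSS (anterior to posterior).

    ``data`` holds columns roi_index, control, label, m0 in arbitrary units;
    ``truth`` (present only for synthetic tables) records the generating
    parameters per ROI plus the CBF and seed.
    """

    data: pd.DataFrame
    truth: dict | None = field(default=None)

    def __post_init__(self):
        missing = {"roi_index", "control", "label", "m0"} - set(self.data.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        if len(self.data) < 1:
            raise ValueError("ROI table must have at least one ROI")
        if (self.data["m0"] <= 0).any():
            raise ValueError("m0 must be positive in every ROI")

    def to_csv(self, path) -> None:
        """Write the table; truth goes to a `<path>.truth.json` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        if self.truth is not None:
            path.with_suffix(path.suffix + ".truth.json").write_text(
                json.dumps(self.truth, indent=2)
            )

    @classmethod
    def read_csv(cls, path) -> "RoiSignalTable":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        truth = json.loads(sidecar.read_text()) if sidecar.exists() else None
        # round_trip parsing keeps the shortest-repr floats bit-exact
        return cls(pd.read_csv(path, float_precision="round_trip"), truth)


@dataclass
class SubjectRecord:
    """One synthetic subject: a single-ROI signal triple plus ground truth."""

    control: float
    label: float
    m0: float
    truth: dict


def _measured_m0(m0_scale: float, physio: PhysioParams, protocol: AcquisitionProtocol) -> float:
    return m0_scale * (1.0 - math.exp(-protocol.m0_tr / physio.t1_blood))


def _add_noise(rng: np.random.Generator, value: float, sd: float, rician: bool) -> float:
    if sd == 0.0:
        return value
    if rician:
        return float(np.hypot(value + rng.normal(0.0, sd), rng.normal(0.0, sd)))
    return float(value + rng.normal(0.0, sd))


def generate_roi_table(
    n_roi: int = 8,
    e_true: float = 0.9,
    vtt_profile: np.ndarray | None = None,
    f: float = 55.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    physio: PhysioParams | None = None,
    protocol: AcquisitionProtocol | None = None,
    m0_scale: float = 1.0,
    noise_on_m0: bool = False,
    rician: bool = False,
) -> RoiSignalTable:
    """Forward-simulate an ROI table along the SSS.

    ``vtt_profile`` defaults to a linear anterior->posterior increase from
    3000 to 3600 ms over ``n_roi`` ROIs; ``e_true`` is spatially constant.
    ``noise_sd`` is the Gaussian noise SD as a fraction of the equilibrium
    venous signal M0, added independently to control and label (and to M0 if
    ``noise_on_m0``).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_roi < 1:
        raise ValueError("n_roi must be >= 1")
    protocol = protocol or AcquisitionProtocol()
    physio = (physio or PhysioParams()).model_copy(update={"f": f})
    if vtt_profile is None:
        vtt_profile = np.linspace(*DEFAULT_VTT_PROFILE, n_roi)
    vtt_profile = np.asarray(vtt_profile, dtype=float)
    if vtt_profile.shape != (n_roi,):
        raise ValueError("vtt_profile length must equal n_roi")

    rng = np.random.default_rng(seed)
    m0_meas = _measured_m0(m0_scale, physio, protocol)
    rows = []
    for i, dv in enumerate(vtt_profile, start=1):
        pair = signal_pair(e_true, float(dv), physio, protocol)
        sd = noise_sd * m0_scale
        rows.append(
            {
                "roi_index": i,
                "control": _add_noise(rng, pair.control * m0_scale, sd, rician),
                "label": _add_noise(rng, pair.label * m0_scale, sd, rician),
                "m0": _add_noise(rng, m0_meas, sd, rician) if noise_on_m0 else m0_meas,
            }
        )
    truth = {
        "e_true": e_true,
        "vtt_profile_ms": [float(v) for v in vtt_profile],
        "f": f,
        "t1_blood": physio.t1_blood,
        "noise_sd": noise_sd,
        "seed": int(seed),
    }
    return RoiSignalTable(pd.DataFrame(rows), truth)


def generate_cohort(
    n_subjects: int = 12,
    e_dist: tuple[float, float] = (0.9, 0.03),
    vtt_dist: tuple[float, float] = (3300.0, 300.0),
    f_dist: tuple[float, float] = (55.0, 6.0),
    t1b_dist: tuple[float, float] = (1742.0, 100.0),
    noise_sd: float = 1.5e-4,
    seed: int = 0,
    physio: PhysioParams | None = None,
    protocol: AcquisitionProtocol | None = None,
) -> list[SubjectRecord]:
    """Draw a synthetic cohort with inter-individual physiological spread.

    Each (mean, sd) pair parameterizes a normal distribution; draws are
    clipped to physiological ranges. One single-ROI WEPCAST signal triple is
    simulated per subject with that subject's true CBF and blood T1, which
    supports the assumed-vs-measured blood-T1 comparison: re-estimating the
    cohort with the sex-default T1 instead of each subject's true value
    isolates the variance that T1 heterogeneity adds to PS.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for cohort statistics")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    protocol = protocol or AcquisitionProtocol()
    base = physio or PhysioParams()
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        e = float(np.clip(rng.normal(*e_dist), 0.40, 0.999))
        dv = float(np.clip(rng.normal(*vtt_dist), 2000.0, 4500.0))
        f = float(np.clip(rng.normal(*f_dist), 20.0, 100.0))
        t1b = float(np.clip(rng.normal(*t1b_dist), 1200.0, 2300.0))
        phys = base.model_copy(update={"f": f, "t1_blood": t1b})
        pair = signal_pair(e, dv, phys, protocol)
        m0_meas = _measured_m0(1.0, phys, protocol)
        subjects.append(
            SubjectRecord(
                control=_add_noise(rng, pair.control, noise_sd, False),
                label=_add_noise(rng, pair.label, noise_sd, False),
                m0=m0_meas,
                truth={"e": e, "vtt": dv, "f": f, "t1_blood": t1b},
            )
        )
    return subjects


def generate_satrec(
    s_t: float,
    s_0: float,
    t1_b: float,
    noise_sd: float = 0.0,
    n_avg: int = 10,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> bt1.SatRecSeries:
    """Noisy Look-Locker saturation-recovery series (``n_avg`` replicates).

    ``noise_sd`` is the Gaussian SD in the same arbitrary units as the
    signal (commonly quoted as a fraction of ``s_0``).
    """
    if s_0 <= 0 or t1_b <= 0 or n_avg < 1 or noise_sd < 0:
        raise ValueError("invalid saturation-recovery generator parameters")
    if times is None:
        times = bt1.looklocker_times(
            bt1.DEFAULT_START_MS, bt1.DEFAULT_INTERVAL_MS, bt1.DEFAULT_N_SAMPLES
        )
    rng = np.random.default_rng(seed)
    clean = bt1.sat_rec_model(times, s_t, s_0, t1_b)
    reps = clean[None, :] + rng.normal(0.0, noise_sd, size=(n_avg, times.size))
    return bt1.SatRecSeries(times=times, signals=reps)
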