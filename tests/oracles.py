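"""Independent brute-force oracles for the closed-form kinetics.

The package solves every magnetization trajectory in exact exponential
segments; these oracles re-solve the same initial-value problems by
fine-step (0.1 ms) Runge-Kutta integration between event times, using only
the pointwise definitions of the forcing terms. Event times are integration
breakpoints and the right-hand side is sampled strictly inside each open
interval so that the integrator never straddles a discontinuity.
"""

from __future__ import annotations

import math

from wepcast.kinetics import arterial_inflow
from wepcast.protocol import AcquisitionProtocol, PhysioParams

_EPS = 1e-9


def _rk4(f, m0: float, a: float, b: float, h: float) -> float:
    """Classic RK4 on [a, b] with the RHS clamped to the open interval."""
    n = max(1, int(math.ceil((b - a) / h)))
    hh = (b - a) / n
    m, t = m0, a

    def rhs(tt, mm):
        return f(min(max(tt, a + _EPS), b - _EPS), mm)

    for _ in range(n):
        k1 = rhs(t, m)
        k2 = rhs(t + hh / 2, m + hh / 2 * k1)
        k3 = rhs(t + hh / 2, m + hh / 2 * k2)
        k4 = rhs(t + hh, m + hh * k3)
        m += hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += hh
    return m


def ode_relax(
    m_start: float,
    t_start: float,
    t_end: float,
    t1: float,
    m_eq: float,
    bs_times=(),
    bs_efficiency: float = 1.0,
    h: float = 0.1,
) -> float:
    """Fine-step integration of dM/dt = (m_eq - M)/t1 with sign flips."""
    events = [t_start] + [u for u in bs_times if t_start < u <= t_end] + [t_end]
    m = m_start
    scale = 1.0 - 2.0 * bs_efficiency
    pulses = set(u for u in bs_times if t_start < u <= t_end)
    for a, b in zip(events[:-1], events[1:]):
        m = _rk4(lambda t, mm: (m_eq - mm) / t1, m, a, b, h)
        if b in pulses:
            m *= scale
    return m


def ode_tissue(
    delta_v: float,
    condition: str,
    physio: PhysioParams,
    protocol: AcquisitionProtocol,
    h: float = 0.1,
) -> float:
    """Fine-step integration of the tissue kinetic equation to capillary exit."""
    t_acq = protocol.t_acq
    t_exit = t_acq - delta_v
    lam = physio.lam
    if t_exit <= 0.0:
        return lam
    da = physio.att_ratio * delta_v
    t1t = physio.t1_tissue
    f_ms = physio.f / 6.0e6

    def mart(tp):
        return arterial_inflow(tp, da, condition, physio, protocol)

    ev = {0.0, t_exit}
    for u in protocol.bs_times:
        if 0.0 < u <= t_exit:
            ev.add(u)
        if condition == "label" and 0.0 < u + da < t_exit:
            ev.add(u + da)
    if condition == "label":
        for edge in (da, protocol.tau + da):
            if 0.0 < edge < t_exit:
                ev.add(edge)
    events = sorted(ev)
    pulses = set(u for u in protocol.bs_times if 0.0 < u <= t_exit)
    scale = 1.0 - 2.0 * protocol.bs_efficiency
    m = lam
    for a, b in zip(events[:-1], events[1:]):
        m = _rk4(
            lambda t, mm: (lam - mm) / t1t + f_ms * (mart(t) - mm / lam), m, a, b, h
        )
        if b in pulses:
            m *= scale
    return m


def ode_venous_tissue(delta_v, condition, physio, protocol, h: float = 0.1) -> float:
    """Tissue path continued through the blood phase, all by fine-step ODE."""
    t_exit = max(0.0, protocol.t_acq - delta_v)
    mv = ode_tissue(delta_v, condition, physio, protocol, h) / physio.lam
    return ode_relax(
        mv, t_exit, protocol.t_acq, physio.t1_blood, 1.0,
        protocol.bs_times, protocol.bs_efficiency, h,
    )


def ode_venous_arterial(delta_v, condition, physio, protocol, h: float = 0.1) -> float:
    """Vessel-only path by fine-step ODE."""
    da = physio.att_ratio * delta_v
    t_cross = protocol.t_acq - (da + delta_v)
    m = 1.0
    if condition == "label" and 0.0 <= t_cross <= protocol.tau:
        m = 1.0 - 2.0 * physio.alpha
    return ode_relax(
        m, t_cross, protocol.t_acq, physio.t1_blood, 1.0,
        protocol.bs_times, protocol.bs_efficiency, h,
    )


def ode_venous_signal(e, delta_v, condition, physio, protocol, h: float = 0.1) -> float:
    """Single-transit (dispersion collapsed) venous signal by fine-step ODE."""
    t_val = ode_venous_tissue(delta_v, condition, physio, protocol, h)
    a_val = ode_venous_arterial(delta_v, condition, physio, protocol, h)
    return e * t_val + (1.0 - e) * a_val
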