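"""Voltage-gated channel kinetics for the nodal / juxtaparanodal membrane.

Four conductances are modelled with Hodgkin-Huxley style gating:

* fast Na (gates m^3 h), nodal, 1.5 S/cm^2
* persistent Na (p^3), nodal, 0.01 S/cm^2
* slow K (s), nodal, 0.088 S/cm^2
* fast K (n^4), juxtaparanodal, 0.02 S/cm^2

plus ohmic leaks in every region.  Rate constants are given at a base
temperature and scaled to the simulation temperature by q10 factors applied
to both the forward and backward rates.  Each region's leak reversal is
calibrated so that -80 mV with steady-state gates is an exact resting
equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import INTERNODE, JUXTAPARANODE, NODE, PARANODE

V_REST_MV = -80.0
DEFAULT_E_NA_MV = 50.0
DEFAULT_E_K_MV = -90.0
DEFAULT_TEMPERATURE_C = 37.0

#: Region leak conductances, S/cm^2.
LEAK_CONDUCTANCE = {
    NODE: 0.007,
    PARANODE: 0.0005,
    JUXTAPARANODE: 0.005,
    INTERNODE: 0.005,
}


class GateStateError(ValueError):
    """Raised when a gating variable leaves [0, 1]."""


@dataclass(frozen=True)
class RateFunction:
    """One alpha/beta rate function, ms^-1.

    Two shapes cover all ten rates:

    * ``linoid``: a * x / (1 - exp(-x / k)) with x = sign * (V - v_half);
      the removable singularity at v_half evaluates to the limit a * k.
    * ``sigmoid``: a / (1 + exp(-sign * (V - v_half) / k)).
    """

    a: float
    v_half: float
    k: float
    sign: int = 1
    kind: str = "linoid"

    def __call__(self, V):
        V = np.asarray(V, dtype=float)
        x = self.sign * (V - self.v_half)
        if self.kind == "linoid":
            # series-safe evaluation around the removable singularity
            u = np.asarray(x / self.k)
            small = np.abs(u) < 1e-7
            den = -np.expm1(-np.clip(u, -700, 700))
            den = np.where(small, 1.0, den)
            out = np.where(
                small,
                self.a * self.k * (1.0 + u / 2.0),
                self.a * np.asarray(x) / den,
            )
            return out if out.ndim else float(out)
        if self.kind == "sigmoid":
            out = self.a / (1.0 + np.exp(-np.clip(x / self.k, -700, 700)))
            return out if out.ndim else float(out)
        raise ValueError(f"unknown rate kind {self.kind!r}")

    @property
    def singular_limit(self) -> float:
        """Value at the removable singularity of a linoid rate (a * k)."""
        if self.kind != "linoid":
            raise ValueError("only linoid rates have a singular point")
        return self.a * self.k


# The ten rate functions.  Negative-direction linoids are written
# a * (-(V - v_half)) / (1 - exp((V - v_half)/k)), i.e. sign = -1.
RATES: dict[str, RateFunction] = {
    "alpha_m": RateFunction(6.57, -20.4, 10.3, +1, "linoid"),
    "beta_m": RateFunction(0.304, -25.7, 9.16, -1, "linoid"),
    "alpha_h": RateFunction(0.34, -114.0, 11.0, -1, "linoid"),
    "beta_h": RateFunction(12.6, -31.8, 13.4, +1, "sigmoid"),
    "alpha_p": RateFunction(0.0353, -27.0, 10.2, +1, "linoid"),
    "beta_p": RateFunction(0.000883, -34.0, 10.0, -1, "linoid"),
    "alpha_s": RateFunction(0.3, -53.0, 5.0, +1, "sigmoid"),
    "beta_s": RateFunction(0.03, -90.0, 1.0, +1, "sigmoid"),
    "alpha_n": RateFunction(0.00798, -93.2, 1.1, +1, "linoid"),
    "beta_n": RateFunction(0.092, -76.0, 10.5, -1, "linoid"),
}

#: Gate name -> (activation direction, alpha, beta).
GATES = {
    "m": (+1, "alpha_m", "beta_m"),
    "h": (-1, "alpha_h", "beta_h"),
    "p": (+1, "alpha_p", "beta_p"),
    "s": (+1, "alpha_s", "beta_s"),
    "n": (+1, "alpha_n", "beta_n"),
}


def rate(name: str, V):
    """Evaluate one named rate function at voltage V (mV) -> ms^-1."""
    return RATES[name](V)


@dataclass(frozen=True)
class ChannelModel:
    """A gated maximal conductance with reversal potential and q10."""

    name: str
    gmax: float  # S/cm^2
    gates: tuple[tuple[str, int], ...]  # ((gate name, exponent), ...)
    e_rev: float  # mV
    q10: float
    t_base: float  # degC

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        for g, p in self.gates:
            if g not in GATES or p < 1:
                raise ValueError(f"bad gate spec ({g}, {p})")

    def open_fraction(self, gate_state: dict[str, float]) -> float:
        f = 1.0
        for g, p in self.gates:
            x = gate_state[g]
            if not 0.0 <= x <= 1.0:
                raise GateStateError(f"gate {g} = {x} outside [0, 1]")
            f *= x**p
        return f


def default_channels(
    e_na: float = DEFAULT_E_NA_MV,
    e_k: float = DEFAULT_E_K_MV,
    q10_na: float = 2.2,
    q10_kf: float = 3.0,
    q10_ks: float = 3.0,
    t_base: float = DEFAULT_TEMPERATURE_C,
) -> dict[str, ChannelModel]:
    """The four channel models with printed maximal conductances.

    The rate equations are taken to be expressed at the default simulation
    temperature (37 degC): their amplitudes give physiological gating time
    constants there (e.g. nodal Na inactivation ~80 us near 0 mV), whereas
    scaling them up by a further q10 factor from room temperature would make
    inactivation faster than activation can charge the internode and
    propagation fails for every calibre.  The q10 values still apply to any
    simulation run away from 37 degC.
    """
    return {
        "na_fast": ChannelModel("na_fast", 1.5, (("m", 3), ("h", 1)), e_na, q10_na, t_base),
        "na_persistent": ChannelModel(
            "na_persistent", 0.01, (("p", 3),), e_na, q10_na, t_base
        ),
        "k_slow": ChannelModel("k_slow", 0.088, (("s", 1),), e_k, q10_ks, t_base),
        "k_fast": ChannelModel("k_fast", 0.02, (("n", 4),), e_k, q10_kf, t_base),
    }


def q10_factor(channel: ChannelModel, temperature: float) -> float:
    """Rate scaling q10^((T - T_base)/10)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (degC)")
    return channel.q10 ** ((temperature - channel.t_base) / 10.0)


def gate_steady_state(gate: str, V, q10: float = 1.0):
    """(x_inf, tau_x) for a gate at voltage V; tau in ms at the given q10 factor."""
    _, a_name, b_name = GATES[gate]
    a = RATES[a_name](V)
    b = RATES[b_name](V)
    denom = np.asarray(a) + np.asarray(b)
    if np.any(denom <= 0):
        raise ValueError("alpha + beta must be positive")
    x_inf = a / denom
    tau = 1.0 / (q10 * denom)
    if np.ndim(x_inf):
        return x_inf, tau
    return float(x_inf), float(tau)


@dataclass(frozen=True)
class RegionChannelSet:
    """Mapping region kind -> channels present, plus leak conductance/reversal.

    ``density`` scales each channel's gmax in that region (1.0 = full printed
    density); it is how juxtaparanodal fast K is partially dislocated into
    the paranode.  Leak reversals default to the calibrated values that make
    -80 mV an exact rest (see :func:`calibrate_leak_reversal`).
    """

    channels: dict[str, ChannelModel]
    region_channels: dict[str, tuple[tuple[str, float], ...]]
    leak_conductance: dict[str, float]
    leak_reversal: dict[str, float]
    temperature: float = DEFAULT_TEMPERATURE_C

    def region_gmax(self, region: str, channel: str) -> float:
        for name, dens in self.region_channels.get(region, ()):
            if name == channel:
                return self.channels[channel].gmax * dens
        return 0.0

    def with_paranodal_kfast(self, density: float) -> "RegionChannelSet":
        """Copy with fast K added to the paranode at the given density scale."""
        rc = dict(self.region_channels)
        entries = tuple(
            (n, d) for n, d in rc.get(PARANODE, ()) if n != "k_fast"
        )
        rc[PARANODE] = entries + (("k_fast", float(density)),)
        lr = dict(self.leak_reversal)
        lr[PARANODE] = calibrate_leak_reversal(
            self.channels, rc[PARANODE], self.leak_conductance[PARANODE]
        )
        return replace(self, region_channels=rc, leak_reversal=lr)


def steady_gate_state(V: float) -> dict[str, float]:
    """All five gates at their steady state for voltage V."""
    return {g: gate_steady_state(g, V)[0] for g in GATES}


def calibrate_leak_reversal(
    channels: dict[str, ChannelModel],
    region_entries: tuple[tuple[str, float], ...],
    gl: float,
    v_rest: float = V_REST_MV,
) -> float:
    """Leak reversal that zeroes the total membrane current at rest.

    Solves sum_ch gmax*gates_inf*(v_rest - E_ch) + gl*(v_rest - E_l) = 0.
    """
    gates = steady_gate_state(v_rest)
    active = 0.0
    for name, dens in region_entries:
        ch = channels[name]
        active += ch.gmax * dens * ch.open_fraction(gates) * (v_rest - ch.e_rev)
    return v_rest + active / gl


def default_region_channel_set(
    e_na: float = DEFAULT_E_NA_MV,
    e_k: float = DEFAULT_E_K_MV,
    temperature: float = DEFAULT_TEMPERATURE_C,
    q10_na: float = 2.2,
    q10_kf: float = 3.0,
    q10_ks: float = 3.0,
) -> RegionChannelSet:
    """Baseline channel placement: Na/slow-K at nodes, fast K at juxtaparanodes."""
    ch = default_channels(e_na, e_k, q10_na, q10_kf, q10_ks)
    region_channels = {
        NODE: (("na_fast", 1.0), ("na_persistent", 1.0), ("k_slow", 1.0)),
        PARANODE: (),
        JUXTAPARANODE: (("k_fast", 1.0),),
        INTERNODE: (),
    }
    leak_reversal = {
        region: calibrate_leak_reversal(ch, entries, LEAK_CONDUCTANCE[region])
        for region, entries in region_channels.items()
    }
    return RegionChannelSet(
        channels=ch,
        region_channels=region_channels,
        leak_conductance=dict(LEAK_CONDUCTANCE),
        leak_reversal=leak_reversal,
        temperature=temperature,
    )


def membrane_current(
    channel_set: RegionChannelSet,
    region: str,
    V: float,
    gate_state: dict[str, float],
) -> tuple[float, float]:
    """Total ionic current density (mA/cm^2) and slope conductance (S/cm^2).

    I = sum_ch gmax * prod(gates) * (V - E_ch) + gl * (V - E_leak).
    """
    g_total = channel_set.leak_conductance[region]
    current = g_total * (V - channel_set.leak_reversal[region])
    for name, dens in channel_set.region_channels.get(region, ()):
        ch = channel_set.channels[name]
        g = ch.gmax * dens * ch.open_fraction(gate_state)
        current += g * (V - ch.e_rev)
        g_total += g
    return current, g_total


def rate_table(v_grid=None):
    """Evaluate all rate functions on a voltage grid as a DataFrame.

    Column order: V followed by the rates in RATES order.  Used by the CLI
    channel dump.
    """
    import pandas as pd

    if v_grid is None:
        v_grid = np.arange(-120.0, 60.0 + 1e-9, 1.0)
    v_grid = np.asarray(v_grid, dtype=float)
    data = {"V_mV": v_grid}
    for name, fn in RATES.items():
        data[name] = fn(v_grid)
    return pd.DataFrame(data)
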