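"""Double-cable network assembly and implicit time integration.

Each myelinated segment carries two unknown potentials (relative to the
extracellular ground): the intracellular potential ``Vi`` and the
peri-axonal potential ``Vp`` in the thin fluid layer between axolemma and
myelin; the axolemmal membrane voltage is ``Vi - Vp``.  Nodes of Ranvier
are bare, so their peri-axonal potential is the ground and they carry a
single unknown.  Three conductive pathways link the unknowns:

* ``Ga`` — axial axoplasmic conductance between neighbouring segments,
* ``Gp`` — longitudinal conductance of the peri-axonal annulus (opening to
  the grounded extracellular space at each nodal gap),
* ``Gm`` — radial trans-myelin conductance (per-lamella conductance and
  capacitance stacked in series, hence divided by the lamella count).

Time stepping is backward Euler on the potentials: at every step the gating
variables are advanced by exact exponential relaxation toward their
voltage-dependent steady state (Rush-Larsen), the resulting ionic
conductances are frozen, and the linear pentadiagonal system for all
potentials is solved with a banded LU factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import solve_banded

from . import kinetics
from .geometry import (
    INTERNODE,
    JUXTAPARANODE,
    NODE,
    PARANODE,
    AxonGeometry,
)
from .kinetics import RATES, RegionChannelSet, V_REST_MV, q10_factor


class AssemblyError(ValueError):
    """Raised when the electrical network cannot be built from the geometry."""


class SolverError(RuntimeError):
    """Raised when the integration diverges (non-finite voltage)."""


@dataclass
class Biophysics:
    """Passive electrical constants of the double cable.

    The four headline values (two capacitances, two resistivities) are not
    uniquely fixed by published measurements for this model class; they are
    exposed here as the calibration surface for the conduction-velocity vs
    fibre-diameter slope.  Defaults are the jointly calibrated values:
    axolemmal capacitance 0.3 uF/cm^2, compact-myelin capacitance 0.2
    uF/cm^2 per lamella (stacked in series), axoplasmic resistivity 100
    Ohm cm, and an effective peri-axonal resistivity of 400 Ohm cm
    reflecting the tortuous submyelin pathway.
    """

    c_axon_uF_cm2: float = 0.3
    c_myelin_lamella_uF_cm2: float = 0.2
    rho_axial_ohm_cm: float = 100.0
    rho_periaxonal_ohm_cm: float = 400.0
    #: nodal constriction: node diameter as a fraction of the core diameter
    node_diameter_ratio: float = 1.0
    #: conductance of one myelin lamella, S/cm^2 (1,000 Ohm cm^2 per lamella)
    g_myelin_lamella_S_cm2: float = 1.0e-3
    #: myelinated compartments longer than this are subdivided, um
    max_segment_length_um: float = 10.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "Biophysics":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class StimulusSpec:
    """Square current pulse injected at a node midpoint.

    ``node`` is 1-based; ``onset_ms`` is measured from the end of the
    settling period.
    """

    node: int = 1
    amplitude_nA: float = 2.0
    onset_ms: float = 0.0
    duration_ms: float = 0.1

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be > 0")


def charge_injected(stimulus: StimulusSpec) -> float:
    """Injected charge, pC (nA x ms)."""
    return stimulus.amplitude_nA * stimulus.duration_ms


@dataclass(frozen=True)
class SolverConfig:
    dt_ms: float = 0.0005
    t_end_ms: float = 10.0
    settle_ms: float = 1.0
    temperature_c: float = 37.0
    samples_per_ms: float = 2000.0
    v_init_mV: float = V_REST_MV
    scheme: str = "backward_euler"

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.samples_per_ms <= 0:
            raise ValueError("samples_per_ms must be > 0")


@dataclass
class SimulationTrace:
    """Sampled axolemmal voltages at every node midpoint.

    ``time_ms`` is zero at stimulus onset; samples start at the beginning of
    the settling period (negative times).
    """

    time_ms: np.ndarray
    node_voltage_mV: np.ndarray  # (n_samples, n_nodes)
    segment_voltage_mV: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_voltage_mV.shape[1]

    def node(self, index: int) -> np.ndarray:
        """Voltage trace at a 1-based node index."""
        if not 1 <= index <= self.n_nodes:
            raise IndexError(f"node index {index} out of range")
        return self.node_voltage_mV[:, index - 1]

    def to_frame(self):
        import pandas as pd

        cols = {
            f"V_node{i + 1:02d}": self.node_voltage_mV[:, i]
            for i in range(self.n_nodes)
        }
        return pd.DataFrame({"time_ms": self.time_ms, **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CableNetwork:
    """Assembled electrical network ready for time stepping."""

    geometry: AxonGeometry
    channel_set: RegionChannelSet
    biophysics: Biophysics
    # per-segment arrays (S segments after subdivision)
    seg_kind: list[str]
    seg_len: np.ndarray
    seg_area_cm2: np.ndarray
    seg_comp_index: np.ndarray
    cm_nF: np.ndarray
    gl_muS: np.ndarray
    e_leak: np.ndarray
    # myelin branch (myelinated segments only, length M)
    myel_idx: np.ndarray
    cmy_nF: np.ndarray
    gmy_muS: np.ndarray
    # couplings
    ga_muS: np.ndarray  # (S-1,) axial between neighbours
    gp_muS: np.ndarray  # (S-1,) periaxonal between neighbours (0 across nodes)
    gp_ground_muS: np.ndarray  # (M,) periaxonal leak to ground at nodal gaps
    # active conductances
    node_seg: np.ndarray  # segment indices of nodes (one per node)
    k_seg: np.ndarray  # segment indices that may carry fast K
    gkf_max_Scm2: np.ndarray  # (len(k_seg),) fast K gmax incl. density scale
    gna_Scm2: float = 0.0
    gnap_Scm2: float = 0.0
    gks_Scm2: float = 0.0
    # unknown layout
    vi_pos: np.ndarray = None
    vp_pos: np.ndarray = None  # (M,)
    n_unknowns: int = 0

    def matrix_dense(self, g_seg_muS: np.ndarray | None = None, dt_ms: float = 0.01) -> np.ndarray:
        """Dense system matrix for inspection/testing (small networks only)."""
        ab, _ = _assemble_banded_const(self, dt_ms)
        g = self.gl_muS.copy() if g_seg_muS is None else g_seg_muS
        a = self.cm_nF / dt_ms + g
        ab = ab.copy()
        ab[2, self.vi_pos] += a
        ab[2, self.vp_pos] += a[self.myel_idx]
        ab[1, self.vp_pos] -= a[self.myel_idx]
        ab[3, self.vi_pos[self.myel_idx]] -= a[self.myel_idx]
        n = self.n_unknowns
        dense = np.zeros((n, n))
        for i in range(n):
            for j in range(max(0, i - 2), min(n, i + 3)):
                dense[i, j] = ab[2 + i - j, j]
        return dense


def _subdivide(geometry: AxonGeometry, max_len: float):
    """Split long compartments into equal sub-segments <= max_len um."""
    kinds, lengths, widths, lamellae, comp_index = [], [], [], [], []
    for ci, comp in enumerate(geometry.compartments):
        n_sub = max(1, int(np.ceil(comp.length / max_len - 1e-12)))
        for _ in range(n_sub):
            kinds.append(comp.kind)
            lengths.append(comp.length / n_sub)
            widths.append(comp.periaxonal_width)
            lamellae.append(comp.n_lamellae)
            comp_index.append(ci)
    return (
        kinds,
        np.asarray(lengths),
        np.asarray(widths),
        np.asarray(lamellae),
        np.asarray(comp_index),
    )


def assemble_network(
    geometry: AxonGeometry,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    paranodal_kfast: dict[int, float] | None = None,
) -> CableNetwork:
    """Build the double-cable network from an axon geometry.

    ``paranodal_kfast`` maps geometry compartment indices (paranodes) to a
    fast-K density scale in [0, 1]; it implements juxtaparanodal channel
    dislocation into selected paranodes.  Leak reversals are calibrated per
    segment so that every segment rests exactly at -80 mV.
    """
    channel_set = channel_set or kinetics.default_region_channel_set()
    bio = biophysics or Biophysics()
    paranodal_kfast = paranodal_kfast or {}

    kinds, lengths, widths, lamellae, comp_index = _subdivide(
        geometry, bio.max_segment_length_um
    )
    S = len(kinds)
    d = geometry.fibre_class.d_core
    # nodal constriction: nodes may be narrower than the internodal core
    d_seg = np.array(
        [
            d * bio.node_diameter_ratio if k == NODE else d
            for k in kinds
        ]
    )

    area_um2 = np.pi * d_seg * lengths
    area_cm2 = area_um2 * 1e-8
    gfac = area_cm2 * 1e6  # S/cm^2 -> uS
    cm_nF = bio.c_axon_uF_cm2 * area_cm2 * 1e3

    myel_mask = np.array([k != NODE for k in kinds])
    if np.any(myel_mask & (widths <= 0)):
        bad = np.where(myel_mask & (widths <= 0))[0][0]
        raise AssemblyError(
            f"segment {bad} ({kinds[bad]}) has zero peri-axonal width but a "
            "peri-axonal pathway is required under myelin"
        )
    myel_idx = np.where(myel_mask)[0]

    lam = np.maximum(lamellae[myel_idx], 1)
    gmy_muS = bio.g_myelin_lamella_S_cm2 / lam * gfac[myel_idx]
    cmy_nF = bio.c_myelin_lamella_uF_cm2 / lam * area_cm2[myel_idx] * 1e3

    # axial half-resistances, Ohm (resistivity Ohm cm -> Ohm um via 1e4)
    rho_ax = bio.rho_axial_ohm_cm * 1e4
    rh_ax = rho_ax * (lengths / 2.0) / (np.pi * d_seg**2 / 4.0)
    ga_muS = 1e6 / (rh_ax[:-1] + rh_ax[1:])

    # peri-axonal half-resistances (annulus cross-section pi d w)
    rho_p = bio.rho_periaxonal_ohm_cm * 1e4
    with np.errstate(divide="ignore"):
        rh_p = np.where(
            myel_mask & (widths > 0),
            rho_p * (lengths / 2.0) / (np.pi * d * widths),
            np.inf,
        )
    gp_muS = np.zeros(S - 1)
    both = myel_mask[:-1] & myel_mask[1:]
    gp_muS[both] = 1e6 / (rh_p[:-1][both] + rh_p[1:][both])

    # peri-axonal opening to ground where a myelinated segment abuts a node
    # (or the axon end, where the sheath terminates)
    gp_ground = np.zeros(len(myel_idx))
    for k, s in enumerate(myel_idx):
        left_open = s == 0 or kinds[s - 1] == NODE
        right_open = s == S - 1 or kinds[s + 1] == NODE
        g_half = 1e6 / rh_p[s]
        gp_ground[k] = g_half * (int(left_open) + int(right_open))

    # region channel placement with optional per-compartment paranodal fast K
    gl_muS = np.empty(S)
    e_leak = np.empty(S)
    node_seg = []
    k_seg, gkf = [], []
    kfast_model = channel_set.channels["k_fast"]
    for s in range(S):
        region = kinds[s]
        entries = channel_set.region_channels.get(region, ())
        if region == PARANODE and comp_index[s] in paranodal_kfast:
            dens = paranodal_kfast[comp_index[s]]
            entries = tuple(e for e in entries if e[0] != "k_fast") + (
                ("k_fast", float(dens)),
            )
        gl = channel_set.leak_conductance[region]
        gl_muS[s] = gl * gfac[s]
        e_leak[s] = kinetics.calibrate_leak_reversal(
            channel_set.channels, entries, gl
        )
        if region == NODE:
            node_seg.append(s)
        if region in (PARANODE, JUXTAPARANODE):
            k_seg.append(s)
            dens = dict(entries).get("k_fast", 0.0)
            gkf.append(kfast_model.gmax * dens)

    # unknown layout: Vi for every segment, Vp interleaved for myelinated ones
    vi_pos = np.empty(S, dtype=np.int64)
    vp_pos = np.empty(len(myel_idx), dtype=np.int64)
    pos = 0
    mk = 0
    for s in range(S):
        vi_pos[s] = pos
        pos += 1
        if myel_mask[s]:
            vp_pos[mk] = pos
            mk += 1
            pos += 1

    net = CableNetwork(
        geometry=geometry,
        channel_set=channel_set,
        biophysics=bio,
        seg_kind=kinds,
        seg_len=lengths,
        seg_area_cm2=area_cm2,
        seg_comp_index=comp_index,
        cm_nF=cm_nF,
        gl_muS=gl_muS,
        e_leak=e_leak,
        myel_idx=myel_idx,
        cmy_nF=cmy_nF,
        gmy_muS=gmy_muS,
        ga_muS=ga_muS,
        gp_muS=gp_muS,
        gp_ground_muS=gp_ground,
        node_seg=np.asarray(node_seg, dtype=np.int64),
        k_seg=np.asarray(k_seg, dtype=np.int64),
        gkf_max_Scm2=np.asarray(gkf),
        gna_Scm2=channel_set.region_gmax(NODE, "na_fast"),
        gnap_Scm2=channel_set.region_gmax(NODE, "na_persistent"),
        gks_Scm2=channel_set.region_gmax(NODE, "k_slow"),
        vi_pos=vi_pos,
        vp_pos=vp_pos,
        n_unknowns=pos,
    )
    return net


def _assemble_banded_const(net: CableNetwork, dt: float):
    """Time-invariant part of the banded system matrix (5 x N, u = l = 2).

    Returns (ab_const, cmy_dt).  The time-varying axolemmal term
    a = Cm/dt + g_ionic is added on top of this each step.
    """
    N = net.n_unknowns
    ab = np.zeros((5, N))
    vi, vp = net.vi_pos, net.vp_pos
    S = len(net.seg_kind)

    def add(i, j, val):
        ab[2 + i - j, j] += val

    # axial couplings
    for s in range(S - 1):
        g = net.ga_muS[s]
        i, j = vi[s], vi[s + 1]
        add(i, i, g)
        add(j, j, g)
        add(i, j, -g)
        add(j, i, -g)

    # peri-axonal longitudinal couplings
    myel_rank = {int(s): k for k, s in enumerate(net.myel_idx)}
    for s in range(S - 1):
        g = net.gp_muS[s]
        if g <= 0:
            continue
        i, j = vp[myel_rank[s]], vp[myel_rank[s + 1]]
        add(i, i, g)
        add(j, j, g)
        add(i, j, -g)
        add(j, i, -g)

    # myelin branch and peri-axonal ground openings
    cmy_dt = net.cmy_nF / dt
    for k in range(len(net.myel_idx)):
        i = vp[k]
        add(i, i, cmy_dt[k] + net.gmy_muS[k] + net.gp_ground_muS[k])

    return ab, cmy_dt


def _gate_update(x, gate, V, qf, dt):
    """Rush-Larsen exponential relaxation of one gate toward x_inf(V)."""
    _, an, bn = kinetics.GATES[gate]
    a = RATES[an](V) * qf
    b = RATES[bn](V) * qf
    ab_sum = a + b
    x_inf = a / ab_sum
    return x_inf + (x - x_inf) * np.exp(-dt * ab_sum)


def run_simulation(
    net: CableNetwork,
    stimulus: StimulusSpec | None = None,
    config: SolverConfig | None = None,
    record_segments: bool = False,
) -> SimulationTrace:
    """Integrate the network and return node-midpoint voltage traces."""
    stimulus = stimulus if stimulus is not None else StimulusSpec()
    config = config or SolverConfig()
    dt = config.dt_ms

    ch = net.channel_set.channels
    qf_na = q10_factor(ch["na_fast"], config.temperature_c)
    qf_kf = q10_factor(ch["k_fast"], config.temperature_c)
    qf_ks = q10_factor(ch["k_slow"], config.temperature_c)
    e_na = ch["na_fast"].e_rev
    e_k = ch["k_fast"].e_rev

    ab_const, cmy_dt = _assemble_banded_const(net, dt)
    cm_dt = net.cm_nF / dt
    vi_pos, vp_pos, myel_idx = net.vi_pos, net.vp_pos, net.myel_idx
    node_seg, k_seg = net.node_seg, net.k_seg
    gfac_node = net.seg_area_cm2[node_seg] * 1e6
    gfac_k = net.seg_area_cm2[k_seg] * 1e6
    gl = net.gl_muS
    ie_leak = net.gl_muS * net.e_leak

    if not 1 <= stimulus.node <= len(node_seg):
        raise AssemblyError(f"stimulus node {stimulus.node} out of range")
    stim_pos = vi_pos[node_seg[stimulus.node - 1]]

    # initial state: membrane at v_init, peri-axonal space at ground
    S = len(net.seg_kind)
    Vi = np.full(S, config.v_init_mV)
    Vp = np.zeros(len(myel_idx))
    Vi[myel_idx] += Vp
    Vm_node = np.full(len(node_seg), config.v_init_mV)
    g0 = kinetics.steady_gate_state(config.v_init_mV)
    m = np.full(len(node_seg), g0["m"])
    h = np.full(len(node_seg), g0["h"])
    p = np.full(len(node_seg), g0["p"])
    s_g = np.full(len(node_seg), g0["s"])
    n_g = np.full(len(k_seg), g0["n"])

    n_steps = int(round((config.settle_ms + config.t_end_ms) / dt))
    stride = max(1, int(round(1.0 / (config.samples_per_ms * dt))))
    n_samples = n_steps // stride + 1
    rec = np.empty((n_samples, len(node_seg)))
    rec_t = np.empty(n_samples)
    rec_seg = np.empty((n_samples, S)) if record_segments else None

    t_on = config.settle_ms + stimulus.onset_ms
    t_off = t_on + stimulus.duration_ms

    Vm = Vi.copy()
    rec[0] = Vi[node_seg]
    rec_t[0] = -config.settle_ms
    if record_segments:
        rec_seg[0] = Vm
    k_rec = 1

    gkf = net.gkf_max_Scm2
    for step in range(1, n_steps + 1):
        t_new = step * dt

        # gates advance with voltages frozen at the previous step
        Vn = Vm[node_seg]
        Vk = Vm[k_seg]
        m = _gate_update(m, "m", Vn, qf_na, dt)
        h = _gate_update(h, "h", Vn, qf_na, dt)
        p = _gate_update(p, "p", Vn, qf_na, dt)
        s_g = _gate_update(s_g, "s", Vn, qf_ks, dt)
        n_g = _gate_update(n_g, "n", Vk, qf_kf, dt)

        g_na = net.gna_Scm2 * m**3 * h + net.gnap_Scm2 * p**3
        g_ks = net.gks_Scm2 * s_g
        g_kf = gkf * n_g**4

        g = gl.copy()
        ie = ie_leak.copy()
        g[node_seg] += (g_na + g_ks) * gfac_node
        ie[node_seg] += (g_na * e_na + g_ks * e_k) * gfac_node
        g[k_seg] += g_kf * gfac_k
        ie[k_seg] += g_kf * e_k * gfac_k

        a = cm_dt + g
        ab = ab_const.copy()
        ab[2, vi_pos] += a
        ab[2, vp_pos] += a[myel_idx]
        ab[1, vp_pos] -= a[myel_idx]
        ab[3, vi_pos[myel_idx]] -= a[myel_idx]

        b = np.zeros(net.n_unknowns)
        rhs_m = cm_dt * Vm + ie
        b[vi_pos] = rhs_m
        b[vp_pos] = -rhs_m[myel_idx] + cmy_dt * Vp
        if t_on < t_new <= t_off + dt / 2:
            b[stim_pos] += stimulus.amplitude_nA

        x = solve_banded(
            (2, 2), ab, b, check_finite=False, overwrite_ab=True, overwrite_b=True
        )
        Vi = x[vi_pos]
        Vp = x[vp_pos]
        Vm = Vi.copy()
        Vm[myel_idx] -= Vp

        if step % stride == 0:
            if not np.isfinite(Vm[0]):
                raise SolverError(f"solver diverged at step {step} (t={t_new} ms)")
            rec[k_rec] = Vm[node_seg]
            rec_t[k_rec] = t_new - config.settle_ms
            if record_segments:
                rec_seg[k_rec] = Vm
            k_rec += 1

    if not np.all(np.isfinite(rec[:k_rec])):
        raise SolverError("solver produced non-finite voltages")

    return SimulationTrace(
        time_ms=rec_t[:k_rec],
        node_voltage_mV=rec[:k_rec],
        segment_voltage_mV=rec_seg[:k_rec] if record_segments else None,
    )
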