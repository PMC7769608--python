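"""Paranodal-disruption experiments on the double-cable axon.

Disruption is modelled as a widening of the peri-axonal space under the
paranode (and optionally the juxtaparanode), with or without dislocation of
juxtaparanodal fast K channels into the paranode.  Four scenario kinds:

* ``a`` — widen the paranodal peri-axonal space only,
* ``b`` — widen both the paranodal and juxtaparanodal spaces,
* ``c`` — widen the paranodal space and dislocate fast K into the paranode,
* ``d`` — widen both spaces and dislocate fast K.

A fold increase ``f`` scales a baseline width ``w0`` to ``w0 * (1 + f)``
(f = 5 is "+500%").  Disrupting a node widens both of its flanking
paranode/juxtaparanode pairs.  Dislocated paranodal fast-K density ramps
linearly with f up to the full juxtaparanodal density at ``f_cap``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import kinetics
from .cable import (
    Biophysics,
    SimulationTrace,
    SolverConfig,
    StimulusSpec,
    assemble_network,
    run_simulation,
)
from .geometry import (
    DEFAULT_PERIAXONAL_WIDTHS_UM,
    JUXTAPARANODE,
    PARANODE,
    AxonGeometry,
    FibreClass,
    build_axon,
    flank_indices,
)
from .kinetics import RegionChannelSet
from .metrics import ConductionResult, conduction_velocity

#: Default fold-increase grid; covers the +500% and +1,000% reference points.
DEFAULT_F_GRID = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0)

#: Fold increase at which dislocated paranodal fast K reaches full density.
DEFAULT_F_CAP = 10.0

SCENARIO_KINDS = ("a", "b", "c", "d")


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class DisruptionScenario:
    """One structural-disruption condition.

    ``pattern`` is a per-node mask (True = disrupted), length n_nodes;
    None means all nodes disrupted.
    """

    kind: str
    f: float
    pattern: tuple[bool, ...] | None = None
    f_cap: float = DEFAULT_F_CAP

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        if self.f < 0:
            raise ScenarioError("fold increase f must be >= 0")

    @property
    def widens_juxtaparanode(self) -> bool:
        return self.kind in ("b", "d")

    @property
    def dislocates_kv(self) -> bool:
        return self.kind in ("c", "d")

    def kv_density(self) -> float:
        """Paranodal fast-K density scale for this fold increase."""
        if not self.dislocates_kv:
            return 0.0
        return min(1.0, self.f / self.f_cap)


@dataclass(frozen=True)
class ScenarioResult:
    fibre_class: FibreClass
    scenario: DisruptionScenario | None
    velocity_m_s: float | None
    normalized_velocity: float | None
    failed: bool


def parse_pattern(text: str) -> tuple[bool, ...]:
    """Parse an H/D mask string (e.g. 'HHDDDHH...') into a boolean tuple."""
    mask = []
    for c in text.strip().upper():
        if c == "D":
            mask.append(True)
        elif c == "H":
            mask.append(False)
        else:
            raise ScenarioError(f"pattern characters must be H or D, got {c!r}")
    return tuple(mask)


def apply_scenario(
    geometry: AxonGeometry,
    channel_set: RegionChannelSet,
    scenario: DisruptionScenario,
) -> tuple[AxonGeometry, RegionChannelSet, dict[int, float]]:
    """Apply a disruption scenario to a baseline axon.

    Returns the modified geometry, the (unchanged) channel set and a map of
    paranode compartment indices to dislocated fast-K density scales, to be
    passed to :func:`paracable.cable.assemble_network`.
    """
    n = geometry.n_nodes
    pattern = scenario.pattern or tuple([True] * n)
    if len(pattern) != n:
        raise ScenarioError(
            f"pattern length {len(pattern)} does not match {n} nodes"
        )

    widths: dict[int, float] = {}
    kfast: dict[int, float] = {}
    dens = scenario.kv_density()
    for node_idx, disrupted in enumerate(pattern, start=1):
        if not disrupted:
            continue
        for ci in flank_indices(geometry, node_idx):
            comp = geometry.compartments[ci]
            if comp.kind == PARANODE:
                widths[ci] = comp.periaxonal_width * (1.0 + scenario.f)
                if dens > 0:
                    kfast[ci] = dens
            elif comp.kind == JUXTAPARANODE and scenario.widens_juxtaparanode:
                widths[ci] = comp.periaxonal_width * (1.0 + scenario.f)
    return geometry.with_widths(widths), channel_set, kfast


def _disrupt_absolute(
    geometry: AxonGeometry,
    pattern: tuple[bool, ...],
    disrupted_widths: tuple[float, float],
    kv_density: float = 0.0,
) -> tuple[AxonGeometry, dict[int, float]]:
    """Set flank widths of disrupted nodes to absolute values (um)."""
    w_pn, w_jxp = disrupted_widths
    widths: dict[int, float] = {}
    kfast: dict[int, float] = {}
    for node_idx, disrupted in enumerate(pattern, start=1):
        if not disrupted:
            continue
        for ci in flank_indices(geometry, node_idx):
            kind = geometry.compartments[ci].kind
            if kind == PARANODE:
                widths[ci] = w_pn
                if kv_density > 0:
                    kfast[ci] = kv_density
            else:
                widths[ci] = w_jxp
    return geometry.with_widths(widths), kfast


def simulate_geometry(
    geometry: AxonGeometry,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    paranodal_kfast: dict[int, float] | None = None,
    stimulus: StimulusSpec | None = None,
    config: SolverConfig | None = None,
    nodes: tuple[int, int] = (4, 16),
) -> tuple[SimulationTrace, ConductionResult]:
    """Assemble, stimulate and measure one axon; the basic experiment unit."""
    channel_set = channel_set or kinetics.default_region_channel_set()
    net = assemble_network(geometry, channel_set, biophysics, paranodal_kfast)
    trace = run_simulation(net, stimulus, config)
    try:
        result = conduction_velocity(trace, geometry, nodes=nodes)
    except Exception:
        result = ConductionResult(None, None, None, failed=True, nodes=nodes)
    return trace, result


def measurement_nodes(n_nodes: int) -> tuple[int, int]:
    """Default recording pair: nodes 4 and 16, shrunk for short axons."""
    if n_nodes >= 16:
        return (4, 16)
    return (2, n_nodes - 1)


def baseline_velocity(
    fibre_class: FibreClass,
    n_nodes: int = 21,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    config: SolverConfig | None = None,
    nodes: tuple[int, int] | None = None,
) -> float:
    """Conduction velocity of the undisrupted axon, m/s."""
    nodes = nodes or measurement_nodes(n_nodes)
    geom = build_axon(fibre_class, n_nodes=n_nodes)
    _, res = simulate_geometry(
        geom, channel_set, biophysics, config=config, nodes=nodes
    )
    if res.failed:
        raise ScenarioError(
            f"baseline axon d_core={fibre_class.d_core} failed to conduct; "
            "check biophysics configuration"
        )
    return res.velocity_m_s


def sweep_space_increase(
    fibre_classes: list[FibreClass],
    kind: str,
    f_grid=DEFAULT_F_GRID,
    n_nodes: int = 21,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    config: SolverConfig | None = None,
) -> tuple[list[ScenarioResult], dict[float, tuple[float, float]]]:
    """Normalised velocity vs fold increase for every fibre class.

    Returns one ScenarioResult per (class, f) plus, per class (keyed by
    d_core), the coefficients (a, b) of a logarithmic fit
    y = a * ln(x) + b with x the percent increase (f > 0 points that
    still conduct).
    """
    f_grid = list(f_grid)
    if sorted(f_grid) != f_grid or (f_grid and f_grid[0] != 0.0):
        raise ScenarioError("f grid must ascend from 0")
    channel_set = channel_set or kinetics.default_region_channel_set()

    results: list[ScenarioResult] = []
    fits: dict[float, tuple[float, float]] = {}
    nodes = measurement_nodes(n_nodes)
    for fc in fibre_classes:
        geom0 = build_axon(fc, n_nodes=n_nodes)
        v0 = None
        xs, ys = [], []
        for f in f_grid:
            scen = DisruptionScenario(kind=kind, f=f)
            geom, chs, kfast = apply_scenario(geom0, channel_set, scen)
            _, res = simulate_geometry(
                geom, chs, biophysics, paranodal_kfast=kfast, config=config,
                nodes=nodes,
            )
            if f == 0.0:
                if res.failed:
                    raise ScenarioError(
                        f"baseline failure at d_core={fc.d_core}: cannot normalise"
                    )
                v0 = res.velocity_m_s
            norm = None if res.failed else res.velocity_m_s / v0
            results.append(
                ScenarioResult(fc, scen, res.velocity_m_s, norm, res.failed)
            )
            if f > 0 and not res.failed:
                xs.append(100.0 * f)
                ys.append(norm)
        if len(xs) >= 2:
            a, b = np.polyfit(np.log(xs), ys, 1)
            fits[fc.d_core] = (float(a), float(b))
    return results, fits


def min_consecutive_for_failure(
    fibre_class: FibreClass,
    disrupted_widths: tuple[float, float],
    max_run: int | None = None,
    n_nodes: int = 21,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    config: SolverConfig | None = None,
    kv_density: float = 0.0,
) -> int | None:
    """Smallest centered run of disrupted nodes that blocks conduction.

    Runs of k consecutive disrupted nodes (all others healthy) are centered
    on the axon; returns the smallest k <= max_run for which no spike
    reaches node 16, or None if none blocks.
    """
    w0 = DEFAULT_PERIAXONAL_WIDTHS_UM
    if disrupted_widths[0] <= w0[0] and disrupted_widths[1] <= w0[1]:
        return None  # not a disruption: baseline conducts by construction
    max_run = max_run or n_nodes
    nodes = measurement_nodes(n_nodes)
    geom0 = build_axon(fibre_class, n_nodes=n_nodes)
    for k in range(1, max_run + 1):
        start = (n_nodes - k) // 2
        pattern = tuple(start <= i < start + k for i in range(n_nodes))
        geom, kfast = _disrupt_absolute(geom0, pattern, disrupted_widths, kv_density)
        _, res = simulate_geometry(
            geom, channel_set, biophysics, paranodal_kfast=kfast, config=config,
            nodes=nodes,
        )
        if res.failed:
            return k
    return None


def pattern_run(
    fibre_class: FibreClass,
    pattern: tuple[bool, ...] | str,
    disrupted_widths: tuple[float, float],
    n_nodes: int = 21,
    channel_set: RegionChannelSet | None = None,
    biophysics: Biophysics | None = None,
    config: SolverConfig | None = None,
    kv_density: float = 0.0,
    baseline_v: float | None = None,
) -> ScenarioResult:
    """Velocity/failure for one interleaving of disrupted and healthy nodes."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if len(pattern) != n_nodes:
        raise ScenarioError(f"pattern length {len(pattern)} != {n_nodes} nodes")
    nodes = measurement_nodes(n_nodes)
    geom0 = build_axon(fibre_class, n_nodes=n_nodes)
    geom, kfast = _disrupt_absolute(geom0, pattern, disrupted_widths, kv_density)
    _, res = simulate_geometry(
        geom, channel_set, biophysics, paranodal_kfast=kfast, config=config,
        nodes=nodes,
    )
    if baseline_v is None:
        baseline_v = baseline_velocity(
            fibre_class, n_nodes, channel_set, biophysics, config
        )
    norm = None if res.failed else res.velocity_m_s / baseline_v
    return ScenarioResult(
        fibre_class,
        DisruptionScenario(kind="b", f=0.0, pattern=tuple(pattern)),
        res.velocity_m_s,
        norm,
        res.failed,
    )


def repeating_pattern(n_nodes: int, n_disrupted: int, n_healthy: int) -> tuple[bool, ...]:
    """Repeat a block of disrupted then healthy nodes along the axon."""
    block = [True] * n_disrupted + [False] * n_healthy
    return tuple(block[i % len(block)] for i in range(n_nodes))
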