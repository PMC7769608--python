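"""Diameter-dependent anatomy of a multi-node CNS myelinated axon.

A fibre is described by its outer (fibre) diameter, its axon-core diameter
and the number of compact-myelin lamellae wrapped around the internodal
segments.  From the fibre diameter two empirical scaling laws give the
node-to-node spacing and the juxtaparanode length; the internode length is
whatever remains once two paranodes, two juxtaparanodes and one node are
carved out of the node-to-node distance.  The result is an ordered list of
compartments (node / paranode / juxtaparanode / internode) that tiles the
axon exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

#: Spacing of one compact myelin wrap (major dense line periodicity), um.
MYELIN_PERIODICITY_UM = 0.0156

#: Default compartment lengths, um.
DEFAULT_NODE_LENGTH_UM = 1.0
DEFAULT_PARANODE_LENGTH_UM = 2.3

#: Default peri-axonal space widths (paranode, juxtaparanode, internode), um.
DEFAULT_PERIAXONAL_WIDTHS_UM = (0.002, 0.02, 0.02)

NODE = "node"
PARANODE = "paranode"
JUXTAPARANODE = "juxtaparanode"
INTERNODE = "internode"

COMPARTMENT_KINDS = (NODE, PARANODE, JUXTAPARANODE, INTERNODE)


class GeometryError(ValueError):
    """Raised when a requested axon geometry is not physically realisable."""


def lamella_count(d_fibre: float, d_core: float) -> int:
    """Number of myelin lamellae from the sheath thickness and periodicity.

    The radial sheath thickness ``(d_fibre - d_core) / 2`` is divided by the
    myelin periodicity and rounded half-up to the nearest integer (minimum 1).
    """
    if d_fibre <= d_core or d_core <= 0:
        raise GeometryError(
            f"require d_fibre > d_core > 0, got d_fibre={d_fibre}, d_core={d_core}"
        )
    n = (d_fibre - d_core) / 2.0 / MYELIN_PERIODICITY_UM
    return max(1, int(math.floor(n + 0.5)))


@dataclass(frozen=True)
class FibreClass:
    """One simulated axon calibre.

    Attributes
    ----------
    d_fibre : float
        Outer fibre diameter (axon + myelin), um.
    d_core : float
        Axon core diameter, um.
    n_lamellae : int
        Number of compact-myelin lamellae.
    """

    d_fibre: float
    d_core: float
    n_lamellae: int

    def __post_init__(self) -> None:
        if not (self.d_fibre > self.d_core > 0):
            raise GeometryError(
                f"require d_fibre > d_core > 0, got {self.d_fibre}, {self.d_core}"
            )
        if self.n_lamellae < 1:
            raise GeometryError("n_lamellae must be >= 1")

    @classmethod
    def from_diameters(cls, d_fibre: float, d_core: float) -> "FibreClass":
        return cls(d_fibre, d_core, lamella_count(d_fibre, d_core))


# (d_fibre, d_core) pairs of the seven simulated calibres, ascending.
_BUILTIN_DIAMETERS = (
    (0.5, 0.4),
    (0.8, 0.6),
    (1.1, 0.8),
    (1.3, 1.0),
    (1.6, 1.2),
    (1.8, 1.4),
    (3.5, 2.7),
)


def builtin_fibre_table() -> list[FibreClass]:
    """The seven built-in fibre calibres with computed lamella counts."""
    return [FibreClass.from_diameters(df, dc) for df, dc in _BUILTIN_DIAMETERS]


def fibre_class_by_core(d_core: float, tol: float = 1e-9) -> FibreClass:
    """Look up a built-in fibre class by its core diameter."""
    for fc in builtin_fibre_table():
        if abs(fc.d_core - d_core) <= tol:
            return fc
    raise GeometryError(f"no built-in fibre class with d_core={d_core}")


def node_to_node_length(d_fibre: float) -> float:
    """Node-to-node spacing, um: linear in fibre diameter (117.52 + 30.47 d)."""
    if d_fibre <= 0:
        raise GeometryError(f"d_fibre must be positive, got {d_fibre}")
    return 117.52 + 30.47 * d_fibre


def juxtaparanode_length(d_fibre: float) -> float:
    """Juxtaparanode length, um: linear in fibre diameter (19.6 + 2.58 d)."""
    if d_fibre <= 0:
        raise GeometryError(f"d_fibre must be positive, got {d_fibre}")
    return 19.6 + 2.58 * d_fibre


@dataclass(frozen=True)
class CompartmentSpec:
    """One axonal compartment.

    ``n_lamellae`` is 0 for nodes (bare axolemma) and the fibre-class count
    for all myelinated compartments.  ``axial_offset`` is the distance from
    the proximal end of the axon to the proximal face of the compartment, um.
    """

    kind: str
    length: float
    periaxonal_width: float
    n_lamellae: int
    axial_offset: float

    def __post_init__(self) -> None:
        if self.kind not in COMPARTMENT_KINDS:
            raise GeometryError(f"unknown compartment kind {self.kind!r}")
        if self.length <= 0:
            raise GeometryError(f"compartment length must be > 0, got {self.length}")
        if self.periaxonal_width < 0:
            raise GeometryError("periaxonal width must be >= 0")
        if self.kind == NODE and self.n_lamellae != 0:
            raise GeometryError("node compartments carry no myelin")


@dataclass(frozen=True)
class AxonGeometry:
    """Ordered compartment list of one myelinated axon."""

    fibre_class: FibreClass
    compartments: tuple[CompartmentSpec, ...]
    n_nodes: int
    node_length: float = DEFAULT_NODE_LENGTH_UM
    paranode_length: float = DEFAULT_PARANODE_LENGTH_UM

    @property
    def total_length(self) -> float:
        return sum(c.length for c in self.compartments)

    def node_positions(self) -> list[float]:
        """Axial midpoint of every node, um from the axon start."""
        return [
            c.axial_offset + c.length / 2.0
            for c in self.compartments
            if c.kind == NODE
        ]

    def node_spacing(self) -> float:
        return node_to_node_length(self.fibre_class.d_fibre)

    def to_frame(self) -> pd.DataFrame:
        """Compartment table (kind, length_um, periaxonal_width_um, n_lamellae, offset_um)."""
        return pd.DataFrame(
            {
                "kind": [c.kind for c in self.compartments],
                "length_um": [c.length for c in self.compartments],
                "periaxonal_width_um": [c.periaxonal_width for c in self.compartments],
                "n_lamellae": [c.n_lamellae for c in self.compartments],
                "offset_um": [c.axial_offset for c in self.compartments],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def with_widths(self, widths: dict[int, float]) -> "AxonGeometry":
        """Copy with the peri-axonal width of selected compartments replaced.

        ``widths`` maps compartment index -> new width, um.
        """
        comps = list(self.compartments)
        for idx, w in widths.items():
            if w < 0:
                raise GeometryError("periaxonal width must be >= 0")
            comps[idx] = replace(comps[idx], periaxonal_width=w)
        return replace(self, compartments=tuple(comps))


def internode_length(
    d_fibre: float,
    paranode_length: float = DEFAULT_PARANODE_LENGTH_UM,
    node_length: float = DEFAULT_NODE_LENGTH_UM,
) -> float:
    """Internode length left between two juxtaparanodes, um.

    L_int = node_to_node - 2 (L_pn + L_jxp) - L_node.  Subtracting the node
    makes the four compartment types tile the node-to-node distance exactly.
    """
    L = (
        node_to_node_length(d_fibre)
        - 2.0 * (paranode_length + juxtaparanode_length(d_fibre))
        - node_length
    )
    if L <= 0:
        raise GeometryError(
            f"paranodes/juxtaparanodes too long for d_fibre={d_fibre}: "
            f"derived internode length {L:.3f} um <= 0"
        )
    return L


def build_axon(
    fibre_class: FibreClass,
    n_nodes: int = 21,
    paranode_length: float = DEFAULT_PARANODE_LENGTH_UM,
    node_length: float = DEFAULT_NODE_LENGTH_UM,
    baseline_widths: tuple[float, float, float] = DEFAULT_PERIAXONAL_WIDTHS_UM,
) -> AxonGeometry:
    """Build the symmetric compartment chain node-pn-jxp-int-jxp-pn-node...

    For ``n_nodes`` nodes this produces n_nodes nodes, 2(n_nodes-1) paranodes,
    2(n_nodes-1) juxtaparanodes and n_nodes-1 internodes.
    """
    if n_nodes < 3:
        raise GeometryError("n_nodes must be >= 3")
    w_pn, w_jxp, w_int = baseline_widths
    d_f = fibre_class.d_fibre
    L_jxp = juxtaparanode_length(d_f)
    L_int = internode_length(d_f, paranode_length, node_length)
    nl = fibre_class.n_lamellae

    comps: list[CompartmentSpec] = []
    offset = 0.0

    def add(kind: str, length: float, width: float, lam: int) -> None:
        nonlocal offset
        comps.append(CompartmentSpec(kind, length, width, lam, offset))
        offset += length

    add(NODE, node_length, 0.0, 0)
    for _ in range(n_nodes - 1):
        add(PARANODE, paranode_length, w_pn, nl)
        add(JUXTAPARANODE, L_jxp, w_jxp, nl)
        add(INTERNODE, L_int, w_int, nl)
        add(JUXTAPARANODE, L_jxp, w_jxp, nl)
        add(PARANODE, paranode_length, w_pn, nl)
        add(NODE, node_length, 0.0, 0)

    return AxonGeometry(
        fibre_class=fibre_class,
        compartments=tuple(comps),
        n_nodes=n_nodes,
        node_length=node_length,
        paranode_length=paranode_length,
    )


def flank_indices(geometry: AxonGeometry, node_index: int) -> list[int]:
    """Compartment indices of the paranodes/juxtaparanodes flanking a node.

    ``node_index`` is 1-based (node 1 = proximal end).  Both flanking
    paranode/juxtaparanode pairs are returned (one pair for an end node).
    """
    if not 1 <= node_index <= geometry.n_nodes:
        raise GeometryError(f"node index {node_index} out of range")
    node_pos = [
        i for i, c in enumerate(geometry.compartments) if c.kind == NODE
    ][node_index - 1]
    out = []
    for i in (node_pos - 2, node_pos - 1, node_pos + 1, node_pos + 2):
        if 0 <= i < len(geometry.compartments):
            if geometry.compartments[i].kind in (PARANODE, JUXTAPARANODE):
                out.append(i)
    return out
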