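"""Signed Boolean networks, state codec, degree distributions, and file I/O.

A gene regulatory network is represented as a set of named binary nodes
connected by signed (activation / inhibition) directed interactions.  The
node declaration order is significant: it fixes the bit order used by the
state codec, so a network state can be written as a bitstring such as
``"00001000100"``.

Self-degradation (a node decaying to 0 after being active with all of its
regulators silent for ``t_d`` consecutive steps) is a node-level flag, not an
interaction edge, and therefore does not contribute to node in-degree or to
the factor-graph degree distribution.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence


class NetworkFormatError(ValueError):
    """Raised when a network file cannot be parsed."""


class CodecError(ValueError):
    """Raised when a bitstring does not match the network's state layout."""


class Sign(str, enum.Enum):
    """Interaction sign: a regulator either activates or inhibits its target."""

    ACTIVATION = "+"
    INHIBITION = "-"

    @classmethod
    def from_token(cls, token: str) -> "Sign":
        try:
            return cls(token)
        except ValueError:
            raise NetworkFormatError(f"unknown sign token {token!r}; expected '+' or '-'")


@dataclass(frozen=True)
class GeneNode:
    """A binary-valued network node (gene, transcription factor, ...)."""

    name: str
    self_degrading: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene names must be non-empty")


@dataclass(frozen=True)
class Interaction:
    """A signed directed regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: Sign


@dataclass(frozen=True)
class BooleanNetwork:
    """A signed Boolean network with optional clamped (fixed-state) genes.

    Parameters
    ----------
    nodes:
        Ordered gene nodes; the order defines the state encoding.
    interactions:
        Signed directed edges.  At most one interaction per ordered
        (source, target) pair.
    t_d:
        Self-degradation delay in time steps (default 1).
    clamps:
        Optional map from gene name to a fixed bit.  A clamped gene has no
        update function: it holds its clamp value at every step (gene
        knockout clamps to 0, over-expression to 1).
    """

    nodes: tuple[GeneNode, ...]
    interactions: tuple[Interaction, ...] = ()
    t_d: int = 1
    clamps: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        object.__setattr__(self, "clamps", dict(self.clamps))
        names = [node.name for node in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        known = set(names)
        seen_pairs: set[tuple[str, str]] = set()
        for ia in self.interactions:
            if ia.source not in known or ia.target not in known:
                raise ValueError(f"interaction {ia.source}->{ia.target} references unknown gene")
            pair = (ia.source, ia.target)
            if pair in seen_pairs:
                raise ValueError(f"duplicate interaction {ia.source}->{ia.target}")
            seen_pairs.add(pair)
        if self.t_d < 1:
            raise ValueError("t_d must be a positive integer")
        for gene, bit in self.clamps.items():
            if gene not in known:
                raise ValueError(f"clamp references unknown gene {gene!r}")
            if bit not in (0, 1):
                raise ValueError(f"clamp value for {gene!r} must be 0 or 1")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(node.name for node in self.nodes)

    @property
    def index(self) -> dict[str, int]:
        return {node.name: i for i, node in enumerate(self.nodes)}

    def regulators(self, target: str) -> tuple[Interaction, ...]:
        """Interactions targeting ``target``, in declaration order."""
        return tuple(ia for ia in self.interactions if ia.target == target)

    def regulator_table(self) -> list[list[tuple[int, Sign]]]:
        """Per-node regulator list as (source index, sign), in node order."""
        idx = self.index
        table: list[list[tuple[int, Sign]]] = [[] for _ in self.nodes]
        for ia in self.interactions:
            table[idx[ia.target]].append((idx[ia.source], ia.sign))
        return table

    def k(self, name: str) -> int:
        """In-degree (number of regulators) of a gene."""
        if name not in self.index:
            raise KeyError(f"unknown gene {name!r}; known genes: {', '.join(self.names)}")
        return sum(1 for ia in self.interactions if ia.target == name)

    def with_clamps(self, new_clamps: Mapping[str, int]) -> "BooleanNetwork":
        merged = dict(self.clamps)
        merged.update(new_clamps)
        return replace(self, clamps=merged)


@dataclass(frozen=True)
class StateVector:
    """An ordered binary assignment, one bit per node in network node order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(int(b) for b in self.bits))
        if any(b not in (0, 1) for b in self.bits):
            raise CodecError("state bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def to_bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_bitstring(cls, bits: str, net: BooleanNetwork) -> "StateVector":
        return decode_state(bits, net)


def encode_state(state: StateVector) -> str:
    """Encode a state as a bitstring in node order."""
    return state.to_bitstring()


def decode_state(bits: str, net: BooleanNetwork) -> StateVector:
    """Decode a bitstring into a :class:`StateVector` for ``net``.

    Position ``i`` of the string corresponds to node ``i`` in declaration
    order.  Raises :class:`CodecError` on wrong length or characters.
    """
    if len(bits) != net.n:
        raise CodecError(f"bitstring length {len(bits)} does not match network size {net.n}")
    if any(c not in "01" for c in bits):
        raise CodecError(f"bitstring may only contain 0/1, got {bits!r}")
    return StateVector(tuple(int(c) for c in bits))


@dataclass(frozen=True)
class DegreeDistribution:
    """Edge-perspective control-node degree distribution rho(x) = sum rho_j x^j.

    ``rho_j`` is the fraction of factor-graph edges incident to a control node
    of degree ``j``; the coefficients are non-negative and sum to one.
    """

    coefficients: Mapping[int, float]

    _TOL = 1e-12

    def __post_init__(self) -> None:
        coeffs = {int(j): float(r) for j, r in self.coefficients.items() if r != 0.0}
        object.__setattr__(self, "coefficients", coeffs)
        if not coeffs:
            raise ValueError("degree distribution must have at least one term")
        if any(j < 1 for j in coeffs):
            raise ValueError("control-node degrees must be >= 1")
        if any(r < 0 for r in coeffs.values()):
            raise ValueError("rho_j coefficients must be non-negative")
        total = math.fsum(coeffs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"rho_j coefficients must sum to 1 (got {total!r})")

    @property
    def d_c(self) -> int:
        """Maximum control-node degree."""
        return max(self.coefficients)

    def rho(self, j: int) -> float:
        return self.coefficients.get(j, 0.0)

    def degrees(self) -> tuple[int, ...]:
        return tuple(sorted(self.coefficients))

    @classmethod
    def from_coefficient_list(cls, rho: Sequence[float]) -> "DegreeDistribution":
        """Build from ``[rho_1, rho_2, ...]`` (degree-1 coefficient first)."""
        return cls({j + 1: r for j, r in enumerate(rho)})

    def as_polynomial(self) -> str:
        terms = []
        for j in self.degrees():
            power = "x" if j == 1 else f"x^{j}"
            terms.append(f"{self.coefficients[j]:g}{power}")
        return " + ".join(terms)


def degree_distribution(net: BooleanNetwork) -> DegreeDistribution:
    """Edge-perspective degree distribution of a network's factor graph.

    The control node of gene ``i`` has factor-graph degree ``k_i + 1``: one
    edge per regulator plus the edge to its own child variable.  Clamped
    genes contribute no control node.
    """
    if net.n == 0:
        raise ValueError("network must have at least one node")
    degree_counts: dict[int, int] = {}
    for node in net.nodes:
        if node.name in net.clamps:
            continue
        degree = net.k(node.name) + 1
        degree_counts[degree] = degree_counts.get(degree, 0) + 1
    total_edges = sum(j * c for j, c in degree_counts.items())
    return DegreeDistribution({j: j * c / total_edges for j, c in degree_counts.items()})


# -- file I/O --------------------------------------------------------------
#
# Plain TSV dialect:
#   node<TAB>NAME<TAB>selfdeg={0,1}      one per gene, in encoding order
#   param<TAB>t_d<TAB><int>              optional, default 1
#   edge<TAB>SOURCE<TAB>TARGET<TAB>{+,-}
#   clamp<TAB>NAME<TAB>{0,1}             optional fixed-state line
#   # comment lines and blank lines are ignored


def load_network(path: str | Path) -> BooleanNetwork:
    """Load a :class:`BooleanNetwork` from the TSV edge-list format."""
    path = Path(path)
    nodes: list[GeneNode] = []
    interactions: list[Interaction] = []
    clamps: dict[str, int] = {}
    t_d = 1
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            try:
                if kind == "node":
                    name, selfdeg = fields[1], fields[2]
                    if not selfdeg.startswith("selfdeg="):
                        raise NetworkFormatError("expected selfdeg={0,1}")
                    flag = selfdeg.split("=", 1)[1]
                    if flag not in ("0", "1"):
                        raise NetworkFormatError(f"bad selfdeg value {flag!r}")
                    nodes.append(GeneNode(name, self_degrading=flag == "1"))
                elif kind == "edge":
                    source, target, sign = fields[1], fields[2], fields[3]
                    interactions.append(Interaction(source, target, Sign.from_token(sign)))
                elif kind == "param":
                    if fields[1] != "t_d":
                        raise NetworkFormatError(f"unknown parameter {fields[1]!r}")
                    t_d = int(fields[2])
                elif kind == "clamp":
                    clamps[fields[1]] = int(fields[2])
                else:
                    raise NetworkFormatError(f"unknown record type {kind!r}")
            except (IndexError, NetworkFormatError, ValueError) as exc:
                raise NetworkFormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return BooleanNetwork(tuple(nodes), tuple(interactions), t_d=t_d, clamps=clamps)
    except ValueError as exc:
        raise NetworkFormatError(f"{path}: {exc}") from exc


def save_network(net: BooleanNetwork, path: str | Path) -> None:
    """Write ``net`` in the TSV format; ``load_network`` round-trips exactly."""
    path = Path(path)
    lines = [f"# boolean network, {net.n} nodes, {len(net.interactions)} interactions"]
    for node in net.nodes:
        lines.append(f"node\t{node.name}\tselfdeg={int(node.self_degrading)}")
    lines.append(f"param\tt_d\t{net.t_d}")
    for ia in net.interactions:
        lines.append(f"edge\t{ia.source}\t{ia.target}\t{ia.sign.value}")
    for gene, bit in net.clamps.items():
        lines.append(f"clamp\t{gene}\t{bit}")
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write network file {path}: {exc}") from exc


# -- built-in yeast cell-cycle fixture ------------------------------------

#: Node order used for bitstring encoding of the budding-yeast network.
YEAST_GENE_ORDER = (
    "Cln3",
    "MBF",
    "SBF",
    "Cln1,2",
    "Cdh1",
    "Swi5",
    "Cdc20,14",
    "Clb5,6",
    "Sic1",
    "Clb1,2",
    "Mcm1/SFF",
)

_YEAST_SELF_DEGRADING = {"Cln3", "Cln1,2", "Swi5", "Cdc20,14", "Mcm1/SFF"}

_YEAST_EDGES: tuple[tuple[str, str, str], ...] = (
    ("Cln3", "MBF", "+"),
    ("Cln3", "SBF", "+"),
    ("Clb1,2", "MBF", "-"),
    ("Clb1,2", "SBF", "-"),
    ("SBF", "Cln1,2", "+"),
    ("Cln1,2", "Cdh1", "-"),
    ("Clb5,6", "Cdh1", "-"),
    ("Clb1,2", "Cdh1", "-"),
    ("Cdc20,14", "Cdh1", "+"),
    ("Mcm1/SFF", "Swi5", "+"),
    ("Cdc20,14", "Swi5", "+"),
    ("Clb1,2", "Swi5", "-"),
    ("Clb1,2", "Cdc20,14", "+"),
    ("Mcm1/SFF", "Cdc20,14", "+"),
    ("MBF", "Clb5,6", "+"),
    ("Sic1", "Clb5,6", "-"),
    ("Cdc20,14", "Clb5,6", "-"),
    ("Cln1,2", "Sic1", "-"),
    ("Clb5,6", "Sic1", "-"),
    ("Clb1,2", "Sic1", "-"),
    ("Swi5", "Sic1", "+"),
    ("Cdc20,14", "Sic1", "+"),
    ("Clb5,6", "Clb1,2", "+"),
    ("Mcm1/SFF", "Clb1,2", "+"),
    ("Cdh1", "Clb1,2", "-"),
    ("Sic1", "Clb1,2", "-"),
    ("Cdc20,14", "Clb1,2", "-"),
    ("Clb5,6", "Mcm1/SFF", "+"),
    ("Clb1,2", "Mcm1/SFF", "+"),
)

#: Stationary G1 fixed point of the yeast network: only Cdh1 and Sic1 active.
YEAST_STATIONARY_G1 = "00001000100"
#: The Start excited state: stationary G1 with the Cln3 size signal on.
YEAST_START_STATE = "10001000100"


def li_yeast_network() -> BooleanNetwork:
    """The 11-node budding-yeast cell-cycle network (Li model).

    Eleven regulators of the G1/S/G2/M progression with 29 signed
    interactions; Cln3, Cln1,2, Swi5, Cdc20,14 and Mcm1/SFF self-degrade
    with delay ``t_d = 1``.  Cln3 has no regulators: it is the "starter
    kinase" switched on by the cell-size signal to trigger Start.
    """
    nodes = tuple(
        GeneNode(name, self_degrading=name in _YEAST_SELF_DEGRADING)
        for name in YEAST_GENE_ORDER
    )
    interactions = tuple(
        Interaction(src, tgt, Sign.from_token(sign)) for src, tgt, sign in _YEAST_EDGES
    )
    return BooleanNetwork(nodes, interactions, t_d=1)
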