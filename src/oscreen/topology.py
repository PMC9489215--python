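"""Signed two- and three-node regulatory topologies.

A topology is a map from ordered node pairs to a sign: +1 (activation),
-1 (inhibition) or 0 (no link).  Self-pairs encode autoregulation.  The
module enumerates the canonical universe of 2- and 3-node topologies,
reduces it modulo node relabeling, and classifies topologies by the core
oscillator motifs they contain (repressilator with/without positive
autoregulation, activator-inhibitor family, delayed negative feedback).
"""

from __future__ import annotations

import itertools
import json
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

NODE_NAMES = ("A", "B", "C")

ACTIVATION = 1
INHIBITION = -1
ABSENT = 0

_VALID_SIGNS = (-1, 0, 1)


class IsolationConvention(Enum):
    """How a node disqualifies a topology from the enumerated universe.

    ``IN_AND_OUT_CROSS`` — every node needs at least one incoming and one
    outgoing link to/from *another* node (self-loops do not count).  This
    is the default: it is the convention under which the combined 2-+3-node
    canonical universe has exactly 1955 members.

    ``CROSS`` — a node is isolated when it has no cross-links at all
    (neither direction); a self-loop does not rescue it.

    ``SELF_RESCUES`` — a node is isolated only when it carries no links at
    all, including self-loops.

    ``IN_AND_OUT_ANY`` — every node needs in-degree >= 1 and out-degree
    >= 1 with self-loops counting toward both.
    """

    IN_AND_OUT_CROSS = "in_and_out_cross"
    CROSS = "cross"
    SELF_RESCUES = "self_rescues"
    IN_AND_OUT_ANY = "in_and_out_any"


@dataclass(frozen=True)
class SignedTopology:
    """Immutable signed adjacency over 2 or 3 nodes.

    ``signs`` is the row-major flattening of the n x n sign matrix:
    entry ``signs[i * n + j]`` is the sign of the link ``i -> j``.
    """

    n_nodes: int
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_nodes not in (2, 3):
            raise ValueError(f"n_nodes must be 2 or 3, got {self.n_nodes}")
        if len(self.signs) != self.n_nodes**2:
            raise ValueError(
                f"expected {self.n_nodes ** 2} signs, got {len(self.signs)}"
            )
        for s in self.signs:
            if s not in _VALID_SIGNS:
                raise ValueError(f"invalid sign {s!r}; signs must be -1, 0 or +1")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_links(
        cls, n_nodes: int, links: Iterable[tuple[str | int, str | int, int]]
    ) -> "SignedTopology":
        """Build from ``(source, target, sign)`` triples; names or indices."""
        signs = [0] * (n_nodes**2)
        for src, tgt, sign in links:
            i = _node_index(src, n_nodes)
            j = _node_index(tgt, n_nodes)
            if sign not in (-1, 1):
                raise ValueError(
                    f"link {src!r}->{tgt!r}: sign must be +1 or -1, got {sign!r}"
                )
            signs[i * n_nodes + j] = sign
        return cls(n_nodes, tuple(signs))

    # -- basic queries ---------------------------------------------------------

    def sign(self, src: int, tgt: int) -> int:
        return self.signs[src * self.n_nodes + tgt]

    @property
    def links(self) -> dict[tuple[str, str], int]:
        """Existing links as ``{(source_name, target_name): sign}``."""
        n = self.n_nodes
        return {
            (NODE_NAMES[i], NODE_NAMES[j]): self.signs[i * n + j]
            for i in range(n)
            for j in range(n)
            if self.signs[i * n + j] != 0
        }

    def relabeled(self, perm: Sequence[int]) -> "SignedTopology":
        """Topology with node ``perm[i]`` taking the role of node ``i``."""
        n = self.n_nodes
        signs = tuple(
            self.signs[perm[i] * n + perm[j]] for i in range(n) for j in range(n)
        )
        return SignedTopology(n, signs)

    def __str__(self) -> str:
        return format_topology(self)


def _node_index(node: str | int, n_nodes: int) -> int:
    if isinstance(node, str):
        try:
            idx = NODE_NAMES.index(node)
        except ValueError:
            raise ValueError(f"unknown node name {node!r}") from None
    else:
        idx = int(node)
    if not 0 <= idx < n_nodes:
        raise ValueError(f"node {node!r} out of range for {n_nodes} nodes")
    return idx


# -- canonicalization ---------------------------------------------------------


def canonical_form(t: SignedTopology) -> SignedTopology:
    """Orbit representative under node relabeling.

    The representative is the lexicographically smallest flattened sign
    vector over all node permutations, so two topologies have equal
    canonical forms iff one is a relabeling of the other.
    """
    best = min(
        t.relabeled(p).signs for p in itertools.permutations(range(t.n_nodes))
    )
    return SignedTopology(t.n_nodes, best)


def topology_id(t: SignedTopology) -> int:
    """Stable integer identifier (CRC of the canonical sign vector)."""
    c = canonical_form(t)
    payload = bytes([c.n_nodes]) + bytes(s + 1 for s in c.signs)
    return zlib.crc32(payload)


# -- isolation / exclusion ----------------------------------------------------


def has_isolated_node(t: SignedTopology) -> bool:
    """True iff some node has no cross-links at all.

    A node is isolated when it has neither incoming nor outgoing links
    to/from *other* nodes; a self-loop does not rescue it.
    """
    n = t.n_nodes
    for k in range(n):
        if all(
            t.sign(k, j) == 0 and t.sign(j, k) == 0 for j in range(n) if j != k
        ):
            return True
    return False


def violates_convention(t: SignedTopology, convention: IsolationConvention) -> bool:
    """Whether a topology is excluded from the universe under ``convention``."""
    n = t.n_nodes
    for k in range(n):
        cross_out = any(t.sign(k, j) != 0 for j in range(n) if j != k)
        cross_in = any(t.sign(j, k) != 0 for j in range(n) if j != k)
        self_loop = t.sign(k, k) != 0
        if convention is IsolationConvention.IN_AND_OUT_CROSS:
            bad = not (cross_out and cross_in)
        elif convention is IsolationConvention.CROSS:
            bad = not (cross_out or cross_in)
        elif convention is IsolationConvention.SELF_RESCUES:
            bad = not (cross_out or cross_in or self_loop)
        elif convention is IsolationConvention.IN_AND_OUT_ANY:
            bad = not ((cross_out or self_loop) and (cross_in or self_loop))
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(convention)
        if bad:
            return True
    return False


def enumerate_topologies(
    convention: IsolationConvention = IsolationConvention.IN_AND_OUT_CROSS,
    n_nodes: Iterable[int] = (2, 3),
) -> list[SignedTopology]:
    """Enumerate the deduplicated universe of 2- and 3-node topologies.

    All ``3**(n*n)`` labeled configurations per node count are generated,
    configurations excluded by ``convention`` are dropped, and the rest are
    reduced modulo node relabeling.  Under the default convention the
    combined 2-+3-node universe has 1955 members.
    """
    out: list[SignedTopology] = []
    for n in sorted(set(n_nodes)):
        seen: set[tuple[int, ...]] = set()
        for signs in itertools.product(_VALID_SIGNS, repeat=n * n):
            t = SignedTopology(n, signs)
            if violates_convention(t, convention):
                continue
            c = canonical_form(t)
            if c.signs not in seen:
                seen.add(c.signs)
                out.append(c)
    return out


# -- cycles and feedback ------------------------------------------------------


def directed_cycles(t: SignedTopology) -> list[tuple[int, ...]]:
    """All simple directed cycles (length 1-3), one rotation each.

    A cycle is reported as the node tuple ``(i, j, ...)`` with links
    ``i -> j -> ... -> i``; the rotation starting at the smallest node
    index is the representative.
    """
    n = t.n_nodes
    cycles: set[tuple[int, ...]] = set()
    for i in range(n):
        if t.sign(i, i) != 0:
            cycles.add((i,))
    for i, j in itertools.permutations(range(n), 2):
        if t.sign(i, j) != 0 and t.sign(j, i) != 0:
            cycles.add((min(i, j), max(i, j)))
    if n == 3:
        for i, j, k in itertools.permutations(range(n), 3):
            if i == min(i, j, k) and t.sign(i, j) != 0 and t.sign(j, k) != 0 and t.sign(k, i) != 0:
                cycles.add((i, j, k))
    return sorted(cycles)


def _cycle_signs(t: SignedTopology, cycle: tuple[int, ...]) -> list[int]:
    return [
        t.sign(cycle[m], cycle[(m + 1) % len(cycle)]) for m in range(len(cycle))
    ]


def contains_negative_feedback(t: SignedTopology) -> bool:
    """True iff some directed cycle carries an odd number of inhibitions."""
    return any(
        sum(1 for s in _cycle_signs(t, c) if s == INHIBITION) % 2 == 1
        for c in directed_cycles(t)
    )


def repressilator_cycles(t: SignedTopology) -> list[tuple[int, int, int]]:
    """Directed 3-cycles whose links are all inhibitory."""
    return [
        c
        for c in directed_cycles(t)
        if len(c) == 3 and all(s == INHIBITION for s in _cycle_signs(t, c))
    ]


def contains_repressilator(t: SignedTopology) -> bool:
    return bool(repressilator_cycles(t))


# -- core motifs ---------------------------------------------------------------

#: Signed link sets for the activator-inhibitor motif and its two 3-node
#: variants, on abstract nodes 0 (activator), 1 (inhibitor), 2 (relay).
#: Containment is subgraph matching: every motif link must exist with the
#: stated sign under some injective node mapping; extra links are allowed.
ACTIVATOR_INHIBITOR_MOTIFS: tuple[tuple[tuple[int, int, int], ...], ...] = (
    # canonical two-node form: 0 -> 0, 0 -> 1, 1 -| 0
    ((0, 0, 1), (0, 1, 1), (1, 0, -1)),
    # variant: the activating arm routed through the relay (0 -> 2 -> 1)
    ((0, 0, 1), (0, 2, 1), (2, 1, 1), (1, 0, -1)),
    # variant: the inhibiting arm routed through the relay (1 -> 2 -| 0)
    ((0, 0, 1), (0, 1, 1), (1, 2, 1), (2, 0, -1)),
)


def _positive_autoregulated(t: SignedTopology, node: int) -> bool:
    return t.sign(node, node) == ACTIVATION


def _has_positive_incoming(t: SignedTopology, node: int) -> bool:
    """Positive incoming cross-link (the self-loop itself does not count)."""
    return any(
        t.sign(j, node) == ACTIVATION for j in range(t.n_nodes) if j != node
    )


def _matches_motif(
    t: SignedTopology, motif: tuple[tuple[int, int, int], ...]
) -> bool:
    motif_nodes = sorted({n for (i, j, _) in motif for n in (i, j)})
    if len(motif_nodes) > t.n_nodes:
        return False
    for mapping in itertools.permutations(range(t.n_nodes), len(motif_nodes)):
        assign = dict(zip(motif_nodes, mapping))
        if all(t.sign(assign[i], assign[j]) == s for i, j, s in motif):
            return True
    return False


def find_core_motifs(
    t: SignedTopology,
    activator_inhibitor_motifs: tuple[tuple[tuple[int, int, int], ...], ...] = ACTIVATOR_INHIBITOR_MOTIFS,
) -> frozenset[int]:
    """Core-motif types (subset of {1..5}) present in the topology.

    Type 1 — repressilator plus a positively autoregulated node on the
    cycle that receives no positive incoming cross-link; type 2 — the same
    but the positive incoming link is present; type 3 — the
    activator-inhibitor motif or one of its relay variants; type 4 — a
    repressilator none of whose nodes is positively autoregulated; type 5
    — delayed negative feedback: a directed cycle of length >= 2 with
    exactly one inhibitory link and no positively autoregulated node on
    the cycle.  The negative clauses of types 1, 2, 4 and 5 are evaluated
    on the full topology, not the embedded subgraph.
    """
    found: set[int] = set()

    for cyc in repressilator_cycles(t):
        auto = [m for m in cyc if _positive_autoregulated(t, m)]
        if not auto:
            found.add(4)
        for m in auto:
            found.add(2 if _has_positive_incoming(t, m) else 1)

    if any(_matches_motif(t, motif) for motif in activator_inhibitor_motifs):
        found.add(3)

    for cyc in directed_cycles(t):
        if len(cyc) < 2:
            continue
        signs = _cycle_signs(t, cyc)
        if sum(1 for s in signs if s == INHIBITION) != 1:
            continue
        if any(_positive_autoregulated(t, m) for m in cyc):
            continue
        found.add(5)

    return frozenset(found)


@dataclass(frozen=True)
class MotifCategory:
    """Category label derived from the set of core motifs present."""

    core_motifs_present: frozenset[int]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        motifs = self.core_motifs_present
        if not motifs <= {1, 2, 3, 4, 5}:
            raise ValueError(f"motif types must be within 1..5, got {sorted(motifs)}")
        label = "C" + "".join(str(k) for k in sorted(motifs)) if motifs else "uncategorized"
        object.__setattr__(self, "label", label)


def assign_category(t: SignedTopology) -> MotifCategory:
    """Label ``Ck`` iff exactly motif type ``k`` is present; combined
    labels (``C13``) when several co-occur; ``uncategorized`` when none.

    Category labels are meaningful on the oscillatory universe; the
    function itself is defined (and relabeling-invariant) everywhere.
    """
    return MotifCategory(find_core_motifs(t))


# -- text / JSON formats -------------------------------------------------------


def format_topology(t: SignedTopology) -> str:
    """One line per link: ``source target sign`` with sign +1/-1."""
    lines = [
        f"{src} {tgt} {sign:+d}" for (src, tgt), sign in sorted(t.links.items())
    ]
    return "\n".join(lines)


def parse_topology(text: str, n_nodes: int | None = None) -> SignedTopology:
    """Parse the line-per-link text format.

    ``n_nodes`` defaults to the smallest node count (2 or 3) covering the
    named nodes.
    """
    triples: list[tuple[str, str, int]] = []
    max_idx = 1
    for raw in text.strip().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed link line {line!r}")
        src, tgt, sign_s = parts
        sign = int(sign_s)
        if sign not in (-1, 1):
            raise ValueError(f"link {src}->{tgt}: sign must be +1 or -1, got {sign_s!r}")
        for name in (src, tgt):
            if name not in NODE_NAMES:
                raise ValueError(f"unknown node name {name!r}")
            max_idx = max(max_idx, NODE_NAMES.index(name))
        triples.append((src, tgt, sign))
    if n_nodes is None:
        n_nodes = max(2, max_idx + 1)
    return SignedTopology.from_links(n_nodes, triples)


def topology_to_dict(t: SignedTopology) -> dict:
    return {
        "n_nodes": t.n_nodes,
        "links": [
            [src, tgt, sign] for (src, tgt), sign in sorted(t.links.items())
        ],
    }


def topology_from_dict(d: dict) -> SignedTopology:
    try:
        n_nodes = int(d["n_nodes"])
        links = d["links"]
    except KeyError as e:
        raise ValueError(f"topology dict missing field {e.args[0]!r}") from None
    triples = []
    for entry in links:
        if len(entry) != 3:
            raise ValueError(f"malformed link entry {entry!r}")
        src, tgt, sign = entry
        if sign not in (-1, 1):
            raise ValueError(
                f"field links[{src!r}->{tgt!r}]: sign must be +1 or -1, got {sign!r}"
            )
        triples.append((src, tgt, int(sign)))
    return SignedTopology.from_links(n_nodes, triples)


def save_topologies(topologies: Iterable[SignedTopology], path) -> None:
    """JSON list of canonical topologies with stable integer IDs."""
    payload = [
        {"id": topology_id(t), **topology_to_dict(canonical_form(t))}
        for t in topologies
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_topologies(path) -> list[SignedTopology]:
    with open(path) as fh:
        payload = json.load(fh)
    return [topology_from_dict(d) for d in payload]
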