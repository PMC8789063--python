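"""Nomenclature and bookkeeping for immobile DNA four-way junctions.

An immobile four-way (Holliday) junction has four strands (Roman numerals
I-IV) and, in the stacked-X form, two coaxially stacked pseudo-duplex
helices.  Which strand runs continuously through a given helix depends on
the crossover isomer: helix 1 contains strand I in isomer 1 and strand II
in isomer 2; helix 2 contains strand III in isomer 1 and strand IV in
isomer 2.  Every analyzed base-pair step is addressed by a compact label

    ``xn^i_(h,b)``

where ``x`` is the construct topology (J: full junction, B: left
single-crossover, D: right single-crossover, N: nicked duplex, d: intact
duplex), ``n`` the core-sequence identifier, ``i`` the isomer (1 or 2),
``h`` the helix (1 or 2) and ``b`` the base-pair step index (1-9 after
excluding the three terminal steps at each arm end, which fray).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping

TOPOLOGY_CODES = ("J", "B", "D", "N", "d")
STRAND_ORDER = ("I", "II", "III", "IV")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

_LABEL_RE = re.compile(
    r"^(?P<topology>[JBDNd])"
    r"(?P<core>[0-9A-Za-z]+?)"
    r"(?:\^(?P<isomer>\d+))?"
    r"(?:_\((?P<helix>\d+),(?P<step>\d+)\))?$"
)


class LabelError(ValueError):
    """Malformed or out-of-range step label."""


@dataclass(frozen=True)
class StepLabel:
    """Structured form of an ``xn^i_(h,b)`` step label."""

    topology: str
    core: str
    isomer: int
    helix: int
    step_index: int

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGY_CODES:
            raise LabelError(f"unknown topology code {self.topology!r}")
        if self.isomer not in (1, 2):
            raise LabelError(f"isomer must be 1 or 2, got {self.isomer}")
        if self.helix not in (1, 2):
            raise LabelError(f"helix must be 1 or 2, got {self.helix}")
        if not 1 <= self.step_index <= 9:
            raise LabelError(
                f"step index must lie in 1..9, got {self.step_index}"
            )

    def render(self) -> str:
        return (
            f"{self.topology}{self.core}^{self.isomer}"
            f"_({self.helix},{self.step_index})"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_step_label(text: str) -> StepLabel:
    """Parse ``xn^i_(h,b)`` into a :class:`StepLabel`.

    All four qualifier fields are required for a full step address; the
    grammar names the offending field when a component is missing or out
    of range.
    """
    m = _LABEL_RE.match(text.strip())
    if m is None:
        raise LabelError(f"cannot parse step label {text!r}")
    if m["isomer"] is None:
        raise LabelError(f"label {text!r} lacks the ^isomer field")
    if m["helix"] is None:
        raise LabelError(f"label {text!r} lacks the _(helix,step) field")
    step = int(m["step"])
    if not 1 <= step <= 9:
        raise LabelError(f"step index {step} outside 1..9 in {text!r}")
    return StepLabel(
        topology=m["topology"],
        core=m["core"],
        isomer=int(m["isomer"]),
        helix=int(m["helix"]),
        step_index=step,
    )


def analyzed_steps(
    arm_length_bp: int, excluded_terminal_steps: int = 3
) -> list[tuple[int, int]]:
    """Physical step numbers retained for analysis and their re-indexing.

    A pseudo-duplex of ``arm_length_bp`` base pairs has ``arm_length_bp-1``
    dinucleotide steps.  The ``excluded_terminal_steps`` outermost steps at
    each end are dropped (terminal fraying) and the remainder re-indexed
    from 1.  Returns ``[(physical_step, step_index), ...]``.
    """
    if arm_length_bp < 2 * excluded_terminal_steps + 2:
        raise ValueError(
            f"arm of {arm_length_bp} bp too short to exclude "
            f"{excluded_terminal_steps} terminal steps per end"
        )
    n_steps = arm_length_bp - 1
    first = excluded_terminal_steps + 1
    last = n_steps - excluded_terminal_steps
    return [(phys, idx + 1) for idx, phys in enumerate(range(first, last + 1))]


# ---------------------------------------------------------------------------
# Topology


@dataclass(frozen=True)
class JunctionTopology:
    """Strand sequences, pairing and helix membership of one construct.

    ``strands`` maps strand id -> 5'->3' sequence.  ``pairing`` maps
    (strand, 1-based position) -> its Watson-Crick partner and is an
    involution.  ``helices`` maps (isomer, helix) -> the ordered reading
    positions (strand, pos) defining the pseudo-duplex 5'->3'.  ``nicks``
    lists backbone breaks as (strand, pos) meaning the phosphodiester bond
    *after* that nucleotide is absent.  ``crossovers`` lists the strands
    that cross at the junction per isomer.
    """

    name: str
    topology_code: str
    strands: Mapping[str, str]
    pairing: Mapping[tuple[str, int], tuple[str, int]]
    helices: Mapping[tuple[int, int], tuple[tuple[str, int], ...]]
    nicks: tuple[tuple[str, int], ...] = ()
    crossovers: Mapping[int, tuple[str, ...]] = None  # type: ignore[assignment]
    mismatches: frozenset[tuple[str, int]] = frozenset()

    def validate(self) -> None:
        for (s, p), (s2, p2) in self.pairing.items():
            back = self.pairing.get((s2, p2))
            if back != (s, p):
                raise ValueError(f"pairing is not an involution at {(s, p)}")
            if (s, p) not in self.mismatches:
                a = self.strands[s][p - 1]
                b = self.strands[s2][p2 - 1]
                if _COMPLEMENT[a] != b:
                    raise ValueError(
                        f"non-Watson-Crick pair {a}-{b} at {(s, p)}/{(s2, p2)}"
                        " not flagged as a mismatch"
                    )

    def helix_strands(self, isomer: int, helix: int) -> tuple[str, tuple[str, ...]]:
        """Reading strand and complement-bearing strands of one pseudo-duplex.

        The reading strand defines the 5'->3' step order of the helix.
        """
        if isomer not in (1, 2) or helix not in (1, 2):
            raise ValueError(f"isomer/helix must be 1 or 2, got {isomer}/{helix}")
        positions = self.helices.get((isomer, helix))
        if positions is None:
            raise ValueError(f"no helix ({isomer},{helix}) in topology {self.name}")
        reading = positions[0][0]
        partners = []
        for sp in positions:
            partner = self.pairing[sp][0]
            if partner not in partners:
                partners.append(partner)
        return reading, tuple(partners)

    def helix_sequence(self, isomer: int, helix: int) -> str:
        positions = self.helices[(isomer, helix)]
        return "".join(self.strands[s][p - 1] for s, p in positions)

    def helix_pairs(
        self, isomer: int, helix: int
    ) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """Ordered (reading, complement) nucleotide pairs of the pseudo-duplex."""
        return [(sp, self.pairing[sp]) for sp in self.helices[(isomer, helix)]]

    def step_labels(self, isomer: int, helix: int,
                    excluded_terminal_steps: int = 3) -> list[StepLabel]:
        n_bp = len(self.helices[(isomer, helix)])
        return [
            StepLabel(self.topology_code, self.name_core, isomer, helix, idx)
            for _, idx in analyzed_steps(n_bp, excluded_terminal_steps)
        ]

    @property
    def name_core(self) -> str:
        """Core-sequence identifier, e.g. '1' for the J1 family."""
        return re.sub(r"^[JBDNd]", "", self.name)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, path: str | Path) -> "JunctionTopology":
        with open(path) as fh:
            doc = json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "JunctionTopology":
        pairing: dict[tuple[str, int], tuple[str, int]] = {}
        for block in doc["pairing_blocks"]:
            s1, a1, b1 = block["strand_a"], block["from_a"], block["to_a"]
            s2, a2 = block["strand_b"], block["from_b"]
            # antiparallel block: a-run ascending pairs with b-run descending
            for k in range(b1 - a1 + 1):
                p, q = (s1, a1 + k), (s2, a2 - k)
                pairing[p] = q
                pairing[q] = p
        helices = {}
        for key, spec in doc.get("helices", {}).items():
            iso, hel = (int(t) for t in key.split(","))
            strand, lo, hi = spec["strand"], spec["from"], spec["to"]
            helices[(iso, hel)] = tuple((strand, p) for p in range(lo, hi + 1))
        topo = cls(
            name=doc["name"],
            topology_code=doc.get("topology_code", "J"),
            strands=dict(doc["strands"]),
            pairing=pairing,
            helices=helices,
            nicks=tuple((n["strand"], n["position"]) for n in doc.get("nicks", [])),
            crossovers={
                int(k): tuple(v) for k, v in doc.get("crossovers", {}).items()
            },
            mismatches=frozenset(
                (m["strand"], m["position"]) for m in doc.get("mismatches", [])
            ),
        )
        topo.validate()
        return topo


def load_builtin_topology(name: str) -> JunctionTopology:
    """Load one of the packaged fixture topologies ('J1' or 'J24')."""
    path = Path(__file__).parent / "data" / f"{name.lower()}.json"
    if not path.exists():
        raise FileNotFoundError(f"no packaged topology named {name}")
    return JunctionTopology.from_json(path)


def helix_strands(
    topology: JunctionTopology, isomer: int, helix: int
) -> tuple[str, tuple[str, ...]]:
    """Functional wrapper around :meth:`JunctionTopology.helix_strands`."""
    return topology.helix_strands(isomer, helix)


# ---------------------------------------------------------------------------
# Variant construction: edits to pairing / backbone connectivity


def pseudo_duplex_variant(
    topology: JunctionTopology, isomer: int, helix: int, *, nicked: bool
) -> JunctionTopology:
    """Extract one pseudo-duplex as a standalone (nicked-)duplex construct.

    The reading strand of the chosen helix becomes strand 'R'; its
    complement becomes strand 'S', carrying a nick at the position mirroring
    the junction crossover when ``nicked`` is true.
    """
    pairs = topology.helix_pairs(isomer, helix)
    n = len(pairs)
    read_seq = topology.helix_sequence(isomer, helix)
    comp_seq = "".join(
        topology.strands[s][p - 1] for s, p in (pr[1] for pr in pairs)
    )[::-1]  # complement read 5'->3'
    # source complement switches strand where the junction crossover sits
    nick_positions: list[int] = []
    comp_sources = [pr[1][0] for pr in pairs]
    for i in range(n - 1):
        if comp_sources[i] != comp_sources[i + 1]:
            # complement index counted 5'->3' on strand S
            nick_positions.append(n - 1 - i)
    pairing_blocks = [
        {"strand_a": "R", "from_a": 1, "to_a": n, "strand_b": "S", "from_b": n}
    ]
    code = "N" if nicked else "d"
    doc = {
        "name": f"{code}{topology.name_core}",
        "topology_code": code,
        "strands": {"R": read_seq, "S": comp_seq},
        "pairing_blocks": pairing_blocks,
        "helices": {f"{isomer},{helix}": {"strand": "R", "from": 1, "to": n}},
        "nicks": [
            {"strand": "S", "position": p} for p in (nick_positions if nicked else [])
        ],
    }
    return JunctionTopology.from_dict(doc)


def single_crossover_variant(
    topology: JunctionTopology, isomer: int, *, side: str
) -> JunctionTopology:
    """Junction with only one intact crossing strand (SXB or SXD).

    ``side`` is 'B' (left crossing strand intact) or 'D' (right intact),
    relative to the conventional junction frame; the broken crossing strand
    receives a backbone nick at the crossover.  Which crossing strand is
    'left' is declared by the topology's ``crossovers`` map order.
    """
    if side not in ("B", "D"):
        raise ValueError("side must be 'B' or 'D'")
    crossing = topology.crossovers.get(isomer)
    if not crossing or len(crossing) != 2:
        raise ValueError(f"topology {topology.name} lacks crossover info")
    left, right = crossing
    broken = right if side == "B" else left
    # nick the broken strand at its crossover midpoint
    seq = topology.strands[broken]
    nick = (broken, len(seq) // 2)
    return replace(
        topology,
        name=f"{side}{topology.name_core}",
        topology_code=side,
        nicks=topology.nicks + (nick,),
    )


def iter_analyzed_labels(
    topology: JunctionTopology, excluded_terminal_steps: int = 3
) -> Iterator[StepLabel]:
    for (iso, hel) in sorted(topology.helices):
        yield from topology.step_labels(iso, hel, excluded_terminal_steps)
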