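"""GNRA tetraloop annotation and structural assignment of footprint calls.

Maps significant protection/enhancement calls onto named secondary-structure
elements, classifies each with respect to the annotated tetraloop-receptor
tertiary contacts (within / adjacent / distal), quantifies what fraction of
protections fall at or immediately adjacent to those motifs, and checks the
three-part protection signature of a docked tetraloop: (i) the tetraloop
itself, (ii) the receptor-helix docking face, and (iii) the receptor-helix
extension toward the molecular exterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .differential import ChangeCall, PROTECTION, ENHANCEMENT
from .synthetic import RnaStructureModel

__all__ = [
    "ElementSummary",
    "MotifSignature",
    "find_gnra_tetraloops",
    "assign_calls",
    "motif_coverage",
    "signature_check",
    "WITHIN",
    "ADJACENT",
    "DISTAL",
]

WITHIN = "within"
ADJACENT = "adjacent"
DISTAL = "distal"

_PURINES = "AG"


@dataclass(frozen=True)
class ElementSummary:
    """Call counts for one structural element within one adjacency class.

    Elements are split by adjacency class because adjacency is a property
    of sequence position: a long junction can border a receptor helix at
    one end yet be distal at the other.
    """

    label: str
    kind: str
    adjacency: str  # within | adjacent | distal
    n_positions: int
    n_protected: int
    n_enhanced: int
    in_tetraloop_receptor: bool

    def __post_init__(self) -> None:
        if self.n_protected + self.n_enhanced > self.n_positions:
            raise ValueError("more calls than positions in element summary")
        if min(self.n_positions, self.n_protected, self.n_enhanced) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MotifSignature:
    """Three-part protection signature of one tetraloop-receptor motif."""

    motif_id: str
    loop_protected: bool
    receptor_contact_protected: bool
    receptor_extension_protected: bool

    @property
    def complete(self) -> bool:
        return (
            self.loop_protected
            and self.receptor_contact_protected
            and self.receptor_extension_protected
        )


def find_gnra_tetraloops(model: RnaStructureModel) -> list[str]:
    """Labels of all GNRA tetraloops: hairpin loops of exactly four unpaired
    nucleotides closed by a base pair, with loop sequence G, any, purine, A
    (5'->3').  Loops matching an annotated loop element return its label;
    unannotated loops get a positional label ``loop<start>-<end>``.
    """
    partner = model.partner()
    labels: list[str] = []
    for i, j in sorted(model.pairs):
        if j - i - 1 != 4:
            continue
        loop = range(i + 1, j)
        if any(partner[p] != 0 for p in loop):
            continue
        seq = model.sequence[i : j - 1]  # 0-based slice of positions i+1..j-1
        if seq[0] == "G" and seq[2] in _PURINES and seq[3] == "A":
            labels.append(_loop_label(model, tuple(loop)))
    return labels


def _loop_label(model: RnaStructureModel, positions: tuple[int, ...]) -> str:
    for el in model.elements:
        if el.kind == "loop" and el.positions == positions:
            return el.label
    return f"loop{positions[0]}-{positions[-1]}"


def _contact_positions(model: RnaStructureModel) -> set[int]:
    """All positions of the elements participating in a tertiary contact."""
    pos: set[int] = set()
    for tc in model.tertiary_contacts:
        pos.update(model.element_by_label(tc.loop_label).positions)
        pos.update(model.element_by_label(tc.receptor_label).positions)
    return pos


def _position_class(pos: int, contact: set[int], adjacency_k: int) -> str:
    if pos in contact:
        return WITHIN
    if any(abs(pos - c) <= adjacency_k for c in contact):
        return ADJACENT
    return DISTAL


def assign_calls(
    calls: list[ChangeCall], model: RnaStructureModel, adjacency_k: int = 2
) -> list[ElementSummary]:
    """Assign each call to the element containing its position and classify
    positions relative to the tetraloop-receptor contacts.

    A position is ``within`` when inside a contact element (tetraloop or
    receptor helix), ``adjacent`` when at most ``adjacency_k`` nucleotides
    along the sequence from one, and ``distal`` otherwise.  Positions not
    covered by any annotated element are grouped as a pseudo-element
    ``unassigned``.  One summary row is produced per (element, adjacency
    class) actually present in the model.
    """
    L = model.length
    for c in calls:
        if not 1 <= c.position <= L:
            raise ValueError(f"call position {c.position} outside model of length {L}")
    contact = _contact_positions(model)
    contact_labels = {
        lab
        for tc in model.tertiary_contacts
        for lab in (tc.loop_label, tc.receptor_label)
    }

    pos_to_element: dict[int, tuple[str, str]] = {}
    for el in model.elements:
        for p in el.positions:
            pos_to_element.setdefault(p, (el.label, el.kind))
    for p in range(1, L + 1):
        pos_to_element.setdefault(p, ("unassigned", "unassigned"))

    groups: dict[tuple[str, str, str], dict[str, int]] = {}
    for p in range(1, L + 1):
        label, kind = pos_to_element[p]
        cls = _position_class(p, contact, adjacency_k)
        key = (label, kind, cls)
        groups.setdefault(key, {"n_positions": 0, "n_protected": 0, "n_enhanced": 0})
        groups[key]["n_positions"] += 1
    for c in calls:
        label, kind = pos_to_element[c.position]
        cls = _position_class(c.position, contact, adjacency_k)
        key = (label, kind, cls)
        groups[key]["n_protected" if c.direction == PROTECTION else "n_enhanced"] += 1

    order = {WITHIN: 0, ADJACENT: 1, DISTAL: 2}
    return [
        ElementSummary(
            label=label,
            kind=kind,
            adjacency=cls,
            n_positions=g["n_positions"],
            n_protected=g["n_protected"],
            n_enhanced=g["n_enhanced"],
            in_tetraloop_receptor=label in contact_labels,
        )
        for (label, kind, cls), g in sorted(
            groups.items(), key=lambda kv: (kv[0][0], order[kv[0][2]])
        )
    ]


def motif_coverage(summaries: list[ElementSummary]) -> float | None:
    """Fraction of protected positions lying within or immediately adjacent
    to a tetraloop-receptor motif.  Returns ``None`` (undefined, not zero)
    when there are no protections at all.
    """
    total = sum(s.n_protected for s in summaries)
    if total == 0:
        return None
    near = sum(s.n_protected for s in summaries if s.adjacency in (WITHIN, ADJACENT))
    return near / total


def signature_check(
    calls: list[ChangeCall], model: RnaStructureModel
) -> list[MotifSignature]:
    """Per-motif three-part protection signature.

    For each annotated tetraloop-receptor contact, reports whether at least
    one protection call falls (i) in the tetraloop, (ii) in the receptor
    docking face, and (iii) in the receptor extension toward the exterior
    (the receptor-helix positions outside the docking face).
    """
    protected = {c.position for c in calls if c.direction == PROTECTION}
    out: list[MotifSignature] = []
    for tc in model.tertiary_contacts:
        extension = model.receptor_extension(tc)
        out.append(
            MotifSignature(
                motif_id=tc.motif_id,
                loop_protected=bool(protected.intersection(tc.loop_positions)),
                receptor_contact_protected=bool(
                    protected.intersection(tc.receptor_positions)
                ),
                receptor_extension_protected=bool(protected.intersection(extension)),
            )
        )
    return out
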