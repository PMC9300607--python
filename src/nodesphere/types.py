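"""Core record types shared across the pipeline.

The analysis unit is a lymph node described by its three principal
diameters (full diameters, in mm), sorted so that ``a <= b <= c``:
``a`` the shortest, ``c`` the longest. All shape scores and classifiers
operate on this canonical ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: Smallest admissible diameter, mm. Segmentation noise can produce
#: nearly flat objects; below this floor a node is rejected as a
#: zero-volume artifact rather than scored.
MIN_DIAMETER_MM = 0.1


@dataclass(frozen=True)
class AxisTriple:
    """Three principal diameters of a lymph node, mm, with a <= b <= c."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (v == v) or v <= 0:  # NaN or non-positive
                raise ValueError(f"axis {name} must be positive, got {v!r}")
        if self.a < MIN_DIAMETER_MM:
            raise ValueError(
                f"shortest diameter {self.a} mm below floor {MIN_DIAMETER_MM} mm"
            )
        if not (self.a <= self.b <= self.c):
            raise ValueError(
                f"axes must satisfy a <= b <= c, got ({self.a}, {self.b}, {self.c})"
            )

    @classmethod
    def from_sorted(cls, values: Sequence[float]) -> "AxisTriple":
        """Build from any order of the three diameters by sorting ascending."""
        if len(values) != 3:
            raise ValueError(f"expected 3 diameters, got {len(values)}")
        a, b, c = sorted(float(v) for v in values)
        return cls(a, b, c)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    def scaled(self, k: float) -> "AxisTriple":
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return AxisTriple(self.a * k, self.b * k, self.c * k)


@dataclass
class NodeRecord:
    """One lymph node: identity, axes, pathology label, computed outputs.

    ``label`` is 1 for metastatic, 0 for non-metastatic, None if unknown.
    ``calls`` maps a method name ("sphericity", "tree", ...) to its
    binary prediction for this node.
    """

    patient_id: str
    node_id: str
    axes: AxisTriple
    label: Optional[int] = None
    ratio_2d: Optional[float] = None
    sphericity: Optional[float] = None
    calls: dict[str, int] = field(default_factory=dict)


@dataclass
class PatientRecord:
    """A patient's nodes plus patient-level truth and imaging reads.

    Patient truth follows the whole-axilla rule: a patient is metastatic
    iff any node is metastatic (partial nodal involvement counts as a
    metastatic patient).
    """

    patient_id: str
    nodes: list[NodeRecord] = field(default_factory=list)
    truth: Optional[int] = None
    imaging_calls: dict[str, Optional[int]] = field(default_factory=dict)
    nac: bool = False

    def derived_truth(self) -> Optional[int]:
        labels = [n.label for n in self.nodes]
        if any(l is None for l in labels) or not labels:
            return None
        return int(any(l == 1 for l in labels))

    def validate(self) -> None:
        derived = self.derived_truth()
        if derived is not None and self.truth is not None and derived != self.truth:
            raise ValueError(
                f"patient {self.patient_id}: truth={self.truth} conflicts with "
                f"node labels (any-positive rule gives {derived})"
            )


def patients_from_records(
    nodes: Iterable[NodeRecord],
    imaging: Optional[Mapping[str, Mapping[str, int]]] = None,
    nac_flags: Optional[Mapping[str, bool]] = None,
) -> list[PatientRecord]:
    """Group node records into patients, deriving patient truth."""
    by_patient: dict[str, PatientRecord] = {}
    for node in nodes:
        rec = by_patient.setdefault(node.patient_id, PatientRecord(node.patient_id))
        rec.nodes.append(node)
    for pid, rec in by_patient.items():
        rec.truth = rec.derived_truth()
        if nac_flags is not None:
            rec.nac = bool(nac_flags.get(pid, False))
        if imaging is not None:
            for method, calls in imaging.items():
                rec.imaging_calls[method] = calls.get(pid)
    return list(by_patient.values())
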