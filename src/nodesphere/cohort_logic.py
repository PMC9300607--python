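"""Patient-level diagnosis: node aggregation and combined rules.

A patient is called metastatic iff any of their nodes is called
metastatic — the whole-axilla rule used for the pathology ground truth
as well, so node-level and patient-level analyses stay commensurable.

Two modality calls (e.g. the sphericity model and ultrasound) combine
under OR (positive if either flags; raises sensitivity, can only lower
specificity) or AND (positive only if both; the reverse). OR is the
default: the study's combined sensitivity exceeds each constituent's,
which only OR guarantees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombinedRule:
    """How two methods' patient calls merge into one diagnosis."""

    mode: str = "OR"
    methods: tuple[str, str] = ("sphericity", "ultrasound")

    def __post_init__(self) -> None:
        if self.mode not in ("OR", "AND"):
            raise ValueError(f"mode must be 'OR' or 'AND', got {self.mode!r}")

    @property
    def name(self) -> str:
        return f"{self.methods[0]}+{self.methods[1]}"


def aggregate_patient(node_calls: Sequence[int]) -> int:
    """Patient call from node calls: positive iff any node positive."""
    calls = list(node_calls)
    if not calls:
        raise ValueError("cannot aggregate an empty node-call list")
    if not all(c in (0, 1) for c in calls):
        raise ValueError("node calls must be binary 0/1")
    return int(any(c == 1 for c in calls))


def aggregate_patients(node_calls: pd.DataFrame) -> pd.DataFrame:
    """Lift a long node-call table to patient calls.

    Expects columns ``patient_id, method, call``; returns one row per
    (patient_id, method) with the any-positive patient call.
    """
    required = {"patient_id", "method", "call"}
    missing = required - set(node_calls.columns)
    if missing:
        raise ValueError(f"node-call table lacks columns {sorted(missing)}")
    if node_calls.empty:
        raise ValueError("cannot aggregate an empty node-call table")
    out = (
        node_calls.groupby(["patient_id", "method"], as_index=False)["call"]
        .max()
    )
    out["call"] = out["call"].astype(int)
    return out


def combine_calls(call_a: int, call_b: int, rule: CombinedRule) -> int:
    """Merge two binary patient calls under the rule's OR/AND mode."""
    for c in (call_a, call_b):
        if c not in (0, 1):
            raise ValueError(f"calls must be binary 0/1, got {c!r}")
    if rule.mode == "OR":
        return int(call_a == 1 or call_b == 1)
    return int(call_a == 1 and call_b == 1)


def combine_frames(
    patient_calls: pd.DataFrame,
    rule: CombinedRule,
    name: Optional[str] = None,
) -> pd.DataFrame:
    """Build a combined method's patient calls from a long call table.

    ``patient_calls`` has columns ``patient_id, method, call``. Patients
    lacking either constituent call are excluded, with a logged count.
    The result uses method name ``name`` (default "A+B") and records the
    combination mode in a ``mode`` column for provenance.
    """
    m_a, m_b = rule.methods
    wide = (
        patient_calls[patient_calls["method"].isin([m_a, m_b])]
        .pivot_table(index="patient_id", columns="method", values="call",
                     aggfunc="first")
    )
    for m in (m_a, m_b):
        if m not in wide.columns:
            wide[m] = pd.NA
    complete = wide.dropna(subset=[m_a, m_b])
    n_excluded = len(wide) - len(complete)
    if n_excluded:
        logger.warning(
            "combine %s: excluded %d patients missing a constituent call",
            rule.name, n_excluded,
        )
    if rule.mode == "OR":
        combined = (complete[m_a].astype(int) | complete[m_b].astype(int))
    else:
        combined = (complete[m_a].astype(int) & complete[m_b].astype(int))
    return pd.DataFrame(
        {
            "patient_id": complete.index,
            "method": name or rule.name,
            "call": combined.to_numpy(dtype=int),
            "mode": rule.mode,
        }
    ).reset_index(drop=True)
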