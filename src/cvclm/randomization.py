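"""Center-stratified 1:1:1:1 permuted-block randomization.

Records are randomized in cohort (insertion-date) order within each center
stratum.  Within a stratum, arms are assigned from consecutive random
permutations of a block containing each arm ``block_size/4`` times, so arm
counts within any prefix of a stratum differ by at most ``block_size - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Cohort

__all__ = ["ARMS", "CONTROL_ARM", "AllocationTable", "RandomizationError",
           "allocate", "allocation_summary"]

ARMS = ("D7rmv", "D14rmv", "D21rmv", "Control")
CONTROL_ARM = "Control"

_VALID_BLOCK_SIZES = (4, 8, 12)


class RandomizationError(ValueError):
    """Raised for invalid allocation requests or cohort/table mismatches."""


@dataclass
class AllocationTable:
    """record_id -> arm assignment, with the randomization parameters."""

    assignments: dict[str, str]
    seed: int
    block_size: int
    #: record_ids left unassigned because --truncate-to-balance dropped a
    #: trailing incomplete block (empty by default).
    unassigned: list[str] = field(default_factory=list)

    def arm_of(self, record_id: str) -> str:
        try:
            return self.assignments[record_id]
        except KeyError:
            raise RandomizationError(
                f"record {record_id!r} has no allocation"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"record_id": list(self.assignments), "arm": list(self.assignments.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = -1,
                   block_size: int = 4) -> "AllocationTable":
        if list(frame.columns) != ["record_id", "arm"]:
            raise RandomizationError(
                f"allocation table must have columns ['record_id', 'arm'], "
                f"got {list(frame.columns)}"
            )
        bad = sorted(set(frame["arm"]) - set(ARMS))
        if bad:
            raise RandomizationError(f"unknown arms in allocation table: {bad}")
        if frame["record_id"].duplicated().any():
            dup = frame.loc[frame["record_id"].duplicated(), "record_id"].iloc[0]
            raise RandomizationError(f"duplicate record_id in allocation table: {dup!r}")
        return cls(assignments=dict(zip(frame["record_id"], frame["arm"])),
                   seed=seed, block_size=block_size)


def allocate(cohort: Cohort, block_size: int = 4, seed: int = 0,
             truncate_to_balance: bool = False) -> AllocationTable:
    """Permuted-block randomization of a cohort, stratified by center.

    Deterministic given ``seed``.  Strata are processed in order of first
    appearance in the cohort; within each stratum, records receive arms from
    consecutive shuffled blocks.  With ``truncate_to_balance`` the trailing
    incomplete block of each stratum is left unassigned (listed in
    ``AllocationTable.unassigned``), which forces exactly equal arm counts
    per stratum.
    """
    if block_size not in _VALID_BLOCK_SIZES:
        raise RandomizationError(
            f"block_size must be one of {_VALID_BLOCK_SIZES}, got {block_size}"
        )
    if len(cohort) == 0:
        raise RandomizationError("cannot randomize an empty cohort")

    strata: dict[str, list[str]] = {}
    for rec in cohort:
        strata.setdefault(rec.center_id, []).append(rec.record_id)

    rng = np.random.default_rng(seed)
    base = np.repeat(np.arange(4), block_size // 4)
    assignments: dict[str, str] = {}
    unassigned: list[str] = []
    for center, ids in strata.items():
        n = len(ids)
        n_assign = (n // block_size) * block_size if truncate_to_balance else n
        pos = 0
        while pos < n_assign:
            block = rng.permutation(base)
            for arm_idx in block[: n_assign - pos]:
                assignments[ids[pos]] = ARMS[arm_idx]
                pos += 1
        unassigned.extend(ids[n_assign:])

    return AllocationTable(assignments=assignments, seed=seed,
                           block_size=block_size, unassigned=unassigned)


def allocation_summary(table: AllocationTable, cohort: Cohort) -> pd.DataFrame:
    """Arm counts per center stratum, plus a Total row.

    Raises if any cohort record is missing from the table (unless it was
    explicitly left unassigned by balance truncation).
    """
    skipped = set(table.unassigned)
    counts: dict[str, dict[str, int]] = {}
    for rec in cohort:
        if rec.record_id in skipped:
            continue
        arm = table.arm_of(rec.record_id)
        row = counts.setdefault(rec.center_id, {a: 0 for a in ARMS})
        row[arm] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=list(ARMS))
    frame.index.name = "center_id"
    frame.loc["Total"] = frame.sum(axis=0)
    return frame.astype(int)
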