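"""Core containers for aligned single-molecule SMRT kinetic data.

A sequencing *molecule* is one circularized double-stranded DNA insert; the
polymerase traverses it repeatedly, producing one *subread* per pass per
strand.  Each incorporated base carries an inter-pulse duration (IPD), the
waiting time before the incorporation event; IPDs at and around methylated
template bases are systematically elevated, which is the signal everything
downstream of this module measures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: Strand encodings relative to the reference (also used on disk).
FORWARD = 0
REVERSE = 1

#: Alignment operation codes (stored as 1-byte strings).
OP_MATCH = b"M"
OP_MISMATCH = b"X"
OP_INSERTION = b"I"
OP_DELETION = b"D"
VALID_OPS = frozenset((OP_MATCH, OP_MISMATCH, OP_INSERTION, OP_DELETION))

#: ref_pos placeholder for events that do not consume reference (insertions).
NULL_POS = -1
#: base placeholder for absent read/reference bases.
NULL_BASE = b"."


@dataclass(frozen=True)
class AlignedEvent:
    """One aligned alignment column of a subread.

    ``ref_pos`` is ``None`` for insertions; ``read_base`` is ``None`` for
    deletions; ``ref_base`` is ``None`` for insertions; ``ipd`` (seconds or
    frames, per dataset metadata) is present iff the event emits a read base.
    """

    ref_pos: int | None
    op: str
    read_base: str | None
    ref_base: str | None
    ipd: float | None


@dataclass
class SubreadRecord:
    """One pass of the polymerase over one strand of one molecule.

    Events are stored columnar and in read (temporal) order: reference
    positions are strictly increasing along forward-strand subreads and
    strictly decreasing along reverse-strand ones.  Bases are recorded in
    reference (forward-strand) orientation on both strands, so ``op`` can be
    validated directly against ``read_base == ref_base``.  Null encodings:
    ``ref_pos == -1`` (insertions), ``b"."`` bases, ``nan`` IPDs (deletions).
    """

    molecule_id: str
    subread_index: int
    strand: int
    mapqv: int
    accuracy: float
    ref_pos: np.ndarray = field(repr=False)
    op: np.ndarray = field(repr=False)
    read_base: np.ndarray = field(repr=False)
    ref_base: np.ndarray = field(repr=False)
    ipd: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.ref_pos)
        self.ref_pos = np.asarray(self.ref_pos, dtype=np.int64)
        self.op = np.asarray(self.op, dtype="S1")
        self.read_base = np.asarray(self.read_base, dtype="S1")
        self.ref_base = np.asarray(self.ref_base, dtype="S1")
        self.ipd = np.asarray(self.ipd, dtype=np.float64)
        for arr in (self.op, self.read_base, self.ref_base, self.ipd):
            if len(arr) != n:
                raise ValueError("event columns must share one length")

    def __len__(self) -> int:
        return len(self.ref_pos)

    @property
    def n_events(self) -> int:
        return len(self.ref_pos)

    @property
    def aligned_length(self) -> int:
        """Number of reference-consuming events (match/mismatch/deletion)."""
        return int(np.count_nonzero(self.op != OP_INSERTION))

    @property
    def n_matches(self) -> int:
        return int(np.count_nonzero(self.op == OP_MATCH))

    def recompute_accuracy(self) -> float:
        """Aligned identity: matches / read bases placed in the alignment."""
        emitted = int(np.count_nonzero(self.op != OP_DELETION))
        if emitted == 0:
            return 0.0
        return self.n_matches / emitted

    def replace(self, **changes) -> "SubreadRecord":
        return dataclasses.replace(self, **changes)

    def iter_events(self) -> Iterator[AlignedEvent]:
        for i in range(len(self)):
            op = self.op[i].decode()
            pos = int(self.ref_pos[i])
            ipd = float(self.ipd[i])
            yield AlignedEvent(
                ref_pos=None if pos == NULL_POS else pos,
                op=op,
                read_base=None if op == "D" else self.read_base[i].decode(),
                ref_base=None if op == "I" else self.ref_base[i].decode(),
                ipd=None if np.isnan(ipd) else ipd,
            )


def _canon_sample_type(sample_type: str) -> str:
    st = sample_type.lower()
    if st not in ("native", "wga"):
        raise ValueError(f"sample_type must be 'native' or 'wga', got {sample_type!r}")
    return st


@dataclass
class KineticsDataset:
    """A collection of subreads plus reference and sample metadata.

    ``sample_type`` distinguishes native DNA (methylation marks intact) from
    whole-genome amplified (WGA) DNA, whose amplification erases all marks
    and which therefore serves as the kinetic null control.
    """

    subreads: list[SubreadRecord]
    reference_id: str
    reference_length: int
    sample_type: str
    ipd_unit: str = "seconds"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_type = _canon_sample_type(self.sample_type)

    def __len__(self) -> int:
        return len(self.subreads)

    @property
    def molecule_ids(self) -> list[str]:
        """Unique molecule ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for sr in self.subreads:
            seen.setdefault(sr.molecule_id, None)
        return list(seen)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def by_molecule(self) -> dict[str, list[SubreadRecord]]:
        groups: dict[str, list[SubreadRecord]] = {}
        for sr in self.subreads:
            groups.setdefault(sr.molecule_id, []).append(sr)
        return groups

    def total_aligned_bases(self) -> int:
        return sum(sr.aligned_length for sr in self.subreads)

    def subset_molecules(self, molecule_ids) -> "KineticsDataset":
        wanted = set(molecule_ids)
        return KineticsDataset(
            subreads=[sr for sr in self.subreads if sr.molecule_id in wanted],
            reference_id=self.reference_id,
            reference_length=self.reference_length,
            sample_type=self.sample_type,
            ipd_unit=self.ipd_unit,
            provenance=dict(self.provenance),
        )
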