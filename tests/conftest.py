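"""Shared fixtures and hand-construction helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinmeth.records import FORWARD, KineticsDataset, NULL_POS, SubreadRecord


def make_subread(
    ops: str,
    molecule_id: str = "m1",
    subread_index: int = 0,
    strand: int = FORWARD,
    mapqv: int = 254,
    accuracy: float = 0.95,
    start: int = 0,
    ipds=None,
) -> SubreadRecord:
    """Build a subread from an op string such as ``"MMMXMID"``.

    Reference positions advance with every reference-consuming op, from
    ``start`` upward (forward strand) or downward (reverse strand); bases
    are synthesized consistently with each op (ref A, mismatch read C).
    """
    n = len(ops)
    if ipds is None:
        ipds = [1.0] * n
    ref_pos, read_b, ref_b, ipd_out = [], [], [], []
    pos = start
    step = 1 if strand == FORWARD else -1
    for op, ipd in zip(ops, ipds):
        if op == "M":
            ref_pos.append(pos); read_b.append("A"); ref_b.append("A"); ipd_out.append(ipd)
            pos += step
        elif op == "X":
            ref_pos.append(pos); read_b.append("C"); ref_b.append("A"); ipd_out.append(ipd)
            pos += step
        elif op == "D":
            ref_pos.append(pos); read_b.append("."); ref_b.append("A"); ipd_out.append(np.nan)
            pos += step
        elif op == "I":
            ref_pos.append(NULL_POS); read_b.append("G"); ref_b.append("."); ipd_out.append(ipd)
        else:
            raise ValueError(op)
    return SubreadRecord(
        molecule_id=molecule_id,
        subread_index=subread_index,
        strand=strand,
        mapqv=mapqv,
        accuracy=accuracy,
        ref_pos=np.array(ref_pos, dtype=np.int64),
        op=np.array(list(ops), dtype="S1"),
        read_base=np.array(read_b, dtype="S1"),
        ref_base=np.array(ref_b, dtype="S1"),
        ipd=np.array(ipd_out, dtype=np.float64),
    )


def make_dataset(subreads, sample_type="native", reference_length=10_000) -> KineticsDataset:
    return KineticsDataset(
        subreads=list(subreads),
        reference_id="ref",
        reference_length=reference_length,
        sample_type=sample_type,
    )


def obs_frame(rows, sample_type="native") -> pd.DataFrame:
    """Observation table from (molecule_id, strand, ref_pos, log_ipd) tuples."""
    obs = pd.DataFrame(
        rows, columns=["molecule_id", "strand", "ref_pos", "log_ipd"]
    ).assign(subread_index=0)
    obs["strand"] = obs["strand"].astype(np.int8)
    obs["ref_pos"] = obs["ref_pos"].astype(np.int64)
    obs.attrs["sample_type"] = sample_type
    return obs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
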