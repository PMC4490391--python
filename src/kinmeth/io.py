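"""Readers and writers for aligned-kinetics and score tables.

Two on-disk forms carry aligned kinetics:

* the canonical plain-text TSV dialect (one row per aligned event, grouped
  into subreads by ``(molecule_id, subread_index)``), with optional
  ``#key=value`` metadata lines; and
* aligned BAM with a per-base IPD array tag (PacBio-style ``ip``), paired
  with the reference FASTA.

Score tables (SM_SN / Agg_SN / SM_P) are TSVs with fixed schemas and
9-significant-digit floats.
"""

from __future__ import annotations

import array
import logging
import math
from pathlib import Path

import numpy as np
import pysam

from .records import (
    FORWARD,
    KineticsDataset,
    NULL_BASE,
    NULL_POS,
    REVERSE,
    SubreadRecord,
    VALID_OPS,
)
from .scoring import AggScore, SmpScore, SmsnScore

log = logging.getLogger(__name__)

KINETICS_COLUMNS = [
    "molecule_id", "subread_index", "strand", "mapqv", "accuracy",
    "ref_pos", "op", "read_base", "ref_base", "ipd",
]

_STRAND_TOKENS = {"0": FORWARD, "1": REVERSE}


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def read_kinetics_tsv(
    path,
    sample_type: str | None = None,
    reference_id: str | None = None,
    reference_length: int | None = None,
    ipd_unit: str | None = None,
) -> KineticsDataset:
    """Read the aligned-kinetics TSV dialect.

    Rows sharing ``(molecule_id, subread_index)`` form one subread, in file
    order.  ``#key=value`` comment lines supply dataset metadata; keyword
    arguments override them.  Malformed rows raise with the line number.
    """
    meta: dict[str, str] = {}
    groups: dict[tuple[str, int], dict] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts != KINETICS_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: unexpected header {parts!r}")
                header_seen = True
                continue
            if len(parts) != len(KINETICS_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(KINETICS_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            (mol, sidx_s, strand_s, mapqv_s, acc_s, pos_s, op, rb, fb, ipd_s) = parts
            if strand_s not in _STRAND_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown strand token {strand_s!r}")
            if op not in ("M", "X", "I", "D"):
                raise ValueError(f"{path}:{lineno}: unknown op {op!r}")
            try:
                sidx = int(sidx_s)
                mapqv = int(mapqv_s)
                accuracy = float(acc_s)
                pos = NULL_POS if pos_s == "." else int(pos_s)
                ipd = math.nan if ipd_s == "." else float(ipd_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})") from None
            if op == "I" and pos != NULL_POS:
                raise ValueError(f"{path}:{lineno}: insertion must have '.' ref_pos")
            if op != "I" and pos == NULL_POS:
                raise ValueError(f"{path}:{lineno}: op {op} requires a ref_pos")
            if op == "D" and not math.isnan(ipd):
                raise ValueError(f"{path}:{lineno}: deletion carries no IPD")
            if op != "D" and math.isnan(ipd):
                raise ValueError(f"{path}:{lineno}: op {op} requires an IPD")
            key = (mol, sidx)
            g = groups.get(key)
            if g is None:
                g = groups[key] = {
                    "strand": _STRAND_TOKENS[strand_s],
                    "mapqv": mapqv,
                    "accuracy": accuracy,
                    "pos": [], "op": [], "rb": [], "fb": [], "ipd": [],
                }
            elif (g["strand"], g["mapqv"], g["accuracy"]) != (
                _STRAND_TOKENS[strand_s], mapqv, accuracy
            ):
                raise ValueError(
                    f"{path}:{lineno}: inconsistent subread-level fields for {key}"
                )
            g["pos"].append(pos)
            g["op"].append(op)
            g["rb"].append(rb)
            g["fb"].append(fb)
            g["ipd"].append(ipd)
    if not header_seen:
        raise ValueError(f"{path}: missing header line")

    subreads = [
        SubreadRecord(
            molecule_id=mol,
            subread_index=sidx,
            strand=g["strand"],
            mapqv=g["mapqv"],
            accuracy=g["accuracy"],
            ref_pos=np.array(g["pos"], dtype=np.int64),
            op=np.array(g["op"], dtype="S1"),
            read_base=np.array(g["rb"], dtype="S1"),
            ref_base=np.array(g["fb"], dtype="S1"),
            ipd=np.array(g["ipd"], dtype=np.float64),
        )
        for (mol, sidx), g in groups.items()
    ]
    ref_len = reference_length
    if ref_len is None and "reference_length" in meta:
        ref_len = int(meta["reference_length"])
    if ref_len is None:
        all_pos = [int(sr.ref_pos.max()) for sr in subreads if len(sr)]
        ref_len = (max(all_pos) + 1) if all_pos else 0
    return KineticsDataset(
        subreads=subreads,
        reference_id=reference_id or meta.get("reference_id", "unknown"),
        reference_length=ref_len,
        sample_type=sample_type or meta.get("sample_type", "native"),
        ipd_unit=ipd_unit or meta.get("ipd_unit", "seconds"),
        provenance={"source": str(path)},
    )


def write_kinetics_tsv(path, ds: KineticsDataset) -> None:
    """Write the canonical aligned-kinetics TSV for ``ds``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#reference_id={ds.reference_id}\n")
        fh.write(f"#reference_length={ds.reference_length}\n")
        fh.write(f"#sample_type={ds.sample_type}\n")
        fh.write(f"#ipd_unit={ds.ipd_unit}\n")
        fh.write("\t".join(KINETICS_COLUMNS) + "\n")
        for sr in ds.subreads:
            prefix = f"{sr.molecule_id}\t{sr.subread_index}\t{sr.strand}\t{sr.mapqv}\t{_fmt(sr.accuracy)}"
            ops = sr.op
            for i in range(len(sr)):
                pos = int(sr.ref_pos[i])
                ipd = sr.ipd[i]
                fh.write(
                    prefix
                    + "\t"
                    + ("." if pos == NULL_POS else str(pos))
                    + "\t"
                    + ops[i].decode()
                    + "\t"
                    + sr.read_base[i].decode()
                    + "\t"
                    + sr.ref_base[i].decode()
                    + "\t"
                    + ("." if np.isnan(ipd) else _fmt(ipd))
                    + "\n"
                )


_CIGAR_FROM_OP = {b"M": 7, b"X": 8, b"I": 1, b"D": 2}  # =, X, I, D


def write_kinetics_bam(path, ds: KineticsDataset, ipd_tag: str = "ip") -> None:
    """Write an aligned BAM twin of ``ds`` with per-base IPDs in ``ipd_tag``.

    Reads are stored in aligned (reference) orientation with ``=``/``X``
    CIGAR ops; reverse-strand subreads set the reverse flag and have their
    event order reversed, so the TSV and BAM forms round-trip to the same
    dataset (up to float32 IPD precision in the tag).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ds.reference_id, "LN": max(int(ds.reference_length), 1)}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for sr in ds.subreads:
            if len(sr) == 0:
                continue
            order = slice(None, None, -1) if sr.strand == REVERSE else slice(None)
            ops = sr.op[order]
            pos = sr.ref_pos[order]
            rb = sr.read_base[order]
            ipd = sr.ipd[order]
            a = pysam.AlignedSegment()
            a.query_name = f"{sr.molecule_id}/{sr.subread_index}"
            a.flag = 16 if sr.strand == REVERSE else 0
            a.reference_id = 0
            ref_consuming = ops != b"I"
            a.reference_start = int(pos[ref_consuming].min())
            a.mapping_quality = min(int(sr.mapqv), 254)
            cigar = []
            for o in ops:
                code = _CIGAR_FROM_OP[o]
                if cigar and cigar[-1][0] == code:
                    cigar[-1][1] += 1
                else:
                    cigar.append([code, 1])
            a.cigartuples = [tuple(c) for c in cigar]
            emits = ops != b"D"
            a.query_sequence = b"".join(rb[emits]).decode()
            a.query_qualities = None
            a.set_tag(ipd_tag, array.array("f", ipd[emits].tolist()))
            bam.write(a)


def read_pacbio_bam(
    bam_path,
    ref_fasta,
    sample_type: str = "native",
    ipd_tag: str = "ip",
    ipd_unit: str = "frames",
) -> KineticsDataset:
    """Read aligned kinetics from a BAM with a per-base IPD array tag.

    Per-base IPDs are paired with alignment columns via the CIGAR; soft
    clips are dropped; unmapped reads are skipped with a warning.  Query
    names of the form ``molecule/subread_index`` recover molecule
    structure; MapQV comes from the mapping-quality field and accuracy is
    recomputed from the alignment (matches / aligned read bases) rather
    than trusted from tags.  The IPD tag is expected in aligned
    orientation, covering every base of the stored sequence.
    """
    fasta = pysam.FastaFile(str(ref_fasta))
    subreads: list[SubreadRecord] = []
    n_unmapped = 0
    reference_id = fasta.references[0]
    reference_length = fasta.lengths[0]
    with pysam.AlignmentFile(str(bam_path), "rb", check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped:
                n_unmapped += 1
                continue
            if read.reference_name not in fasta.references:
                raise ValueError(
                    f"reference name mismatch: BAM contig {read.reference_name!r} "
                    f"absent from {ref_fasta}"
                )
            if not read.has_tag(ipd_tag):
                raise ValueError(
                    f"read {read.query_name!r} lacks the per-base IPD tag {ipd_tag!r}"
                )
            ipds = np.asarray(read.get_tag(ipd_tag), dtype=np.float64)
            seq = read.query_sequence
            if seq is None or len(ipds) != len(seq):
                raise ValueError(
                    f"read {read.query_name!r}: IPD tag length does not match SEQ"
                )
            ref_seq = fasta.fetch(
                read.reference_name, read.reference_start, read.reference_end
            ).upper()
            pos_l, op_l, rb_l, fb_l, ipd_l = [], [], [], [], []
            qpos = 0
            rpos = 0  # offset into ref_seq
            for code, length in read.cigartuples:
                if code in (0, 7, 8):  # M, =, X
                    for k in range(length):
                        q = seq[qpos + k]
                        r = ref_seq[rpos + k]
                        pos_l.append(read.reference_start + rpos + k)
                        op_l.append("M" if q == r else "X")
                        rb_l.append(q)
                        fb_l.append(r)
                        ipd_l.append(ipds[qpos + k])
                    qpos += length
                    rpos += length
                elif code == 1:  # I
                    for k in range(length):
                        pos_l.append(NULL_POS)
                        op_l.append("I")
                        rb_l.append(seq[qpos + k])
                        fb_l.append(".")
                        ipd_l.append(ipds[qpos + k])
                    qpos += length
                elif code == 2:  # D
                    for k in range(length):
                        pos_l.append(read.reference_start + rpos + k)
                        op_l.append("D")
                        rb_l.append(".")
                        fb_l.append(ref_seq[rpos + k])
                        ipd_l.append(math.nan)
                    rpos += length
                elif code == 4:  # S: soft-clipped bases dropped
                    qpos += length
                elif code == 5:  # H
                    continue
                else:
                    raise ValueError(
                        f"read {read.query_name!r}: unsupported CIGAR op code {code}"
                    )
            if read.is_reverse:
                pos_l.reverse(); op_l.reverse(); rb_l.reverse(); fb_l.reverse(); ipd_l.reverse()
            name = read.query_name or ""
            if "/" in name:
                mol, _, sidx_s = name.rpartition("/")
                try:
                    sidx = int(sidx_s)
                except ValueError:
                    mol, sidx = name, 0
            else:
                mol, sidx = name, 0
            sr = SubreadRecord(
                molecule_id=mol,
                subread_index=sidx,
                strand=REVERSE if read.is_reverse else FORWARD,
                mapqv=int(read.mapping_quality),
                accuracy=0.0,
                ref_pos=np.array(pos_l, dtype=np.int64),
                op=np.array(op_l, dtype="S1"),
                read_base=np.array(rb_l, dtype="S1"),
                ref_base=np.array(fb_l, dtype="S1"),
                ipd=np.array(ipd_l, dtype=np.float64),
            )
            sr.accuracy = sr.recompute_accuracy()
            subreads.append(sr)
    fasta.close()
    if n_unmapped:
        log.warning("skipped %d unmapped reads in %s", n_unmapped, bam_path)
    return KineticsDataset(
        subreads=subreads,
        reference_id=reference_id,
        reference_length=reference_length,
        sample_type=sample_type,
        ipd_unit=ipd_unit,
        provenance={"source": str(bam_path), "unmapped_skipped": n_unmapped},
    )


_SCORE_SCHEMAS = {
    "smsn": (SmsnScore, ["molecule_id", "strand", "ref_pos", "cov_sm", "score"]),
    "agg": (AggScore, ["strand", "ref_pos", "native_n", "wga_n", "score"]),
    "smp": (SmpScore, ["molecule_id", "strand", "n_sites", "score"]),
}


def _score_kind(score) -> str:
    for kind, (cls, _) in _SCORE_SCHEMAS.items():
        if isinstance(score, cls):
            return kind
    raise ValueError(f"unknown score type {type(score).__name__}")


def write_scores(path, scores, kind: str | None = None) -> None:
    """Write a homogeneous score list as a TSV (one row per score).

    ``kind`` ('smsn' | 'agg' | 'smp') is only needed for empty lists, where
    it defaults to 'smsn'.  Approximate SM_SN scores are flagged with a
    ``#approximate=1`` metadata line.  Mixed score kinds are an error.
    """
    if scores:
        kind = _score_kind(scores[0])
        cls, _ = _SCORE_SCHEMAS[kind]
        if any(not isinstance(s, cls) for s in scores):
            raise ValueError("mixed score kinds in one table")
    elif kind is None:
        kind = "smsn"
    _, columns = _SCORE_SCHEMAS[kind]
    approximate = bool(scores) and kind == "smsn" and scores[0].approximate
    with open(path, "w", encoding="utf-8") as fh:
        if approximate:
            fh.write("#approximate=1\n")
        fh.write("\t".join(columns) + "\n")
        for s in scores:
            fh.write(
                "\t".join(
                    _fmt(v) if isinstance(v, float) else str(v)
                    for v in (getattr(s, c) for c in columns)
                )
                + "\n"
            )


def read_scores(path):
    """Read back a score TSV; the kind is detected from the header."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    body = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, value = ln[1:].partition("=")
            meta[key] = value
        else:
            body.append(ln)
    if not body:
        raise ValueError(f"{path}: missing header")
    header = body[0].split("\t")
    for kind, (cls, columns) in _SCORE_SCHEMAS.items():
        if header == columns:
            break
    else:
        raise ValueError(f"{path}: unrecognized score header {header!r}")
    approximate = meta.get("approximate") == "1"
    out = []
    int_cols = {"strand", "ref_pos", "cov_sm", "native_n", "wga_n", "n_sites"}
    for ln in body[1:]:
        parts = ln.split("\t")
        kwargs = {}
        for col, val in zip(columns, parts):
            if col == "score":
                kwargs[col] = float(val)
            elif col in int_cols:
                kwargs[col] = int(val)
            else:
                kwargs[col] = val
        if kind == "smsn":
            kwargs["approximate"] = approximate
        out.append(cls(**kwargs))
    return out
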