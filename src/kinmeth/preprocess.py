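"""Subread filtering and IPD cleaning.

The pipeline turns raw aligned subreads into per-(molecule, strand,
position) log-IPD observations suitable for kinetic scoring:

1. drop subreads with ambiguous alignment (MapQV < 240), low accuracy
   (< 80%) or short aligned length (< 100 bases);
2. mask IPDs at and within a small radius of every alignment error
   (mismatch, insertion, deletion) — error-adjacent kinetics are noise;
3. trim the first 10 and last 15 events of each subread, where adapter
   transitions bias the kinetics;
4. per molecule, natural-log transform all surviving IPDs (pooled over the
   molecule's subreads) and subtract their mean.  This removes per-molecule
   polymerase speed differences and any gradual slow-down over the read,
   and makes every downstream statistic invariant to the raw IPD unit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .records import (
    KineticsDataset,
    OP_MATCH,
    SubreadRecord,
)

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Tunable thresholds of the cleaning pipeline.

    Defaults implement the standard SMRT kinetics filters: strict
    inequalities, i.e. a subread fails only when strictly below a
    threshold.  ``zero_ipd_policy`` decides what to do with IPDs of 0
    (log-undefined): ``"drop"`` discards them (counted), ``"floor"`` clips
    them up to ``zero_ipd_floor``.  ``center_pre_trim`` reproduces the
    alternative normalization scope where the per-molecule mean is taken
    before edge trimming.
    """

    min_mapqv: int = 240
    min_accuracy: float = 0.80
    min_aligned_len: int = 100
    error_mask_radius: int = 1
    head_trim: int = 10
    tail_trim: int = 15
    zero_ipd_policy: str = "drop"
    zero_ipd_floor: float = 1e-3
    center_pre_trim: bool = False

    def __post_init__(self) -> None:
        for name in ("min_mapqv", "min_aligned_len", "error_mask_radius",
                     "head_trim", "tail_trim"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.min_accuracy <= 1.0:
            raise ValueError("min_accuracy must be a fraction in [0, 1]")
        if self.zero_ipd_policy not in ("drop", "floor"):
            raise ValueError("zero_ipd_policy must be 'drop' or 'floor'")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def filter_subreads(ds: KineticsDataset, cfg: PreprocessConfig) -> KineticsDataset:
    """Keep subreads passing the MapQV, accuracy and aligned-length gates."""
    kept = [
        sr
        for sr in ds.subreads
        if sr.mapqv >= cfg.min_mapqv
        and sr.accuracy >= cfg.min_accuracy
        and sr.aligned_length >= cfg.min_aligned_len
    ]
    out = dataclasses.replace(ds, subreads=kept, provenance=dict(ds.provenance))
    out.provenance["filtered_out"] = len(ds.subreads) - len(kept)
    return out


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """True wherever ``mask`` is True within ``radius`` (inclusive)."""
    if radius == 0 or not mask.any():
        return mask.copy()
    n = len(mask)
    idx = np.flatnonzero(mask)
    diff = np.zeros(n + 1, dtype=np.int64)
    np.add.at(diff, np.maximum(idx - radius, 0), 1)
    np.add.at(diff, np.minimum(idx + radius + 1, n), -1)
    return np.cumsum(diff[:-1]) > 0


def mask_error_adjacent(subread: SubreadRecord, radius: int) -> SubreadRecord:
    """Drop IPDs at and around alignment errors.

    Every event whose read-order index lies within ``radius`` of a
    mismatch, insertion or deletion loses its IPD (set to nan); the error
    event's own IPD is always dropped.  Events themselves are kept so that
    coordinates and trimming are unaffected.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    is_error = subread.op != OP_MATCH
    if not is_error.any():
        return subread
    masked = _dilate(is_error, radius)
    ipd = subread.ipd.copy()
    ipd[masked] = np.nan
    return subread.replace(ipd=ipd)


def trim_edges(subread: SubreadRecord, head: int, tail: int) -> SubreadRecord:
    """Remove the first ``head`` and last ``tail`` events in read order."""
    if head < 0 or tail < 0:
        raise ValueError("head and tail must be >= 0")
    n = len(subread)
    if head + tail >= n:
        sl = slice(0, 0)
    else:
        sl = slice(head, n - tail if tail else n)
    return subread.replace(
        ref_pos=subread.ref_pos[sl],
        op=subread.op[sl],
        read_base=subread.read_base[sl],
        ref_base=subread.ref_base[sl],
        ipd=subread.ipd[sl],
    )


def _surviving(subread: SubreadRecord, cfg: PreprocessConfig):
    """Match events with finite positive (or floored) IPDs; returns
    (ref_pos, subread_index-compatible arrays, ipd) plus the nonpositive-IPD
    drop count."""
    keep = (subread.op == OP_MATCH) & np.isfinite(subread.ipd)
    ipd = subread.ipd[keep]
    pos = subread.ref_pos[keep]
    dropped = 0
    nonpos = ipd <= 0
    if nonpos.any():
        if cfg.zero_ipd_policy == "drop":
            dropped = int(nonpos.sum())
            ipd = ipd[~nonpos]
            pos = pos[~nonpos]
        else:
            ipd = np.maximum(ipd, cfg.zero_ipd_floor)
    return pos, ipd, dropped


_OBS_COLUMNS = ["molecule_id", "strand", "ref_pos", "subread_index", "log_ipd"]


def _empty_obs() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "molecule_id": pd.Series(dtype=object),
            "strand": pd.Series(dtype=np.int8),
            "ref_pos": pd.Series(dtype=np.int64),
            "subread_index": pd.Series(dtype=np.int32),
            "log_ipd": pd.Series(dtype=np.float64),
        }
    )


def normalize_and_log(
    ds: KineticsDataset,
    cfg: PreprocessConfig,
    position_filter: dict[int, np.ndarray] | None = None,
    molecule_means: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-molecule mean-centred log IPDs as an observation table.

    Runs last in the pipeline: filtering, masking and trimming are assumed
    done.  For each molecule, all surviving IPDs across its subreads are
    log-transformed and their mean subtracted, so each molecule's emitted
    observations average to zero (exactly, up to float rounding) and any
    molecule-wise rescaling of raw IPDs cancels.

    ``position_filter`` optionally restricts the *emitted* rows to given
    per-strand sorted position arrays (the centring mean still uses every
    surviving IPD).  ``molecule_means`` overrides the per-molecule centring
    constants (used for the pre-trim normalization variant).
    """
    per_mol: dict[str, list] = {}
    for sr in ds.subreads:
        per_mol.setdefault(sr.molecule_id, []).append(sr)

    out_mol: list[str] = []
    out_strand: list[int] = []
    out_sidx: list[int] = []
    out_counts: list[int] = []
    out_pos: list[np.ndarray] = []
    out_logs: list[np.ndarray] = []
    total_dropped = 0
    for mol_id, subs in per_mol.items():
        parts = []
        for sr in subs:
            pos, ipd, dropped = _surviving(sr, cfg)
            total_dropped += dropped
            if len(ipd):
                parts.append((sr.strand, sr.subread_index, pos, np.log(ipd)))
        if not parts:
            continue
        if molecule_means is not None:
            center = molecule_means.get(mol_id)
            if center is None:
                continue
        else:
            sums = sum(float(p[3].sum()) for p in parts)
            count = sum(len(p[3]) for p in parts)
            center = sums / count
        for strand, sidx, pos, logs in parts:
            logs = logs - center
            if position_filter is not None:
                allowed = position_filter.get(strand)
                if allowed is None or len(allowed) == 0:
                    continue
                idx = np.searchsorted(allowed, pos)
                idx[idx == len(allowed)] = 0
                keep = allowed[idx] == pos
                pos, logs = pos[keep], logs[keep]
            if not len(pos):
                continue
            out_mol.append(mol_id)
            out_strand.append(strand)
            out_sidx.append(sidx)
            out_counts.append(len(pos))
            out_pos.append(pos.astype(np.int64))
            out_logs.append(logs)
    if out_counts:
        counts = np.array(out_counts)
        obs = pd.DataFrame(
            {
                "molecule_id": np.repeat(np.array(out_mol, dtype=object), counts),
                "strand": np.repeat(np.array(out_strand, dtype=np.int8), counts),
                "ref_pos": np.concatenate(out_pos),
                "subread_index": np.repeat(
                    np.array(out_sidx, dtype=np.int32), counts
                ),
                "log_ipd": np.concatenate(out_logs),
            }
        )
    else:
        obs = _empty_obs()
    if total_dropped:
        log.info("dropped %d nonpositive IPD values (log undefined)", total_dropped)
    obs.attrs.update(
        sample_type=ds.sample_type,
        ipd_unit=ds.ipd_unit,
        reference_id=ds.reference_id,
        reference_length=ds.reference_length,
        nonpositive_ipds_dropped=total_dropped,
    )
    return obs


def _pre_trim_means(ds: KineticsDataset, cfg: PreprocessConfig) -> dict[str, float]:
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for sr in ds.subreads:
        _, ipd, _ = _surviving(sr, cfg)
        if len(ipd):
            logs = np.log(ipd)
            sums[sr.molecule_id] = sums.get(sr.molecule_id, 0.0) + logs.sum()
            counts[sr.molecule_id] = counts.get(sr.molecule_id, 0) + len(logs)
    return {m: sums[m] / counts[m] for m in sums}


def preprocess(
    ds: KineticsDataset,
    cfg: PreprocessConfig | None = None,
    position_filter: dict[int, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Full pipeline: filter -> mask -> trim -> normalize."""
    cfg = cfg or PreprocessConfig()
    ds = filter_subreads(ds, cfg)
    masked = [mask_error_adjacent(sr, cfg.error_mask_radius) for sr in ds.subreads]
    ds = dataclasses.replace(ds, subreads=masked, provenance=dict(ds.provenance))
    molecule_means = _pre_trim_means(ds, cfg) if cfg.center_pre_trim else None
    trimmed = [trim_edges(sr, cfg.head_trim, cfg.tail_trim) for sr in ds.subreads]
    ds = dataclasses.replace(ds, subreads=trimmed, provenance=dict(ds.provenance))
    return normalize_and_log(
        ds, cfg, position_filter=position_filter, molecule_means=molecule_means
    )


def write_observations(path, obs: pd.DataFrame) -> None:
    """Write an observation table with its metadata as ``#key=value`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in ("sample_type", "ipd_unit", "reference_id", "reference_length"):
            if key in obs.attrs:
                fh.write(f"#{key}={obs.attrs[key]}\n")
        fh.write("\t".join(_OBS_COLUMNS) + "\n")
        for r in obs.itertuples(index=False):
            fh.write(
                f"{r.molecule_id}\t{r.strand}\t{r.ref_pos}\t{r.subread_index}\t"
                f"{r.log_ipd:.9g}\n"
            )


def read_observations(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_observations`."""
    meta: dict[str, str] = {}
    rows = {c: [] for c in _OBS_COLUMNS}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts != _OBS_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: unexpected header {parts!r}")
                header_seen = True
                continue
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            rows["molecule_id"].append(parts[0])
            rows["strand"].append(int(parts[1]))
            rows["ref_pos"].append(int(parts[2]))
            rows["subread_index"].append(int(parts[3]))
            rows["log_ipd"].append(float(parts[4]))
    obs = pd.DataFrame(
        {
            "molecule_id": rows["molecule_id"],
            "strand": np.array(rows["strand"], dtype=np.int8),
            "ref_pos": np.array(rows["ref_pos"], dtype=np.int64),
            "subread_index": np.array(rows["subread_index"], dtype=np.int32),
            "log_ipd": np.array(rows["log_ipd"], dtype=np.float64),
        }
    )
    if "reference_length" in meta:
        meta["reference_length"] = int(meta["reference_length"])  # type: ignore[assignment]
    obs.attrs.update(meta)
    return obs
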