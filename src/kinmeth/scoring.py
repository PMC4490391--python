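"""The three kinetic methylation statistics and their WGA control.

All scores are differences of mean natural-log IPDs between native DNA and
a whole-genome-amplified (WGA, methylation-free) control:

* ``Agg_SN``  — population level, per (strand, position): the classical
  molecule-aggregated statistic.
* ``SM_SN``   — per (molecule, strand, position): single-molecule,
  single-nucleotide resolution; its precision is governed by cov_SM, the
  number of subread IPD observations the molecule supplies at the position.
* ``SM_P``    — per (molecule, strand): pools a long read's observations
  across every motif site it covers, for epigenetic phasing of MTase
  activity along single molecules.

Inputs are the cleaned per-observation tables produced by
:mod:`kinmeth.preprocess` (one row per surviving log-IPD observation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif import MotifSite

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmsnScore:
    """Single-molecule single-nucleotide score at one strand/position."""

    molecule_id: str
    strand: int
    ref_pos: int
    cov_sm: int
    score: float
    approximate: bool = False


@dataclass(frozen=True)
class AggScore:
    """Molecule-aggregated single-nucleotide score at one strand/position."""

    strand: int
    ref_pos: int
    native_n: int
    wga_n: int
    score: float


@dataclass(frozen=True)
class SmpScore:
    """Single-molecule pooled score over the motif sites of one long read."""

    molecule_id: str
    strand: int
    n_sites: int
    score: float


class ControlLookup:
    """WGA mean log-IPD (and observation count) per (strand, ref_pos).

    The WGA control is aggregated across all molecules because amplified
    DNA carries no methylation: pooling is free statistical power, and the
    per-position mean captures the sequence-context baseline that is then
    subtracted from every native statistic.
    """

    def __init__(self, table: pd.DataFrame):
        if list(table.columns) != ["mean_log_ipd", "n"]:
            raise ValueError("control table must have columns mean_log_ipd, n")
        if (table["n"] < 1).any():
            raise ValueError("control entries require at least one observation")
        self._table = table.sort_index()

    @classmethod
    def from_observations(cls, wga_obs: pd.DataFrame) -> "ControlLookup":
        sample_type = wga_obs.attrs.get("sample_type")
        if sample_type == "native":
            raise ValueError(
                "control must be built from WGA observations, got sample_type='native'"
            )
        g = wga_obs.groupby(["strand", "ref_pos"], sort=True)["log_ipd"]
        table = pd.DataFrame({"mean_log_ipd": g.mean(), "n": g.size()})
        return cls(table)

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self._table.index

    def lookup(self, strand: int, ref_pos: int) -> tuple[float, int]:
        row = self._table.loc[(strand, ref_pos)]
        return float(row["mean_log_ipd"]), int(row["n"])


def build_control(wga_obs: pd.DataFrame) -> ControlLookup:
    """Aggregate WGA observations into the per-(strand, position) control."""
    return ControlLookup.from_observations(wga_obs)


def _sites_frame(sites: list[MotifSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strand": np.fromiter((s.strand for s in sites), dtype=np.int64, count=len(sites)),
            "ref_pos": np.fromiter((s.ref_pos for s in sites), dtype=np.int64, count=len(sites)),
        }
    ).drop_duplicates()


def _obs_at_sites(obs: pd.DataFrame, sites: list[MotifSite]) -> pd.DataFrame:
    if not sites or obs.empty:
        return obs.iloc[0:0]
    return obs.merge(_sites_frame(sites), on=["strand", "ref_pos"], how="inner")


def _control_frame(control: ControlLookup) -> pd.DataFrame:
    c = control.table.reset_index()
    c.columns = ["strand", "ref_pos", "c_mean", "c_n"]
    return c


def smsn_scores(
    native_obs: pd.DataFrame,
    control: ControlLookup,
    sites: list[MotifSite],
    min_cov: int = 10,
) -> tuple[list[SmsnScore], dict]:
    """SM_SN scores at motif sites.

    Per (molecule, strand, site position) with at least ``min_cov`` surviving
    native observations and a control entry:
    ``score = mean(native log IPD) - WGA control mean``.  Groups failing
    either condition are skipped and tallied in the returned report.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    site_obs = _obs_at_sites(native_obs, sites)
    report = {"no_control": 0, "low_coverage": 0, "scored": 0}
    if site_obs.empty:
        return [], report
    g = site_obs.groupby(["molecule_id", "strand", "ref_pos"], sort=True)["log_ipd"]
    stats = pd.DataFrame({"m": g.mean(), "cov": g.size()}).reset_index()
    merged = stats.merge(_control_frame(control), on=["strand", "ref_pos"], how="left")
    no_control = merged["c_mean"].isna()
    low_cov = merged["cov"] < min_cov
    report["no_control"] = int(no_control.sum())
    report["low_coverage"] = int((~no_control & low_cov).sum())
    kept = merged[~no_control & ~low_cov]
    report["scored"] = len(kept)
    scores = [
        SmsnScore(r.molecule_id, int(r.strand), int(r.ref_pos), int(r.cov), float(r.m - r.c_mean))
        for r in kept.itertuples(index=False)
    ]
    return scores, report


def approx_smsn_scores(
    native_obs: pd.DataFrame,
    sites: list[MotifSite],
    min_cov: int = 10,
) -> tuple[list[SmsnScore], dict]:
    """WGA-free approximate SM_SN scores.

    When no amplified control exists, the score is simply the mean native
    molecule/strand/position log IPD (the control mean is treated as zero).
    Context biases are not removed, but per-read normalization keeps the
    methylated/non-methylated components resolvable; scores are flagged
    ``approximate``.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    site_obs = _obs_at_sites(native_obs, sites)
    report = {"low_coverage": 0, "scored": 0}
    if site_obs.empty:
        return [], report
    g = site_obs.groupby(["molecule_id", "strand", "ref_pos"], sort=True)["log_ipd"]
    stats = pd.DataFrame({"m": g.mean(), "cov": g.size()}).reset_index()
    kept = stats[stats["cov"] >= min_cov]
    report["low_coverage"] = int(len(stats) - len(kept))
    report["scored"] = len(kept)
    scores = [
        SmsnScore(
            r.molecule_id, int(r.strand), int(r.ref_pos), int(r.cov), float(r.m),
            approximate=True,
        )
        for r in kept.itertuples(index=False)
    ]
    return scores, report


def agg_scores(
    native_obs: pd.DataFrame,
    control: ControlLookup,
    sites: list[MotifSite],
) -> tuple[list[AggScore], dict]:
    """Molecule-aggregated scores: pooled native mean minus control mean,
    per (strand, site position), emitted wherever both sides have data."""
    site_obs = _obs_at_sites(native_obs, sites)
    report = {"no_control": 0, "scored": 0}
    if site_obs.empty:
        return [], report
    g = site_obs.groupby(["strand", "ref_pos"], sort=True)["log_ipd"]
    stats = pd.DataFrame({"m": g.mean(), "n": g.size()}).reset_index()
    merged = stats.merge(_control_frame(control), on=["strand", "ref_pos"], how="left")
    no_control = merged["c_mean"].isna()
    report["no_control"] = int(no_control.sum())
    kept = merged[~no_control]
    report["scored"] = len(kept)
    scores = [
        AggScore(int(r.strand), int(r.ref_pos), int(r.n), int(r.c_n), float(r.m - r.c_mean))
        for r in kept.itertuples(index=False)
    ]
    return scores, report


def smp_scores(
    native_obs: pd.DataFrame,
    control: ControlLookup,
    sites: list[MotifSite],
    min_sites: int = 10,
) -> tuple[list[SmpScore], dict]:
    """SM_P scores: per (molecule, strand), native observations pooled over
    every covered motif site, minus the unweighted mean of the control's
    per-site means over those same sites.

    Sites without a control entry are excluded from both sides; molecules
    covering fewer than ``min_sites`` eligible sites are skipped.  The
    default of 10 follows standard practice for short (4-mer) motifs on
    long reads.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    site_obs = _obs_at_sites(native_obs, sites)
    report = {"site_slots_no_control": 0, "below_min_sites": 0, "scored": 0}
    if site_obs.empty:
        return [], report
    merged = site_obs.merge(_control_frame(control), on=["strand", "ref_pos"], how="left")
    no_control = merged["c_mean"].isna()
    if no_control.any():
        dropped = merged[no_control][["molecule_id", "strand", "ref_pos"]].drop_duplicates()
        report["site_slots_no_control"] = len(dropped)
        merged = merged[~no_control]
    if merged.empty:
        return [], report
    native_g = merged.groupby(["molecule_id", "strand"], sort=True)["log_ipd"].agg(
        ["mean", "size"]
    )
    per_site = merged[["molecule_id", "strand", "ref_pos", "c_mean"]].drop_duplicates()
    ctrl_g = per_site.groupby(["molecule_id", "strand"], sort=True)["c_mean"].agg(
        ["mean", "size"]
    )
    joined = native_g.join(ctrl_g, lsuffix="_nat", rsuffix="_ctl")
    n_sites = joined["size_ctl"].astype(int)
    ok = n_sites >= min_sites
    report["below_min_sites"] = int((~ok).sum())
    report["scored"] = int(ok.sum())
    scores = [
        SmpScore(str(mol), int(strand), int(ns), float(m_nat - m_ctl))
        for (mol, strand), m_nat, m_ctl, ns in zip(
            joined.index[ok],
            joined.loc[ok, "mean_nat"],
            joined.loc[ok, "mean_ctl"],
            n_sites[ok],
        )
    ]
    return scores, report


def scores_to_frame(scores) -> pd.DataFrame:
    """Tabulate a homogeneous score list (convenience for analysis code)."""
    if not scores:
        return pd.DataFrame()
    return pd.DataFrame([s.__dict__ for s in scores])
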