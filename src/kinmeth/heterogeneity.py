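"""From score distributions to population-level epigenetic estimates.

The SM_SN score distribution of a motif is, to good approximation, a
two-component Gaussian mixture: a null component centred at 0
(non-methylated sites, native kinetics match the WGA control) and a
shifted component centred near the methylation effect size (approximately
+2 natural-log units for 6mA).  This module provides

* a self-contained 1-D two-component EM fit and the methylated-fraction
  readout (weight of the higher-mean component);
* negative-control constructions: IPD shuffling across molecules, and
  in-silico native/WGA molecule mixing at known proportions;
* empirical FDR curves for calling methylated (or non-methylated)
  molecules from SM_P scores against a matched control distribution;
* molecule downsampling to a target genomic coverage, and a
  sensitivity/specificity evaluation table.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import KineticsDataset
from .scoring import ControlLookup, SmpScore, smp_scores

log = logging.getLogger(__name__)


class NotConvergedError(RuntimeError):
    """EM did not converge; carries the partial fit."""

    def __init__(self, fit: "MixtureFit"):
        super().__init__("mixture fit did not converge")
        self.fit = fit


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture, components ordered by mean."""

    weight_lo: float
    weight_hi: float
    mean_lo: float
    mean_hi: float
    sd_lo: float
    sd_hi: float
    loglik: float
    n_iter: int
    converged: bool
    n: int
    bic_components: int = 2
    degenerate: bool = False

    @property
    def pooled_mean(self) -> float:
        return self.weight_lo * self.mean_lo + self.weight_hi * self.mean_hi

    @property
    def pooled_sd(self) -> float:
        mu = self.pooled_mean
        var = self.weight_lo * (self.sd_lo**2 + (self.mean_lo - mu) ** 2)
        var += self.weight_hi * (self.sd_hi**2 + (self.mean_hi - mu) ** 2)
        return float(np.sqrt(var))

    def is_bimodal(
        self, min_weight: float = 0.1, min_separation_sds: float = 2.0
    ) -> bool:
        """Whether the fit describes two genuinely distinct populations:
        BIC must prefer two components, both must carry at least
        ``min_weight`` of the mass, and the means must be separated by at
        least ``min_separation_sds`` of the wider component's sd."""
        return (
            self.bic_components == 2
            and min(self.weight_lo, self.weight_hi) >= min_weight
            and (self.mean_hi - self.mean_lo)
            >= min_separation_sds * max(self.sd_lo, self.sd_hi)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _log_normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def _em_run(x, w, mu, sd, tol, max_iter, sd_floor):
    n = x.size
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_dens = np.stack(
            [np.log(w[k]) + _log_normal_pdf(x, mu[k], sd[k]) for k in (0, 1)]
        )
        log_norm = np.logaddexp(log_dens[0], log_dens[1])
        new_loglik = float(log_norm.sum())
        resp = np.exp(log_dens - log_norm)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in (0, 1)])
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        if new_loglik - loglik < tol * n and it > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return w, mu, sd, loglik, it, converged


def fit_two_gaussian_em(
    scores,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 1000,
    sd_floor: float = 1e-3,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to 1-D scores by EM.

    Convergence is declared when the per-observation log-likelihood gain
    drops below ``tol`` (so the criterion is sample-size free), or at
    ``max_iter``.  Deterministic given ``seed``: a median-split
    initialization and one seeded random-responsibility restart are run
    and the higher-likelihood solution kept.  Components are reported ordered by mean.  The fit also
    records whether BIC prefers one or two components, which the
    methylated-fraction readout uses to recognise effectively unimodal
    data.  All-identical input degenerates to a single point mass
    (``degenerate=True``) with the weight assigned by mean sign.
    """
    x = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores,
                   dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    n = x.size
    if n < 20:
        raise ValueError(f"need at least 20 scores to fit a mixture, got {n}")
    if np.ptp(x) == 0.0:
        log.warning("all %d scores identical; returning degenerate single component", n)
        v = float(x[0])
        hi = 1.0 if v > 0 else 0.0
        return MixtureFit(
            weight_lo=1.0 - hi, weight_hi=hi, mean_lo=v, mean_hi=v,
            sd_lo=sd_floor, sd_hi=sd_floor, loglik=float("nan"), n_iter=0,
            converged=True, n=n, bic_components=1, degenerate=True,
        )

    xs = np.sort(x)
    half = n // 2
    lo, hi = xs[:half], xs[half:]
    init_a = (
        np.array([0.5, 0.5]),
        np.array([lo.mean(), hi.mean()]),
        np.maximum(np.array([lo.std(), hi.std()]), sd_floor),
    )
    rng = np.random.default_rng(seed)
    r = rng.uniform(0.25, 0.75, size=n)
    w0 = np.array([r.mean(), 1.0 - r.mean()])
    mu0 = np.array([(r @ x) / r.sum(), ((1 - r) @ x) / (1 - r).sum()])
    sd0 = np.maximum(
        np.array(
            [
                np.sqrt((r @ (x - mu0[0]) ** 2) / r.sum()),
                np.sqrt(((1 - r) @ (x - mu0[1]) ** 2) / (1 - r).sum()),
            ]
        ),
        sd_floor,
    )
    init_b = (w0, mu0, sd0)

    best = None
    for w, mu, sd in (init_a, init_b):
        out = _em_run(x, w.copy(), mu.copy(), sd.copy(), tol, max_iter, sd_floor)
        if best is None or out[3] > best[3]:
            best = out
    w, mu, sd, loglik, n_iter, converged = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]

    # single-component BIC comparison (2 params vs 5)
    mu1, sd1 = x.mean(), max(x.std(), sd_floor)
    loglik1 = float(_log_normal_pdf(x, mu1, sd1).sum())
    bic1 = 2 * np.log(n) - 2 * loglik1
    bic2 = 5 * np.log(n) - 2 * loglik
    return MixtureFit(
        weight_lo=float(w[0]), weight_hi=float(w[1]),
        mean_lo=float(mu[0]), mean_hi=float(mu[1]),
        sd_lo=float(sd[0]), sd_hi=float(sd[1]),
        loglik=loglik, n_iter=n_iter, converged=converged, n=n,
        bic_components=1 if bic1 <= bic2 else 2,
    )


def methylated_fraction(fit: MixtureFit, unimodal_margin: float = 2.0) -> float:
    """Fraction of the population in the methylated (higher-mean) component.

    For a genuinely bimodal fit this is simply ``weight_hi``; no posterior
    thresholding is applied.  When BIC prefers a single component the
    weight split between two coincident Gaussians is arbitrary, so a
    location rule applies instead: the population counts as fully
    methylated (1.0) if its pooled mean sits more than ``unimodal_margin``
    pooled standard deviations above zero, and fully non-methylated (0.0)
    otherwise.  A two-component fit whose means coincide exactly carries
    no usable split and raises.
    """
    if not fit.converged:
        raise NotConvergedError(fit)
    if fit.degenerate:
        return fit.weight_hi
    if fit.bic_components == 1:
        return 1.0 if fit.pooled_mean > unimodal_margin * fit.pooled_sd else 0.0
    if fit.mean_hi == fit.mean_lo:
        raise ValueError("no separable components: mixture means coincide")
    return fit.weight_hi


@dataclass
class FdrCurve:
    """Empirical FDR along candidate score thresholds.

    ``direction='greater'`` targets methylated calls (scores beyond means
    above the threshold); ``'less'`` targets non-methylated calls.  The FDR
    at a threshold is the control tail fraction over the native tail
    fraction, capped at 1 and monotone-adjusted to be non-increasing as
    the threshold becomes more extreme.
    """

    thresholds: np.ndarray
    native_beyond: np.ndarray
    control_beyond: np.ndarray
    fdr: np.ndarray
    direction: str
    n_native: int
    n_control: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "native_beyond": self.native_beyond,
                "control_beyond": self.control_beyond,
                "fdr": self.fdr,
            }
        )

    def fraction_called(self, max_fdr: float) -> float:
        """Fraction of native molecules callable at FDR <= ``max_fdr``."""
        ok = self.fdr <= max_fdr
        if not ok.any():
            return 0.0
        return float(self.native_beyond[ok].max() / self.n_native)


def _score_values(scores) -> np.ndarray:
    return np.array(
        [getattr(s, "score", s) for s in scores], dtype=np.float64
    )


def empirical_fdr(native_scores, control_scores, direction: str = "greater") -> FdrCurve:
    """Empirical FDR curve from native scores against a negative control."""
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    nat = _score_values(native_scores)
    ctl = _score_values(control_scores)
    if nat.size == 0 or ctl.size == 0:
        raise ValueError("both native and control score lists must be non-empty")
    thresholds = np.unique(nat)
    nat_sorted = np.sort(nat)
    ctl_sorted = np.sort(ctl)
    if direction == "greater":
        native_beyond = nat.size - np.searchsorted(nat_sorted, thresholds, side="left")
        control_beyond = ctl.size - np.searchsorted(ctl_sorted, thresholds, side="left")
    else:
        native_beyond = np.searchsorted(nat_sorted, thresholds, side="right")
        control_beyond = np.searchsorted(ctl_sorted, thresholds, side="right")
    raw = np.minimum(
        1.0, (control_beyond / ctl.size) / (native_beyond / nat.size)
    )
    # Running minimum from the least extreme threshold outward: the curve is
    # non-increasing as t becomes more extreme, and a sparse extreme tail
    # (where a raw ratio of 0/1 is meaningless) never drags down the stable
    # central estimates.
    if direction == "greater":
        fdr = np.minimum.accumulate(raw)
    else:
        fdr = np.minimum.accumulate(raw[::-1])[::-1]
    return FdrCurve(
        thresholds=thresholds,
        native_beyond=native_beyond.astype(np.int64),
        control_beyond=control_beyond.astype(np.int64),
        fdr=fdr,
        direction=direction,
        n_native=nat.size,
        n_control=ctl.size,
    )


def shuffle_site_observations(
    native_obs: pd.DataFrame, sites, seed: int = 0
) -> pd.DataFrame:
    """Permute motif-site log-IPD values across (molecule, strand, site) slots.

    Each slot keeps its observation count and every molecule its
    covered-site structure; only the values move, dispersing any
    non-methylated minority so the shuffled data behave like a mostly
    methylated control.  Returns the site-restricted observation table with
    permuted values.
    """
    from .scoring import _obs_at_sites  # local import to avoid cycle at module load

    site_obs = _obs_at_sites(native_obs, list(sites)).copy()
    rng = np.random.default_rng(seed)
    values = site_obs["log_ipd"].to_numpy()
    site_obs["log_ipd"] = rng.permutation(values)
    site_obs.attrs.update(native_obs.attrs)
    site_obs.attrs["shuffled"] = True
    return site_obs


def shuffled_smp_scores(
    native_obs: pd.DataFrame,
    control: ControlLookup,
    sites,
    seed: int = 0,
    min_sites: int = 10,
) -> tuple[list[SmpScore], dict]:
    """SM_P recomputed after IPD shuffling (the non-methylation control)."""
    shuffled = shuffle_site_observations(native_obs, sites, seed=seed)
    return smp_scores(shuffled, control, list(sites), min_sites=min_sites)


def insilico_mix(
    native_ds: KineticsDataset,
    wga_ds: KineticsDataset,
    native_fraction: float,
    n_total: int,
    seed: int = 0,
) -> KineticsDataset:
    """Mix native and WGA molecules at a known proportion.

    Samples ``round(native_fraction * n_total)`` native molecules and the
    remainder WGA molecules, each without replacement; molecules are
    relabeled to avoid id collisions.  The result plays the native role
    downstream (its true methylated fraction is ``native_fraction`` times
    the native sample's).
    """
    if not 0.0 <= native_fraction <= 1.0:
        raise ValueError("native_fraction must be in [0, 1]")
    if native_ds.ipd_unit != wga_ds.ipd_unit:
        raise ValueError(
            f"IPD units differ: {native_ds.ipd_unit} vs {wga_ds.ipd_unit}"
        )
    n_native = int(round(native_fraction * n_total))
    n_wga = n_total - n_native
    nat_ids = native_ds.molecule_ids
    wga_ids = wga_ds.molecule_ids
    if n_native > len(nat_ids):
        raise ValueError(
            f"insufficient native molecules: need {n_native}, have {len(nat_ids)} "
            f"(short by {n_native - len(nat_ids)})"
        )
    if n_wga > len(wga_ids):
        raise ValueError(
            f"insufficient WGA molecules: need {n_wga}, have {len(wga_ids)} "
            f"(short by {n_wga - len(wga_ids)})"
        )
    rng = np.random.default_rng(seed)
    take_nat = set(rng.choice(len(nat_ids), size=n_native, replace=False).tolist())
    take_wga = set(rng.choice(len(wga_ids), size=n_wga, replace=False).tolist())
    chosen_nat = {nat_ids[i] for i in take_nat}
    chosen_wga = {wga_ids[i] for i in take_wga}
    subreads = []
    for sr in native_ds.subreads:
        if sr.molecule_id in chosen_nat:
            subreads.append(sr.replace(molecule_id="nat:" + sr.molecule_id))
    for sr in wga_ds.subreads:
        if sr.molecule_id in chosen_wga:
            subreads.append(sr.replace(molecule_id="wga:" + sr.molecule_id))
    return KineticsDataset(
        subreads=subreads,
        reference_id=native_ds.reference_id,
        reference_length=native_ds.reference_length,
        sample_type="native",
        ipd_unit=native_ds.ipd_unit,
        provenance={
            "insilico_mix": {
                "native_fraction": native_fraction,
                "n_native": n_native,
                "n_wga": n_wga,
                "seed": seed,
            }
        },
    )


def downsample_molecules(
    ds: KineticsDataset,
    target_coverage: float,
    reference_length: int | None = None,
    seed: int = 0,
) -> KineticsDataset:
    """Random molecule subset whose total aligned bases approximate a
    genomic coverage target (within one molecule's worth of bases)."""
    if target_coverage < 0:
        raise ValueError("target_coverage must be >= 0")
    ref_len = reference_length or ds.reference_length
    per_mol = ds.by_molecule()
    mol_ids = list(per_mol)
    bases = np.array(
        [sum(sr.aligned_length for sr in per_mol[m]) for m in mol_ids], dtype=np.int64
    )
    target_bases = target_coverage * ref_len
    if bases.sum() <= target_bases:
        if bases.sum() < target_bases:
            log.warning(
                "target coverage %.3gx exceeds available %.3gx; returning all molecules",
                target_coverage, bases.sum() / ref_len,
            )
        return ds.subset_molecules(mol_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mol_ids))
    cum = np.cumsum(bases[order])
    n_keep = int(np.searchsorted(cum, target_bases, side="left")) + 1
    keep = {mol_ids[i] for i in order[:n_keep]}
    return ds.subset_molecules(keep)


def sensitivity_specificity(
    pos_scores,
    neg_scores,
    min_cov_grid=(10, 15, 25),
    threshold_grid=None,
) -> pd.DataFrame:
    """Detection performance table over coverage bins and score thresholds.

    ``pos_scores`` are scores from sites/molecules assumed methylated (a
    native sample of a constitutively active motif, or synthetic truth);
    ``neg_scores`` from unmethylated material (WGA).  Sensitivity is the
    positive fraction at or above each threshold, specificity the negative
    fraction below it; rows with an empty bin are omitted with a warning.
    The coverage attribute is ``cov_sm`` for SM_SN scores and ``n_sites``
    for SM_P scores.
    """

    def cov_of(s):
        v = getattr(s, "cov_sm", None)
        if v is None:
            v = getattr(s, "n_sites", None)
        return v if v is not None else 1

    pos = np.array([(cov_of(s), getattr(s, "score", s)) for s in pos_scores])
    neg = np.array([(cov_of(s), getattr(s, "score", s)) for s in neg_scores])
    if threshold_grid is None:
        pool = np.concatenate([pos[:, 1], neg[:, 1]]) if len(pos) and len(neg) else np.array([0.0])
        threshold_grid = np.quantile(pool, np.linspace(0.0, 1.0, 51))
    rows = []
    for mc in min_cov_grid:
        p = pos[pos[:, 0] >= mc][:, 1] if len(pos) else np.array([])
        n = neg[neg[:, 0] >= mc][:, 1] if len(neg) else np.array([])
        if p.size == 0 or n.size == 0:
            log.warning("empty bin at min_cov=%s; row omitted", mc)
            continue
        for thr in threshold_grid:
            rows.append(
                {
                    "min_cov": mc,
                    "threshold": float(thr),
                    "n_pos": p.size,
                    "n_neg": n.size,
                    "sensitivity": float(np.mean(p >= thr)),
                    "specificity": float(np.mean(n < thr)),
                }
            )
    return pd.DataFrame(rows)
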