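"""End-to-end simulation studies that validate the method at desk scale.

Each function runs one self-contained experiment on synthetic kinetics with
known ground truth and returns the headline numbers as a dict.  The designs
mirror the analyses a methylome study would run — EM recovery of known
mixture fractions, null centring of single-molecule scores against a WGA
control, phasing-regime discrimination on long reads, empirical-FDR sanity
checks, and stability of the methylated-fraction estimate down to ~x1
genomic coverage.  Problem sizes are chosen so the full battery runs on a
laptop in minutes; docs/methods.md discusses the scaling.

Every experiment takes a single integer ``seed`` and is bit-reproducible.
"""

from __future__ import annotations

import logging

import numpy as np

from .heterogeneity import (
    downsample_molecules,
    empirical_fdr,
    fit_two_gaussian_em,
    insilico_mix,
    methylated_fraction,
    shuffled_smp_scores,
)
from .motif import find_motif_sites
from .preprocess import PreprocessConfig, preprocess
from .records import FORWARD, REVERSE
from .scoring import build_control, smp_scores, smsn_scores
from .synthetic import SimConfig, simulate_dataset, simulate_reference

log = logging.getLogger(__name__)

#: Short-insert library emulating current circular-consensus chemistry:
#: ~250 bp inserts under a 12 kb polymerase read give ~17 passes per strand,
#: i.e. a cov_SM distribution centred near 12 after masking and trimming,
#: comfortably above the default min_cov of 10.
_SHORT = dict(insert_mean=250.0, insert_sd=25.0, read_length=12_000)
#: Long-insert single-pass control library: cheap dense footprint for the
#: per-position WGA baseline.
_CONTROL = dict(insert_mean=10_000.0, insert_sd=1_000.0, read_length=12_000)


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


def _site_filter(sites) -> dict[int, np.ndarray]:
    return {
        s: np.array(sorted(x.ref_pos for x in sites if x.strand == s), dtype=np.int64)
        for s in (FORWARD, REVERSE)
    }


def em_fraction_recovery(
    seed: int,
    true_fractions=(0.05, 1.0),
    n: int = 10_000,
    mu_methylated: float = 2.0,
    sd: float = 0.5,
) -> dict:
    """EM recovery of known two-Gaussian mixture weights.

    Scores are drawn from the canonical simulation design — a methylated
    component at +2 and a non-methylated component at 0, sd 0.5 each — and
    the estimated methylated fraction is compared with the truth.
    """
    out = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 40]))
    for fraction in true_fractions:
        n_hi = int(round(fraction * n))
        x = np.concatenate(
            [rng.normal(mu_methylated, sd, n_hi), rng.normal(0.0, sd, n - n_hi)]
        )
        fit = fit_two_gaussian_em(rng.permutation(x), seed=seed)
        out[fraction] = {
            "estimate": methylated_fraction(fit),
            "n": n,
            "converged": fit.converged,
        }
    return out


def smsn_null_centering(
    seed: int,
    n_native: int = 800,
    reference_length: int = 100_000,
    control_footprint: float = 25.0,
    min_cov: int = 10,
) -> dict:
    """SM_SN scores with no methylation effect against a matched control.

    The native sample is simulated with delta = 0, so every score's
    expectation is 0; the experiment reports the observed mean, its
    standard error, and the z statistic |mean| / SE.
    """
    s_nat, s_ctl, ctx = _subseeds(seed, 3)
    nat_cfg = SimConfig(
        seed=s_nat, context_seed=ctx, reference_length=reference_length,
        n_molecules=n_native, delta=0.0, **_SHORT,
    )
    reference = simulate_reference(reference_length, ctx)
    native, _ = simulate_dataset(nat_cfg, reference)
    n_control = int(control_footprint * reference_length / _CONTROL["insert_mean"])
    ctl_cfg = SimConfig(
        seed=s_ctl, context_seed=ctx, reference_length=reference_length,
        n_molecules=n_control, sample_type="wga", **_CONTROL,
    )
    control_ds, _ = simulate_dataset(ctl_cfg, reference)
    sites = find_motif_sites(reference, nat_cfg.motif)
    pf = _site_filter(sites)
    pcfg = PreprocessConfig()
    control = build_control(preprocess(control_ds, pcfg, position_filter=pf))
    scores, report = smsn_scores(
        preprocess(native, pcfg, position_filter=pf), control, sites, min_cov=min_cov
    )
    vals = np.array([s.score for s in scores])
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return {
        "n_scores": len(vals),
        "mean": float(vals.mean()),
        "se": se,
        "z": float(abs(vals.mean()) / se),
        "skip_report": report,
    }


def _long_read_smp(seed, regime, *, n_molecules, reference, control, sites, pcfg,
                   context_seed, min_sites=10, **regime_kw):
    cfg = SimConfig.long_library(
        seed=seed, context_seed=context_seed, reference_length=len(reference),
        n_molecules=n_molecules, regime=regime, **regime_kw,
    )
    ds, truth = simulate_dataset(cfg, reference)
    obs = preprocess(ds, pcfg)
    native, _ = smp_scores(obs, control, sites, min_sites=min_sites)
    shuffled, _ = shuffled_smp_scores(obs, control, sites, seed=seed, min_sites=min_sites)
    return cfg, truth, native, shuffled


def regime_discrimination(
    seed: int,
    n_molecules: int = 500,
    reference_length: int = 20_000,
    n_control: int = 400,
    f_active: float = 0.2,
    p_site: float = 0.6,
) -> dict:
    """Phase-variable versus intracellular-stochastic methylation on long reads.

    A phase-variable MTase active in a fraction ``f_active`` of cells
    produces a bimodal SM_P distribution whose high-mode mass estimates
    ``f_active``; a universally active but processivity-limited MTase
    (per-site probability ``p_site``) produces a unimodal distribution
    centred near ``p_site * delta``.  IPD shuffling collapses either
    structure into a unimodal control.
    """
    s_pv, s_st, s_ctl, ctx = _subseeds(seed, 4)
    reference = simulate_reference(reference_length, ctx)
    base = SimConfig.long_library(seed=s_ctl, context_seed=ctx,
                                  reference_length=reference_length,
                                  n_molecules=n_control, sample_type="wga")
    control_ds, _ = simulate_dataset(base, reference)
    sites = find_motif_sites(reference, base.motif)
    pcfg = PreprocessConfig()
    control = build_control(preprocess(control_ds, pcfg))

    pv_cfg, pv_truth, pv_scores, pv_shuffled = _long_read_smp(
        s_pv, "phase_variable", n_molecules=n_molecules, reference=reference,
        control=control, sites=sites, pcfg=pcfg, context_seed=ctx,
        f_active=f_active,
    )
    st_cfg, st_truth, st_scores, st_shuffled = _long_read_smp(
        s_st, "stochastic", n_molecules=n_molecules, reference=reference,
        control=control, sites=sites, pcfg=pcfg, context_seed=ctx,
        p_site=p_site,
    )

    pv_vals = np.array([s.score for s in pv_scores])
    st_vals = np.array([s.score for s in st_scores])
    pv_fit = fit_two_gaussian_em(pv_vals, seed=seed)
    st_fit = fit_two_gaussian_em(st_vals, seed=seed)
    pv_shuf_fit = fit_two_gaussian_em([s.score for s in pv_shuffled], seed=seed)
    st_shuf_fit = fit_two_gaussian_em([s.score for s in st_shuffled], seed=seed)
    return {
        "phase_variable": {
            "n_scores": len(pv_vals),
            "high_mode_mass": methylated_fraction(pv_fit),
            "true_active_fraction": float(pv_truth.molecules["methylated"].mean()),
            "bimodal": pv_fit.is_bimodal(),
            "shuffled_bimodal": pv_shuf_fit.is_bimodal(),
        },
        "stochastic": {
            "n_scores": len(st_vals),
            "mean_score_over_delta": float(st_vals.mean() / st_cfg.delta),
            "true_site_fraction": float(st_truth.sites["methylated"].mean()),
            "bimodal": st_fit.is_bimodal(),
            "shuffled_bimodal": st_shuf_fit.is_bimodal(),
        },
        "delta": st_cfg.delta,
    }


def fdr_sanity(seed: int, n_molecules: int = 300, reference_length: int = 20_000) -> dict:
    """Empirical FDR behaviour on a pure null and on separated distributions.

    Null: SM_P scores of one WGA sample split into relabeled halves — the
    central FDR should sit near 1.  Separated: constitutively methylated
    native molecules against the WGA control — everything is callable at
    FDR ~ 0.
    """
    s_nat, s_ctl, ctx = _subseeds(seed, 3)
    reference = simulate_reference(reference_length, ctx)
    ctl_cfg = SimConfig.long_library(
        seed=s_ctl, context_seed=ctx, reference_length=reference_length,
        n_molecules=2 * n_molecules, sample_type="wga",
    )
    control_ds, _ = simulate_dataset(ctl_cfg, reference)
    sites = find_motif_sites(reference, ctl_cfg.motif)
    pcfg = PreprocessConfig()
    ctl_obs = preprocess(control_ds, pcfg)
    control = build_control(ctl_obs)
    ctl_smp, _ = smp_scores(ctl_obs, control, sites, min_sites=10)

    half = len(ctl_smp) // 2
    null_curve = empirical_fdr(ctl_smp[:half], ctl_smp[half:], "greater")
    central = null_curve.fdr[
        (null_curve.native_beyond >= 0.25 * half)
        & (null_curve.native_beyond <= 0.75 * half)
    ]

    nat_cfg = SimConfig.long_library(
        seed=s_nat, context_seed=ctx, reference_length=reference_length,
        n_molecules=n_molecules,
    )
    native_ds, _ = simulate_dataset(nat_cfg, reference)
    nat_smp, _ = smp_scores(preprocess(native_ds, pcfg), control, sites, min_sites=10)
    sep_curve = empirical_fdr(nat_smp, ctl_smp, "greater")
    return {
        "null_central_fdr_min": float(central.min()),
        "null_central_fdr_median": float(np.median(central)),
        "n_null_scores": len(ctl_smp),
        "separated_fraction_called_at_1pct": sep_curve.fraction_called(0.01),
        "n_native_scores": len(nat_smp),
    }


def coverage_stability(
    seed: int,
    native_fraction: float = 0.6,
    reference_length: int = 4_000_000,
    high_coverage: float = 20.0,
    low_coverage: float = 1.0,
    control_footprint: float = 25.0,
    min_cov: int = 10,
) -> dict:
    """Stability of the EM methylated-fraction estimate at low coverage.

    Native (constitutively methylated) and WGA molecules are mixed in
    silico at a known fraction to the high-coverage target, SM_SN scores
    are computed against an independent WGA control, and the EM estimate is
    compared between the full mixture and a random downsample whose total
    aligned bases correspond to the low-coverage target.
    """
    s_nat, s_mix, s_ctl, s_ds, ctx = _subseeds(seed, 5)
    per_mol_bases = _SHORT["read_length"] // (
        int(_SHORT["insert_mean"]) + 100
    ) * int(_SHORT["insert_mean"])
    n_total = int(high_coverage * reference_length / per_mol_bases)
    n_native = int(round(native_fraction * n_total))  # matches insilico_mix
    n_wga = n_total - n_native
    reference = simulate_reference(reference_length, ctx)
    pcfg = PreprocessConfig()

    # control first so its raw events can be freed before the mixture exists
    n_control = int(control_footprint * reference_length / _CONTROL["insert_mean"])
    ctl_cfg = SimConfig(
        seed=s_ctl, context_seed=ctx, reference_length=reference_length,
        n_molecules=n_control, sample_type="wga", **_CONTROL,
    )
    control_ds, _ = simulate_dataset(ctl_cfg, reference)
    sites = find_motif_sites(reference, ctl_cfg.motif)
    pf = _site_filter(sites)
    control = build_control(preprocess(control_ds, pcfg, position_filter=pf))
    del control_ds

    nat_cfg = SimConfig(
        seed=s_nat, context_seed=ctx, reference_length=reference_length,
        n_molecules=n_native, **_SHORT,
    )
    native_pool, _ = simulate_dataset(nat_cfg, reference)
    wga_cfg = nat_cfg.replace(seed=s_mix, n_molecules=n_wga, sample_type="wga")
    wga_pool, _ = simulate_dataset(wga_cfg, reference)
    mixture = insilico_mix(native_pool, wga_pool, native_fraction, n_total, seed=s_mix)
    del native_pool, wga_pool

    def estimate(ds):
        scores, _ = smsn_scores(
            preprocess(ds, pcfg, position_filter=pf), control, sites, min_cov=min_cov
        )
        vals = [s.score for s in scores]
        return methylated_fraction(fit_two_gaussian_em(vals, seed=seed)), len(vals)

    est_high, n_high = estimate(mixture)
    low_ds = downsample_molecules(mixture, low_coverage, seed=s_ds)
    est_low, n_low = estimate(low_ds)
    return {
        "native_fraction": native_fraction,
        "high_coverage": {"target_x": high_coverage, "estimate": est_high, "n_scores": n_high},
        "low_coverage": {
            "target_x": low_coverage, "estimate": est_low, "n_scores": n_low,
            "n_molecules": low_ds.n_molecules,
        },
        "abs_difference": abs(est_high - est_low),
    }
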