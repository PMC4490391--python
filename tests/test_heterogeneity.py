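"""EM mixture fitting, empirical FDR, shuffling, mixing, downsampling."""

from __future__ import annotations

import numpy as np
import pytest

from kinmeth.heterogeneity import (
    MixtureFit,
    NotConvergedError,
    downsample_molecules,
    empirical_fdr,
    fit_two_gaussian_em,
    insilico_mix,
    methylated_fraction,
    sensitivity_specificity,
    shuffle_site_observations,
    shuffled_smp_scores,
)
from kinmeth.motif import MotifSite
from kinmeth.records import FORWARD
from kinmeth.scoring import SmpScore, SmsnScore, build_control, smp_scores
from kinmeth.synthetic import SimConfig, simulate_dataset

from conftest import obs_frame


def _mixture_sample(fraction, n=10_000, seed=0, mu_hi=2.0, sd=0.5):
    rng = np.random.default_rng(seed)
    n_hi = int(round(fraction * n))
    return rng.permutation(
        np.concatenate(
            [rng.normal(mu_hi, sd, n_hi), rng.normal(0.0, sd, n - n_hi)]
        )
    )


class TestEmFit:
    @pytest.mark.parametrize("fraction", [0.05, 0.25, 0.5, 0.75, 1.0])
    def test_recovers_known_mixing_weight(self, fraction):
        """Two Gaussians at 0 and 2 (sd 0.5): the methylated-fraction
        readout lands within 2 percentage points of truth at n=10,000."""
        x = _mixture_sample(fraction, seed=17)
        fit = fit_two_gaussian_em(x, seed=1)
        assert fit.converged
        assert methylated_fraction(fit) == pytest.approx(fraction, abs=0.02)

    def test_input_order_invariance(self):
        x = _mixture_sample(0.6, n=2000, seed=3)
        a = fit_two_gaussian_em(x, seed=1)
        b = fit_two_gaussian_em(x[::-1].copy(), seed=1)
        assert a.weight_hi == pytest.approx(b.weight_hi, abs=1e-12)
        assert a.mean_hi == pytest.approx(b.mean_hi, abs=1e-12)

    def test_components_ordered_and_weights_sum_to_one(self):
        fit = fit_two_gaussian_em(_mixture_sample(0.4, n=1000, seed=5), seed=2)
        assert fit.mean_lo <= fit.mean_hi
        assert fit.weight_lo + fit.weight_hi == pytest.approx(1.0, abs=1e-9)
        assert min(fit.sd_lo, fit.sd_hi) >= 1e-3

    def test_degenerate_identical_scores(self):
        fit = fit_two_gaussian_em([1.5] * 30)
        assert fit.degenerate and methylated_fraction(fit) == 1.0
        fit0 = fit_two_gaussian_em([-0.2] * 30)
        assert methylated_fraction(fit0) == 0.0

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_two_gaussian_em([0.0] * 19)

    def test_single_population_near_zero_reads_as_unmethylated(self):
        rng = np.random.default_rng(8)
        fit = fit_two_gaussian_em(rng.normal(0.0, 0.5, 5000), seed=1)
        assert fit.bic_components == 1
        assert methylated_fraction(fit) == 0.0

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = _mixture_sample(0.6, n=5000, seed=11)
        ours = fit_two_gaussian_em(x, seed=1)
        gm = sklearn.GaussianMixture(n_components=2, random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        hi = int(np.argmax(gm.means_.ravel()))
        assert ours.weight_hi == pytest.approx(gm.weights_[hi], abs=0.01)
        assert ours.mean_hi == pytest.approx(float(gm.means_.ravel()[hi]), abs=0.05)


class TestMethylatedFraction:
    def _fit(self, **kw):
        base = dict(
            weight_lo=0.396, weight_hi=0.604, mean_lo=0.0, mean_hi=2.0,
            sd_lo=0.5, sd_hi=0.5, loglik=-1.0, n_iter=10, converged=True, n=1000,
        )
        base.update(kw)
        return MixtureFit(**base)

    def test_bimodal_fit_returns_high_component_weight(self):
        assert methylated_fraction(self._fit()) == pytest.approx(0.604)

    def test_equal_means_is_an_error(self):
        with pytest.raises(ValueError, match="separable"):
            methylated_fraction(self._fit(mean_lo=1.0, mean_hi=1.0))

    def test_not_converged_carries_partial_fit(self):
        fit = self._fit(converged=False)
        with pytest.raises(NotConvergedError) as err:
            methylated_fraction(fit)
        assert err.value.fit is fit


class TestEmpiricalFdr:
    def test_hand_computed_five_vs_five(self):
        native = [1.0, 2.0, 3.0, 4.0, 5.0]
        control = [0.5, 1.5, 2.5, 3.5, 4.5]
        curve = empirical_fdr(native, control, "greater")
        assert curve.thresholds.tolist() == native
        assert curve.native_beyond.tolist() == [5, 4, 3, 2, 1]
        assert curve.control_beyond.tolist() == [4, 3, 2, 1, 0]
        assert np.allclose(curve.fdr, [0.8, 0.75, 2 / 3, 0.5, 0.0])

    def test_null_gives_fdr_one_everywhere(self):
        scores = [0.1, 0.5, 0.9, 1.3, 2.0]
        curve = empirical_fdr(scores, list(scores), "greater")
        assert np.allclose(curve.fdr, 1.0)

    def test_fully_separated_gives_zero(self):
        curve = empirical_fdr([5.0, 6.0, 7.0], [0.0, 1.0], "greater")
        assert np.allclose(curve.fdr, 0.0)
        assert curve.fraction_called(0.01) == 1.0

    def test_less_direction_mirrors_greater(self):
        nat = [1.0, 2.0, 3.0]
        ctl = [4.0, 5.0]
        curve = empirical_fdr(nat, ctl, "less")
        assert np.allclose(curve.fdr, 0.0)
        mirrored = empirical_fdr([-x for x in nat], [-x for x in ctl], "greater")
        assert np.allclose(curve.fdr, mirrored.fdr[::-1])

    def test_monotone_toward_extreme(self):
        rng = np.random.default_rng(4)
        nat = rng.normal(1.0, 1.0, 300)
        ctl = rng.normal(0.0, 1.0, 300)
        curve = empirical_fdr(nat, ctl, "greater")
        assert (np.diff(curve.fdr) <= 1e-12).all()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            empirical_fdr([], [1.0], "greater")

    def test_score_objects_accepted(self):
        nat = [SmpScore("a", 0, 10, 2.0), SmpScore("b", 0, 10, 3.0)]
        ctl = [SmpScore("c", 0, 10, 0.0)]
        curve = empirical_fdr(nat, ctl, "greater")
        assert curve.n_native == 2 and curve.n_control == 1


def _site_obs_fixture(rng, n_mol=30, sites=(3, 9, 15, 21)):
    rows = []
    for m in range(n_mol):
        for pos in sites:
            rows.append((f"m{m}", FORWARD, pos, float(rng.normal(1.0, 0.7))))
    obs = obs_frame(rows)
    site_list = [MotifSite(p, FORWARD, "GATC") for p in sites]
    ctrl = build_control(
        obs_frame(
            [(f"w{i}", FORWARD, p, float(rng.normal(0.0, 0.3)))
             for p in sites for i in range(5)],
            sample_type="wga",
        )
    )
    return obs, site_list, ctrl


class TestShuffle:
    def test_value_multiset_and_structure_conserved(self, rng):
        obs, sites, _ = _site_obs_fixture(rng)
        shuffled = shuffle_site_observations(obs, sites, seed=9)
        assert np.allclose(
            np.sort(shuffled["log_ipd"]), np.sort(obs["log_ipd"])
        )
        before = obs.groupby(["molecule_id", "strand", "ref_pos"]).size()
        after = shuffled.groupby(["molecule_id", "strand", "ref_pos"]).size()
        assert before.equals(after)

    def test_n_sites_and_pooled_mean_unchanged(self, rng):
        obs, sites, ctrl = _site_obs_fixture(rng)
        native, _ = smp_scores(obs, ctrl, sites, min_sites=1)
        shuf, _ = shuffled_smp_scores(obs, ctrl, sites, seed=9, min_sites=1)
        assert sorted((s.molecule_id, s.n_sites) for s in native) == sorted(
            (s.molecule_id, s.n_sites) for s in shuf
        )
        # one observation per (molecule, site): the n_sites-weighted mean of
        # SM_P is a function of the conserved value multiset only
        w_native = sum(s.n_sites * s.score for s in native) / sum(
            s.n_sites for s in native
        )
        w_shuf = sum(s.n_sites * s.score for s in shuf) / sum(s.n_sites for s in shuf)
        assert w_native == pytest.approx(w_shuf, abs=1e-9)

    def test_seeded_determinism(self, rng):
        obs, sites, _ = _site_obs_fixture(rng)
        a = shuffle_site_observations(obs, sites, seed=5)
        b = shuffle_site_observations(obs, sites, seed=5)
        assert np.array_equal(a["log_ipd"], b["log_ipd"])


@pytest.fixture(scope="module")
def pools():
    nat, _ = simulate_dataset(SimConfig(seed=21, n_molecules=30, reference_length=3000))
    wga, _ = simulate_dataset(
        SimConfig(seed=22, n_molecules=30, reference_length=3000, sample_type="wga")
    )
    return nat, wga


@pytest.fixture(scope="module")
def clean_ds():
    out, _ = simulate_dataset(
        SimConfig(seed=31, n_molecules=40, reference_length=5000, error_rate=0.0)
    )
    return out


class TestInsilicoMix:
    def test_exact_composition(self, pools):
        nat, wga = pools
        mix = insilico_mix(nat, wga, 0.05, 20, seed=1)
        ids = mix.molecule_ids
        assert sum(i.startswith("nat:") for i in ids) == 1
        assert sum(i.startswith("wga:") for i in ids) == 19
        assert mix.sample_type == "native"

    def test_all_native_and_all_wga(self, pools):
        nat, wga = pools
        assert all(i.startswith("nat:") for i in insilico_mix(nat, wga, 1.0, 25, 1).molecule_ids)
        assert all(i.startswith("wga:") for i in insilico_mix(nat, wga, 0.0, 25, 1).molecule_ids)

    def test_insufficient_molecules_reports_shortfall(self, pools):
        nat, wga = pools
        with pytest.raises(ValueError, match="short by 20"):
            insilico_mix(nat, wga, 1.0, 50, seed=1)

    def test_sampling_without_replacement(self, pools):
        nat, wga = pools
        mix = insilico_mix(nat, wga, 0.5, 30, seed=7)
        assert len(mix.molecule_ids) == 30
        assert len(set(mix.molecule_ids)) == 30


class TestDownsample:
    def test_full_target_is_identity(self, clean_ds):
        ds = clean_ds
        full_cov = ds.total_aligned_bases() / ds.reference_length
        out = downsample_molecules(ds, full_cov + 1.0, seed=3)
        assert out.n_molecules == ds.n_molecules

    def test_same_seed_same_subset(self, clean_ds):
        ds = clean_ds
        a = downsample_molecules(ds, 5.0, seed=11)
        b = downsample_molecules(ds, 5.0, seed=11)
        assert a.molecule_ids == b.molecule_ids
        assert downsample_molecules(ds, 5.0, seed=12).molecule_ids != a.molecule_ids

    def test_coverage_within_one_molecule(self, clean_ds):
        ds = clean_ds
        target = 5.0
        out = downsample_molecules(ds, target, seed=2)
        per_mol = max(
            sum(sr.aligned_length for sr in subs)
            for subs in out.by_molecule().values()
        )
        achieved = out.total_aligned_bases()
        assert achieved >= target * ds.reference_length
        assert achieved - per_mol < target * ds.reference_length


class TestSensitivitySpecificity:
    def test_roc_endpoints(self):
        pos = [SmsnScore("p", 0, 1, 15, 2.0)] * 5
        neg = [SmsnScore("n", 0, 1, 15, 0.0)] * 5
        table = sensitivity_specificity(
            pos, neg, min_cov_grid=(1,), threshold_grid=[-np.inf, np.inf]
        )
        lo = table[table.threshold == -np.inf].iloc[0]
        hi = table[table.threshold == np.inf].iloc[0]
        assert (lo.sensitivity, lo.specificity) == (1.0, 0.0)
        assert (hi.sensitivity, hi.specificity) == (0.0, 1.0)

    def test_identical_distributions_track_chance_line(self, rng):
        vals = rng.normal(0, 1, 400)
        pos = [SmsnScore("p", 0, i, 15, float(v)) for i, v in enumerate(vals)]
        neg = [SmsnScore("n", 0, i, 15, float(v)) for i, v in enumerate(vals)]
        table = sensitivity_specificity(pos, neg, min_cov_grid=(1,))
        assert np.allclose(table.sensitivity + table.specificity, 1.0, atol=0.01)

    def test_sensitivity_nondecreasing_in_coverage(self, rng):
        """Higher single-molecule coverage tightens the score distribution
        around the methylation effect, so sensitivity at a fixed threshold
        cannot degrade as the coverage filter rises."""
        pos, neg = [], []
        for i in range(2000):
            cov = int(rng.integers(4, 40))
            pos.append(SmsnScore("p", 0, i, cov, float(rng.normal(2.0, 1.2 / np.sqrt(cov)))))
            neg.append(SmsnScore("n", 0, i, cov, float(rng.normal(0.0, 1.2 / np.sqrt(cov)))))
        grid = (5, 10, 15, 25)
        table = sensitivity_specificity(pos, neg, min_cov_grid=grid, threshold_grid=[1.0])
        sens = [float(table[table.min_cov == mc].sensitivity.iloc[0]) for mc in grid]
        assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_empty_bin_omitted(self):
        pos = [SmsnScore("p", 0, 1, 5, 2.0)] * 3
        neg = [SmsnScore("n", 0, 1, 5, 0.0)] * 3
        table = sensitivity_specificity(pos, neg, min_cov_grid=(5, 50))
        assert set(table.min_cov) == {5}
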