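"""SM_SN / Agg_SN / SM_P statistics against hand and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kinmeth.motif import MotifSite
from kinmeth.records import FORWARD, REVERSE
from kinmeth.scoring import (
    ControlLookup,
    agg_scores,
    approx_smsn_scores,
    build_control,
    smp_scores,
    smsn_scores,
)

from conftest import obs_frame


def _control_from(rows):
    return build_control(obs_frame(rows, sample_type="wga"))


def _site(pos, strand=FORWARD):
    return MotifSite(pos, strand, "GATC")


class TestBuildControl:
    def test_mean_and_count(self):
        ctrl = _control_from([("w1", FORWARD, 5, 0.2), ("w2", FORWARD, 5, 0.4)])
        assert ctrl.lookup(FORWARD, 5) == (pytest.approx(0.3), 2)

    def test_uncovered_key_absent(self):
        ctrl = _control_from([("w1", FORWARD, 5, 0.2)])
        assert (FORWARD, 6) not in ctrl
        with pytest.raises(KeyError):
            ctrl.lookup(FORWARD, 6)

    def test_native_input_rejected(self):
        with pytest.raises(ValueError, match="native"):
            build_control(obs_frame([("m", 0, 1, 0.0)], sample_type="native"))

    def test_matches_group_by_oracle(self, rng):
        rows = [
            (f"w{rng.integers(20)}", int(rng.integers(2)), int(rng.integers(30)),
             float(rng.normal()))
            for _ in range(1000)
        ]
        ctrl = _control_from(rows)
        expected = {}
        for _, strand, pos, v in rows:
            expected.setdefault((strand, pos), []).append(v)
        assert len(ctrl) == len(expected)
        for (strand, pos), vals in expected.items():
            mean, n = ctrl.lookup(strand, pos)
            assert mean == pytest.approx(np.mean(vals), abs=1e-12)
            assert n == len(vals)


class TestSmsn:
    def test_hand_arithmetic(self):
        obs = obs_frame(
            [("m1", FORWARD, 7, 1.0), ("m1", FORWARD, 7, 1.2), ("m1", FORWARD, 7, 0.8)]
        )
        ctrl = _control_from([("w", FORWARD, 7, 0.5)])
        scores, report = smsn_scores(obs, ctrl, [_site(7)], min_cov=3)
        (s,) = scores
        assert (s.cov_sm, s.score) == (3, pytest.approx(0.5))
        assert report == {"no_control": 0, "low_coverage": 0, "scored": 1}

    def test_native_equal_to_control_scores_zero(self):
        obs = obs_frame([("m1", FORWARD, 7, 0.5), ("m1", FORWARD, 7, 0.5)])
        ctrl = _control_from([("w", FORWARD, 7, 0.5)])
        scores, _ = smsn_scores(obs, ctrl, [_site(7)], min_cov=1)
        assert scores[0].score == pytest.approx(0.0)

    def test_skip_accounting(self):
        obs = obs_frame(
            [("m1", FORWARD, 7, 1.0), ("m1", FORWARD, 8, 1.0), ("m1", FORWARD, 8, 1.1)]
        )
        ctrl = _control_from([("w", FORWARD, 8, 0.0)])
        scores, report = smsn_scores(obs, ctrl, [_site(7), _site(8)], min_cov=2)
        assert len(scores) == 1
        assert report["no_control"] == 1  # site 7
        assert report["low_coverage"] == 0

    def test_approx_reduces_to_zero_control(self):
        rows = [("m1", FORWARD, 7, 1.0), ("m1", FORWARD, 7, 1.4), ("m2", FORWARD, 7, 0.2)]
        obs = obs_frame(rows)
        zero_ctrl = _control_from([("w", FORWARD, 7, 0.0), ("w2", FORWARD, 7, 0.0)])
        exact, _ = smsn_scores(obs, zero_ctrl, [_site(7)], min_cov=1)
        approx, _ = approx_smsn_scores(obs, [_site(7)], min_cov=1)
        assert [(a.molecule_id, a.score) for a in approx] == [
            (e.molecule_id, pytest.approx(e.score)) for e in exact
        ]
        assert all(a.approximate for a in approx)

    def test_empty_sites_empty_output(self):
        obs = obs_frame([("m1", FORWARD, 7, 1.0)])
        scores, _ = approx_smsn_scores(obs, [], min_cov=1)
        assert scores == []


class TestAgg:
    def test_single_molecule_equals_smsn(self):
        obs = obs_frame([("m1", FORWARD, 3, 0.9), ("m1", FORWARD, 3, 1.1)])
        ctrl = _control_from([("w", FORWARD, 3, 0.25)])
        (agg,), _ = agg_scores(obs, ctrl, [_site(3)])
        (sm,), _ = smsn_scores(obs, ctrl, [_site(3)], min_cov=1)
        assert agg.score == pytest.approx(sm.score)
        assert (agg.native_n, agg.wga_n) == (2, 1)

    def test_weighted_mean_oracle(self):
        # molecule means m1=1.0 (2 obs), m2=2.5 (3 obs); control 0.5
        obs = obs_frame(
            [("m1", FORWARD, 3, 0.8), ("m1", FORWARD, 3, 1.2)]
            + [("m2", FORWARD, 3, v) for v in (2.0, 2.5, 3.0)]
        )
        ctrl = _control_from([("w", FORWARD, 3, 0.5)])
        (agg,), _ = agg_scores(obs, ctrl, [_site(3)])
        expected = (2 * 1.0 + 3 * 2.5) / 5 - 0.5
        assert agg.score == pytest.approx(expected, abs=1e-12)

    def test_equals_covsm_weighted_smsn(self, rng):
        rows = []
        for m in range(6):
            for pos in (3, 9):
                for _ in range(int(rng.integers(1, 6))):
                    rows.append((f"m{m}", FORWARD, pos, float(rng.normal())))
        obs = obs_frame(rows)
        ctrl = _control_from(
            [("w", FORWARD, 3, 0.1), ("w", FORWARD, 9, -0.2), ("w2", FORWARD, 9, 0.0)]
        )
        sites = [_site(3), _site(9)]
        aggs, _ = agg_scores(obs, ctrl, sites)
        smsns, _ = smsn_scores(obs, ctrl, sites, min_cov=1)
        for a in aggs:
            group = [s for s in smsns if (s.strand, s.ref_pos) == (a.strand, a.ref_pos)]
            weighted = sum(s.cov_sm * s.score for s in group) / sum(
                s.cov_sm for s in group
            )
            assert a.score == pytest.approx(weighted, abs=1e-9)

    def test_pooled_mean_equal_to_control_is_zero(self):
        obs = obs_frame([("m1", FORWARD, 3, 0.4), ("m2", FORWARD, 3, 0.6)])
        ctrl = _control_from([("w", FORWARD, 3, 0.5)])
        (agg,), _ = agg_scores(obs, ctrl, [_site(3)])
        assert agg.score == pytest.approx(0.0)


class TestSmp:
    def test_hand_arithmetic(self):
        obs = obs_frame(
            [("m1", FORWARD, 3, 1.8), ("m1", FORWARD, 3, 2.0), ("m1", FORWARD, 9, 1.9)]
        )
        ctrl = _control_from(
            [("w", FORWARD, 3, 0.1), ("w", FORWARD, 9, -0.1)]
        )
        (s,), report = smp_scores(obs, ctrl, [_site(3), _site(9)], min_sites=2)
        # native pooled mean = 1.9; control per-site means {0.1, -0.1} -> 0.0
        assert s.score == pytest.approx(1.9)
        assert s.n_sites == 2
        assert report["scored"] == 1

    def test_min_sites_threshold(self):
        obs = obs_frame([("m1", FORWARD, 3, 1.0)])
        ctrl = _control_from([("w", FORWARD, 3, 0.0)])
        scores, report = smp_scores(obs, ctrl, [_site(3)], min_sites=2)
        assert scores == []
        assert report["below_min_sites"] == 1

    def test_sites_without_control_excluded_from_both_sides(self):
        obs = obs_frame(
            [("m1", FORWARD, 3, 1.0), ("m1", FORWARD, 9, 100.0)]  # 9 lacks control
        )
        ctrl = _control_from([("w", FORWARD, 3, 0.25)])
        (s,), report = smp_scores(obs, ctrl, [_site(3), _site(9)], min_sites=1)
        assert s.score == pytest.approx(0.75)
        assert s.n_sites == 1
        assert report["site_slots_no_control"] == 1

    def test_single_site_reduces_to_smsn(self):
        obs = obs_frame([("m1", FORWARD, 3, 1.1), ("m1", FORWARD, 3, 0.9)])
        ctrl = _control_from([("w", FORWARD, 3, 0.3)])
        (smp,), _ = smp_scores(obs, ctrl, [_site(3)], min_sites=1)
        (smsn,), _ = smsn_scores(obs, ctrl, [_site(3)], min_cov=1)
        assert smp.score == pytest.approx(smsn.score, abs=1e-12)

    def test_strands_scored_separately(self):
        obs = obs_frame(
            [("m1", FORWARD, 3, 1.0), ("m1", REVERSE, 3, -1.0)]
        )
        ctrl = _control_from([("w", FORWARD, 3, 0.0), ("w", REVERSE, 3, 0.0)])
        scores, _ = smp_scores(
            obs, ctrl, [_site(3, FORWARD), _site(3, REVERSE)], min_sites=1
        )
        assert {(s.strand, round(s.score, 9)) for s in scores} == {
            (FORWARD, 1.0),
            (REVERSE, -1.0),
        }


def test_three_molecule_fixture_brute_force_equivalence(rng):
    """All three statistics recomputed by plain loops agree to 1e-9."""
    sites = [_site(3), _site(9), _site(4, REVERSE)]
    site_keys = {(s.strand, s.ref_pos) for s in sites}
    rows = []
    for m in ("a", "b", "c"):
        for strand, pos in [(FORWARD, 3), (FORWARD, 9), (REVERSE, 4), (FORWARD, 99)]:
            for _ in range(int(rng.integers(2, 6))):
                rows.append((m, strand, pos, float(rng.normal(1.0, 0.5))))
    obs = obs_frame(rows)
    wga_rows = [
        (f"w{i}", strand, pos, float(rng.normal(0.0, 0.3)))
        for strand, pos in site_keys
        for i in range(4)
    ]
    ctrl = build_control(obs_frame(wga_rows, sample_type="wga"))

    by_msp: dict = {}
    for m, strand, pos, v in rows:
        if (strand, pos) in site_keys:
            by_msp.setdefault((m, strand, pos), []).append(v)
    ctrl_mean = {}
    for w, strand, pos, v in wga_rows:
        ctrl_mean.setdefault((strand, pos), []).append(v)
    ctrl_mean = {k: np.mean(v) for k, v in ctrl_mean.items()}

    smsns, _ = smsn_scores(obs, ctrl, sites, min_cov=1)
    assert len(smsns) == len(by_msp)
    for s in smsns:
        vals = by_msp[(s.molecule_id, s.strand, s.ref_pos)]
        assert s.cov_sm == len(vals)
        assert s.score == pytest.approx(
            np.mean(vals) - ctrl_mean[(s.strand, s.ref_pos)], abs=1e-9
        )

    aggs, _ = agg_scores(obs, ctrl, sites)
    by_sp: dict = {}
    for (m, strand, pos), vals in by_msp.items():
        by_sp.setdefault((strand, pos), []).extend(vals)
    assert len(aggs) == len(by_sp)
    for a in aggs:
        vals = by_sp[(a.strand, a.ref_pos)]
        assert a.score == pytest.approx(
            np.mean(vals) - ctrl_mean[(a.strand, a.ref_pos)], abs=1e-9
        )

    smps, _ = smp_scores(obs, ctrl, sites, min_sites=1)
    by_ms: dict = {}
    for (m, strand, pos), vals in by_msp.items():
        by_ms.setdefault((m, strand), {})[pos] = vals
    assert len(smps) == len(by_ms)
    for s in smps:
        per_site = by_ms[(s.molecule_id, s.strand)]
        pooled = [v for vals in per_site.values() for v in vals]
        ctl = np.mean([ctrl_mean[(s.strand, p)] for p in per_site])
        assert s.n_sites == len(per_site)
        assert s.score == pytest.approx(np.mean(pooled) - ctl, abs=1e-9)
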