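"""Paired-run screening: confirmation logic, controls, scoring, reporting."""

import math

import numpy as np
import pytest

import oxypair as ox
from oxypair.constants import O18_O16_DELTA
from oxypair.pair_finder import (
    CANDIDATE_ONLY,
    CONFIRMED,
    LABEL_UNCONFIRMABLE,
    PairHit,
    control_filter,
    report,
    score_pair,
)
from .conftest import compact_scenario, compact_sim_config


@pytest.fixture(scope="module")
def screened(paired_runs, bupivacaine):
    air, o18, controls, planted = paired_runs
    hits = ox.screen(air, o18, controls, bupivacaine)
    return hits, planted


def test_all_oxygen_inserting_plants_confirmed(screened):
    hits, planted = screened
    confirmed = {h.candidate.class_label for h in hits if h.status == CONFIRMED}
    expected = {p.candidate.class_label for p in planted if p.candidate.z >= 1}
    assert confirmed == expected


def test_dealkylated_plant_is_label_unconfirmable(screened):
    hits, _ = screened
    da = [h for h in hits if h.candidate.class_label == "DA"]
    assert da and all(h.status == LABEL_UNCONFIRMABLE for h in da)
    # a Z=0 candidate can never be confirmed, by construction
    assert not any(
        h.status == CONFIRMED for h in hits if h.candidate.z == 0
    )


def test_labeling_degree_recovered(screened):
    hits, planted = screened
    truth = {p.candidate.class_label: p.q for p in planted}
    for h in hits:
        if h.status == CONFIRMED:
            assert h.labeling.q_hat == pytest.approx(
                truth[h.candidate.class_label], abs=0.02
            )


def test_confirmed_deltas_match_label_shift(screened):
    hits, _ = screened
    for h in hits:
        if h.status == CONFIRMED:
            expected = h.candidate.z * O18_O16_DELTA
            tol = 2 * 5e-6 * h.candidate.theoretical_mz
            assert abs(h.observed_delta - expected) <= tol
            assert abs(h.rt_offset) <= 0.1


def test_confirmed_hits_score_high(screened):
    hits, _ = screened
    for h in hits:
        if h.status == CONFIRMED:
            assert 0.8 < h.score <= 1.0


def test_no_false_confirmation_on_identical_runs(bupivacaine, candidates):
    """Screening a run against itself must never confirm anything:
    the shifted channel is either absent or fails the q gate."""
    for seed in range(20):
        planted = compact_scenario(candidates)
        air, _, controls = ox.make_paired_runs(
            bupivacaine, planted, compact_sim_config(seed=100 + seed)
        )
        hits = ox.screen(air, air, controls, bupivacaine)
        assert not any(h.status == CONFIRMED for h in hits), f"seed {seed}"


def test_parent_is_not_reported(screened, bupivacaine):
    hits, _ = screened
    assert all(h.candidate.formula != bupivacaine for h in hits)


def test_polarity_mismatch_rejected(paired_runs, bupivacaine):
    air, o18, controls, _ = paired_runs
    negative = ox.Run(scans=o18.scans, polarity="negative")
    with pytest.raises(ValueError, match="polarity"):
        ox.screen(air, negative, controls, bupivacaine)


def test_control_veto_suppresses_hit(bupivacaine, candidates):
    """A 'control' identical to the air run kills every feature."""
    planted = compact_scenario(candidates)
    air, o18, _ = ox.make_paired_runs(
        bupivacaine, planted, compact_sim_config(seed=5)
    )
    hits = ox.screen(air, o18, [air], bupivacaine)
    assert not any(h.status in (CONFIRMED, LABEL_UNCONFIRMABLE) for h in hits)


# -- control_filter ---------------------------------------------------------


def _feature(area, rt=1.0):
    return ox.Feature(mz=305.2224, rt_apex=rt, area=area, fwhm=0.05,
                      max_intensity=area)


def _run_with_feature(mz, rt, area, span=(0.0, 2.0)):
    rts = np.arange(span[0] + 0.01, span[1], 0.01)
    sigma = 0.05 / 2.3548
    heights = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((rts - rt) / sigma) ** 2
    )
    scans = [
        ox.Scan(rt=float(t), mz=np.array([mz]), intensity=np.array([h]))
        if h > 1e-6 else ox.Scan(rt=float(t), mz=np.empty(0), intensity=np.empty(0))
        for t, h in zip(rts, heights)
    ]
    return ox.Run(scans=scans)


def test_control_filter_passes_small_control_signal():
    cfg = ox.ScreenConfig()
    ctrl = _run_with_feature(305.2224, 1.0, 10.0)
    ok, worst = control_filter(_feature(1000.0), 305.2224, [ctrl], cfg)
    assert ok and worst == pytest.approx(10.0, rel=0.05)


def test_control_filter_fails_on_comparable_control_signal():
    cfg = ox.ScreenConfig()
    ctrl = _run_with_feature(305.2224, 1.0, 900.0)
    ok, worst = control_filter(_feature(1000.0), 305.2224, [ctrl], cfg)
    assert not ok and worst == pytest.approx(900.0, rel=0.05)


def test_control_filter_without_controls_passes():
    ok, worst = control_filter(_feature(1000.0), 305.2224, [], ox.ScreenConfig())
    assert ok and worst == 0.0


# -- score_pair -------------------------------------------------------------


def _hit(candidates, ppm=0.0, rt_offset=0.0, q=0.35):
    cand = candidates["H"]
    shifted = cand.theoretical_mz + O18_O16_DELTA
    f16 = ox.Feature(mz=cand.theoretical_mz, rt_apex=5.0, area=1000.0,
                     fwhm=0.05, max_intensity=100.0)
    f18 = ox.Feature(mz=shifted * (1 + ppm * 1e-6), rt_apex=5.0 + rt_offset,
                     area=500.0, fwhm=0.05, max_intensity=50.0)
    labeling = ox.LabelingEstimate(q_hat=q, ci_low=q, ci_high=q,
                                   areas_used=(1000.0, 500.0))
    return PairHit(candidate=cand, feature_16=f16, feature_18=f18,
                   observed_delta=f18.mz - f16.mz, rt_offset=rt_offset,
                   labeling=labeling)


def test_perfect_pair_scores_one(candidates):
    assert score_pair(_hit(candidates), ox.ScreenConfig()) == pytest.approx(1.0)


def test_score_at_mass_tolerance_is_inverse_e(candidates):
    cfg = ox.ScreenConfig()
    s = score_pair(_hit(candidates, ppm=cfg.mz_tol_ppm), cfg)
    assert s == pytest.approx(math.exp(-1), rel=1e-6)


def test_low_labeling_penalized_monotonically(candidates):
    cfg = ox.ScreenConfig()
    assert score_pair(_hit(candidates, q=0.02), cfg) < score_pair(
        _hit(candidates, q=0.3), cfg
    )


def test_score_requires_both_channels(candidates):
    h = _hit(candidates)
    h.feature_18 = None
    with pytest.raises(ValueError):
        score_pair(h, ox.ScreenConfig())


# -- report -----------------------------------------------------------------


def test_report_joins_isomer_retention_times(candidates):
    hits = [_hit(candidates) for _ in range(3)]
    for h, rt in zip(hits, (5.08, 7.51, 7.92)):
        h.feature_16.rt_apex = rt
        h.status = CONFIRMED
    df, detail = report(hits)
    assert len(df) == 1
    assert df.iloc[0]["rt_list"] == "5.08; 7.51; 7.92"
    assert df.iloc[0]["n_isomers"] == 3


def test_report_empty_is_header_only():
    df, detail = report([])
    assert len(df) == 0
    assert "class" in df.columns and "rt_list" in df.columns
    assert detail == {}


def test_report_details_statuses_per_hit(candidates):
    h1, h2 = _hit(candidates), _hit(candidates)
    h1.status = CONFIRMED
    h2.status = CANDIDATE_ONLY
    h2.feature_16.rt_apex = 6.0
    df, detail = report([h1, h2])
    (key,) = detail
    statuses = {d["status"] for d in detail[key]}
    assert statuses == {CONFIRMED, CANDIDATE_ONLY}
    assert "|" in df.iloc[0]["status"]


# -- config -----------------------------------------------------------------


def test_config_file_round_trip(tmp_path):
    cfg = ox.ScreenConfig(mz_tol_ppm=3.0, q_min=0.2, max_steps=2)
    path = tmp_path / "screen.cfg"
    cfg.to_file(path)
    back = ox.ScreenConfig.from_file(path)
    assert back == cfg


def test_config_rejects_unknown_key(tmp_path):
    path = tmp_path / "bad.cfg"
    path.write_text("mz_tol_ppm = 5\nwarp_factor = 9\n")
    with pytest.raises(ValueError, match="warp_factor"):
        ox.ScreenConfig.from_file(path)


@pytest.mark.parametrize(
    "kwargs", [dict(mz_tol_ppm=-1), dict(q_min=1.5), dict(polarity="both")]
)
def test_config_validates_fields(kwargs):
    with pytest.raises(ValueError):
        ox.ScreenConfig(**kwargs)
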