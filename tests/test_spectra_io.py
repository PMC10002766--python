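"""mzML round trips, XIC extraction and chromatographic peak picking."""

import numpy as np
import pytest

import oxypair as ox
from oxypair.spectra_io import ProfileModeError, detect_features, write_peaklist

# -- run I/O ----------------------------------------------------------------


def _small_run(n_scans=6):
    scans = [
        ox.Scan(
            rt=0.1 * (i + 1),
            mz=np.array([150.0, 305.2224, 500.5]),
            intensity=np.array([10.0, 100.0 + i, 5.0]),
        )
        for i in range(n_scans)
    ]
    return ox.Run(scans=scans, provenance="air")


def test_mzml_round_trip(tmp_path):
    run = _small_run(3)
    path = tmp_path / "run.mzML"
    ox.write_mzml(run, path)
    back = ox.read_run(path, provenance="air")
    assert len(back.scans) == 3
    for a, b in zip(run.scans, back.scans):
        assert b.rt == pytest.approx(a.rt, abs=1e-6)
        np.testing.assert_allclose(b.mz, a.mz, atol=1e-6)
        np.testing.assert_allclose(b.intensity, a.intensity, atol=1e-6)


def test_ms2_scans_routed_to_msms(tmp_path):
    run = _small_run(3)
    run.msms.append(
        ox.MsmsSpectrum(
            precursor_mz=305.2224,
            rt=0.25,
            mz=np.array([84.0808, 156.1383]),
            intensity=np.array([100.0, 80.0]),
        )
    )
    path = tmp_path / "run.mzML"
    ox.write_mzml(run, path)
    back = ox.read_run(path)
    assert len(back.scans) == 3
    assert len(back.msms) == 1
    assert back.msms[0].precursor_mz == pytest.approx(305.2224, abs=1e-4)
    np.testing.assert_allclose(back.msms[0].mz, [84.0808, 156.1383], atol=1e-6)


def test_truncated_file_reports_parse_position(tmp_path):
    run = _small_run(3)
    path = tmp_path / "run.mzML"
    ox.write_mzml(run, path)
    text = path.read_text()
    trunc = tmp_path / "trunc.mzML"
    trunc.write_text(text[: len(text) // 2])
    with pytest.raises(ValueError, match="line"):
        ox.read_run(trunc)


def test_profile_mode_rejected(tmp_path):
    # hand-built minimal mzML carrying the profile-spectrum cvParam
    content = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="0">
   <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
   <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
   <scanList count="1"><scan>
    <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="0.5"
             unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
   </scan></scanList>
   <binaryDataArrayList count="2">
    <binaryDataArray encodedLength="0">
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>
     <binary></binary>
    </binaryDataArray>
    <binaryDataArray encodedLength="0">
     <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
     <binary></binary>
    </binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run>
</mzML>"""
    path = tmp_path / "profile.mzML"
    path.write_text(content)
    with pytest.raises(ProfileModeError):
        ox.read_run(path)


def test_refuse_to_write_empty_run(tmp_path):
    with pytest.raises(ValueError):
        ox.write_mzml(ox.Run(scans=[]), tmp_path / "empty.mzML")


def test_rt_must_increase():
    scans = [
        ox.Scan(rt=0.2, mz=np.array([100.0]), intensity=np.array([1.0])),
        ox.Scan(rt=0.1, mz=np.array([100.0]), intensity=np.array([1.0])),
    ]
    with pytest.raises(ValueError):
        ox.Run(scans=scans)


def test_peaklist_round_trip(tmp_path):
    spec = ox.MsmsSpectrum(
        precursor_mz=305.2224, rt=7.51,
        mz=np.array([84.0808, 156.1383]), intensity=np.array([100.0, 80.0]),
    )
    path = tmp_path / "spec.txt"
    write_peaklist(spec, path)
    back = ox.read_peaklist(path)
    assert back.precursor_mz == pytest.approx(305.2224, abs=1e-4)
    assert back.rt == pytest.approx(7.51, abs=1e-4)
    np.testing.assert_allclose(back.mz, spec.mz, atol=1e-6)


# -- XIC --------------------------------------------------------------------


def _run_with_centroids(centroids_per_scan):
    scans = []
    for i, cents in enumerate(centroids_per_scan):
        mz = np.array([c[0] for c in cents])
        inten = np.array([c[1] for c in cents])
        scans.append(ox.Scan(rt=0.1 * (i + 1), mz=mz, intensity=inten))
    return ox.Run(scans=scans)


def test_xic_exact_match():
    run = _run_with_centroids([[(300.0, 111.0)], [], [(300.0, 222.0)]])
    rts, trace = ox.xic(run, 300.0, tol_ppm=5)
    np.testing.assert_allclose(trace, [111.0, 0.0, 222.0])


def test_xic_outside_tolerance_is_zero():
    off = 300.0 * (1 + 10e-6)  # 10 ppm away
    run = _run_with_centroids([[(off, 100.0)]] * 3)
    _, trace = ox.xic(run, 300.0, tol_ppm=5)
    assert np.all(trace == 0.0)


def test_xic_sums_coeluting_centroids():
    a, b = 300.0, 300.0 * (1 + 3e-6)  # 3 ppm apart
    run = _run_with_centroids([[(a, 100.0), (b, 50.0)]] * 3)
    _, trace = ox.xic(run, 300.0, tol_ppm=5)
    np.testing.assert_allclose(trace, [150.0] * 3)


def test_xic_widening_tolerance_is_monotone():
    rng = np.random.default_rng(3)
    scans = [
        [(float(m), float(i)) for m, i in zip(
            rng.uniform(299.99, 300.01, 10), rng.uniform(1, 100, 10))]
        for _ in range(8)
    ]
    run = _run_with_centroids(scans)
    _, narrow = ox.xic(run, 300.0, tol_ppm=5)
    _, wide = ox.xic(run, 300.0, tol_ppm=20)
    assert np.all(wide >= narrow)


# -- feature detection ------------------------------------------------------


def _gaussian_trace(rts, apex, fwhm, area):
    sigma = fwhm / 2.3548200450309493
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((rts - apex) / sigma) ** 2
    )


def test_single_gaussian_area_and_apex():
    rts = np.arange(0, 2, 0.005)
    trace = _gaussian_trace(rts, 1.0, 0.1, 1000.0)
    feats = detect_features(rts, trace)
    assert len(feats) == 1
    f = feats[0]
    assert f.area == pytest.approx(1000.0, rel=0.01)
    assert abs(f.rt_apex - 1.0) < 0.005 / 2
    assert f.fwhm == pytest.approx(0.1, rel=0.05)


def test_flat_trace_yields_nothing():
    rts = np.arange(0, 1, 0.01)
    assert detect_features(rts, np.zeros_like(rts)) == []


def test_two_separated_gaussians():
    rts = np.arange(0, 3, 0.005)
    trace = _gaussian_trace(rts, 1.0, 0.1, 500.0) + _gaussian_trace(
        rts, 1.5, 0.1, 800.0
    )
    feats = detect_features(rts, trace)
    assert len(feats) == 2
    assert feats[0].rt_apex < feats[1].rt_apex
    assert feats[0].rt_apex == pytest.approx(1.0, abs=0.01)
    assert feats[1].rt_apex == pytest.approx(1.5, abs=0.01)


def test_area_scales_linearly():
    rts = np.arange(0, 2, 0.005)
    trace = _gaussian_trace(rts, 1.0, 0.1, 1000.0)
    a1 = detect_features(rts, trace)[0].area
    a2 = detect_features(rts, 7.0 * trace)[0].area
    assert a2 == pytest.approx(7.0 * a1, rel=1e-6)


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        detect_features(np.array([0.0, 0.1]), np.array([0.0, 1.0]))


def test_detection_on_noise_no_false_positives_and_full_recovery():
    """At the default threshold: planted peaks at >= 10x noise sigma are
    always found; pure-noise traces never produce a feature (50 seeds)."""
    rts = np.arange(0, 15, 0.005)
    recovered = 0
    false_positives = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        noise = np.clip(rng.normal(100, 5, rts.size), 0, None)
        false_positives += len(detect_features(rts, noise))
        # amplitude exactly 10x the noise sigma, fwhm 0.08 min
        planted = noise + 50.0 * np.exp(-0.5 * ((rts - 7.5) / (0.08 / 2.3548)) ** 2)
        feats = detect_features(rts, planted)
        recovered += any(abs(f.rt_apex - 7.5) < 0.05 for f in feats)
    assert false_positives == 0
    assert recovered == 50


def test_extract_features_fills_weighted_mz(paired_runs):
    air, _, _, planted = paired_runs
    h = next(p for p in planted if p.candidate.class_label == "H")
    feats = ox.extract_features(air, h.candidate.theoretical_mz, 5, 3)
    match = [f for f in feats if abs(f.rt_apex - h.rt_apex) < 0.05]
    assert len(match) == 1
    assert abs(ox.ppm_diff(match[0].mz, h.candidate.theoretical_mz)) < 2
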