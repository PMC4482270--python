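import numpy as np
import pytest

from eegbm.preprocess import preprocess_recording
from eegbm.spectral import loglog_slope, mean_spectrum, peak_alpha_ratio
from eegbm.synthetic import (
    DIFFERENTIAL_EDGES,
    ZERO_LAG_EDGES,
    CohortConfig,
    SubjectParams,
    generate_cohort,
    generate_subject,
)


def test_generation_is_deterministic():
    p = SubjectParams(seed=42, duration=20.0)
    a = generate_subject(p)
    b = generate_subject(p)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_invalid_fs_names_field():
    with pytest.raises(ValueError, match="fs"):
        generate_subject(SubjectParams(fs=123.0))


def test_invalid_alpha_band_names_field():
    with pytest.raises(ValueError, match="alpha_band"):
        generate_subject(SubjectParams(alpha_band=(8.0, 55.0)))


def test_negative_gain_rejected():
    with pytest.raises(ValueError, match="coupled_edges"):
        generate_subject(SubjectParams(
            coupled_edges=[(("F7-T3", "F4-C4"), 50.0, -1.0)]))


def test_overlapping_artifacts_rejected():
    with pytest.raises(ValueError, match="artifact_intervals"):
        generate_subject(SubjectParams(
            duration=20.0, artifact_intervals=[(1.0, 5.0), (4.0, 6.0)]))


def test_artifact_intervals_annotated_and_loud():
    p = SubjectParams(seed=3, duration=30.0, artifact_intervals=[(10.0, 12.0)])
    rec = generate_subject(p)
    assert rec.artifact_annotations == [(10.0, 12.0)]
    clean_rms = np.sqrt((rec.samples[:int(9 * 200)] ** 2).mean())
    artifact_rms = np.sqrt((rec.samples[int(10.2 * 200):int(11.8 * 200)] ** 2).mean())
    assert artifact_rms > 3 * clean_rms


def test_background_slope_recovered():
    # background-only subject: fitted log-log slope within +/-0.3 of target
    p = SubjectParams(seed=7, duration=120.0, posterior_alpha_amp=0.0,
                      anterior_alpha_amp=0.0, background_slope=-2.0)
    rec = generate_subject(p)
    spec = mean_spectrum(preprocess_recording(rec, "spectral"))
    for deriv in ("Fp1-F7", "C3-P3", "T6-O2"):
        assert loglog_slope(spec, deriv) == pytest.approx(-2.0, abs=0.3)


def test_flat_gradient_gives_unit_alpha_ratio():
    p = SubjectParams(seed=11, duration=120.0, posterior_alpha_amp=30.0,
                      anterior_alpha_amp=30.0)
    rec = generate_subject(p)
    ratio = peak_alpha_ratio(mean_spectrum(preprocess_recording(rec, "spectral")))
    assert ratio == pytest.approx(1.0, abs=0.25)


def test_planted_gradient_recovered_for_strong_alpha():
    # in-band alpha >= 5x background on every ratio derivation; a long
    # record keeps the max-over-band statistic's upward noise bias small
    p = SubjectParams(seed=13, duration=600.0, posterior_alpha_amp=60.0,
                      anterior_alpha_amp=30.0, background_amp=10.0)
    rec = generate_subject(p)
    measured = peak_alpha_ratio(mean_spectrum(preprocess_recording(rec, "spectral")))
    assert measured == pytest.approx(p.planted_alpha_ratio(), rel=0.20)


def test_strong_planted_edge_detected_in_most_epochs():
    from eegbm import connectivity as conn
    from eegbm import networks as net
    from eegbm.channels import PAIR_INDEX

    from eegbm.synthetic import STRONG_EDGE_GAIN

    pair = ("F7-T3", "F4-C4")
    p = SubjectParams(seed=5, duration=120.0, posterior_alpha_amp=30.0,
                      anterior_alpha_amp=3.0,
                      coupled_edges=[(pair, 50.0, STRONG_EDGE_GAIN)])
    rec = generate_subject(p)
    es = preprocess_recording(rec, "network")
    sc = conn.subject_connectivity(es.epochs, es.fs)
    nets = [net.network_from_stats(*sc.edge_stats(e), sc.model)
            for e in range(es.n_epochs)]
    k = PAIR_INDEX[frozenset(pair)]
    detected = np.mean([nw.adjacency[k] for nw in nets])
    assert detected > 0.9
    # unplanted pairs stay near the FDR floor
    others = np.ones(153, bool)
    others[k] = False
    false_rate = np.mean([nw.adjacency[others].mean() for nw in nets])
    assert false_rate < 0.01


def test_zero_lag_source_is_excluded_not_detected():
    from eegbm import connectivity as conn
    from eegbm import networks as net
    from eegbm.channels import PAIR_INDEX

    pair = ZERO_LAG_EDGES[0]
    p = SubjectParams(seed=6, duration=120.0,
                      zero_lag_edges=[(pair, 90.0)])
    rec = generate_subject(p)
    es = preprocess_recording(rec, "network")
    sc = conn.subject_connectivity(es.epochs, es.fs)
    nets = [net.network_from_stats(*sc.edge_stats(e), sc.model)
            for e in range(es.n_epochs)]
    k = PAIR_INDEX[frozenset(pair)]
    excluded = np.mean([nw.zero_lag_excluded[k] for nw in nets])
    present = np.mean([nw.adjacency[k] for nw in nets])
    assert excluded > 0.9
    assert present < 0.05


def test_cohort_sizes_and_split_tags():
    cfg = CohortConfig(duration=20.0, n_artifacts=0, seed=0)
    recordings, truth = generate_cohort(cfg)
    training = [r for r in recordings if r.split == "training"]
    validation = [r for r in recordings if r.split == "validation"]
    assert len(training) == 37   # 13 ASD + 24 control
    assert len(validation) == 45
    assert sum(r.group_label == "ASD" for r in training) == 13
    asp = [r for r in recordings if r.subtype == "aspergers"]
    assert len(asp) == 5
    assert all(r.group_label == "ASD" for r in asp)
    assert len(truth.subjects) == 82


def test_cohort_determinism():
    cfg = CohortConfig(n_training=(2, 2), n_validation=(2, 2),
                       n_aspergers=(0, 0), duration=10.0, n_artifacts=0, seed=9)
    rec_a, truth_a = generate_cohort(cfg)
    rec_b, truth_b = generate_cohort(cfg)
    for a, b in zip(rec_a, rec_b):
        np.testing.assert_array_equal(a.samples, b.samples)
    assert truth_a.group_alpha_ratio == truth_b.group_alpha_ratio


def test_zero_group_size_rejected():
    with pytest.raises(ValueError, match="positive"):
        generate_cohort(CohortConfig(n_training=(0, 5)))


def test_truth_records_planted_effects():
    cfg = CohortConfig(n_training=(2, 2), n_validation=(2, 2),
                       n_aspergers=(0, 0), duration=10.0, n_artifacts=0, seed=4)
    _, truth = generate_cohort(cfg)
    assert truth.group_alpha_ratio["control"] > truth.group_alpha_ratio["ASD"]
    for pair in DIFFERENTIAL_EDGES:
        name = f"{pair[0]}/{pair[1]}"
        assert truth.group_edge_gains["control"][name] > \
            truth.group_edge_gains["ASD"][name]
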