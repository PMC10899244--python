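import numpy as np
import pytest

from thetasort import detect, dsp, phase, synth


@pytest.fixture(scope="session")
def two_unit_recording():
    """120 s two-channel recording with two phase-locked units on ch1.

    Amplitudes 100/60 µV on 15 µV noise, 5 spikes/s each, preferred theta
    phases 330° and 45°, and a 15 ms theta propagation delay to ch2 —
    shared across the end-to-end recovery tests because the simulation
    and filtering dominate their cost.
    """
    units = {
        "u1": synth.UnitSpec("ch1", base_rate=5.0, amplitude=100.0,
                             preferred_phase=330.0, kappa=4.0),
        "u2": synth.UnitSpec("ch1", base_rate=5.0, amplitude=60.0,
                             trough_width_ms=0.5, repol_width_ms=1.0,
                             preferred_phase=45.0, kappa=4.0),
    }
    lfp = synth.LfpSpec(theta_freq=6.0, theta_amp=150.0,
                        delays={"ch2": 0.015}, pink_rms=10.0)
    rec, gt = synth.simulate_recording(
        ["ch1", "ch2"], units, lfp, None, duration=120.0,
        noise_rms=15.0, rate=24414.0, seed=0,
    )
    return rec, gt


@pytest.fixture(scope="session")
def two_unit_sorted(two_unit_recording):
    """Detected, snipped, PCA'd and k-means-sorted view of the shared recording."""
    rec, gt = two_unit_recording
    filt = dsp.bandpass(rec, dsp.SPIKE_BAND)
    train = detect.detect_spikes(filt.channel("ch1"), rec.rate)
    snippets, _ = detect.extract_snippets(
        filt.channel("ch1"), train.spike_times, rec.rate
    )
    feats = detect.pca_features(snippets)
    labels = detect.kmeans_cluster(feats, k=2, seed=0)
    theta = dsp.bandpass(rec, dsp.THETA_BAND)
    return {
        "rec": rec,
        "gt": gt,
        "snippets": snippets,
        "features": feats,
        "labels": labels,
        "theta": theta,
    }


def match_to_ground_truth(
    detected_times: np.ndarray, gt_trains: dict[str, np.ndarray],
    tol: float = 0.0005,
) -> np.ndarray:
    """For each detected spike, the matching ground-truth unit index (or -1)."""
    out = np.full(len(detected_times), -1)
    for j, times in enumerate(gt_trains.values()):
        if len(times) == 0:
            continue
        for i, t in enumerate(detected_times):
            if np.min(np.abs(times - t)) < tol:
                out[i] = j
    return out
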