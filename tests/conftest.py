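import numpy as np
import pytest

from stridekit import (
    PipelineConfig,
    SimConfig,
    match_events,
    run_pipeline,
    simulate_trial,
)


@pytest.fixture(scope="session")
def default_trial():
    """One complete simulated recording with ground truth."""
    return simulate_trial(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_trial):
    imu, emg, _ = default_trial
    return run_pipeline(imu, emg, PipelineConfig())


@pytest.fixture(scope="session")
def repeated_runs():
    """Detection metrics over 100 seeded simulations at default conditions.

    Computed once per session and shared by the half-trial-recovery and
    heel-strike-accuracy tests.
    """
    records = []
    for seed in range(100):
        imu, emg, truth = simulate_trial(SimConfig(seed=seed))
        result = run_pipeline(imu, emg)
        detected = (
            np.sort(np.concatenate([e.times_s for e in result.events]))
            if result.events
            else np.array([])
        )
        report = match_events(detected, truth.all_hs_times_s, tol_s=0.05)
        records.append(
            {
                "n_half_trials": len(result.half_trials),
                "n_bouts_true": len(truth.bout_intervals_s),
                "precision": report.precision,
                "recall": report.recall,
                "mean_abs_error_s": report.mean_abs_error_s,
            }
        )
    return records
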