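import numpy as np
import pandas as pd
import pytest

from bpcluster.synth import default_regimes, generate_population, sample_truth_features


@pytest.fixture(scope="session")
def noise_free_population():
    """Five-regime synthetic population at zero pressure noise, fs=125."""
    return generate_population(default_regimes(n_beats=200, noise_sd_mmHg=0.0),
                               sampling_rate_hz=125.0, seed=7)


@pytest.fixture(scope="session")
def truth_features():
    """Feature-space draw of the default population (no waveform synthesis)."""
    rng = np.random.default_rng(11)
    parts = []
    offset = 0
    for spec in default_regimes():
        t = sample_truth_features(spec, rng)
        t["record_id"] = f"regime{spec.regime_id}"
        parts.append(t)
        offset += len(t)
    return pd.concat(parts, ignore_index=True)


@pytest.fixture
def small_feature_table():
    rng = np.random.default_rng(3)
    n = 12
    sbp = rng.uniform(100, 160, n)
    return pd.DataFrame({
        "record_id": "r0",
        "cycle_index": np.arange(n),
        "ptt_s": rng.uniform(0.1, 0.4, n),
        "pir_ratio": rng.uniform(1.2, 2.5, n),
        "hr_bpm": rng.uniform(60, 110, n),
        "sbp_mmHg": sbp,
        "dbp_mmHg": sbp - rng.uniform(20, 50, n),
    })
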