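import numpy as np
import pandas as pd
import pytest

import raddose as rd

PUB_K = (0.906, 0.274, 0.549)  # published microarray dose-model coefficients
PUB_B = (2.592, -0.785, 0.048)  # published qPCR reduced-model coefficients


@pytest.fixture(scope="session")
def noiseless_array_config() -> rd.ArraySimConfig:
    """Zero-noise array study on conditions where no sample is floored
    (every dose exceeds k3*sqrt(T)), so the dose model holds exactly."""
    return rd.ArraySimConfig(
        noise_sd=0.0,
        baseline_sd=0.0,
        study_effects=(0.0,),
        doses=(2.0, 4.0, 6.0, 8.0, 10.0),
        times=(1.0, 2.0, 4.0),
        samples_per_condition=2,
        k1=PUB_K[0],
        k2=PUB_K[1],
        k3=PUB_K[2],
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_array(noiseless_array_config):
    return rd.generate_array_study(noiseless_array_config)


@pytest.fixture(scope="session")
def noisy_array():
    """Default study conditions (noise, batch offsets, background genes)."""
    return rd.generate_array_study(rd.ArraySimConfig(seed=5))


@pytest.fixture(scope="session")
def noiseless_qpcr_config() -> rd.QpcrSimConfig:
    return rd.QpcrSimConfig(ct_noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def noiseless_qpcr(noiseless_qpcr_config):
    return rd.generate_qpcr_cohort(noiseless_qpcr_config)


@pytest.fixture(scope="session")
def noisy_qpcr():
    return rd.generate_qpcr_cohort(rd.QpcrSimConfig(seed=17))


def qpcr_net_signal(ct_table: pd.DataFrame, config: rd.QpcrSimConfig):
    """Full Ct -> delta-Ct -> N path; returns (NetSignalVector, per-sample metadata)."""
    collapsed = rd.collapse_wells(ct_table)
    dct, _ = rd.delta_ct(collapsed, list(config.reference_genes))
    ns = rd.net_signal_qpcr(dct, config.signature)
    meta = (
        dct[["sample_id", "sex", "dose_gy"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[ns.sample_ids]
    )
    return ns, meta
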