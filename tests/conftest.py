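import numpy as np
import pandas as pd
import pytest

from insideout.containers import EnvelopeEpochs, ResultTable, StudyDesign
from insideout.hierarchy import profile
from insideout.irreversibility import dataset_irrev
from insideout.synthetic import CohortSpec, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_env(rng):
    """Random positive envelope container: 3 epochs, 5 regions, 1 s @ 200 Hz."""
    values = np.abs(rng.standard_normal((3, 5, 200))) + 0.5
    return EnvelopeEpochs(values, fs=200.0, epoch_length_s=1.0)


@pytest.fixture(scope="session")
def mini_cohort():
    """Strong-drug-effect cohort reused across hierarchy/classification tests.

    8 subjects x 2 drug levels x 2 conditions, 6 regions, 10 one-second
    epochs; asymmetry reduced by 80% under the drug level.
    """
    spec = CohortSpec(
        n_subjects=8, n_regions=6, epochs_per_dataset=10, epoch_length_s=1.0,
        drug_effect=0.8, kappa_mean=0.6, kappa_sd=0.1, spectral_radius=0.8,
        seed=777,
    )
    design = StudyDesign(
        tuple(f"s{i:02d}" for i in range(8)), condition_levels=("Open", "Closed")
    )
    datasets, design = make_cohort(spec, design)
    return datasets, design


@pytest.fixture(scope="session")
def mini_cohort_metrics(mini_cohort):
    """Long-format r / H_c / H_i table for the mini cohort at tau = 2."""
    datasets, design = mini_cohort
    rows = []
    for (pid, drug, cond), env in datasets.items():
        res = dataset_irrev(env, tau=2, percentile=95.0)
        prof = profile(env, tau=2, percentile=95.0)
        for name, value in [
            ("r", res.r), ("H_c", prof.coherence), ("H_i", prof.inhomogeneity),
        ]:
            rows.append(
                dict(participant=pid, drug=drug, condition=cond,
                     metric_name=name, value=value)
            )
    return ResultTable(pd.DataFrame(rows)), design
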