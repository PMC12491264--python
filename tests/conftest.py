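import numpy as np
import pandas as pd
import pytest

from multioptosis import (
    CohortConfig,
    MultiOptosisModel,
    PlantedEffect,
    generate_pan_cancer_dataset,
)


@pytest.fixture(scope="session")
def planted_dataset():
    """One cohort with recoverable effects on several layers.

    Effects are overexpressed or polarity-neutral so that planted
    infiltration correlation signs translate directly into presence.
    """
    effects = [
        PlantedEffect(
            "G0001", "mrna", "TSM", target_rho=-0.6, tumor_shift=-1.2,
            log_hr=(0.7, 0.7, 0.7, 0.7),
        ),
        PlantedEffect(
            "G0002", "mrna", "TMB", target_rho=0.6, tumor_shift=1.2,
            infiltration_profile={
                "T cells CD8": 1, "NK cells activated": 1, "Macrophages M1": 1,
            },
        ),
        PlantedEffect("G0003", "cnv", "MSI", target_rho=-0.55, log_hr=(0.6, 0.6, 0.6, 0.6)),
        PlantedEffect("G0004", "mutation", "TMB", target_rho=0.6),
        PlantedEffect("G0006.T1", "transcript", "TSM", target_rho=0.62, tumor_shift=1.0),
    ]
    cfg = CohortConfig(
        cancer_code="ACC", n_tumor=400, n_normal=50, n_genes=120,
        planted_effects=effects, censoring_rate=0.3, seed=11,
    )
    return generate_pan_cancer_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_results(planted_dataset):
    return MultiOptosisModel(planted_dataset).fit()
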