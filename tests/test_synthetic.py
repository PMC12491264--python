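import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multioptosis import (
    CohortConfig,
    PlantedEffect,
    generate_metaz_fixture,
    generate_pan_cancer_dataset,
    generate_rcd_inventory,
    generate_survival,
)
from multioptosis.errors import ConfigurationError, ParameterError, SizeError
from multioptosis.synthetic import DEFAULT_CNV_PROBS


def test_config_validation_guards():
    with pytest.raises(ConfigurationError):
        CohortConfig(cancer_code="acc")
    with pytest.raises(SizeError):
        CohortConfig(cancer_code="ACC", n_tumor=1)
    with pytest.raises(ConfigurationError):
        PlantedEffect("f", "proteome", "TSM")
    with pytest.raises(ConfigurationError):
        PlantedEffect("f", "mrna", "BMI")
    with pytest.raises(ConfigurationError):
        PlantedEffect("f", "mrna", "TSM", target_rho=1.5)


def test_layer_codomains_and_shapes():
    cfg = CohortConfig(cancer_code="BRCA", n_tumor=120, n_normal=20, n_genes=40, seed=2)
    ds = generate_pan_cancer_dataset(cfg)
    assert set(ds.layers) == {
        "protein", "mutation", "cnv", "mirna", "transcript", "mrna", "methylation"
    }
    assert set(np.unique(ds.layers["mutation"].values)) <= {0.0, 1.0}
    assert set(np.unique(ds.layers["cnv"].values)) <= {-2.0, -1.0, 0.0, 1.0, 2.0}
    meth = ds.layers["methylation"].values.to_numpy()
    assert meth.min() >= 0.0 and meth.max() <= 1.0
    assert ds.layers["transcript"].values.shape[0] == 40 * cfg.transcripts_per_gene
    assert list(ds.phenotypes.indices.columns) == ["TMB", "MSI", "TSM"]
    assert ds.phenotypes.infiltration.shape == (120, 29)
    # normals only for expression layers, distinct sample ids
    assert set(ds.normals) == {"mrna", "transcript"}
    assert not set(ds.normals["mrna"].values.columns) & set(ds.samples)


def test_planted_rho_is_recovered_within_band():
    cfg = CohortConfig(
        cancer_code="ACC", n_tumor=500, n_normal=0, n_genes=30,
        planted_effects=[PlantedEffect("G0001", "mrna", "TSM", target_rho=0.6)],
        seed=1,
    )
    ds = generate_pan_cancer_dataset(cfg)
    rho, _ = stats.spearmanr(
        ds.layers["mrna"].values.loc["G0001"], ds.phenotypes.indices["TSM"]
    )
    assert 0.45 <= rho <= 0.75


def test_null_dataset_false_positive_rate_is_calibrated():
    cfg = CohortConfig(cancer_code="ACC", n_tumor=100, n_normal=0, n_genes=2000,
                       transcripts_per_gene=1, mirna_count=0, protein_count=0, seed=4)
    ds = generate_pan_cancer_dataset(cfg)
    vals = ds.layers["mrna"].values.to_numpy()
    pheno = ds.phenotypes.indices["TSM"].to_numpy()
    rx = stats.rankdata(vals, axis=1)
    ry = stats.rankdata(pheno)
    rho = np.array([np.corrcoef(r, ry)[0, 1] for r in rx])
    t = rho * np.sqrt(98 / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), 98)
    fpr = np.mean(p < 0.05)
    assert fpr == pytest.approx(0.05, abs=0.02)
    assert np.abs(rho).max() < 0.5


def test_dataset_is_deterministic_given_seed():
    cfg = CohortConfig(
        cancer_code="LGG", n_tumor=60, n_normal=10, n_genes=25, seed=9,
        planted_effects=[PlantedEffect("G0002", "mrna", "TMB", target_rho=0.5)],
    )
    a = generate_pan_cancer_dataset(cfg)
    b = generate_pan_cancer_dataset(cfg)
    for layer in a.layers:
        pd.testing.assert_frame_equal(a.layers[layer].values, b.layers[layer].values)
    for ep in a.phenotypes.survival:
        pd.testing.assert_frame_equal(a.phenotypes.survival[ep], b.phenotypes.survival[ep])
    pd.testing.assert_frame_equal(a.phenotypes.infiltration, b.phenotypes.infiltration)
    assert a.inventory == b.inventory


def test_unknown_planted_feature_is_rejected():
    cfg_kwargs = dict(cancer_code="ACC", n_tumor=50, n_normal=0, n_genes=10, seed=0)
    with pytest.raises(ConfigurationError):
        generate_pan_cancer_dataset(
            CohortConfig(planted_effects=[PlantedEffect("G9999", "mrna", "TSM", 0.5)],
                         **cfg_kwargs)
        )


# ---------------------------------------------------------------------------
# inventory generator
# ---------------------------------------------------------------------------


def test_inventory_hits_calibrated_form_fractions():
    inv = generate_rcd_inventory(5913, seed=7)
    n = len(inv)
    apoptosis = sum(1 for f in inv.membership.values() if "apoptosis" in f) / n
    multi = sum(1 for f in inv.membership.values() if len(f) >= 2) / n
    assert 0.794 <= apoptosis <= 0.834
    assert 0.36 <= multi <= 0.44
    assert all(inv.membership.values())  # every gene non-empty


def test_inventory_forced_single_form():
    inv = generate_rcd_inventory(1, {"apoptosis": 1.0}, multi_form_fraction=0.0, seed=0)
    assert inv.membership == {"G0001": frozenset({"apoptosis"})}


def test_inventory_rejects_unknown_form():
    with pytest.raises(Exception, match="zombosis"):
        generate_rcd_inventory(10, {"zombosis": 0.5})


# ---------------------------------------------------------------------------
# survival generator
# ---------------------------------------------------------------------------


def test_survival_no_censoring_all_events():
    surv = generate_survival(np.zeros(100), censoring_rate=0.0, seed=1)
    assert (surv["event"] == 1).all()
    assert (surv["time"] > 0).all()


def test_survival_censoring_fraction_tracks_request():
    surv = generate_survival(np.zeros(500), censoring_rate=0.35, seed=2)
    assert 1 - surv["event"].mean() == pytest.approx(0.35, abs=0.1)


def test_survival_beta_recovery_via_cox():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(3)
    x = rng.standard_normal(500)
    surv = generate_survival(0.7 * x, censoring_rate=0.0, seed=3)
    df = surv.assign(x=x)
    cph = CoxPHFitter().fit(df, "time", "event")
    assert float(cph.params_["x"]) == pytest.approx(0.7, abs=0.2)


def test_survival_determinism_and_guards():
    a = generate_survival(np.ones(50), censoring_rate=0.2, seed=8)
    b = generate_survival(np.ones(50), censoring_rate=0.2, seed=8)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ParameterError):
        generate_survival(np.zeros(10), baseline_hazard=0.0)


# ---------------------------------------------------------------------------
# meta-Z fixture
# ---------------------------------------------------------------------------


def test_metaz_fixture_plants_exact_values_and_null_tail():
    inv = generate_rcd_inventory(2500, seed=1)
    table = generate_metaz_fixture(inv, ["ACC", "BRCA", "LGG", "LUAD"],
                                   planted={("G0001", "ACC"): 4.0}, seed=5)
    assert table.lookup("G0001", "ACC") == 4.0
    assert np.isnan(table.lookup("NOPE", "ACC"))
    z = table.values.to_numpy().ravel()
    tail = np.mean(np.abs(z) > 3.09)
    assert tail == pytest.approx(0.002, abs=0.002)
    with pytest.raises(KeyError):
        generate_metaz_fixture(inv, ["ACC"], planted={("G0001", "XXX"): 1.0})


def test_dataset_round_trips_to_tsv_dir(tmp_path):
    cfg = CohortConfig(cancer_code="ACC", n_tumor=30, n_normal=5, n_genes=8, seed=3)
    ds = generate_pan_cancer_dataset(cfg)
    ds.to_dir(tmp_path / "out")
    written = {p.name for p in (tmp_path / "out").iterdir()}
    assert {"layer_mrna.tsv", "normal_mrna.tsv", "survival.tsv",
            "phenotype_indices.tsv", "infiltration.tsv", "inventory.tsv"} <= written
    back = pd.read_csv(tmp_path / "out" / "layer_mrna.tsv", sep="\t", index_col=0)
    pd.testing.assert_frame_equal(back, ds.layers["mrna"].values, check_names=False)
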