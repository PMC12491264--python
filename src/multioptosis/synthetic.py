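"""Synthetic pan-cancer cohorts with planted, recoverable effects.

The generator emulates the logical shape of a pan-cancer multi-omic study:
per-cohort tumor samples carrying seven omic layers (continuous expression
for protein/miRNA/transcript/mRNA, binary somatic mutation, gistic-style
ordinal copy number in {-2..2}, methylation beta values in [0, 1]), three
continuous tumor-intrinsic indices (TMB, MSI, TSM), four right-censored
survival endpoints (DSS, DFI, PFI, OS), 29 cell-infiltrate scores and
matched non-tumor expression.  Every effect is *planted*: a target Spearman
correlation with a phenotype, a per-endpoint log hazard ratio, a tumor-vs-
normal location shift, and per-cell-type infiltration correlation signs.
Downstream stages are tested against this ground truth.

Correlations are planted through a Gaussian copula: feature and phenotype
share a latent bivariate-normal with Pearson r = 2 sin(pi * rho_s / 6) (the
exact relation between Pearson and Spearman correlation under bivariate
normality), then each margin is transformed monotonically to its observed
scale, which preserves rank correlation exactly in population.  Discretized
layers (mutation, CNV) attenuate the realized rank correlation; planted
effects on those layers land below the nominal target.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .config import CONTINUOUS_LAYERS, ENDPOINTS, LAYERS, PHENOTYPES
from .errors import (
    ConfigurationError,
    ParameterError,
    SizeError,
    ValidationError,
    VocabularyError,
)
from .inventory import RCD_FORMS, RCD_FORM_SET, RCDInventory
from .ranking import MetaZTable

#: Paper-calibrated default marginal frequencies for the 25 RCD forms.
#: Apoptosis dominates at 81.4%; the rarest forms are alkaliptosis,
#: lysosome-dependent cell death and methuosis.
DEFAULT_FORM_FREQUENCIES: dict[str, float] = {
    "apoptosis": 0.814,
    "autophagy": 0.20,
    "necrosis": 0.12,
    "ferroptosis": 0.08,
    "pyroptosis": 0.05,
    "necroptosis": 0.04,
    "cellular_senescence": 0.035,
    "anoikis": 0.03,
    "cuproptosis": 0.02,
    "immunogenic_cell_death": 0.018,
    "mitotic_catastrophe": 0.016,
    "entosis": 0.014,
    "parthanatos": 0.012,
    "netosis": 0.011,
    "autosis": 0.010,
    "mitochondrial_permeability_transition": 0.009,
    "efferocytosis": 0.008,
    "disulfidptosis": 0.007,
    "oxeiptosis": 0.006,
    "paraptosis": 0.005,
    "mitoptosis": 0.004,
    "erebosis": 0.003,
    "alkaliptosis": 0.002,
    "lysosome_dependent_cell_death": 0.002,
    "methuosis": 0.001,
}

DEFAULT_MULTI_FORM_FRACTION = 0.40

#: gistic-thresholded copy-number state marginals {-2..2}.
DEFAULT_CNV_PROBS: dict[int, float] = {-2: 0.02, -1: 0.18, 0: 0.60, 1: 0.18, 2: 0.02}

#: Somatic mutations are rare per gene; even low-prevalence mutations matter.
DEFAULT_MUTATION_PREVALENCE = 0.05

DEFAULT_BASELINE_HAZARD = 0.1
#: Latent loading used for planted infiltration correlations.
INFILTRATION_LOADING = 0.5


@dataclass
class PlantedEffect:
    """Ground-truth effect attached to one feature of one omic layer."""

    feature_id: str
    layer: str
    phenotype: str = "TSM"
    target_rho: float = 0.0
    tumor_shift: float = 0.0
    log_hr: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    infiltration_profile: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ConfigurationError(f"unknown layer {self.layer!r}")
        if self.phenotype not in PHENOTYPES:
            raise ConfigurationError(f"unknown phenotype {self.phenotype!r}")
        if not -1.0 <= self.target_rho <= 1.0:
            raise ConfigurationError("target_rho must lie in [-1, 1]")
        if len(self.log_hr) != 4:
            raise ConfigurationError("log_hr must be a 4-vector (DSS, DFI, PFI, OS)")
        for sign in self.infiltration_profile.values():
            if sign not in (-1, 1):
                raise ConfigurationError("infiltration signs must be +1 or -1")


@dataclass
class CohortConfig:
    """Shape and planted truth of one synthetic cancer cohort."""

    cancer_code: str
    n_tumor: int = 300
    n_normal: int = 50
    n_genes: int = 500
    transcripts_per_gene: int = 2
    #: None -> min(50, n_genes) miRNAs / min(40, n_genes) proteins
    mirna_count: int | None = None
    protein_count: int | None = None
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    censoring_rate: float = 0.3
    seed: int = 0
    mutation_prevalence: float = DEFAULT_MUTATION_PREVALENCE
    cnv_probs: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CNV_PROBS))

    def __post_init__(self) -> None:
        if not self.cancer_code.isalpha() or not self.cancer_code.isupper() or not (
            3 <= len(self.cancer_code) <= 4
        ):
            raise ConfigurationError("cancer_code must be 3-4 uppercase letters")
        if self.mirna_count is None:
            self.mirna_count = min(50, self.n_genes)
        if self.protein_count is None:
            self.protein_count = min(40, self.n_genes)
        for name in ("n_tumor", "n_normal", "n_genes", "mirna_count", "protein_count"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.transcripts_per_gene < 1:
            raise ConfigurationError("transcripts_per_gene must be >= 1")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1]")
        if self.n_tumor < 2:
            raise SizeError("n_tumor must be at least 2")
        if self.mirna_count > self.n_genes or self.protein_count > self.n_genes:
            raise ConfigurationError("mirna_count/protein_count cannot exceed n_genes")

    def to_yaml(self, path) -> None:
        raw = {
            "cancer_code": self.cancer_code,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_genes": self.n_genes,
            "transcripts_per_gene": self.transcripts_per_gene,
            "mirna_count": self.mirna_count,
            "protein_count": self.protein_count,
            "censoring_rate": self.censoring_rate,
            "seed": self.seed,
            "mutation_prevalence": self.mutation_prevalence,
            "planted_effects": [
                {
                    "feature_id": e.feature_id,
                    "layer": e.layer,
                    "phenotype": e.phenotype,
                    "target_rho": e.target_rho,
                    "tumor_shift": e.tumor_shift,
                    "log_hr": list(e.log_hr),
                    "infiltration_profile": dict(e.infiltration_profile),
                }
                for e in self.planted_effects
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        effects = [PlantedEffect(**{**e, "log_hr": tuple(e.get("log_hr", (0, 0, 0, 0)))})
                   for e in raw.pop("planted_effects", [])]
        return cls(planted_effects=effects, **raw)


@dataclass
class OmicLayerMatrix:
    """One omic layer: features x samples, with layer kind and gene parents."""

    layer: str
    kind: str  # 'continuous' | 'binary' | 'ordinal'
    values: pd.DataFrame
    feature_gene: pd.Series  # feature id -> parent gene symbol

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise VocabularyError(f"unknown layer {self.layer!r}")
        v = self.values.to_numpy()
        if self.kind == "binary" and not np.isin(v[~np.isnan(v)], (0, 1)).all():
            raise ValidationError("mutation layer values must lie in {0, 1}")
        if self.kind == "ordinal" and not np.isin(
            v[~np.isnan(v)], (-2, -1, 0, 1, 2)
        ).all():
            raise ValidationError("CNV layer values must lie in {-2..2}")
        if self.layer == "methylation":
            ok = v[~np.isnan(v)]
            if ((ok < 0) | (ok > 1)).any():
                raise ValidationError("methylation beta values must lie in [0, 1]")

    def to_tsv(self, path) -> None:
        self.values.rename_axis("feature").to_csv(path, sep="\t")


@dataclass
class PhenotypeTable:
    """Per-sample indices, survival endpoints and infiltration scores."""

    indices: pd.DataFrame  # samples x (TMB, MSI, TSM)
    survival: dict[str, pd.DataFrame]  # endpoint -> (time, event) per sample
    infiltration: pd.DataFrame  # samples x 29 cell types

    def to_tsv(self, indices_path, survival_path, infiltration_path) -> None:
        long = (
            self.indices.rename_axis("sample")
            .reset_index()
            .melt(id_vars="sample", var_name="variable", value_name="value")
        )
        long.to_csv(indices_path, sep="\t", index=False)
        rows = []
        for ep, df in self.survival.items():
            part = df.rename_axis("sample").reset_index()
            part.insert(1, "endpoint", ep)
            rows.append(part)
        pd.concat(rows).to_csv(survival_path, sep="\t", index=False)
        self.infiltration.rename_axis("sample").to_csv(infiltration_path, sep="\t")


@dataclass
class PanCancerDataset:
    """One cohort's layers, phenotypes, normals, inventory and planted truth."""

    cancer_code: str
    layers: dict[str, OmicLayerMatrix]
    normals: dict[str, OmicLayerMatrix]
    phenotypes: PhenotypeTable
    inventory: RCDInventory
    truth: list[PlantedEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = set(self.phenotypes.indices.index)
        for name, layer in self.layers.items():
            if set(layer.values.columns) != samples:
                raise ValidationError(f"layer {name!r} samples do not match phenotypes")
        for eff in self.truth:
            if eff.feature_id not in self.layers[eff.layer].values.index:
                raise ValidationError(
                    f"planted feature {eff.feature_id!r} absent from layer {eff.layer!r}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.phenotypes.indices.index)

    def companion_feature(self, layer: str, feature_id: str) -> str:
        """The mRNA feature standing in for a non-transcriptomic feature.

        mRNA, transcript and miRNA features are their own companions (native
        continuous expression); protein, mutation, CNV and methylation
        features delegate to the parent gene's mRNA feature.
        """
        if layer in ("mrna", "transcript", "mirna"):
            return feature_id
        gene = self.layers[layer].feature_gene[feature_id]
        return gene

    def companion_values(self, layer: str, feature_id: str) -> pd.Series:
        comp = self.companion_feature(layer, feature_id)
        if layer in ("transcript", "mirna"):
            return self.layers[layer].values.loc[feature_id]
        if layer == "mrna":
            return self.layers["mrna"].values.loc[comp]
        return self.layers["mrna"].values.loc[comp]

    def to_dir(self, path) -> None:
        """Write all tables as TSV plus the sample manifest."""
        import os

        os.makedirs(path, exist_ok=True)
        for name, layer in self.layers.items():
            layer.to_tsv(os.path.join(path, f"layer_{name}.tsv"))
        for name, layer in self.normals.items():
            layer.to_tsv(os.path.join(path, f"normal_{name}.tsv"))
        self.phenotypes.to_tsv(
            os.path.join(path, "phenotype_indices.tsv"),
            os.path.join(path, "survival.tsv"),
            os.path.join(path, "infiltration.tsv"),
        )
        self.inventory.to_tsv(os.path.join(path, "inventory.tsv"))


# ---------------------------------------------------------------------------
# RCD inventory generator
# ---------------------------------------------------------------------------


def _poisson_binomial_p0_p1(probs: np.ndarray) -> tuple[float, float]:
    p0 = float(np.prod(1.0 - probs))
    with np.errstate(divide="ignore"):
        ratios = np.where(probs < 1.0, probs / (1.0 - probs), np.inf)
    if np.isinf(ratios).any():
        # some prob is exactly 1: K >= count of ones
        ones = int((probs >= 1.0).sum())
        if ones >= 2:
            return 0.0, 0.0
        rest = probs[probs < 1.0]
        return 0.0, float(np.prod(1.0 - rest))
    p1 = p0 * float(ratios.sum())
    return p0, p1


def _expected_multi_fraction(p_anchor: float, other: np.ndarray, c: float) -> float:
    p0, p1 = _poisson_binomial_p0_p1(np.clip(c * other, 0.0, 1.0))
    return p_anchor * (1.0 - p0) + (1.0 - p_anchor) * (1.0 - p0 - p1)


def generate_rcd_inventory(
    n_genes: int,
    form_frequencies: Mapping[str, float] | None = None,
    multi_form_fraction: float = DEFAULT_MULTI_FORM_FRACTION,
    seed: int = 0,
) -> RCDInventory:
    """Draw a gene inventory with calibrated form marginals.

    Each form is an independent per-gene Bernoulli.  The apoptosis marginal
    is fixed at its requested frequency; the other marginals are rescaled by
    a bisection-calibrated common factor so the expected fraction of genes
    with >= 2 forms equals ``multi_form_fraction``.  Genes that draw no form
    receive a single non-apoptosis form (frequency-weighted), keeping the
    realized apoptosis fraction at its target.
    """
    freqs = dict(DEFAULT_FORM_FREQUENCIES if form_frequencies is None else form_frequencies)
    unknown = set(freqs) - RCD_FORM_SET
    if unknown:
        raise VocabularyError(f"unknown RCD form(s): {sorted(unknown)}")
    for form, f in freqs.items():
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"frequency for {form!r} must lie in [0, 1]")
    if not 0.0 <= multi_form_fraction <= 1.0:
        raise ParameterError("multi_form_fraction must lie in [0, 1]")

    anchor = "apoptosis"
    p_anchor = freqs.get(anchor, 0.0)
    other_forms = [f for f in RCD_FORMS if f != anchor and freqs.get(f, 0.0) > 0]
    other_p = np.array([freqs[f] for f in other_forms], dtype=float)

    # calibrate the common rescaling factor for the non-anchor marginals
    if multi_form_fraction <= 0 or other_p.size == 0:
        c = 0.0
    else:
        c_hi = float(1.0 / other_p.max())
        if _expected_multi_fraction(p_anchor, other_p, c_hi) <= multi_form_fraction:
            c = c_hi  # target unreachable; use the maximum feasible scaling
        else:
            lo, hi = 0.0, c_hi
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if _expected_multi_fraction(p_anchor, other_p, mid) < multi_form_fraction:
                    lo = mid
                else:
                    hi = mid
            c = 0.5 * (lo + hi)

    rng = np.random.default_rng(seed)
    scaled = np.clip(c * other_p, 0.0, 1.0)
    has_anchor = rng.random(n_genes) < p_anchor
    draws = rng.random((n_genes, len(other_forms))) < scaled[None, :]

    fallback_w = other_p / other_p.sum() if other_p.size else None
    membership: dict[str, frozenset[str]] = {}
    for i in range(n_genes):
        forms = set(np.array(other_forms)[draws[i]]) if other_forms else set()
        if has_anchor[i]:
            forms.add(anchor)
        if not forms:
            if fallback_w is not None:
                forms = {other_forms[rng.choice(len(other_forms), p=fallback_w)]}
            elif p_anchor > 0:
                forms = {anchor}
            else:
                raise ConfigurationError("all form frequencies are zero")
        membership[f"G{i + 1:04d}"] = frozenset(forms)
    return RCDInventory(membership)


# ---------------------------------------------------------------------------
# survival generator
# ---------------------------------------------------------------------------


def generate_survival(
    linear_predictor: Sequence[float],
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with administrative censoring.

    hazard_i = baseline * exp(linear_predictor_i).  Censoring truncates at
    the (1 - censoring_rate) quantile of the drawn event times, so the
    realized censoring fraction tracks the request.
    """
    if baseline_hazard <= 0:
        raise ParameterError("baseline_hazard must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ParameterError("censoring_rate must lie in [0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)
    index = (
        linear_predictor.index
        if isinstance(linear_predictor, pd.Series)
        else pd.RangeIndex(len(lp))
    )
    rng = np.random.default_rng(seed)
    times = rng.exponential(scale=1.0 / (baseline_hazard * np.exp(lp)))
    if censoring_rate <= 0:
        return pd.DataFrame({"time": times, "event": np.ones(len(lp), dtype=int)}, index=index)
    cutoff = float(np.quantile(times, 1.0 - censoring_rate))
    event = (times <= cutoff).astype(int)
    return pd.DataFrame({"time": np.minimum(times, cutoff), "event": event}, index=index)


# ---------------------------------------------------------------------------
# meta-Z fixture
# ---------------------------------------------------------------------------


def generate_metaz_fixture(
    inventory: RCDInventory,
    cancer_codes: Sequence[str],
    planted: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> MetaZTable:
    """Standard-normal meta-Z table with exact planted entries."""
    rng = np.random.default_rng(seed)
    genes = inventory.genes
    values = pd.DataFrame(
        rng.standard_normal((len(genes), len(cancer_codes))),
        index=genes,
        columns=list(cancer_codes),
    )
    for (gene, cancer), z in (planted or {}).items():
        if gene not in values.index:
            raise KeyError(f"planted gene {gene!r} not in inventory")
        if cancer not in values.columns:
            raise KeyError(f"planted cancer {cancer!r} not in cancer_codes")
        values.loc[gene, cancer] = z
    return MetaZTable(values)


# ---------------------------------------------------------------------------
# full cohort generator
# ---------------------------------------------------------------------------


def _pearson_for_spearman(rho_s: float) -> float:
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _cnv_cuts(probs: Mapping[int, float]) -> np.ndarray:
    cum = np.cumsum([probs[k] for k in (-2, -1, 0, 1)])
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


def _feature_ids(config: CohortConfig) -> dict[str, tuple[list[str], list[str]]]:
    """Per layer: (feature ids, parent genes)."""
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    out: dict[str, tuple[list[str], list[str]]] = {}
    out["mrna"] = (genes, genes)
    tx, tx_g = [], []
    for g in genes:
        for k in range(config.transcripts_per_gene):
            tx.append(f"{g}.T{k + 1}")
            tx_g.append(g)
    out["transcript"] = (tx, tx_g)
    mir = [f"miR-{i + 1:03d}-5p" for i in range(config.mirna_count)]
    out["mirna"] = (mir, genes[: config.mirna_count])
    prot = [f"{g}_protein" for g in genes[: config.protein_count]]
    out["protein"] = (prot, genes[: config.protein_count])
    out["mutation"] = (list(genes), genes)
    out["cnv"] = (list(genes), genes)
    out["methylation"] = ([f"cg_{g}" for g in genes], genes)
    return out


def generate_pan_cancer_dataset(config: CohortConfig) -> PanCancerDataset:
    """Build one cohort deterministically from (config, seed).

    Planted effects couple a feature's latent to its phenotype latent (the
    Gaussian copula described in the module docstring), to the survival
    linear predictors via ``log_hr``, to the cell-infiltrate scores via
    ``infiltration_profile``, and to the matched normals via ``tumor_shift``.
    For effects on non-transcriptomic layers the parent gene's mRNA latent is
    coupled to the same signal, mirroring the expression-centric companion
    annotation used downstream.
    """
    rng = np.random.default_rng(config.seed)
    nt, nn = config.n_tumor, config.n_normal
    tumor_samples = [f"{config.cancer_code}-T{i + 1:04d}" for i in range(nt)]
    normal_samples = [f"{config.cancer_code}-N{i + 1:04d}" for i in range(nn)]

    inventory = generate_rcd_inventory(
        config.n_genes, seed=int(rng.integers(0, 2**31 - 1))
    )

    pheno_latent = {ph: rng.standard_normal(nt) for ph in PHENOTYPES}
    immune_axis = rng.standard_normal(nt)

    ids = _feature_ids(config)
    for eff in config.planted_effects:
        if eff.feature_id not in ids[eff.layer][0]:
            raise ConfigurationError(
                f"planted feature {eff.feature_id!r} not generated in layer {eff.layer!r}"
            )

    # latent z per layer, iid normal rows; planted rows get copula coupling
    latents: dict[str, np.ndarray] = {
        layer: rng.standard_normal((len(ids[layer][0]), nt)) for layer in LAYERS
    }
    planted_latent: dict[tuple[str, str], np.ndarray] = {}
    shifts: dict[str, float] = {}  # parent gene -> tumor log-scale shift
    for eff in config.planted_effects:
        feats, genes_of = ids[eff.layer]
        row = feats.index(eff.feature_id)
        r = _pearson_for_spearman(eff.target_rho)
        eps = rng.standard_normal(nt)
        z = r * pheno_latent[eff.phenotype] + np.sqrt(max(0.0, 1 - r**2)) * eps
        latents[eff.layer][row] = z
        planted_latent[(eff.layer, eff.feature_id)] = z
        gene = genes_of[row]
        if eff.layer != "mrna":
            # couple the companion mRNA of the same locus to the same signal
            mrow = ids["mrna"][0].index(gene)
            latents["mrna"][mrow] = z
        if eff.tumor_shift:
            shifts[gene] = eff.tumor_shift

    # observed layer values via monotone margins
    mu = {
        layer: rng.normal(3.0, 1.0, size=len(ids[layer][0]))
        for layer in ("protein", "mirna", "transcript", "mrna")
    }
    cuts = _cnv_cuts(config.cnv_probs)
    mut_threshold = stats.norm.ppf(1.0 - config.mutation_prevalence)

    def continuous(layer: str) -> np.ndarray:
        return np.exp(mu[layer][:, None] + latents[layer])

    layer_values: dict[str, np.ndarray] = {
        "protein": continuous("protein"),
        "mirna": continuous("mirna"),
        "transcript": continuous("transcript"),
        "mrna": continuous("mrna"),
        "methylation": stats.norm.cdf(latents["methylation"]),
        "mutation": (latents["mutation"] > mut_threshold).astype(float),
        "cnv": (np.digitize(latents["cnv"], cuts) - 2).astype(float),
    }

    kinds = {
        "mutation": "binary",
        "cnv": "ordinal",
        **{l: "continuous" for l in CONTINUOUS_LAYERS},
    }
    layers = {
        layer: OmicLayerMatrix(
            layer=layer,
            kind=kinds[layer],
            values=pd.DataFrame(layer_values[layer], index=ids[layer][0], columns=tumor_samples),
            feature_gene=pd.Series(ids[layer][1], index=ids[layer][0]),
        )
        for layer in LAYERS
    }

    # matched non-tumor expression for the mRNA and transcript layers
    normals: dict[str, OmicLayerMatrix] = {}
    if nn > 0:
        for layer in ("mrna", "transcript"):
            feats, genes_of = ids[layer]
            z = rng.standard_normal((len(feats), nn))
            shift = np.array([shifts.get(g, 0.0) for g in genes_of])
            vals = np.exp(mu[layer][:, None] - shift[:, None] + z)
            normals[layer] = OmicLayerMatrix(
                layer=layer,
                kind="continuous",
                values=pd.DataFrame(vals, index=feats, columns=normal_samples),
                feature_gene=pd.Series(genes_of, index=feats),
            )

    # phenotype indices on interpretable monotone scales
    indices = pd.DataFrame(
        {
            "TMB": np.exp(pheno_latent["TMB"]),
            "MSI": stats.norm.cdf(pheno_latent["MSI"]),
            "TSM": stats.norm.cdf(pheno_latent["TSM"]),
        },
        index=tumor_samples,
    )

    # survival: one exponential model per endpoint with planted log-HRs
    survival: dict[str, pd.DataFrame] = {}
    for k, ep in enumerate(ENDPOINTS):
        lp = np.zeros(nt)
        for eff in config.planted_effects:
            if eff.log_hr[k]:
                lp += eff.log_hr[k] * planted_latent[(eff.layer, eff.feature_id)]
        surv = generate_survival(
            pd.Series(lp, index=tumor_samples),
            baseline_hazard=DEFAULT_BASELINE_HAZARD,
            censoring_rate=config.censoring_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        survival[ep] = surv

    # 29 cell-infiltrate scores: shared immune axis + planted feature loadings
    from .contexture import CellCategoryMap

    cells = sorted(CellCategoryMap.default().cells)
    scores = {}
    for cell in cells:
        s = 0.5 * immune_axis + 0.7 * rng.standard_normal(nt)
        for eff in config.planted_effects:
            sign = eff.infiltration_profile.get(cell)
            if sign:
                s = s + sign * INFILTRATION_LOADING * planted_latent[
                    (eff.layer, eff.feature_id)
                ]
        scores[cell] = s
    infiltration = pd.DataFrame(scores, index=tumor_samples)

    phenotypes = PhenotypeTable(indices=indices, survival=survival, infiltration=infiltration)
    return PanCancerDataset(
        cancer_code=config.cancer_code,
        layers=layers,
        normals=normals,
        phenotypes=phenotypes,
        inventory=inventory,
        truth=list(config.planted_effects),
    )
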