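"""Analysis thresholds and closed vocabularies used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ParameterError

#: Omic layers, in genomic-feature-code (GFC) order 1..7.
LAYERS: tuple[str, ...] = (
    "protein",
    "mutation",
    "cnv",
    "mirna",
    "transcript",
    "mrna",
    "methylation",
)

#: Tumor-intrinsic phenotype indices screened genome-wide, in PFC order 1..3.
PHENOTYPES: tuple[str, ...] = ("TMB", "MSI", "TSM")

#: Survival endpoints in identifier-array order (positions 1..4).
ENDPOINTS: tuple[str, ...] = ("DSS", "DFI", "PFI", "OS")

#: Layers whose values are expression-like (continuous, median-splittable).
CONTINUOUS_LAYERS = frozenset({"protein", "mirna", "transcript", "mrna", "methylation"})


@dataclass
class AnalysisConfig:
    """Thresholds of the screening and annotation stages.

    genome_wide_alpha
        Holm-adjusted significance level for the TMB/MSI/TSM screens; only
        features passing it enter signatures.
    per_feature_alpha
        Unadjusted level for all per-feature follow-up tests (Cox, log-rank,
        Wilcoxon polarity, cell-infiltrate correlations).
    metaz_threshold
        |meta-Z| needed to call an external prognostic validation
        (3.09 ~ two-sided p < 0.001).
    """

    genome_wide_alpha: float = 5e-8
    per_feature_alpha: float = 0.05
    metaz_threshold: float = 3.09
    endpoints: tuple[str, ...] = ENDPOINTS
    #: continuous features are dichotomized at the median; exact-median
    #: samples go to the Low group (deterministic tie rule)
    dichotomization: str = "median"
    #: exact-tie window for TMC/TIC aggregate comparisons
    tie_epsilon: float = 1e-9
    #: z-score members before summing composite scores
    standardize_composite: bool = False

    def __post_init__(self) -> None:
        for name in ("genome_wide_alpha", "per_feature_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ParameterError(f"{name} must lie in (0, 1), got {a}")
        if self.metaz_threshold <= 0:
            raise ParameterError("metaz_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "endpoints" in known:
            known["endpoints"] = tuple(known["endpoints"])
        return cls(**known)


DEFAULT_CONFIG = AnalysisConfig()
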