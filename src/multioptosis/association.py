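"""Genome-wide screening and per-feature survival annotation.

Per cancer type and omic layer, every feature is rank-correlated with the
three tumor-intrinsic indices (TMB, MSI, TSM).  Each screen is one
multiple-testing family, adjusted by Holm-Bonferroni; features pass at the
genome-wide level padj < 5e-8.  Significant features are then annotated
per-feature (unadjusted p < 0.05) with

* TNC -- tumor vs non-tumor polarity from a two-sided rank-sum test,
* HRC -- per-endpoint univariate Cox hazard classes A/B/C,
* SMC -- per-endpoint Kaplan-Meier/log-rank classes over layer-specific
  patient groups (High/Low, MT/WT, Deleted/Duplicated).

Cox and log-rank machinery comes from lifelines; rank statistics from scipy;
multiplicity adjustment from statsmodels.  Models are univariate by design:
no clinical covariates enter at the discovery stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, CONTINUOUS_LAYERS, DEFAULT_CONFIG
from .errors import AlignmentError, ParameterError, SizeError, ValidationError

HRC_LETTERS = frozenset("ABC")
SMC_LETTERS = frozenset("ABCD")


@dataclass(frozen=True)
class AssociationRecord:
    """One feature x phenotype screening result."""

    feature_id: str
    layer: str
    cancer_code: str
    phenotype: str
    rho: float
    p: float
    padj: float
    significant: bool
    scs: str  # 'P' | 'N'
    n: int


@dataclass
class ScreenResult:
    """Records plus the features excluded from the screen, with reasons."""

    records: list[AssociationRecord]
    excluded: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


@dataclass(frozen=True)
class CoxFit:
    endpoint: str
    hazard_ratio: float
    p: float
    n_events: int
    log_hr: float = float("nan")
    flag: str = ""


@dataclass(frozen=True)
class EndpointArray:
    """4 letters over the endpoint order (DSS, DFI, PFI, OS)."""

    kind: str  # 'HRC' | 'SMC'
    letters: tuple[str, str, str, str]
    layer: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("HRC", "SMC"):
            raise ValidationError(f"unknown endpoint-array kind {self.kind!r}")
        if len(self.letters) != 4:
            raise ValidationError("endpoint array needs exactly 4 letters")
        allowed = HRC_LETTERS if self.kind == "HRC" else SMC_LETTERS
        for let in self.letters:
            if let not in allowed:
                raise ValidationError(f"letter {let!r} not allowed for {self.kind}")
        if self.kind == "SMC" and "D" in self.letters and self.layer != "cnv":
            raise ValidationError("SMC letter D is reserved for the CNV layer")

    def __str__(self) -> str:
        return "".join(self.letters)


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm-Bonferroni step-down adjustment, in input order, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjustment (used for the tumor-vs-normal screen)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def _spearman_fast(values: np.ndarray, pheno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided t-approximation p-values.

    Average ranks handle ties; this is the screening path.  Tests compare it
    against a naive rank-then-Pearson oracle.
    """
    n = values.shape[1]
    rx = stats.rankdata(values, axis=1)
    ry = stats.rankdata(pheno)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def spearman_screen(
    layer_values: pd.DataFrame,
    phenotype_values: pd.Series,
    config: AnalysisConfig = DEFAULT_CONFIG,
    *,
    layer: str = "mrna",
    cancer_code: str = "",
    phenotype: str = "",
) -> ScreenResult:
    """Screen every feature (row) against one phenotype index.

    ``layer_values`` is features x samples; columns must match the phenotype
    index.  Zero-variance features are excluded with an explicit reason, and
    the Holm family is the set of testable features in this screen.
    """
    pheno = phenotype_values.dropna()
    common = layer_values.columns.intersection(pheno.index)
    if len(common) != len(layer_values.columns) or len(common) != len(pheno):
        if len(common) == 0:
            raise AlignmentError("no shared samples between layer and phenotype")
    if len(common) < 3:
        raise SizeError("spearman_screen requires at least 3 samples")
    vals = layer_values[common]
    pheno = pheno[common]

    excluded: dict[str, str] = {}
    v = vals.to_numpy(dtype=float)
    n_missing = np.isnan(v).sum(axis=1)
    enough = (v.shape[1] - n_missing) >= 3
    constant = np.zeros(v.shape[0], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        constant[enough] = np.nanstd(v[enough], axis=1) == 0
    for fid, few, const in zip(vals.index, ~enough, constant):
        if few:
            excluded[fid] = "fewer than 3 non-missing samples"
        elif const:
            excluded[fid] = "zero variance"
    keep = enough & ~constant
    if not keep.any():
        warnings.warn("all features constant or unusable; empty screen result")
        return ScreenResult([], excluded)

    kept_ids = vals.index[keep]
    kept = v[keep]
    if np.isnan(kept).any():
        # slow pairwise-complete path for layers with missing values
        rho = np.empty(kept.shape[0])
        p = np.empty(kept.shape[0])
        py = pheno.to_numpy(dtype=float)
        for i, row in enumerate(kept):
            ok = ~np.isnan(row)
            r, pv = stats.spearmanr(row[ok], py[ok])
            rho[i], p[i] = r, pv
        ns = (~np.isnan(kept)).sum(axis=1)
    else:
        rho, p = _spearman_fast(kept, pheno.to_numpy(dtype=float))
        ns = np.full(kept.shape[0], kept.shape[1])

    padj = holm_adjust(p)
    records = [
        AssociationRecord(
            feature_id=fid,
            layer=layer,
            cancer_code=cancer_code,
            phenotype=phenotype,
            rho=float(r),
            p=float(pv),
            padj=float(pa),
            significant=bool(pa < config.genome_wide_alpha),
            scs="P" if r > 0 else "N",
            n=int(nn),
        )
        for fid, r, pv, pa, nn in zip(kept_ids, rho, p, padj, ns)
    ]
    return ScreenResult(records, excluded)


# ---------------------------------------------------------------------------
# tumor vs non-tumor polarity (TNC)
# ---------------------------------------------------------------------------

TNC_NO_DATA = 0
TNC_UNCHANGED = 1
TNC_UNDER = 2
TNC_OVER = 3


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided unpaired rank-sum (Mann-Whitney) p-value."""
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def tumor_normal_screen(
    tumor: pd.DataFrame, normal: pd.DataFrame
) -> pd.DataFrame:
    """Per-feature rank-sum p and BH-adjusted padj for shared features."""
    common = tumor.index.intersection(normal.index)
    ps = []
    for fid in common:
        tv = tumor.loc[fid].dropna().to_numpy(dtype=float)
        nv = normal.loc[fid].dropna().to_numpy(dtype=float)
        if len(tv) == 0 or len(nv) == 0 or (np.std(tv) == 0 and np.std(nv) == 0 and tv[0] == nv[0]):
            ps.append(1.0)
        else:
            ps.append(rank_sum_p(tv, nv))
    out = pd.DataFrame({"p": ps}, index=common)
    out["padj"] = bh_adjust(out["p"]) if len(out) else []
    return out


def classify_tnc(
    tumor_values: Sequence[float] | None,
    normal_values: Sequence[float] | None,
    padj: float | None = None,
) -> int:
    """Code tumor-vs-normal polarity: 0 no data, 1 unchanged, 2 under, 3 over.

    A significant test with exactly tied medians is coded unchanged (1).
    When ``padj`` is not supplied it is computed unadjusted from the two
    groups; pipeline callers pass the BH-adjusted value.
    """
    tumor = np.asarray([] if tumor_values is None else list(tumor_values), dtype=float)
    if tumor.size == 0:
        raise SizeError("classify_tnc requires a non-empty tumor group")
    normal = np.asarray(
        [] if normal_values is None else list(normal_values), dtype=float
    )
    if normal.size == 0:
        return TNC_NO_DATA
    if padj is None:
        padj = rank_sum_p(tumor, normal)
    if padj >= 0.05:
        return TNC_UNCHANGED
    mt, mn = np.median(tumor), np.median(normal)
    if mt > mn:
        return TNC_OVER
    if mt < mn:
        return TNC_UNDER
    return TNC_UNCHANGED


# ---------------------------------------------------------------------------
# hazard-ratio contexture (HRC)
# ---------------------------------------------------------------------------


def _check_survival(surv: pd.DataFrame) -> None:
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")


def _cox_single(
    x: pd.Series, surv: pd.DataFrame, endpoint: str
) -> CoxFit:
    df = pd.concat([surv[["time", "event"]], x.rename("x")], axis=1, join="inner").dropna()
    n_events = int(df["event"].sum())
    if n_events < 2:
        return CoxFit(endpoint, 1.0, 1.0, n_events, flag="fit_skipped")
    if df["x"].std() == 0:
        return CoxFit(endpoint, 1.0, 1.0, n_events, flag="constant_covariate")
    _check_survival(df)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxFit(endpoint, 1.0, 1.0, n_events, flag="convergence")
    beta = float(cph.params_["x"])
    p = float(cph.summary.loc["x", "p"])
    if not np.isfinite(beta) or not np.isfinite(p) or abs(beta) > 50:
        return CoxFit(endpoint, 1.0, 1.0, n_events, flag="convergence")
    return CoxFit(endpoint, float(np.exp(beta)), p, n_events, log_hr=beta)


def fit_hrc(
    feature_values: pd.Series,
    survival: Mapping[str, pd.DataFrame],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[EndpointArray, dict[str, CoxFit]]:
    """Per-endpoint univariate Cox classes: A no effect, B risky, C protective."""
    letters = []
    fits: dict[str, CoxFit] = {}
    for ep in config.endpoints:
        surv = survival.get(ep)
        if surv is None or surv.empty:
            fits[ep] = CoxFit(ep, 1.0, 1.0, 0, flag="no_data")
            letters.append("A")
            continue
        fit = _cox_single(feature_values, surv, ep)
        fits[ep] = fit
        if fit.flag or fit.p >= config.per_feature_alpha:
            letters.append("A")
        elif fit.hazard_ratio > 1:
            letters.append("B")
        else:
            letters.append("C")
    return EndpointArray("HRC", tuple(letters)), fits


# ---------------------------------------------------------------------------
# survival-metric contexture (SMC)
# ---------------------------------------------------------------------------


def _rmst(surv: pd.DataFrame, tau: float) -> float:
    km = KaplanMeierFitter()
    km.fit(surv["time"], surv["event"])
    return float(restricted_mean_survival_time(km, t=tau))


def _two_group_letter(
    g1: pd.DataFrame,
    g2: pd.DataFrame,
    letter_if_g1_poorer: str,
    letter_if_g2_poorer: str,
    alpha: float,
) -> str | None:
    """Log-rank the two groups; return the poorer group's letter or None."""
    res = logrank_test(g1["time"], g2["time"], g1["event"], g2["event"])
    if res.p_value >= alpha:
        return None
    tau = float(min(g1["time"].max(), g2["time"].max()))
    r1, r2 = _rmst(g1, tau), _rmst(g2, tau)
    if r1 < r2:
        return letter_if_g1_poorer
    if r2 < r1:
        return letter_if_g2_poorer
    return None


def fit_smc(
    feature_values: pd.Series,
    layer: str,
    survival: Mapping[str, pd.DataFrame],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> tuple[EndpointArray, dict[str, str]]:
    """Per-endpoint Kaplan-Meier/log-rank classes.

    Patient groups by layer: continuous layers split High/Low at the median
    (ties to Low); mutation splits MT (1) vs WT (0); CNV contrasts Deleted
    ({-2,-1}) vs Duplicated ({1,2}) first and, failing that, pooled
    non-neutral vs neutral (letter D when the pooled group fares worse).
    """
    letters = []
    flags: dict[str, str] = {}
    x = feature_values.dropna()
    for ep in config.endpoints:
        surv = survival.get(ep)
        if surv is None or surv.empty:
            letters.append("A")
            flags[ep] = "no_data"
            continue
        df = pd.concat([surv[["time", "event"]], x.rename("x")], axis=1, join="inner").dropna()
        if df.empty:
            letters.append("A")
            flags[ep] = "no_data"
            continue
        _check_survival(df)
        letter = "A"
        if layer == "mutation":
            mt, wt = df[df["x"] == 1], df[df["x"] == 0]
            if len(mt) == 0 or len(wt) == 0:
                flags[ep] = "group_empty"
            else:
                letter = _two_group_letter(mt, wt, "B", "C", config.per_feature_alpha) or "A"
        elif layer == "cnv":
            deleted = df[df["x"] < 0]
            duplicated = df[df["x"] > 0]
            neutral = df[df["x"] == 0]
            got = None
            if len(deleted) and len(duplicated):
                got = _two_group_letter(
                    deleted, duplicated, "B", "C", config.per_feature_alpha
                )
            if got is None:
                pooled = df[df["x"] != 0]
                if len(pooled) and len(neutral):
                    got = _two_group_letter(
                        pooled, neutral, "D", "", config.per_feature_alpha
                    )
                    if got == "":  # neutral poorer: no letter encodes this
                        got = None
                elif not (len(deleted) and len(duplicated)):
                    flags[ep] = "group_empty"
            letter = got or "A"
        else:
            med = df["x"].median()
            high, low = df[df["x"] > med], df[df["x"] <= med]
            if len(high) == 0 or len(low) == 0:
                flags[ep] = "group_empty"
            else:
                letter = _two_group_letter(high, low, "B", "C", config.per_feature_alpha) or "A"
        letters.append(letter)
    return EndpointArray("SMC", tuple(letters), layer=layer), flags
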