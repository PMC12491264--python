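"""Tumor-microenvironment (TMC) and immune-infiltrate (TIC) contexture.

Each feature or signature is correlated (Spearman) against deconvoluted
scores for 29 cell-infiltrate types.  Because correlation with expression is
read through the tumor's own polarity, a *presence sign* first converts each
correlation into "the cell type is more (+1) or less (-1) present": for
underexpressed features the raw sign flips.

TMC sums |rho| over significantly correlated, presence-indicating cell types
within each tumor role (anti-tumoral / pro-tumoral / dual); the role with the
largest aggregate wins.  TIC compares a hot score (CD8 T, NK, M1) against a
cold score (M2, Treg), doubling the CD8/NK weight to break near-ties -- the
cytotoxic compartment dominates the hot/cold call.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .association import TNC_UNDER
from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import ValidationError, VocabularyError

TMC_ANTI = 1
TMC_DUAL = 2
TMC_PRO = 3
TMC_NO_DATA = 4

TIC_HOT = 1
TIC_VARIABLE = 2
TIC_COLD = 3
TIC_NO_DATA = 4

TUMOR_ROLES = ("anti_tumoral", "pro_tumoral", "dual")
TIC_ROLES = ("hot_marker", "cold_marker", "other")


@dataclass
class CellCategoryMap:
    """29 cell types with a tumor role and a hot/cold marker role each."""

    tumor_role: dict[str, str]
    tic_role: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.tumor_role) != set(self.tic_role):
            raise ValidationError("tumor_role and tic_role must cover the same cells")
        for cell, role in self.tumor_role.items():
            if role not in TUMOR_ROLES:
                raise VocabularyError(f"unknown tumor role {role!r} for {cell!r}")
        for cell, role in self.tic_role.items():
            if role not in TIC_ROLES:
                raise VocabularyError(f"unknown TIC role {role!r} for {cell!r}")
        hot = {c for c, r in self.tic_role.items() if r == "hot_marker"}
        cold = {c for c, r in self.tic_role.items() if r == "cold_marker"}
        if hot & cold:
            raise ValidationError("hot and cold marker sets must be disjoint")

    @property
    def cells(self) -> frozenset[str]:
        return frozenset(self.tumor_role)

    @property
    def hot_markers(self) -> frozenset[str]:
        return frozenset(c for c, r in self.tic_role.items() if r == "hot_marker")

    @property
    def cold_markers(self) -> frozenset[str]:
        return frozenset(c for c, r in self.tic_role.items() if r == "cold_marker")

    @classmethod
    def from_tsv(cls, path) -> "CellCategoryMap":
        df = pd.read_csv(path, sep="\t")
        return cls(
            tumor_role=dict(zip(df["cell"], df["tumor_role"])),
            tic_role=dict(zip(df["cell"], df["tic_role"])),
        )

    @classmethod
    def default(cls) -> "CellCategoryMap":
        path = importlib.resources.files("multioptosis") / "data" / "cell_categories.tsv"
        return cls.from_tsv(path)


def correlation_profile(
    expression: pd.Series,
    infiltration: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Spearman rho/p of one expression vector against every cell score.

    Rows are cell types; ``significant`` gates on unadjusted p < 0.05.
    """
    common = expression.dropna().index.intersection(infiltration.index)
    x = expression[common].to_numpy(dtype=float)
    rows = []
    for cell in infiltration.columns:
        y = infiltration.loc[common, cell].to_numpy(dtype=float)
        rho, p = stats.spearmanr(x, y)
        rows.append((cell, float(rho), float(p)))
    prof = pd.DataFrame(rows, columns=["cell", "rho", "p"]).set_index("cell")
    prof["significant"] = prof["p"] < config.per_feature_alpha
    return prof


def presence_sign(rho: float, tnc: int) -> int:
    """+1 when the correlation indicates higher cell presence, -1 when lower.

    For underexpressed features (TNC 2) the raw correlation sign inverts;
    overexpressed, unchanged and no-data polarities keep it.
    """
    if rho == 0:
        raise ValidationError("presence undefined for rho = 0")
    sign = 1 if rho > 0 else -1
    return -sign if tnc == TNC_UNDER else sign


def _check_cells(profile: pd.DataFrame, catmap: CellCategoryMap) -> None:
    unknown = set(profile.index) - catmap.cells
    if unknown:
        raise VocabularyError(f"unknown cell type(s): {sorted(unknown)}")


def classify_tmc(
    profile: pd.DataFrame,
    tnc: int,
    catmap: CellCategoryMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> int:
    """Classify tumor-microenvironment contexture from a correlation profile.

    Only significant cells count.  Per tumor role the aggregate is the sum of
    |rho| over cells whose presence sign is +1; the largest aggregate decides
    (1 anti-tumoral, 3 pro-tumoral, 2 dual).  No significant cell, or every
    aggregate zero, yields 4 (no significant data); an exact tie at the top
    is coded dual.
    """
    _check_cells(profile, catmap)
    sig = profile[profile["significant"] & (profile["rho"] != 0)]
    if sig.empty:
        return TMC_NO_DATA
    agg = dict.fromkeys(TUMOR_ROLES, 0.0)
    for cell, row in sig.iterrows():
        if presence_sign(row["rho"], tnc) > 0:
            agg[catmap.tumor_role[cell]] += abs(row["rho"])
    best = max(agg.values())
    if best <= 0:
        return TMC_NO_DATA
    top = [r for r, v in agg.items() if abs(v - best) < config.tie_epsilon]
    if len(top) > 1:
        return TMC_DUAL
    return {"anti_tumoral": TMC_ANTI, "pro_tumoral": TMC_PRO, "dual": TMC_DUAL}[top[0]]


def classify_tic(
    profile: pd.DataFrame,
    tnc: int,
    catmap: CellCategoryMap,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> int:
    """Classify hot/variable/cold immune contexture from the marker cells.

    Hot score sums presence-adjusted significant rho over CD8 T, NK and M1
    markers; cold score over M2 and Treg markers.  Near-ties are re-decided
    with the cytotoxic (CD8/NK) markers weighted x2; a residual tie is
    'variable'.
    """
    markers = catmap.hot_markers | catmap.cold_markers
    missing = markers - set(profile.index)
    if missing:
        raise ValidationError(f"marker cell(s) missing from profile: {sorted(missing)}")
    _check_cells(profile, catmap)
    sig = profile.loc[profile.index.isin(markers)]
    sig = sig[sig["significant"] & (sig["rho"] != 0)]
    if sig.empty:
        return TIC_NO_DATA

    # cytotoxic compartment = hot markers that are not macrophages
    cytotoxic = {c for c in catmap.hot_markers if not c.startswith("Macrophages")}

    def scores(cd8_nk_weight: float) -> tuple[float, float]:
        hot = cold = 0.0
        for cell, row in sig.iterrows():
            adj = presence_sign(row["rho"], tnc) * abs(row["rho"])
            if cell in catmap.hot_markers:
                w = cd8_nk_weight if cell in cytotoxic else 1.0
                hot += w * adj
            else:
                cold += adj
        return hot, cold

    hot, cold = scores(1.0)
    if hot <= 0 and cold <= 0:
        return TIC_NO_DATA
    if abs(hot - cold) < config.tie_epsilon:
        hot, cold = scores(2.0)
        if abs(hot - cold) < config.tie_epsilon:
            return TIC_VARIABLE
    if hot > cold and hot > 0:
        return TIC_HOT
    if cold > hot and cold > 0:
        return TIC_COLD
    return TIC_VARIABLE
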