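"""Summary statistics, tabulations and drug-interaction arithmetic.

All printed percentages and ratios round half-up at the stated precision so
reports regenerate byte-identically from the same inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ENDPOINTS, LAYERS
from .errors import SizeError
from .inventory import RCD_FORMS, RCDInventory

_UNINFORMATIVE_TYPES = {"", "unknown", "undefined", "na", "n/a", "none"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass(frozen=True)
class CohortCountRow:
    cancer_code: str
    n_patients: int
    n_signatures: int

    @property
    def ratio(self) -> float:
        return cohort_ratio(self.n_signatures, self.n_patients)


@dataclass(frozen=True)
class InteractionRow:
    gene: str
    drug: str
    interaction_type: str | None = None


def cohort_ratio(n_signatures: int, n_patients: int) -> float:
    """Signatures per patient, rounded half-up to 2 decimals."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return round_half_up(n_signatures / n_patients, 2)


def cohort_size_correlation(rows: Sequence[CohortCountRow]) -> tuple[float, float]:
    """Spearman rho between cohort size and signature yield across cancers.

    Returns (rho, p); (nan, nan) when the correlation is undefined because
    one margin is constant.
    """
    if len(rows) < 3:
        raise SizeError("need at least 3 cohorts")
    x = np.array([r.n_patients for r in rows], dtype=float)
    y = np.array([r.n_signatures for r in rows], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def summarize_by_omic(signatures: Sequence) -> pd.DataFrame:
    """Per-layer signature tabulation with a totals row.

    Columns: total; risky (B) and protective (C) hazard counts per endpoint;
    Kaplan-Meier poorer-prognosis (non-A) counts per endpoint; TMC
    anti/pro/dual counts; TIC hot/cold/variable counts.  The totals row
    equals the column sums.
    """
    cols: dict[str, dict[str, int]] = {}
    layers_present = list(LAYERS)

    def bucket(layer: str) -> dict[str, int]:
        return cols.setdefault(layer, {})

    for s in signatures:
        b = bucket(s.layer)
        b["total"] = b.get("total", 0) + 1
        for ep, h, k in zip(ENDPOINTS, s.hrc_letters, s.smc_letters):
            if h == "B":
                b[f"risky_{ep}"] = b.get(f"risky_{ep}", 0) + 1
            elif h == "C":
                b[f"protective_{ep}"] = b.get(f"protective_{ep}", 0) + 1
            if k != "A":
                b[f"km_poorer_{ep}"] = b.get(f"km_poorer_{ep}", 0) + 1
        tmc_name = {1: "anti_tumoral", 2: "dual", 3: "pro_tumoral"}.get(s.tmc)
        if tmc_name:
            b[f"tmc_{tmc_name}"] = b.get(f"tmc_{tmc_name}", 0) + 1
        tic_name = {1: "hot", 2: "variable", 3: "cold"}.get(s.tic)
        if tic_name:
            b[f"tic_{tic_name}"] = b.get(f"tic_{tic_name}", 0) + 1

    columns = (
        ["total"]
        + [f"risky_{ep}" for ep in ENDPOINTS]
        + [f"protective_{ep}" for ep in ENDPOINTS]
        + [f"km_poorer_{ep}" for ep in ENDPOINTS]
        + ["tmc_anti_tumoral", "tmc_pro_tumoral", "tmc_dual"]
        + ["tic_hot", "tic_cold", "tic_variable"]
    )
    table = pd.DataFrame(
        [[cols.get(l, {}).get(c, 0) for c in columns] for l in layers_present],
        index=layers_present,
        columns=columns,
    )
    table.loc["total"] = table.sum(axis=0)
    return table


def drug_interaction_summary(
    genes: Iterable[str], interactions: Iterable[InteractionRow]
) -> tuple[int, int, dict[str, int]]:
    """(genes with interactions, interaction count, counts by type).

    Rows with missing/unknown/undefined interaction types are excluded
    before counting, duplicates of (gene, drug, type) count once, and only
    interactions for the queried genes are considered.
    """
    query = set(genes)
    seen: set[tuple[str, str, str]] = set()
    by_type: dict[str, int] = {}
    genes_hit: set[str] = set()
    for row in interactions:
        itype = (row.interaction_type or "").strip().lower()
        if itype in _UNINFORMATIVE_TYPES:
            continue
        if row.gene not in query:
            continue
        key = (row.gene, row.drug, itype)
        if key in seen:
            continue
        seen.add(key)
        genes_hit.add(row.gene)
        by_type[itype] = by_type.get(itype, 0) + 1
    return len(genes_hit), len(seen), by_type


def inventory_summary(inventory: RCDInventory) -> pd.DataFrame:
    """Per-form gene counts plus multi-form and apoptosis-only fractions.

    Percentages print to one decimal, rounded half-up.
    """
    n = len(inventory)
    if n == 0:
        return pd.DataFrame(columns=["count", "pct"])
    rows = {}
    for form in RCD_FORMS:
        cnt = sum(1 for forms in inventory.membership.values() if form in forms)
        rows[form] = cnt
    multi = sum(1 for forms in inventory.membership.values() if len(forms) >= 2)
    apoptosis_only = sum(
        1 for forms in inventory.membership.values() if forms == frozenset({"apoptosis"})
    )
    rows["multi_form"] = multi
    rows["apoptosis_only"] = apoptosis_only
    df = pd.DataFrame({"count": rows})
    df["pct"] = [pct(c, n) for c in df["count"]]
    return df
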