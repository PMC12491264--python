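"""Clinical-meaningfulness ranking and independent meta-Z validation.

Ranks are additive: each identifier component contributes an integer from a
configurable map, plus a capped bonus per extra member.  The default map
encodes the ordering intuitions of the framework -- hot immune infiltrates,
anti-tumoral microenvironments and all-endpoint survival signals rank
highest -- and is fully user-overridable via YAML/JSON.

Validation queries an external gene x cancer table of prognostic meta-Z
scores (meta-analytic z for the association of expression with overall
survival; |Z| > 3.09 ~ two-sided p < 0.001).  Positive Z means poor
prognosis.  Multi-gene signatures take the median across member genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import RankConfigurationError

VALIDATED = "validated"
NOT_VALIDATED = "not_validated"
MISSING = "missing"


def _non_a_count(letters: Iterable[str]) -> int:
    return sum(1 for l in letters if l != "A")


@dataclass
class RankMap:
    """Integer contributions per identifier component value.

    ``hrc``/``smc`` map 4-letter arrays to integers; by default each non-A
    letter contributes 1.  ``member_bonus`` adds 1 per member beyond the
    first, capped at ``member_cap``.
    """

    tic: dict[int, int] = field(
        default_factory=lambda: {1: 3, 2: 2, 3: 1, 4: 0}  # hot > variable > cold
    )
    tmc: dict[int, int] = field(
        default_factory=lambda: {1: 3, 2: 2, 3: 1, 4: 0}  # anti > dual > pro
    )
    tnc: dict[int, int] = field(
        default_factory=lambda: {0: 0, 1: 0, 2: 1, 3: 1}  # informative polarity
    )
    member_bonus: int = 1
    member_cap: int = 5

    def letters_contribution(self, letters: Iterable[str]) -> int:
        return _non_a_count(letters)

    def component(self, name: str, value: int) -> int:
        table = getattr(self, name)
        if value not in table:
            raise RankConfigurationError(f"no rank contribution for {name}={value!r}")
        return table[value]

    @classmethod
    def from_file(cls, path) -> "RankMap":
        text = open(path).read()
        raw = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        ) or {}
        kwargs = {}
        for key in ("tic", "tmc", "tnc"):
            if key in raw:
                kwargs[key] = {int(k): int(v) for k, v in raw[key].items()}
        for key in ("member_bonus", "member_cap"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)


def rank_signature(record, rank_map: RankMap) -> int:
    """Sum of component contributions for a fully annotated signature.

    ``record`` needs attributes ``tic``, ``tmc``, ``tnc``, ``hrc_letters``,
    ``smc_letters`` and ``members``.  Deterministic and monotone in every
    single component's contribution.
    """
    r = 0
    r += rank_map.component("tic", record.tic)
    r += rank_map.component("tmc", record.tmc)
    r += rank_map.component("tnc", record.tnc)
    r += rank_map.letters_contribution(record.hrc_letters)
    r += rank_map.letters_contribution(record.smc_letters)
    extra = max(0, len(record.members) - 1)
    r += rank_map.member_bonus * min(extra, rank_map.member_cap)
    return r


_TIE_ORDER_DOC = "(rank, member count, TIC, TMC, SMC, HRC), then identifier string"


def _tie_key(sig) -> tuple:
    """Descending-preference sort key implementing the tie-break chain.

    After rank, ties prefer more members, then better (hot/anti) TIC and TMC
    -- lower codes are better there -- then more informative SMC and HRC
    arrays (more non-A letters), then ascending identifier for determinism.
    """
    return (
        -sig.rank,
        -len(sig.members),
        sig.tic,
        sig.tmc,
        -_non_a_count(sig.smc_letters),
        -_non_a_count(sig.hrc_letters),
        sig.identifier,
    )


def select_representatives(
    signatures: Sequence, mode: str = "per_rcd_form"
) -> list:
    """Best signature per group (RCD form or omic layer) under the tie chain.

    In ``per_omic_feature`` mode every omic layer present in *no* selected
    signature is back-filled with its own best-ranked signature, so the
    selection covers all layers seen in the input.  Output is ordered by
    descending rank.
    """
    if mode not in ("per_rcd_form", "per_omic_feature"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if not signatures:
        return []
    groups: dict[str, list] = {}
    for sig in signatures:
        if mode == "per_rcd_form":
            for form in sig.rcd_forms:
                groups.setdefault(form, []).append(sig)
        else:
            groups.setdefault(sig.layer, []).append(sig)
    chosen: dict[str, object] = {}
    for key, members in groups.items():
        chosen[key] = min(members, key=_tie_key)
    selected = {id(s): s for s in chosen.values()}
    if mode == "per_omic_feature":
        covered = {s.layer for s in selected.values()}
        for layer in sorted({s.layer for s in signatures} - covered):
            best = min((s for s in signatures if s.layer == layer), key=_tie_key)
            selected[id(best)] = best
    return sorted(selected.values(), key=_tie_key)


class MetaZTable:
    """Gene x cancer matrix of prognostic meta-Z scores; NaN marks missing."""

    def __init__(self, values: pd.DataFrame):
        if not np.isfinite(values.fillna(0.0).to_numpy()).all():
            raise ValueError("meta-Z table must contain finite values or NaN")
        self.values = values

    def lookup(self, gene: str, cancer_code: str) -> float:
        """Meta-Z for (gene, cancer); NaN when either key is absent."""
        if gene not in self.values.index or cancer_code not in self.values.columns:
            return float("nan")
        return float(self.values.loc[gene, cancer_code])

    @property
    def cancer_codes(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path) -> "MetaZTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot(index="gene", columns="cancer", values="meta_z")
        return cls(wide)

    def to_tsv(self, path) -> None:
        long = (
            self.values.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="cancer", value_name="meta_z")
            .dropna(subset=["meta_z"])
        )
        long.to_csv(path, sep="\t", index=False)


def signature_metaz(
    member_genes: Sequence[str], cancer_code: str, table: MetaZTable
) -> tuple[float, int]:
    """Median meta-Z over the member genes found in the table.

    Returns ``(meta_z, n_excluded)``; meta_z is NaN when every gene is
    missing.  Single-gene signatures return that gene's score directly.
    """
    zs = [table.lookup(g, cancer_code) for g in member_genes]
    found = [z for z in zs if not np.isnan(z)]
    excluded = len(zs) - len(found)
    if not found:
        return float("nan"), excluded
    return float(np.median(found)), excluded


def expected_direction_from_hrc(hrc_letters: Sequence[str]) -> str | None:
    """Map an HRC array to the prognosis direction meta-Z should confirm.

    A risky OS call dominates; likewise protective OS.  Without an OS signal
    the majority across endpoints decides; a tie or an all-A array leaves the
    direction unresolved (validation is skipped with reason).
    """
    os_letter = hrc_letters[3]
    if os_letter == "B":
        return "poor"
    if os_letter == "C":
        return "favorable"
    b = sum(1 for l in hrc_letters if l == "B")
    c = sum(1 for l in hrc_letters if l == "C")
    if b > c:
        return "poor"
    if c > b:
        return "favorable"
    return None


def validate_signature(
    metaz: float,
    expected_direction: str,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> str:
    """Verdict against |meta-Z| > 3.09 with matching prognosis direction."""
    if expected_direction not in ("poor", "favorable"):
        raise ValueError(f"unknown direction {expected_direction!r}")
    if metaz is None or np.isnan(metaz):
        return MISSING
    if abs(metaz) <= config.metaz_threshold:
        return NOT_VALIDATED
    sign_ok = metaz > 0 if expected_direction == "poor" else metaz < 0
    return VALIDATED if sign_ok else NOT_VALIDATED
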