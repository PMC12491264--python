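"""The 11-component signature identifier codec.

Every signature is addressed by a dotted string

    CTAB-GSI.GFC.PFC.SCS.TNC.HRC.SMC.TMC.TIC.RCD

e.g. ``KIRP-107.3.2.N.1.44.44.1.1.2``: cancer type KIRP, 107th signature in
that cohort, omic layer CNV (3), phenotype MSI (2), negative correlation,
unchanged tumor-vs-normal expression, hazard array coded 44 (risky on all
four endpoints), survival array coded 44, anti-tumoral microenvironment (1),
hot immune infiltrate (1), two shared RCD forms.

The mapping between 4-letter endpoint arrays (DSS, DFI, PFI, OS over
A/B/C/D) and integer codes is data-driven.  Two tables ship with the
package: ``paper_anchors`` (default), a lexicographic enumeration with the
published code assignments swapped into place, and ``fallback``, the plain
lexicographic enumeration over {A,B,C,D} (codes 0-255).  Correctness of
encode/decode is defined relative to the loaded table, which is validated as
a bijection at load time.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass

import pandas as pd

from .config import ENDPOINTS, LAYERS, PHENOTYPES
from .errors import (
    IdentifierParseError,
    UnmappedArrayError,
    UnmappedCodeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GFC_NAMES = {
    1: "Protein expression",
    2: "Mutation",
    3: "CNV",
    4: "miRNA expression",
    5: "Transcript expression",
    6: "mRNA expression",
    7: "CpG methylation",
}
LAYER_TO_GFC = {layer: i + 1 for i, layer in enumerate(LAYERS)}
GFC_TO_LAYER = {v: k for k, v in LAYER_TO_GFC.items()}

PFC_NAMES = {1: "TMB", 2: "MSI", 3: "TSM"}
PHENOTYPE_TO_PFC = {ph: i + 1 for i, ph in enumerate(PHENOTYPES)}

TNC_NAMES = {0: "no data", 1: "unchanged", 2: "underexpressed", 3: "overexpressed"}
TMC_NAMES = {1: "anti-tumoral", 2: "dual", 3: "pro-tumoral", 4: "no significant data"}
TIC_NAMES = {1: "hot", 2: "variable", 3: "cold", 4: "no significant data"}
HRC_LETTER_NAMES = {"A": "no effect", "B": "risky", "C": "protective"}
SMC_LETTER_NAMES = {
    "continuous": {"A": "NS", "B": "High", "C": "Low"},
    "mutation": {"A": "NS", "B": "MT", "C": "WT"},
    "cnv": {"A": "NS", "B": "Deleted", "C": "Duplicated", "D": "Deleted/Duplicated"},
}


class ArrayCodeTable:
    """Bijection between 4-letter endpoint arrays and integer codes."""

    def __init__(self, mapping: dict[str, int], name: str = "custom"):
        self.name = name
        self._enc = dict(mapping)
        for arr in self._enc:
            if not re.fullmatch(r"[ABCD]{4}", arr):
                raise ValidationError(f"malformed array {arr!r}")
        codes = list(self._enc.values())
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate codes in array table")
        if len(set(self._enc)) != len(self._enc):
            raise ValidationError("duplicate arrays in array table")
        self._dec = {c: a for a, c in self._enc.items()}
        logger.info("array code table %r active (%d entries)", name, len(self._enc))

    def __len__(self) -> int:
        return len(self._enc)

    @property
    def arrays(self) -> list[str]:
        return list(self._enc)

    def encode(self, letters) -> int:
        arr = "".join(letters)
        if arr not in self._enc:
            raise UnmappedArrayError(f"array {arr!r} not in table {self.name!r}")
        return self._enc[arr]

    def decode(self, code: int) -> tuple[str, str, str, str]:
        if code not in self._dec:
            raise UnmappedCodeError(f"code {code!r} not in table {self.name!r}")
        return tuple(self._dec[code])

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "ArrayCodeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["array"], df["code"].astype(int))), name or str(path))

    @classmethod
    def load_packaged(cls, which: str = "paper_anchors") -> "ArrayCodeTable":
        fname = {
            "paper_anchors": "array_codes_paper_anchors.tsv",
            "fallback": "array_codes_fallback.tsv",
        }[which]
        path = importlib.resources.files("multioptosis") / "data" / fname
        return cls.from_tsv(path, name=which)


def encode_endpoint_array(letters, table: ArrayCodeTable) -> int:
    return table.encode(letters)


def decode_endpoint_array(code: int, table: ArrayCodeTable) -> tuple[str, str, str, str]:
    return table.decode(code)


@dataclass(frozen=True)
class IdentifierComponents:
    ctab: str
    gsi: int
    gfc: int
    pfc: int
    scs: str
    tnc: int
    hrc_code: int
    smc_code: int
    tmc: int
    tic: int
    rcd: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z]{3,4}", self.ctab):
            raise ValidationError(f"ctab must be 3-4 uppercase letters, got {self.ctab!r}")
        checks = [
            ("gsi", self.gsi, 1, 9999),
            ("gfc", self.gfc, 1, 7),
            ("pfc", self.pfc, 1, 3),
            ("tnc", self.tnc, 0, 3),
            ("hrc_code", self.hrc_code, 0, 10**9),
            ("smc_code", self.smc_code, 0, 10**9),
            ("tmc", self.tmc, 1, 4),
            ("tic", self.tic, 1, 4),
            ("rcd", self.rcd, 1, 25),
        ]
        for name, val, lo, hi in checks:
            if not isinstance(val, (int,)) or isinstance(val, bool):
                raise ValidationError(f"{name} must be an integer, got {val!r}")
            if not lo <= val <= hi:
                raise ValidationError(f"{name}={val} out of range [{lo}, {hi}]")
        if self.scs not in ("P", "N"):
            raise ValidationError(f"scs must be 'P' or 'N', got {self.scs!r}")


def format_identifier(c: IdentifierComponents) -> str:
    """Canonical dotted string for valid components."""
    return (
        f"{c.ctab}-{c.gsi}.{c.gfc}.{c.pfc}.{c.scs}.{c.tnc}"
        f".{c.hrc_code}.{c.smc_code}.{c.tmc}.{c.tic}.{c.rcd}"
    )


_IDENT_RE = re.compile(
    r"^([A-Z]{3,4})-(\d{1,4})\.\s*(\d)\.\s*(\d)\.\s*([PN])\.\s*(\d)"
    r"\.\s*(\d+)\.\s*(\d+)\.\s*(\d)\.\s*(\d)\.\s*(\d{1,2})$"
)


def parse_identifier(s: str) -> IdentifierComponents:
    """Parse a canonical identifier (spaces after dots are tolerated)."""
    m = _IDENT_RE.match(s.strip())
    if not m:
        raise IdentifierParseError(
            f"identifier {s!r} does not match CTAB-GSI.GFC.PFC.SCS.TNC.HRC.SMC.TMC.TIC.RCD"
        )
    ctab, gsi, gfc, pfc, scs, tnc, hrc, smc, tmc, tic, rcd = m.groups()
    return IdentifierComponents(
        ctab=ctab,
        gsi=int(gsi),
        gfc=int(gfc),
        pfc=int(pfc),
        scs=scs,
        tnc=int(tnc),
        hrc_code=int(hrc),
        smc_code=int(smc),
        tmc=int(tmc),
        tic=int(tic),
        rcd=int(rcd),
    )


def interpret_identifier(s: str, table: ArrayCodeTable | None = None) -> str:
    """Plain-text report explaining each identifier component."""
    if table is None:
        table = ArrayCodeTable.load_packaged()
    c = parse_identifier(s)
    layer = GFC_TO_LAYER[c.gfc]
    smc_style = "cnv" if layer == "cnv" else ("mutation" if layer == "mutation" else "continuous")
    lines = [
        f"Signature identifier: {format_identifier(c)}",
        f"  Cancer type (CTAB): {c.ctab}",
        f"  Signature number within cohort (GSI): {c.gsi}",
        f"  Omic layer (GFC {c.gfc}): {GFC_NAMES[c.gfc]}",
        f"  Phenotype (PFC {c.pfc}): {PFC_NAMES[c.pfc]}",
        f"  Correlation sign (SCS): {'positive' if c.scs == 'P' else 'negative'}",
        f"  Tumor vs non-tumor expression (TNC {c.tnc}): {TNC_NAMES[c.tnc]}",
    ]
    for label, code, names in (
        ("Hazard contexture (HRC", c.hrc_code, None),
        ("Survival contexture (SMC", c.smc_code, None),
    ):
        try:
            letters = table.decode(code)
        except UnmappedCodeError:
            lines.append(f"  {label} {code}): unmapped code in table {table.name!r}")
            continue
        if label.startswith("Hazard"):
            per_ep = ", ".join(
                f"{ep}={HRC_LETTER_NAMES.get(l, l)}" for ep, l in zip(ENDPOINTS, letters)
            )
        else:
            names_map = SMC_LETTER_NAMES[smc_style]
            per_ep = ", ".join(
                f"{ep}={names_map.get(l, l + ' (unmapped letter for this layer)')}"
                for ep, l in zip(ENDPOINTS, letters)
            )
        lines.append(f"  {label} {code}): {''.join(letters)} -> {per_ep}")
    lines += [
        f"  Tumor microenvironment (TMC {c.tmc}): {TMC_NAMES[c.tmc]}",
        f"  Immune infiltrate (TIC {c.tic}): {TIC_NAMES[c.tic]}",
        f"  Number of shared RCD forms (RCD): {c.rcd}",
        f"  [array table: {table.name}]",
    ]
    return "\n".join(lines)
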