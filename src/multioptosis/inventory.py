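"""Gene <-> regulated-cell-death (RCD) form membership.

The multi-optosis framework treats 25 genetically controlled cell-death
programs jointly.  Gene membership in a form is term-based tagging stored as
data: it records that a gene has been associated with the form in the
literature and does *not* imply direct functional or causative involvement.
Signatures inherit form sets at the gene level, so transcript, miRNA, protein
and methylation features carry their parent gene's forms.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError, VocabularyError

#: The closed vocabulary of the 25 regulated-cell-death forms.
RCD_FORMS: tuple[str, ...] = (
    "alkaliptosis",
    "anoikis",
    "apoptosis",
    "autophagy",
    "autosis",
    "cellular_senescence",
    "cuproptosis",
    "disulfidptosis",
    "efferocytosis",
    "entosis",
    "erebosis",
    "ferroptosis",
    "immunogenic_cell_death",
    "lysosome_dependent_cell_death",
    "methuosis",
    "mitochondrial_permeability_transition",
    "mitoptosis",
    "mitotic_catastrophe",
    "necroptosis",
    "necrosis",
    "netosis",
    "oxeiptosis",
    "paraptosis",
    "parthanatos",
    "pyroptosis",
)

RCD_FORM_SET = frozenset(RCD_FORMS)

MODALITY_RCD_SPECIFIC = "rcd_specific"
MODALITY_MULTI_MODULAR = "multi_modular"


@dataclass(frozen=True)
class RCDFormSet:
    """A subset of the 25-form vocabulary attached to a gene or signature."""

    forms: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.forms - RCD_FORM_SET
        if unknown:
            raise VocabularyError(f"unknown RCD form(s): {sorted(unknown)}")

    @property
    def count(self) -> int:
        return len(self.forms)

    def __iter__(self):
        return iter(sorted(self.forms))

    def __len__(self) -> int:
        return len(self.forms)


@dataclass
class RCDInventory:
    """Maps every gene to a non-empty subset of the 25 RCD forms."""

    membership: dict[str, frozenset[str]] = field(default_factory=dict)
    forms: frozenset[str] = RCD_FORM_SET

    def __post_init__(self) -> None:
        for gene, forms in self.membership.items():
            if not forms:
                raise ValidationError(f"gene {gene!r} has an empty form set")
            unknown = set(forms) - self.forms
            if unknown:
                raise VocabularyError(
                    f"gene {gene!r} carries unknown form(s): {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.membership)

    def __contains__(self, gene: str) -> bool:
        return gene in self.membership

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.membership[gene]

    @property
    def genes(self) -> list[str]:
        return list(self.membership)

    def to_tsv(self, path) -> None:
        """Write a two-column TSV (gene, semicolon-joined forms)."""
        df = pd.DataFrame(
            {
                "gene": list(self.membership),
                "forms": [";".join(sorted(v)) for v in self.membership.values()],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, RCDInventory) and self.membership == other.membership


def load_inventory(path) -> RCDInventory:
    """Parse a two-column (gene, semicolon-joined forms) TSV.

    Duplicate gene rows are merged by union of their form sets.  Unknown form
    tokens and empty form lists raise immediately, naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "forms"}.issubset(df.columns):
        raise ValidationError("inventory TSV requires 'gene' and 'forms' columns")
    membership: dict[str, set[str]] = {}
    for gene, raw in zip(df["gene"], df["forms"]):
        tokens = [t.strip() for t in str(raw).split(";") if t.strip()]
        if not tokens:
            raise ValidationError(f"gene {gene!r} has an empty form list")
        for tok in tokens:
            if tok not in RCD_FORM_SET:
                raise VocabularyError(f"unknown RCD form token {tok!r} for gene {gene!r}")
        membership.setdefault(gene, set()).update(tokens)
    return RCDInventory({g: frozenset(v) for g, v in membership.items()})


def shared_forms(genes: Iterable[str], inventory: RCDInventory) -> RCDFormSet:
    """Intersection of the form sets of ``genes``.

    An empty intersection is returned explicitly as an ``RCDFormSet`` with
    ``count == 0`` rather than silently dropped; callers that require a
    non-empty set must check ``count``.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("shared_forms requires at least one gene")
    missing = [g for g in genes if g not in inventory]
    if missing:
        raise KeyError(f"gene(s) not in inventory: {missing}")
    common = frozenset.intersection(*(inventory[g] for g in genes))
    # bypass the non-empty guard of RCDFormSet deliberately: an empty
    # intersection is a reportable outcome, not a vocabulary violation
    obj = object.__new__(RCDFormSet)
    object.__setattr__(obj, "forms", common)
    return obj


def classify_modularity(form_set: RCDFormSet) -> str:
    """``rcd_specific`` for a single shared form, ``multi_modular`` for >= 2."""
    if form_set.count == 0:
        raise ValidationError("cannot classify an empty RCD form set")
    return MODALITY_RCD_SPECIFIC if form_set.count == 1 else MODALITY_MULTI_MODULAR


def packaged_forms_path():
    """Path to the packaged 25-form vocabulary file."""
    return importlib.resources.files("multioptosis.data") / "rcd_forms.txt"


def gene_form_sets(
    genes: Iterable[str], inventory: RCDInventory
) -> Mapping[str, frozenset[str]]:
    return {g: inventory[g] for g in genes}
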