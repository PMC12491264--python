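"""Grouping annotated features into mono-omic, multi-phenotypic signatures.

A signature collects features from a single omic layer of one cancer type
that share *every* phenotypic code: correlation sign, tumor-vs-normal
polarity, hazard (HRC) and survival (SMC) endpoint arrays, microenvironment
(TMC) and immune (TIC) contexture, and the identical gene-level RCD form
set.  Features with divergent patterns split into separate signatures.
Composite scores are member-wise sums re-evaluated with the same Cox /
log-rank machinery; member-level codes stay authoritative for the
identifier, and composite disagreement is recorded, not silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .association import AssociationRecord, EndpointArray, fit_hrc, fit_smc
from .config import AnalysisConfig, DEFAULT_CONFIG
from .errors import ValidationError
from .inventory import RCDInventory
from .nomenclature import (
    ArrayCodeTable,
    IdentifierComponents,
    LAYER_TO_GFC,
    PHENOTYPE_TO_PFC,
    format_identifier,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A genome-wide-significant feature with its complete phenotypic codes."""

    association: AssociationRecord
    gene: str
    tnc: int
    hrc: EndpointArray
    smc: EndpointArray
    tmc: int
    tic: int
    form_set: frozenset[str]

    @property
    def feature_id(self) -> str:
        return self.association.feature_id


def annotate_feature(
    association: AssociationRecord,
    gene: str,
    tnc: int,
    hrc: EndpointArray,
    smc: EndpointArray,
    tmc: int,
    tic: int,
    form_set: frozenset[str],
) -> FeatureAnnotation:
    """Join the screening record with its contexture codes.

    Only genome-wide-significant associations may enter signatures; anything
    else is rejected with the reason in the error message.  Missing
    contexture is carried as the no-data codes, never dropped.
    """
    if not association.significant:
        raise ValidationError(
            f"feature {association.feature_id!r} rejected: padj="
            f"{association.padj:.3g} is not genome-wide significant"
        )
    if not form_set:
        raise ValidationError(f"feature {association.feature_id!r} has no RCD forms")
    return FeatureAnnotation(
        association=association,
        gene=gene,
        tnc=tnc,
        hrc=hrc,
        smc=smc,
        tmc=tmc,
        tic=tic,
        form_set=frozenset(form_set),
    )


@dataclass(frozen=True)
class GroupingKey:
    cancer_code: str
    layer: str
    phenotype: str
    scs: str
    tnc: int
    hrc_letters: tuple[str, str, str, str]
    smc_letters: tuple[str, str, str, str]
    tmc: int
    tic: int
    rcd_forms: frozenset[str]

    @classmethod
    def of(cls, ann: FeatureAnnotation) -> "GroupingKey":
        a = ann.association
        return cls(
            cancer_code=a.cancer_code,
            layer=a.layer,
            phenotype=a.phenotype,
            scs=a.scs,
            tnc=ann.tnc,
            hrc_letters=ann.hrc.letters,
            smc_letters=ann.smc.letters,
            tmc=ann.tmc,
            tic=ann.tic,
            rcd_forms=ann.form_set,
        )


@dataclass
class SignatureRecord:
    """One emitted signature with its identifier components and members."""

    key: GroupingKey
    gsi: int
    members: list[str]
    member_genes: list[str]
    annotations: list[FeatureAnnotation] = field(repr=False, default_factory=list)
    hrc_code: int | None = None
    smc_code: int | None = None
    identifier: str = ""
    rank: int | None = None
    composite_hrc: EndpointArray | None = None
    composite_smc: EndpointArray | None = None
    composite_consistent: bool | None = None

    # convenience accessors used by ranking and reporting
    @property
    def cancer_code(self) -> str:
        return self.key.cancer_code

    @property
    def layer(self) -> str:
        return self.key.layer

    @property
    def phenotype(self) -> str:
        return self.key.phenotype

    @property
    def scs(self) -> str:
        return self.key.scs

    @property
    def tnc(self) -> int:
        return self.key.tnc

    @property
    def hrc_letters(self) -> tuple[str, ...]:
        return self.key.hrc_letters

    @property
    def smc_letters(self) -> tuple[str, ...]:
        return self.key.smc_letters

    @property
    def tmc(self) -> int:
        return self.key.tmc

    @property
    def tic(self) -> int:
        return self.key.tic

    @property
    def rcd_forms(self) -> frozenset[str]:
        return self.key.rcd_forms

    @property
    def rcd_count(self) -> int:
        return len(self.key.rcd_forms)

    def components(self) -> IdentifierComponents:
        if self.hrc_code is None or self.smc_code is None:
            raise ValidationError("endpoint-array codes not assigned yet")
        return IdentifierComponents(
            ctab=self.cancer_code,
            gsi=self.gsi,
            gfc=LAYER_TO_GFC[self.layer],
            pfc=PHENOTYPE_TO_PFC[self.phenotype],
            scs=self.scs,
            tnc=self.tnc,
            hrc_code=self.hrc_code,
            smc_code=self.smc_code,
            tmc=self.tmc,
            tic=self.tic,
            rcd=self.rcd_count,
        )


def group_signatures(
    annotations: list[FeatureAnnotation],
    inventory: RCDInventory | None = None,
    table: ArrayCodeTable | None = None,
) -> list[SignatureRecord]:
    """Partition annotations by exact key equality into signatures.

    Every annotation lands in exactly one signature.  GSI numbering is
    deterministic: within a cancer type, signatures sort lexicographically
    by (layer, phenotype, first member id) and are numbered from 1, so
    shuffled input yields identical output.  The annotations already carry
    their gene-level form sets, so the inventory argument is accepted for
    symmetry with the rest of the API but only used to sanity-check genes
    when provided.
    """
    if inventory is not None:
        for ann in annotations:
            if ann.gene not in inventory:
                raise KeyError(f"gene {ann.gene!r} not in inventory")
    if table is None:
        table = ArrayCodeTable.load_packaged()
    buckets: dict[GroupingKey, list[FeatureAnnotation]] = {}
    for ann in annotations:
        buckets.setdefault(GroupingKey.of(ann), []).append(ann)

    prelim = []
    for key, anns in buckets.items():
        anns = sorted(anns, key=lambda a: a.feature_id)
        members = [a.feature_id for a in anns]
        prelim.append((key, anns, members))

    out: list[SignatureRecord] = []
    by_cancer: dict[str, list] = {}
    for key, anns, members in prelim:
        by_cancer.setdefault(key.cancer_code, []).append((key, anns, members))
    for cancer in sorted(by_cancer):
        rows = sorted(
            by_cancer[cancer], key=lambda t: (t[0].layer, t[0].phenotype, t[2][0])
        )
        for gsi, (key, anns, members) in enumerate(rows, start=1):
            rec = SignatureRecord(
                key=key,
                gsi=gsi,
                members=members,
                member_genes=[a.gene for a in anns],
                annotations=anns,
                hrc_code=table.encode(key.hrc_letters),
                smc_code=table.encode(key.smc_letters),
            )
            rec.identifier = format_identifier(rec.components())
            out.append(rec)
    return out


def composite_score(
    signature: SignatureRecord,
    dataset,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Member-wise sum of the signature's (companion) expression values.

    Layers under bi-layer annotation contribute the companion mRNA values of
    each member's gene locus.  A sample missing any member value is missing
    from the composite.  With ``config.standardize_composite`` members are
    z-scored before summing.
    """
    layer = signature.layer
    parts = []
    for fid in signature.members:
        if fid not in dataset.layers[layer].values.index:
            raise KeyError(f"member {fid!r} absent from layer {layer!r}")
        vals = dataset.companion_values(layer, fid)
        if config.standardize_composite:
            sd = vals.std()
            vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        parts.append(vals)
    total = parts[0].copy()
    for p in parts[1:]:
        total = total + p  # NaN propagates per sample
    return total


def evaluate_composite(
    signature: SignatureRecord,
    dataset,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SignatureRecord:
    """Re-run Cox and Kaplan-Meier on the composite score.

    The composite is continuous by construction, so the Kaplan-Meier stage
    uses the High/Low median split regardless of the native layer.  The
    consistency flag records whether the composite arrays reproduce the
    member-shared arrays; on disagreement the member-level codes remain
    authoritative and a warning is logged.
    """
    score = composite_score(signature, dataset, config)
    survival = dataset.phenotypes.survival
    hrc, _ = fit_hrc(score, survival, config)
    smc, _ = fit_smc(score, "mrna", survival, config)
    consistent = (
        hrc.letters == signature.key.hrc_letters
        and smc.letters == signature.key.smc_letters
    )
    if not consistent:
        logger.warning(
            "signature %s: composite arrays %s/%s diverge from member arrays %s/%s",
            signature.identifier or signature.gsi,
            "".join(hrc.letters),
            "".join(smc.letters),
            "".join(signature.key.hrc_letters),
            "".join(signature.key.smc_letters),
        )
    signature.composite_hrc = hrc
    signature.composite_smc = smc
    signature.composite_consistent = consistent
    return signature


def signatures_frame(signatures: list[SignatureRecord]) -> pd.DataFrame:
    """One row per signature: identifier components, members, rank."""
    rows = []
    for s in signatures:
        rows.append(
            {
                "identifier": s.identifier,
                "cancer": s.cancer_code,
                "gsi": s.gsi,
                "layer": s.layer,
                "phenotype": s.phenotype,
                "scs": s.scs,
                "tnc": s.tnc,
                "hrc": "".join(s.hrc_letters),
                "hrc_code": s.hrc_code,
                "smc": "".join(s.smc_letters),
                "smc_code": s.smc_code,
                "tmc": s.tmc,
                "tic": s.tic,
                "rcd_count": s.rcd_count,
                "rcd_forms": ";".join(sorted(s.rcd_forms)),
                "members": ";".join(s.members),
                "member_count": len(s.members),
                "rank": s.rank,
                "composite_consistent": s.composite_consistent,
            }
        )
    return pd.DataFrame(rows)


def members_frame(signatures: list[SignatureRecord]) -> pd.DataFrame:
    rows = []
    for s in signatures:
        for fid, gene in zip(s.members, s.member_genes):
            rows.append(
                {"identifier": s.identifier, "feature": fid, "gene": gene,
                 "cancer": s.cancer_code, "layer": s.layer}
            )
    return pd.DataFrame(rows)
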