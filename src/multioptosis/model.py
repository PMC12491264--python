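"""Model/Results facade tying the pipeline together.

``MultiOptosisModel`` wraps one or more synthetic or user-supplied cohorts;
``fit()`` runs the full discovery pipeline -- genome-wide Spearman screens
with Holm-Bonferroni control, tumor-vs-normal polarity, per-endpoint Cox and
Kaplan-Meier contexture, microenvironment and immune classification,
signature grouping, identifier encoding and ranking -- and returns a
``MultiOptosisResults`` carrying the estimates, diagnostics and summaries.

    >>> cfg = CohortConfig(cancer_code="ACC", seed=1, ...)
    >>> ds = generate_pan_cancer_dataset(cfg)
    >>> res = MultiOptosisModel(ds).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .association import (
    TNC_NO_DATA,
    classify_tnc,
    fit_hrc,
    fit_smc,
    spearman_screen,
    tumor_normal_screen,
)
from .config import AnalysisConfig, DEFAULT_CONFIG, LAYERS, PHENOTYPES
from .contexture import CellCategoryMap, classify_tic, classify_tmc, correlation_profile
from .errors import ValidationError
from .nomenclature import ArrayCodeTable
from .ranking import (
    MetaZTable,
    RankMap,
    expected_direction_from_hrc,
    rank_signature,
    select_representatives,
    signature_metaz,
    validate_signature,
)
from .reporting import CohortCountRow, cohort_size_correlation, summarize_by_omic
from .signatures import (
    FeatureAnnotation,
    SignatureRecord,
    annotate_feature,
    evaluate_composite,
    group_signatures,
    members_frame,
    signatures_frame,
)
from .synthetic import PanCancerDataset

logger = logging.getLogger(__name__)


class MultiOptosisModel:
    """Pan-cancer multi-omic RCD signature discovery model.

    Parameters
    ----------
    datasets
        One ``PanCancerDataset`` or a sequence of them (one per cancer type).
    config
        Screening and annotation thresholds.
    cell_map, code_table, rank_map
        Cell-role assignments, endpoint-array code table and rank map;
        packaged defaults are used when omitted.
    """

    def __init__(
        self,
        datasets: PanCancerDataset | Sequence[PanCancerDataset],
        config: AnalysisConfig | None = None,
        cell_map: CellCategoryMap | None = None,
        code_table: ArrayCodeTable | None = None,
        rank_map: RankMap | None = None,
    ):
        if isinstance(datasets, PanCancerDataset):
            datasets = [datasets]
        self.datasets = list(datasets)
        codes = [d.cancer_code for d in self.datasets]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate cancer codes across datasets")
        self.config = config or DEFAULT_CONFIG
        self.cell_map = cell_map or CellCategoryMap.default()
        self.code_table = code_table or ArrayCodeTable.load_packaged()
        self.rank_map = rank_map or RankMap()

    def fit(self, evaluate_composites: bool = True) -> "MultiOptosisResults":
        """Run the pipeline end-to-end and return the results object."""
        all_records = []
        excluded: dict[str, str] = {}
        annotations: list[FeatureAnnotation] = []
        for ds in self.datasets:
            tnc_tables = {
                layer: tumor_normal_screen(
                    ds.layers[layer].values, ds.normals[layer].values
                )
                for layer in ds.normals
            }
            for layer in LAYERS:
                if layer not in ds.layers:
                    continue
                mat = ds.layers[layer]
                for phenotype in PHENOTYPES:
                    screen = spearman_screen(
                        mat.values,
                        ds.phenotypes.indices[phenotype],
                        self.config,
                        layer=layer,
                        cancer_code=ds.cancer_code,
                        phenotype=phenotype,
                    )
                    for fid, reason in screen.excluded.items():
                        excluded[f"{ds.cancer_code}/{layer}/{phenotype}/{fid}"] = reason
                    all_records.extend(screen.records)
                    for rec in screen.records:
                        if rec.significant:
                            annotations.append(self._annotate(ds, rec, tnc_tables))
        signatures = group_signatures(annotations, None, table=self.code_table)
        ds_by_code = {d.cancer_code: d for d in self.datasets}
        if evaluate_composites:
            for sig in signatures:
                evaluate_composite(sig, ds_by_code[sig.cancer_code], self.config)
        for sig in signatures:
            sig.rank = rank_signature(sig, self.rank_map)
        return MultiOptosisResults(self, all_records, annotations, signatures, excluded)

    def _annotate(
        self, ds: PanCancerDataset, rec, tnc_tables: dict[str, pd.DataFrame]
    ) -> FeatureAnnotation:
        layer, fid = rec.layer, rec.feature_id
        gene = ds.layers[layer].feature_gene[fid]
        companion = ds.companion_values(layer, fid)
        comp_id = ds.companion_feature(layer, fid)

        # tumor-vs-normal polarity from the companion expression layer
        tnc = TNC_NO_DATA
        tnc_layer = layer if layer in ("mrna", "transcript") else "mrna"
        table = tnc_tables.get(tnc_layer)
        if table is not None and comp_id in table.index:
            normal_vals = ds.normals[tnc_layer].values.loc[comp_id]
            tnc = classify_tnc(
                companion, normal_vals, padj=float(table.loc[comp_id, "padj"])
            )

        survival = ds.phenotypes.survival
        hrc, _ = fit_hrc(companion, survival, self.config)
        native = ds.layers[layer].values.loc[fid]
        if layer in ("mutation", "cnv"):
            smc, _ = fit_smc(native, layer, survival, self.config)
        else:
            smc, _ = fit_smc(companion, layer, survival, self.config)

        profile = correlation_profile(companion, ds.phenotypes.infiltration, self.config)
        tmc = classify_tmc(profile, tnc, self.cell_map, self.config)
        tic = classify_tic(profile, tnc, self.cell_map, self.config)
        form_set = ds.inventory[gene]
        return annotate_feature(rec, gene, tnc, hrc, smc, tmc, tic, form_set)


class MultiOptosisResults:
    """Fitted signatures with their identifiers, codes, ranks and diagnostics."""

    def __init__(self, model, records, annotations, signatures, excluded):
        self.model = model
        self.records = records
        self.annotations = annotations
        self.signatures: list[SignatureRecord] = signatures
        self.excluded = excluded

    # -- tables ------------------------------------------------------------
    @property
    def associations(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def signatures_table(self) -> pd.DataFrame:
        return signatures_frame(self.signatures)

    @property
    def members_table(self) -> pd.DataFrame:
        return members_frame(self.signatures)

    def summarize_by_omic(self) -> pd.DataFrame:
        return summarize_by_omic(self.signatures)

    def cohort_counts(self) -> list[CohortCountRow]:
        per_cancer: dict[str, int] = {}
        for s in self.signatures:
            per_cancer[s.cancer_code] = per_cancer.get(s.cancer_code, 0) + 1
        return [
            CohortCountRow(
                cancer_code=ds.cancer_code,
                n_patients=len(ds.samples),
                n_signatures=per_cancer.get(ds.cancer_code, 0),
            )
            for ds in self.model.datasets
        ]

    def select_representatives(self, mode: str = "per_rcd_form"):
        return select_representatives(self.signatures, mode)

    # -- external validation ----------------------------------------------
    def validate(self, metaz: MetaZTable) -> pd.DataFrame:
        """Meta-Z validation of every signature with a resolvable direction."""
        rows = []
        for s in self.signatures:
            direction = expected_direction_from_hrc(s.hrc_letters)
            z, n_excl = signature_metaz(s.member_genes, s.cancer_code, metaz)
            if direction is None:
                verdict = "skipped_unresolved_direction"
            else:
                verdict = validate_signature(z, direction, self.model.config)
            rows.append(
                {
                    "identifier": s.identifier,
                    "meta_z": z,
                    "direction": direction,
                    "verdict": verdict,
                    "excluded_genes": n_excl,
                }
            )
        return pd.DataFrame(rows)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary in the style of a model results table."""
        sigs = self.signatures
        n_assoc = len(self.records)
        n_sig = sum(1 for r in self.records if r.significant)
        counts = pd.Series([len(s.members) for s in sigs], dtype=float)
        lines = [
            "Multi-optosis signature discovery",
            "=" * 54,
            f"Cohorts:                {len(self.model.datasets)}",
            f"Associations screened:  {n_assoc}",
            f"Genome-wide significant:{n_sig:>7}",
            f"Signatures:             {len(sigs)}",
        ]
        if len(counts):
            lines += [
                f"Members per signature:  mean={counts.mean():.1f}; "
                f"median={counts.median():.0f}; max={counts.max():.0f}",
            ]
        rows = self.cohort_counts()
        if len(rows) >= 3:
            rho, p = cohort_size_correlation(rows)
            if not np.isnan(rho):
                lines.append(f"Cohort-size correlation: rho={rho:.3f} (p={p:.2g})")
        lines.append("-" * 54)
        lines.append(f"{'cancer':<8}{'patients':>10}{'signatures':>12}{'ratio':>8}")
        for row in rows:
            lines.append(
                f"{row.cancer_code:<8}{row.n_patients:>10}{row.n_signatures:>12}"
                f"{row.ratio:>8.2f}"
            )
        return "\n".join(lines)

    def plot_km(self, signature: SignatureRecord, endpoint: str = "OS", ax=None):
        """Kaplan-Meier curves for High/Low composite groups of a signature."""
        from lifelines import KaplanMeierFitter
        from .signatures import composite_score

        ds = {d.cancer_code: d for d in self.model.datasets}[signature.cancer_code]
        score = composite_score(signature, ds, self.model.config)
        surv = ds.phenotypes.survival[endpoint]
        df = pd.concat([surv, score.rename("x")], axis=1, join="inner").dropna()
        med = df["x"].median()
        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        for label, grp in (("High", df[df["x"] > med]), ("Low", df[df["x"] <= med])):
            if len(grp) == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(grp["time"], grp["event"], label=label)
            km.plot_survival_function(ax=ax)
        ax.set_title(f"{signature.identifier} ({endpoint})")
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        return ax

    def save(self, outdir) -> None:
        """Write the standard report files as TSV."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.associations.to_csv(os.path.join(outdir, "associations.tsv"), sep="\t", index=False)
        ann_rows = [
            {
                "cancer": a.association.cancer_code,
                "layer": a.association.layer,
                "feature": a.feature_id,
                "phenotype": a.association.phenotype,
                "rho": a.association.rho,
                "padj": a.association.padj,
                "scs": a.association.scs,
                "tnc": a.tnc,
                "hrc": "".join(a.hrc.letters),
                "smc": "".join(a.smc.letters),
                "tmc": a.tmc,
                "tic": a.tic,
            }
            for a in self.annotations
        ]
        pd.DataFrame(ann_rows).to_csv(
            os.path.join(outdir, "annotations.tsv"), sep="\t", index=False
        )
        self.signatures_table.to_csv(
            os.path.join(outdir, "signatures.tsv"), sep="\t", index=False
        )
        self.members_table.to_csv(os.path.join(outdir, "members.tsv"), sep="\t", index=False)
        self.summarize_by_omic().rename_axis("layer").to_csv(
            os.path.join(outdir, "summary_by_omic.tsv"), sep="\t"
        )
        pd.DataFrame(
            [
                {
                    "cancer": r.cancer_code,
                    "n_patients": r.n_patients,
                    "n_signatures": r.n_signatures,
                    "ratio": r.ratio,
                }
                for r in self.cohort_counts()
            ]
        ).to_csv(os.path.join(outdir, "cohort_counts.tsv"), sep="\t", index=False)
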