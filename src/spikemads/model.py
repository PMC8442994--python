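"""Model/Results facade over the normalization -> co-expression pipeline.

``CoexpressionModel`` is built from a raw Cq table (plus the reference
panel and rule parameters); ``fit()`` runs reference selection,
relative quantification, optional antisense-overlap correction, Pearson
correlation, set assignment and the hierarchical-clustering cross-check,
and returns a ``CoexpressionResults`` carrying the estimates and
diagnostics with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import coexpression as cx
from . import qpcr, reports
from .stages import DEFAULT_GRID, StageGrid


@dataclass
class CoexpressionModel:
    """Threshold-graph co-expression analysis of an RT-qPCR experiment.

    Parameters
    ----------
    cq : pandas.DataFrame
        Long-format Cq table with columns gene, condition_type
        (``stage``/``organ``), condition, replicate, cq (NaN = no
        amplification).
    panel : sequence of str
        Candidate reference genes; the best ``norm_params.k`` are selected
        per batch by average pairwise variation.
    norm_params, rule_params
        Normalization and set-rule settings.
    overlap_pair : (observed, background) or None
        Antisense-overlap assay pair; the observed assay is replaced by its
        background-subtracted profile and the background assay is dropped
        from the analysis.
    grid : StageGrid
        Stage ordering used for profiles and set numbering.
    """

    cq: pd.DataFrame
    panel: tuple[str, ...]
    norm_params: qpcr.NormalizationParams = field(
        default_factory=qpcr.NormalizationParams)
    rule_params: cx.SetRuleParams = field(default_factory=cx.SetRuleParams)
    overlap_pair: tuple[str, str] | None = None
    grid: StageGrid = DEFAULT_GRID
    class_map: dict[str, str] | None = None

    @classmethod
    def from_tsv(cls, path, panel, **kwargs) -> "CoexpressionModel":
        from .simulate import read_cq_tsv

        return cls(read_cq_tsv(path), tuple(panel), **kwargs)

    def fit(self, cluster_k: int | None = None) -> "CoexpressionResults":
        batches: dict[str, qpcr.ExpressionMatrix] = {}
        refs: dict[str, list[str]] = {}
        scores: dict[str, dict[str, float]] = {}
        for ctype in self.cq["condition_type"].drop_duplicates():
            sub = self.cq[self.cq["condition_type"] == ctype]
            sc = qpcr.score_reference_stability(sub, self.panel)
            chosen = qpcr.select_reference_genes(sc, self.norm_params.k)
            expr = qpcr.normalize(
                sub, chosen, self.norm_params, condition_type=ctype,
                grid=self.grid if ctype == "stage" else None,
            )
            leftover = [g for g in self.panel if g in expr.mean.index]
            if leftover:  # unselected candidates are not family members
                expr = expr.drop(leftover)
            if self.overlap_pair is not None:
                expr = qpcr.apply_overlap_correction(expr, *self.overlap_pair)
            scores[ctype] = sc
            refs[ctype] = chosen
            batches[ctype] = expr

        if "stage" not in batches:
            raise ValueError("no time-course (stage) conditions in Cq table")
        stage_expr = batches["stage"]
        corr = cx.pearson_matrix(stage_expr)
        assignment = cx.assign_sets(corr, self.rule_params, stage_expr)

        k = cluster_k if cluster_k is not None else assignment.n_sets + 1
        clusters = cx.hierarchical_cluster(stage_expr, k)
        common = {g: assignment.label_of[g] for g in clusters}
        cluster_ari = cx.compare_groupings(
            common, {g: clusters[g] for g in common}
        ) if len(set(common.values())) > 1 else float("nan")

        report = reports.profile_report(
            stage_expr, batches.get("organ"), self.class_map
        )
        return CoexpressionResults(
            model=self,
            expression=stage_expr,
            organ_expression=batches.get("organ"),
            reference_scores=scores,
            references=refs,
            correlation=corr,
            assignment=assignment,
            cluster_labels=clusters,
            cluster_ari=cluster_ari,
            report=report,
        )


@dataclass
class CoexpressionResults:
    """Fitted quantities of a :class:`CoexpressionModel`."""

    model: CoexpressionModel
    expression: qpcr.ExpressionMatrix
    organ_expression: qpcr.ExpressionMatrix | None
    reference_scores: dict[str, dict[str, float]]
    references: dict[str, list[str]]
    correlation: pd.DataFrame
    assignment: cx.SetAssignment
    cluster_labels: dict[str, int]
    cluster_ari: float
    report: pd.DataFrame

    def summary(self) -> str:
        lines = ["Co-expression set assignment", "=" * 60]
        for ctype, chosen in self.references.items():
            lines.append(f"references ({ctype}): {', '.join(chosen)}")
        rp = self.model.rule_params
        lines.append(
            f"rule: r > {rp.tau} with >= {rp.m} other members"
            f" (pseudoset threshold {rp.tau2})"
        )
        lines.append(
            f"sets: {self.assignment.n_sets}, clustering ARI vs sets:"
            f" {self.cluster_ari:.3f}"
        )
        lines.append("-" * 60)
        frame = self.assignment.to_frame().merge(
            self.report[["gene", "onset_stage"]], on="gene"
        )
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)

    def verify_rule(self) -> bool:
        """Check the defining post-condition: every set member has at least
        ``m`` partners with r > tau inside its own set."""
        rp = self.model.rule_params
        for name, comp in self.assignment.members.items():
            if not name.startswith("set_"):
                continue
            for gene in comp:
                if self.assignment.n_partners[gene] < rp.m:
                    return False
        return True
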