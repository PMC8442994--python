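"""Relative quantification of RT-qPCR Cq tables.

Implements the normalization chain used for transcript profiling of a gene
family over a developmental time course and an organ panel:

* reference-gene stability scoring (geNorm-style average pairwise
  variation of the Cq difference across conditions),
* selection of the best-``k`` references,
* per-replicate relative quantification ``Q = E^(-Cq)`` scaled by a
  normalization factor (mean relative quantity of the selected references),
* replicate aggregation into mean and standard deviation,
* subtraction of an antisense-overlap background assay from a contaminated
  target assay.

The time-course and floral-organ samples form separate normalization
batches and are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stages import StageGrid


class NormalizationError(ValueError):
    """Raised when a Cq table cannot be normalized as requested."""


@dataclass(frozen=True)
class NormalizationParams:
    """Settings of the relative-quantification step.

    efficiency
        Amplification fold-change per cycle (2.0 = perfect doubling).
    k
        Number of reference genes retained from the candidate panel.
    averaging
        How reference relative quantities combine into the normalization
        factor: ``"arithmetic"`` (default) or ``"geometric"``.
    """

    efficiency: float = 2.0
    panel: tuple[str, ...] = ()
    k: int = 3
    averaging: str = "arithmetic"

    def __post_init__(self) -> None:
        if self.efficiency <= 1.0:
            raise ValueError("efficiency must be > 1")
        if self.panel and not (1 <= self.k <= len(self.panel)):
            raise ValueError("k must satisfy 1 <= k <= len(panel)")
        if self.averaging not in ("arithmetic", "geometric"):
            raise ValueError("averaging must be 'arithmetic' or 'geometric'")


class ExpressionMatrix:
    """Normalized relative expression, genes x conditions, with replicate sd.

    Attributes
    ----------
    mean, sd : pandas.DataFrame
        Per-gene, per-condition mean and standard deviation of the
        normalized replicate values.
    condition_type : str
        ``"stage"`` or ``"organ"``.
    """

    def __init__(self, mean: pd.DataFrame, sd: pd.DataFrame,
                 condition_type: str = "stage",
                 grid: StageGrid | None = None) -> None:
        if not mean.index.equals(sd.index) or not mean.columns.equals(sd.columns):
            raise ValueError("mean and sd must share index and columns")
        if (mean.to_numpy() < 0).any() or (sd.to_numpy() < 0).any():
            raise ValueError("expression means and sds must be non-negative")
        self.mean = mean
        self.sd = sd
        self.condition_type = condition_type
        self.grid = grid

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.mean.columns)

    def row(self, gene: str) -> pd.Series:
        return self.mean.loc[gene]

    def drop(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.mean.drop(index=genes), self.sd.drop(index=genes),
            self.condition_type, self.grid,
        )

    def to_tsv(self, path) -> None:
        long = (
            self.mean.stack().rename("mean").to_frame()
            .join(self.sd.stack().rename("sd"))
            .reset_index()
        )
        long.columns = ["gene", "condition", "mean", "sd"]
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, condition_type: str = "stage",
                 grid: StageGrid | None = None) -> "ExpressionMatrix":
        long = pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
        mean = long.pivot(index="gene", columns="condition", values="mean")
        sd = long.pivot(index="gene", columns="condition", values="sd")
        order = long["condition"].drop_duplicates().tolist()
        genes = long["gene"].drop_duplicates().tolist()
        return cls(mean.loc[genes, order], sd.loc[genes, order],
                   condition_type, grid)


# ---------------------------------------------------------------------------
# reference-gene handling


def _mean_cq(cq: pd.DataFrame, gene: str) -> pd.Series:
    """Replicate-mean Cq per condition for one gene."""
    sub = cq[cq["gene"] == gene]
    return sub.groupby("condition", sort=False)["cq"].mean()


def score_reference_stability(cq: pd.DataFrame, panel) -> dict[str, float]:
    """Score each candidate by its average pairwise variation.

    For candidate *a*, the score is the mean over all other candidates *b*
    of the standard deviation, across conditions, of the replicate-mean Cq
    difference ``Cq_a - Cq_b``. A perfectly co-varying pair has sd 0; an
    unstable candidate drifts against every partner. Lower is more stable.
    """
    panel = list(panel)
    if len(panel) < 2:
        raise NormalizationError("need at least 2 reference candidates")
    conditions = cq["condition"].drop_duplicates().tolist()
    profiles = {}
    for name in panel:
        prof = _mean_cq(cq, name)
        missing = [c for c in conditions if c not in prof.index or
                   not np.isfinite(prof.get(c, np.nan))]
        if missing:
            raise NormalizationError(
                f"reference candidate {name!r} has no Cq in condition(s) "
                f"{missing}"
            )
        profiles[name] = prof.reindex(conditions)
    scores = {}
    for a in panel:
        sds = [float((profiles[a] - profiles[b]).std(ddof=1))
               for b in panel if b != a]
        scores[a] = float(np.mean(sds))
    return scores


def select_reference_genes(scores: dict[str, float], k: int) -> list[str]:
    """Return the ``k`` most stable candidates, ties broken by gene name."""
    if k > len(scores):
        raise NormalizationError(
            f"cannot select {k} references from {len(scores)} candidates"
        )
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


# ---------------------------------------------------------------------------
# normalization


def normalize(cq: pd.DataFrame, refs, params: NormalizationParams,
              condition_type: str | None = None,
              grid: StageGrid | None = None) -> ExpressionMatrix:
    """Normalize a single batch of Cq measurements to relative expression.

    Per replicate *j* and condition *c* the relative quantity of gene *g* is
    ``E^(-Cq(g,c,j))``; the normalization factor ``NF(c,j)`` is the mean of
    the reference relative quantities, and the normalized value is the
    quotient. Technical replicates are normalized individually and then
    aggregated into mean and sd. A missing Cq contributes quantity 0; a
    gene missing in all replicates of a condition has Q = 0 and sd = 0.
    """
    refs = list(refs)
    if not refs:
        raise NormalizationError("empty reference list")
    if condition_type is not None:
        cq = cq[cq["condition_type"] == condition_type]
    elif "condition_type" in cq.columns:
        types = cq["condition_type"].drop_duplicates().tolist()
        if len(types) > 1:
            raise NormalizationError(
                "Cq table mixes condition types; normalize batches separately"
            )
        condition_type = types[0] if types else "stage"
    if cq.empty:
        raise NormalizationError("no Cq records in this batch")

    conditions = cq["condition"].drop_duplicates().tolist()
    quantity = np.power(params.efficiency, -cq["cq"].to_numpy(dtype=float))
    work = cq.assign(quantity=np.where(np.isfinite(quantity), quantity, 0.0))

    ref_q = work[work["gene"].isin(refs)].pivot_table(
        index=["condition", "replicate"], columns="gene", values="quantity",
        aggfunc="mean",
    )
    for ref in refs:
        bad = (ref not in ref_q.columns) or (ref_q[ref] <= 0).any() \
            or ref_q[ref].isna().any()
        if bad:
            missing_conditions = sorted(
                set(conditions)
                - set(c for c, _ in ref_q.index)
                if ref not in ref_q.columns else
                {c for (c, r) in ref_q.index[(ref_q[ref].isna())
                                             | (ref_q[ref] <= 0)]}
            ) or conditions
            raise NormalizationError(
                f"reference gene {ref!r} missing or unamplified in "
                f"condition(s) {missing_conditions}"
            )
    missing_conds = [c for c in conditions
                     if c not in ref_q.index.get_level_values(0)]
    if missing_conds:
        raise NormalizationError(
            f"references not measured in condition(s) {missing_conds}"
        )
    if params.averaging == "arithmetic":
        nf = ref_q[refs].mean(axis=1)
    else:
        nf = np.exp(np.log(ref_q[refs]).mean(axis=1))

    targets = work[~work["gene"].isin(refs)].copy()
    key = pd.MultiIndex.from_frame(targets[["condition", "replicate"]])
    targets["q_norm"] = targets["quantity"].to_numpy() / nf.reindex(key).to_numpy()

    mean = targets.pivot_table(index="gene", columns="condition",
                               values="q_norm", aggfunc="mean", sort=False)
    sd = targets.pivot_table(index="gene", columns="condition",
                             values="q_norm",
                             aggfunc=lambda v: v.std(ddof=1), sort=False)
    gene_order = targets["gene"].drop_duplicates().tolist()
    mean = mean.reindex(index=gene_order, columns=conditions).fillna(0.0)
    sd = sd.reindex(index=gene_order, columns=conditions).fillna(0.0)
    return ExpressionMatrix(mean, sd, condition_type or "stage", grid)


def subtract_overlap(observed_mean: pd.Series, background_mean: pd.Series,
                     observed_sd: pd.Series | None = None,
                     background_sd: pd.Series | None = None
                     ) -> tuple[pd.Series, pd.Series]:
    """Correct a target assay contaminated by an overlapping transcript.

    ``corrected(c) = max(0, observed(c) - background(c))`` with the sds
    combined in quadrature. Negative corrected expression is clipped to 0
    because negative transcript abundance is physically meaningless.
    """
    if not observed_mean.index.equals(background_mean.index):
        raise ValueError("observed and background rows must share conditions")
    corrected = (observed_mean - background_mean).clip(lower=0.0)
    if observed_sd is None:
        observed_sd = pd.Series(0.0, index=observed_mean.index)
    if background_sd is None:
        background_sd = pd.Series(0.0, index=background_mean.index)
    if not observed_sd.index.equals(background_sd.index) or \
            not observed_sd.index.equals(observed_mean.index):
        raise ValueError("sd rows must share the mean rows' conditions")
    sd = np.sqrt(observed_sd**2 + background_sd**2)
    return corrected, sd


def apply_overlap_correction(expr: ExpressionMatrix, observed: str,
                             background: str) -> ExpressionMatrix:
    """Replace ``observed`` with its background-subtracted profile and drop
    the background-only assay from the matrix."""
    for g in (observed, background):
        if g not in expr.mean.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    corrected, sd = subtract_overlap(
        expr.mean.loc[observed], expr.mean.loc[background],
        expr.sd.loc[observed], expr.sd.loc[background],
    )
    mean = expr.mean.copy()
    sds = expr.sd.copy()
    mean.loc[observed] = corrected
    sds.loc[observed] = sd
    return ExpressionMatrix(mean.drop(index=background),
                            sds.drop(index=background),
                            expr.condition_type, expr.grid)
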