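"""Developmental-timing summaries and ABCDE-model conformance calls.

The ABCDE model assigns floral-organ identity combinatorially: A- and
E-class genes pattern the first whorl (lemma/palea in grasses), A + B + E
the second (lodicules), B + C + E the third (stamens) and C + E the fourth
(carpel); D-class genes act in the ovule within the carpel. Given
per-organ expression of each family member and its class, this module
binarizes the organ profile, compares the called organs with the class
expectation and reports conforming/deviating verdicts together with the
organs that are unexpectedly present or absent.

The E-class expectation is split by default into its two SEPALLATA
subclades - LOFSEP genes expected in the outer whorl (lemma, palea) and
SEP3 genes in the inner organs (lodicule, stamen, carpel) - reflecting the
expression split observed in cereals; the classic undivided E expectation
is available via ``split_e=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qpcr import ExpressionMatrix
from .stages import ORGANS

_CLASSIC_E = frozenset(ORGANS)


def default_expectation(split_e: bool = True) -> dict[str, frozenset]:
    """Expected organ set per ABCDE class."""
    exp = {
        "A": frozenset({"lemma", "palea", "lodicule"}),
        "B": frozenset({"lodicule", "stamen"}),
        "C": frozenset({"stamen", "carpel"}),
        "D": frozenset({"carpel"}),
    }
    if split_e:
        exp["E-LOFSEP"] = frozenset({"lemma", "palea"})
        exp["E-SEP3"] = frozenset({"lodicule", "stamen", "carpel"})
    else:
        exp["E"] = _CLASSIC_E
        exp["E-LOFSEP"] = _CLASSIC_E
        exp["E-SEP3"] = _CLASSIC_E
    return exp


@dataclass(frozen=True)
class ABCDEExpectation:
    """Class label -> expected organ subset over the five floral organs."""

    expected: dict[str, frozenset] = field(default_factory=default_expectation)

    def organs_for(self, klass: str) -> frozenset | None:
        """Expected organs, or None for classes outside the model."""
        return self.expected.get(klass)


@dataclass
class GeneConformance:
    gene: str
    klass: str
    called: frozenset
    expected: frozenset | None
    unexpected: frozenset
    absent: frozenset
    verdict: str  # "conforming" | "deviating" | "n/a"


# ---------------------------------------------------------------------------
# profile summaries


def peak_stage(profile: pd.Series) -> str:
    """Condition of maximum mean expression; ties break to the earliest
    condition; an all-zero profile reports ``"none"``."""
    if profile.empty:
        raise ValueError("empty profile")
    vals = profile.to_numpy(dtype=float)
    if np.all(vals == 0.0):
        return "none"
    return str(profile.index[int(np.argmax(vals))])


def onset_stage(profile: pd.Series, f: float = 0.1) -> str:
    """Earliest condition where expression reaches ``f`` of the profile
    maximum."""
    if not 0.0 < f < 1.0:
        raise ValueError("onset fraction must be in (0, 1)")
    if profile.empty:
        raise ValueError("empty profile")
    vals = profile.to_numpy(dtype=float)
    peak = vals.max()
    if peak <= 0.0:
        return "none"
    idx = np.nonzero(vals >= f * peak)[0]
    return str(profile.index[int(idx[0])])


def call_expressed_organs(organ_row: pd.Series,
                          rel_threshold: float = 0.1) -> frozenset:
    """Binarize an organ profile: an organ is called expressed when its mean
    expression reaches ``rel_threshold`` of the gene's maximum over organs."""
    missing = [o for o in ORGANS if o not in organ_row.index]
    if missing:
        raise KeyError(f"organ column(s) missing: {missing}")
    row = organ_row.reindex(list(ORGANS)).to_numpy(dtype=float)
    peak = row.max()
    if peak <= 0.0:
        return frozenset()
    return frozenset(o for o, v in zip(ORGANS, row) if v >= rel_threshold * peak)


def classify_abcde(calls: dict[str, frozenset], class_map: dict[str, str],
                   expectation: ABCDEExpectation | None = None
                   ) -> list[GeneConformance]:
    """Compare called organs with the per-class ABCDE expectation.

    A gene conforms when its call set equals the expectation exactly;
    otherwise the unexpectedly expressed and unexpectedly absent organs are
    reported. Genes of classes outside the model get verdict ``"n/a"``.
    """
    expectation = expectation or ABCDEExpectation()
    report = []
    for gene, called in calls.items():
        bad = [o for o in called if o not in ORGANS]
        if bad:
            raise KeyError(f"unknown organ name(s) {bad} for gene {gene!r}")
        klass = class_map.get(gene, "other")
        expected = expectation.organs_for(klass)
        if expected is None:
            report.append(GeneConformance(gene, klass, frozenset(called),
                                          None, frozenset(), frozenset(),
                                          "n/a"))
            continue
        unexpected = frozenset(called - expected)
        absent = frozenset(expected - called)
        verdict = "conforming" if not unexpected and not absent else "deviating"
        report.append(GeneConformance(gene, klass, frozenset(called), expected,
                                      unexpected, absent, verdict))
    return report


def conformance_frame(report: list[GeneConformance]) -> pd.DataFrame:
    def fmt(s):
        return ",".join(sorted(s)) if s else ""

    return pd.DataFrame(
        {
            "gene": [r.gene for r in report],
            "class": [r.klass for r in report],
            "organs_called": [fmt(r.called) for r in report],
            "expected": [fmt(r.expected) if r.expected is not None else "n/a"
                         for r in report],
            "unexpected": [fmt(r.unexpected) for r in report],
            "absent": [fmt(r.absent) for r in report],
            "verdict": [r.verdict for r in report],
        }
    )


def profile_report(stage_expr: ExpressionMatrix,
                   organ_expr: ExpressionMatrix | None = None,
                   class_map: dict[str, str] | None = None,
                   onset_fraction: float = 0.1,
                   rel_threshold: float = 0.1,
                   expectation: ABCDEExpectation | None = None
                   ) -> pd.DataFrame:
    """Per-gene summary: peak stage, onset stage and, when organ data and a
    class map are supplied, the ABCDE conformance columns."""
    rows = pd.DataFrame(
        {
            "gene": stage_expr.genes,
            "peak_stage": [peak_stage(stage_expr.row(g))
                           for g in stage_expr.genes],
            "onset_stage": [onset_stage(stage_expr.row(g), onset_fraction)
                            for g in stage_expr.genes],
        }
    )
    if organ_expr is None or class_map is None:
        return rows
    calls = {
        g: call_expressed_organs(organ_expr.row(g), rel_threshold)
        for g in stage_expr.genes if g in organ_expr.mean.index
    }
    conf = conformance_frame(classify_abcde(calls, class_map, expectation))
    return rows.merge(conf, on="gene", how="left")
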