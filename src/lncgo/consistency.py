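"""Consistency of centroid-model predictions with annotation transfer.

An alternative, widely used way to annotate a lncRNA is to transfer the GO
terms of its target genes (CLIP/chromatin-interaction partners or genes
differentially expressed on knockdown). For each lncRNA this module asks
whether the centroid model's predicted term set overlaps the transferred
term set more than chance, via the upper-tail hypergeometric test over a
shared term universe; the summary is the fraction of lncRNAs whose overlap
is significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from lncgo.centroid_model import PredictionRecord
from lncgo.go_prep import GoTermSet


class ConsistencyError(ValueError):
    pass


@dataclass
class LncTargetSet:
    """A lncRNA's target genes from one evidence source."""

    lncrna_id: str
    target_genes: frozenset[str]
    source_tag: str = "unknown"

    def __post_init__(self) -> None:
        if not self.target_genes:
            raise ConsistencyError(f"{self.lncrna_id}: empty target set")


def transfer_annotations(
    targets: LncTargetSet,
    terms: Mapping[str, GoTermSet],
    min_overlap: int = 1,
) -> set[str]:
    """Terms whose propagated gene set shares ≥ min_overlap target genes."""
    return {
        t
        for t, ts in terms.items()
        if len(ts.propagated_genes & targets.target_genes) >= min_overlap
    }


def hypergeom_consistency(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric P(X ≥ |a ∩ b|).

    N = |universe| terms, K = |a| drawn by one method, n = |b| by the
    other; under the null the overlap is hypergeometric.
    """
    if not set_a <= universe or not set_b <= universe:
        raise ConsistencyError("term sets must be subsets of the universe")
    overlap = len(set_a & set_b)
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, len(universe), len(set_a), len(set_b)))


def consistency_report(
    predictions: Iterable[PredictionRecord],
    target_sets: Iterable[LncTargetSet],
    terms: Mapping[str, GoTermSet],
    universe: set[str],
    alpha: float = 0.05,
    min_confidence: float = 1.0,
    min_overlap: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Per-lncRNA overlap table plus the consistent fraction.

    A lncRNA counts as consistent when the hypergeometric p of its two
    term sets is < alpha. lncRNAs with no target set are excluded from the
    denominator and reported separately.
    """
    pred_by_lnc: dict[str, set[str]] = {}
    for rec in predictions:
        if rec.confidence >= min_confidence and rec.term_id in universe:
            pred_by_lnc.setdefault(rec.lncrna_id, set()).add(rec.term_id)
    targets_by_lnc = {t.lncrna_id: t for t in target_sets}

    rows = []
    no_targets = sorted(set(pred_by_lnc) - set(targets_by_lnc))
    for lnc in sorted(set(pred_by_lnc) & set(targets_by_lnc)):
        set_a = pred_by_lnc[lnc]
        set_b = transfer_annotations(targets_by_lnc[lnc], terms, min_overlap)
        set_b &= universe
        p = hypergeom_consistency(set_a, set_b, universe)
        rows.append(
            {
                "lncrna_id": lnc,
                "n_model_terms": len(set_a),
                "n_transfer_terms": len(set_b),
                "overlap": len(set_a & set_b),
                "p_hypergeom": p,
                "consistent": p < alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "n_model_terms",
            "n_transfer_terms",
            "overlap",
            "p_hypergeom",
            "consistent",
        ],
    )
    n_eval = len(table)
    summary = {
        "n_evaluated": n_eval,
        "n_without_targets": len(no_targets),
        "lncrnas_without_targets": no_targets,
        "alpha": alpha,
        "universe_size": len(universe),
        "consistent_fraction": (
            float(table["consistent"].mean()) if n_eval else float("nan")
        ),
    }
    return table, summary


def read_target_sets(path: str | Path) -> list[LncTargetSet]:
    """Read a TSV ``lncrna_id<TAB>gene_id<TAB>source_tag``."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ConsistencyError("target-set file needs ≥ 2 columns")
    out = []
    for (lnc, tag), g in df.groupby(
        [0, df[2] if df.shape[1] > 2 else pd.Series("unknown", index=df.index)]
    ):
        out.append(
            LncTargetSet(
                lncrna_id=str(lnc),
                target_genes=frozenset(g[1]),
                source_tag=str(tag),
            )
        )
    return out
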