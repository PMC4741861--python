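"""The end-to-end workflow: normalize → GO prep → train → predict.

``run_pipeline`` ties the modules together on a directory of inputs laid
out as the fixture generator writes them, producing a model store, a
predictions table and a JSON manifest (config hash, seeds, per-stage
outputs). Reruns with the same inputs and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

import lncgo
from lncgo.centroid_model import (
    PredictionRecord,
    predict_lncrnas,
    save_term_model,
    train_term_model,
)
from lncgo.config import RunConfig
from lncgo.go_prep import (
    build_gold_standard,
    propagate_annotations,
    read_annotations,
    read_dag,
    size_filter,
)
from lncgo.io_normalize import (
    EXPRESSION_FEATURE,
    SignalMatrix,
    filter_and_log2z,
    read_signal_matrix,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _load_matrices(input_dir: Path) -> tuple[dict[str, SignalMatrix], dict[str, SignalMatrix]]:
    """Load gene and lncRNA matrices from the standard layout.

    chromatin/<mark>.tsv (RPM), expression.tsv (FPKM), and the lncRNA
    counterparts under lnc_chromatin/ and lnc_expression.tsv. Expression
    files are optional (chromatin-only runs).
    """
    matrices: dict[str, SignalMatrix] = {}
    lnc: dict[str, SignalMatrix] = {}
    chrom_dir = input_dir / "chromatin"
    if chrom_dir.is_dir():
        for path in sorted(chrom_dir.glob("*.tsv")):
            matrices[path.stem] = read_signal_matrix(path, path.stem, state="rpm")
    expr = input_dir / "expression.tsv"
    if expr.exists():
        matrices[EXPRESSION_FEATURE] = read_signal_matrix(
            expr, EXPRESSION_FEATURE, state="fpkm"
        )
    lchrom = input_dir / "lnc_chromatin"
    if lchrom.is_dir():
        for path in sorted(lchrom.glob("*.tsv")):
            lnc[path.stem] = read_signal_matrix(path, path.stem, state="rpm")
    lexpr = input_dir / "lnc_expression.tsv"
    if lexpr.exists():
        lnc[EXPRESSION_FEATURE] = read_signal_matrix(
            lexpr, EXPRESSION_FEATURE, state="fpkm"
        )
    if not matrices:
        raise PipelineError("normalize", f"no signal matrices under {input_dir}")
    return matrices, lnc


def write_predictions(records: list[PredictionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.lncrna_id, r.term_id, r.namespace, r.selected_feature, r.confidence)
            for r in records
        ],
        columns=["lncrna_id", "term_id", "namespace", "selected_feature", "confidence"],
    )
    df = df.sort_values(["lncrna_id", "term_id"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def run_pipeline(
    config: RunConfig, input_dir: str | Path, out_dir: str | Path
) -> dict:
    """Execute the full workflow and return the manifest dict."""
    input_dir, out = Path(input_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lncgo",
        "version": lncgo.__version__,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "input_dir": str(input_dir),
        "stages": [],
    }

    # -- stage 1: normalize -------------------------------------------------
    try:
        raw, raw_lnc = _load_matrices(input_dir)
        norm: dict[str, SignalMatrix] = {}
        norm_lnc: dict[str, SignalMatrix] = {}
        for fname, m in raw.items():
            mode = "expression" if fname == EXPRESSION_FEATURE else "chromatin"
            norm[fname] = filter_and_log2z(m, mode, ddof=config.zscore_ddof)
        for fname, m in raw_lnc.items():
            mode = "expression" if fname == EXPRESSION_FEATURE else "chromatin"
            norm_lnc[fname] = filter_and_log2z(m, mode, ddof=config.zscore_ddof)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("normalize", str(exc)) from exc
    manifest["stages"].append(
        {"name": "normalize", "features": sorted(norm), "lnc_features": sorted(norm_lnc)}
    )

    # -- stage 2: prep-go ---------------------------------------------------
    try:
        direct, namespaces = read_annotations(input_dir / "annotations.tsv")
        dag = read_dag(input_dir / "dag.tsv")
        terms = propagate_annotations(
            direct, dag, namespaces, propagation=config.propagation
        )
        universe: set[str] = set.intersection(
            *(set(m.data.index) for m in norm.values())
        )
        kept = size_filter(
            terms, universe, config.min_term_genes, config.max_term_genes
        )
        if not kept:
            raise ValueError("no term passes the size filter")
        golds = {
            t: build_gold_standard(
                terms[t], universe, n_gsn=config.n_gsn, seed=config.master_seed
            )
            for t in kept
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("prep-go", str(exc)) from exc
    manifest["stages"].append(
        {"name": "prep-go", "n_terms": len(kept), "universe_size": len(universe)}
    )

    # -- stage 3: train -----------------------------------------------------
    models = {}
    model_dir = out / "models"
    try:
        for t in kept:
            model = train_term_model(
                golds[t],
                norm,
                k_folds=config.k_folds,
                seed=config.master_seed,
                cv_auc=config.cv_auc,
                strictness=config.strictness,
                namespace=terms[t].namespace,
            )
            models[t] = model
            save_term_model(model, model_dir / t.replace(":", "_"))
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc
    manifest["stages"].append(
        {
            "name": "train",
            "selected_features": {t: m.selected_feature for t, m in models.items()},
            "mean_auc": {
                t: m.auc_by_feature[m.selected_feature] for t, m in models.items()
            },
        }
    )

    # -- stage 4: predict ---------------------------------------------------
    records: list[PredictionRecord] = []
    try:
        for t, model in models.items():
            lnc_m = norm_lnc.get(model.selected_feature)
            if lnc_m is None:
                logger.warning(
                    "%s: no lncRNA matrix for feature %s; term skipped",
                    t,
                    model.selected_feature,
                )
                continue
            records.extend(
                predict_lncrnas(model, lnc_m, min_confidence=config.min_confidence)
            )
        write_predictions(records, out / "predictions.tsv")
    except Exception as exc:
        raise PipelineError("predict", str(exc)) from exc
    manifest["stages"].append({"name": "predict", "n_records": len(records)})

    # -- stage 5: report ----------------------------------------------------
    manifest["stages"].append({"name": "report", "outputs": ["predictions.tsv", "models/"]})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
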