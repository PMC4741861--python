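"""Per-term nearest-centroid classifiers: Δd scoring, cross-validated AUC
feature selection, Youden cutoffs, and resampling-based lncRNA confidence.

For a GO term and one feature (a chromatin mark or expression), the
classifier is a pair of centroids in sample space: the per-sample mean
profile of the gold-standard positive genes (GSP) and of one gold-standard
negative replicate (GSN). A profile p(i) is scored by

    Δd(i) = ||p(i) − GSP_centroid||₂ − ||p(i) − GSN_centroid||₂

so Δd < 0 means closer to the positive centroid. The decision score is
−Δd (higher = more positive-like) and a profile is called positive when
the score reaches the classifier's cutoff, chosen to maximize Youden's
J = sensitivity + specificity − 1.

Per term, every feature is evaluated by five-fold cross-validated AUC
averaged over the GSN replicates; the feature with the maximum average AUC
is selected, final classifiers are refit on the full GSP ∪ GSN for each
replicate, and a lncRNA's confidence for the term is the fraction of those
replicate classifiers that call it positive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lncgo.go_prep import GoldStandard, replicate_seed
from lncgo.io_normalize import SignalMatrix

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


@dataclass
class CentroidClassifier:
    """Positive/negative centroid pair in one feature's sample space."""

    feature_label: str
    sample_ids: list[str]
    pos_centroid: np.ndarray
    neg_centroid: np.ndarray
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.pos_centroid = np.asarray(self.pos_centroid, dtype=float)
        self.neg_centroid = np.asarray(self.neg_centroid, dtype=float)
        n = len(self.sample_ids)
        if n < 2:
            raise ModelError("need at least 2 samples")
        if self.pos_centroid.shape != (n,) or self.neg_centroid.shape != (n,):
            raise ModelError("centroid length must equal the number of samples")


@dataclass
class TermModel:
    """Trained per-term artifacts.

    ``auc_by_feature`` holds each feature's cross-validated AUC averaged
    over the GSN replicates; ``final_classifiers`` holds one full-training
    classifier (with Youden cutoff) per replicate, all in the selected
    feature's space.
    """

    term_id: str
    auc_by_feature: dict[str, float]
    selected_feature: str
    final_classifiers: list[CentroidClassifier]
    namespace: str = "BP"
    seed: int = 0
    skipped_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.auc_by_feature:
            best = max(self.auc_by_feature.values())
            ties = sorted(
                f for f, a in self.auc_by_feature.items() if a == best
            )
            if self.selected_feature != ties[0]:
                raise ModelError(
                    "selected_feature must be the argmax of auc_by_feature "
                    "(lexicographic tie-break)"
                )

    @property
    def n_gsn(self) -> int:
        return len(self.final_classifiers)


@dataclass
class PredictionRecord:
    """(lncRNA, term) association with a resampling confidence score."""

    lncrna_id: str
    term_id: str
    confidence: float
    selected_feature: str
    namespace: str = "BP"


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def delta_d(profile: np.ndarray, clf: CentroidClassifier) -> float:
    """Distance-to-positive minus distance-to-negative centroid.

    Negative values mean the profile sits closer to the positive centroid.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != clf.pos_centroid.shape:
        raise ModelError(
            f"profile has {profile.shape[0] if profile.ndim else 0} dims, "
            f"classifier space has {clf.pos_centroid.shape[0]}"
        )
    d_pos = float(np.linalg.norm(profile - clf.pos_centroid))
    d_neg = float(np.linalg.norm(profile - clf.neg_centroid))
    return d_pos - d_neg


def decision_score(profile: np.ndarray, clf: CentroidClassifier) -> float:
    """−Δd, so that HIGHER score = more positive-like.

    A profile is called positive when its score is ≥ the cutoff.
    """
    return -delta_d(profile, clf)


def _scores_matrix(
    profiles: np.ndarray, pos_centroid: np.ndarray, neg_centroid: np.ndarray
) -> np.ndarray:
    """Vectorized decision scores (−Δd) for rows of ``profiles``."""
    d_pos = np.linalg.norm(profiles - pos_centroid, axis=-1)
    d_neg = np.linalg.norm(profiles - neg_centroid, axis=-1)
    return d_neg - d_pos


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (Mann–Whitney), ties contributing 1/2.

    Equivalent to the trapezoidal area under the ROC curve swept over all
    distinct score cutoffs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ModelError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def youden_cutoff(scores, labels) -> float:
    """Score threshold maximizing J = sensitivity + specificity − 1.

    Candidate thresholds are the observed scores; a point at the threshold
    is classified positive (≥ convention). Ties on J are broken toward
    higher specificity, then toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ModelError("youden_cutoff requires both classes present")
    thresholds = np.unique(scores)
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    # sens(t) = #(pos >= t)/n_pos ; spec(t) = #(neg < t)/n_neg
    sens = 1.0 - np.searchsorted(pos, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg, thresholds, side="left") / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    cand = np.flatnonzero(j >= best_j - 1e-12)
    best_spec = spec[cand].max()
    cand = cand[spec[cand] >= best_spec - 1e-12]
    return float(thresholds[cand[0]])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_assignment(n: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffle indices and deal round-robin into k approximately equal parts."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k_folds
    return folds


def crossval_auc(
    gsp_profiles: np.ndarray,
    gsn_profiles: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    cv_auc: str = "pooled",
) -> float:
    """Stratified k-fold cross-validated AUC for one (term, feature, GSN).

    GSP and GSN are folded separately; for each fold the centroids are the
    per-sample means of the remaining training folds and the held-out genes
    are scored with −Δd. ``cv_auc="pooled"`` computes one ROC over all
    held-out scores; ``"mean"`` averages the per-fold AUCs.
    """
    gsp = np.asarray(gsp_profiles, dtype=float)
    gsn = np.asarray(gsn_profiles, dtype=float)
    if gsp.shape[0] < k_folds or gsn.shape[0] < k_folds:
        raise ModelError(
            f"each class needs ≥ {k_folds} members "
            f"(got {gsp.shape[0]} positives, {gsn.shape[0]} negatives)"
        )
    if cv_auc not in ("pooled", "mean"):
        raise ModelError(f"unknown cv_auc mode {cv_auc!r}")
    rng = np.random.default_rng(seed)
    pos_folds = _fold_assignment(gsp.shape[0], k_folds, rng)
    neg_folds = _fold_assignment(gsn.shape[0], k_folds, rng)

    all_scores, all_labels, fold_aucs = [], [], []
    for f in range(k_folds):
        pos_tr, pos_te = gsp[pos_folds != f], gsp[pos_folds == f]
        neg_tr, neg_te = gsn[neg_folds != f], gsn[neg_folds == f]
        pos_centroid = pos_tr.mean(axis=0)
        neg_centroid = neg_tr.mean(axis=0)
        s_pos = _scores_matrix(pos_te, pos_centroid, neg_centroid)
        s_neg = _scores_matrix(neg_te, pos_centroid, neg_centroid)
        scores = np.concatenate([s_pos, s_neg])
        labels = np.concatenate(
            [np.ones(len(s_pos), bool), np.zeros(len(s_neg), bool)]
        )
        if cv_auc == "mean":
            fold_aucs.append(roc_auc(scores, labels))
        else:
            all_scores.append(scores)
            all_labels.append(labels)
    if cv_auc == "mean":
        return float(np.mean(fold_aucs))
    return roc_auc(np.concatenate(all_scores), np.concatenate(all_labels))


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def _covered(
    gold: GoldStandard, m: SignalMatrix, strictness: str
) -> tuple[list[str], list[list[str]]] | None:
    """Restrict the gold standard to genes present in matrix ``m``.

    strict: the feature is unusable if ANY gold-standard gene is missing.
    lenient: restrict to covered genes when ≥ 90% of the GSP and of every
    GSN replicate remain, else unusable. Returns None when unusable.
    """
    present = set(m.data.index)
    gsp = [g for g in gold.gsp if g in present]
    gsns = [[g for g in gsn if g in present] for gsn in gold.gsn_replicates]
    if strictness == "strict":
        if len(gsp) < len(gold.gsp) or any(
            len(a) < len(b) for a, b in zip(gsns, gold.gsn_replicates)
        ):
            return None
        return gsp, gsns
    frac_gsp = len(gsp) / len(gold.gsp)
    fracs = [len(a) / len(b) for a, b in zip(gsns, gold.gsn_replicates)]
    if frac_gsp < 0.9 or min(fracs, default=1.0) < 0.9:
        return None
    return gsp, gsns


def train_term_model(
    gold: GoldStandard,
    matrices: dict[str, SignalMatrix],
    k_folds: int = 5,
    seed: int = 0,
    cv_auc: str = "pooled",
    strictness: str = "strict",
    namespace: str = "BP",
) -> TermModel:
    """Evaluate every feature by CV AUC, select the best, refit final models.

    ``auc_by_feature[f]`` is the mean cross-validated AUC over all GSN
    replicates; the selected feature is the argmax (lexicographic
    tie-break). For each replicate a final classifier is trained on the
    FULL GSP ∪ GSN in the selected feature's space, and its cutoff is the
    Youden-J maximizer of the training decision scores.
    """
    auc_by_feature: dict[str, float] = {}
    covered_by_feature: dict[str, tuple[list[str], list[list[str]]]] = {}
    skipped: list[str] = []
    for fname in sorted(matrices):
        m = matrices[fname]
        cov = _covered(gold, m, strictness)
        if cov is None:
            skipped.append(fname)
            logger.warning(
                "%s: feature %s skipped (gold-standard genes missing)",
                gold.term_id,
                fname,
            )
            continue
        gsp_ids, gsn_ids = cov
        gsp = m.subset(gsp_ids)
        aucs = np.empty(gold.n_gsn)
        for r, gsn_rep in enumerate(gsn_ids):
            aucs[r] = crossval_auc(
                gsp,
                m.subset(gsn_rep),
                k_folds=k_folds,
                seed=replicate_seed(seed, gold.term_id + "|cv", r),
                cv_auc=cv_auc,
            )
        auc_by_feature[fname] = float(aucs.mean())
        covered_by_feature[fname] = cov
    if not auc_by_feature:
        raise ModelError(f"{gold.term_id}: no feature usable for this term")

    best = max(auc_by_feature.values())
    selected = sorted(f for f, a in auc_by_feature.items() if a == best)[0]

    m = matrices[selected]
    gsp_ids, gsn_ids = covered_by_feature[selected]
    gsp = m.subset(gsp_ids)
    classifiers = []
    for gsn_rep in gsn_ids:
        gsn = m.subset(gsn_rep)
        clf = CentroidClassifier(
            feature_label=selected,
            sample_ids=m.sample_ids,
            pos_centroid=gsp.mean(axis=0),
            neg_centroid=gsn.mean(axis=0),
        )
        scores = np.concatenate(
            [
                _scores_matrix(gsp, clf.pos_centroid, clf.neg_centroid),
                _scores_matrix(gsn, clf.pos_centroid, clf.neg_centroid),
            ]
        )
        labels = np.concatenate(
            [np.ones(gsp.shape[0], bool), np.zeros(gsn.shape[0], bool)]
        )
        clf.cutoff = youden_cutoff(scores, labels)
        classifiers.append(clf)
    return TermModel(
        term_id=gold.term_id,
        auc_by_feature=auc_by_feature,
        selected_feature=selected,
        final_classifiers=classifiers,
        namespace=namespace,
        seed=seed,
        skipped_features=skipped,
    )


def predict_lncrnas(
    model: TermModel,
    lnc_matrix: SignalMatrix,
    min_confidence: float = 0.0,
) -> list[PredictionRecord]:
    """Score every lncRNA against all replicate classifiers of one term.

    The confidence is the fraction of the replicate classifiers calling the
    lncRNA positive (decision score ≥ cutoff); records below
    ``min_confidence`` (and zero-confidence records by default) are omitted.
    """
    if lnc_matrix.feature_label != model.selected_feature:
        raise ModelError(
            f"{model.term_id}: lncRNA matrix is {lnc_matrix.feature_label!r} "
            f"but the model uses {model.selected_feature!r}"
        )
    space = model.final_classifiers[0].sample_ids
    if lnc_matrix.sample_ids != space:
        raise ModelError(
            f"{model.term_id}: sample mismatch between lncRNA matrix and "
            f"classifier space"
        )
    profiles = lnc_matrix.values  # (n_lnc, d)
    pos = np.stack([c.pos_centroid for c in model.final_classifiers])
    neg = np.stack([c.neg_centroid for c in model.final_classifiers])
    cut = np.array([c.cutoff for c in model.final_classifiers])
    # (n_lnc, n_clf) decision scores via broadcasting
    scores = _scores_matrix(profiles[:, None, :], pos[None, :, :], neg[None, :, :])
    positive = scores >= cut
    confidence = positive.sum(axis=1) / model.n_gsn
    out = []
    for i, lnc in enumerate(lnc_matrix.entity_ids):
        c = float(confidence[i])
        if c > 0 and c >= min_confidence:
            out.append(
                PredictionRecord(
                    lncrna_id=lnc,
                    term_id=model.term_id,
                    confidence=c,
                    selected_feature=model.selected_feature,
                    namespace=model.namespace,
                )
            )
    return out


# ---------------------------------------------------------------------------
# model store
# ---------------------------------------------------------------------------

def save_term_model(model: TermModel, directory: str | Path) -> None:
    """One directory per term: JSON metadata + TSV of centroids/cutoffs."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "term_id": model.term_id,
        "namespace": model.namespace,
        "seed": model.seed,
        "selected_feature": model.selected_feature,
        "auc_by_feature": model.auc_by_feature,
        "skipped_features": model.skipped_features,
        "sample_ids": model.final_classifiers[0].sample_ids,
        "n_gsn": model.n_gsn,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    n = len(meta["sample_ids"])
    rows = []
    for r, clf in enumerate(model.final_classifiers):
        rows.append(
            [r, clf.cutoff, *clf.pos_centroid.tolist(), *clf.neg_centroid.tolist()]
        )
    cols = (
        ["replicate", "cutoff"]
        + [f"pos_{s}" for s in meta["sample_ids"]]
        + [f"neg_{s}" for s in meta["sample_ids"]]
    )
    pd.DataFrame(rows, columns=cols).to_csv(
        d / "classifiers.tsv", sep="\t", index=False, float_format="%.12g"
    )


def load_term_model(directory: str | Path) -> TermModel:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    df = pd.read_csv(d / "classifiers.tsv", sep="\t")
    samples = meta["sample_ids"]
    classifiers = []
    for _, row in df.iterrows():
        classifiers.append(
            CentroidClassifier(
                feature_label=meta["selected_feature"],
                sample_ids=samples,
                pos_centroid=row[[f"pos_{s}" for s in samples]].to_numpy(float),
                neg_centroid=row[[f"neg_{s}" for s in samples]].to_numpy(float),
                cutoff=float(row["cutoff"]),
            )
        )
    return TermModel(
        term_id=meta["term_id"],
        auc_by_feature=meta["auc_by_feature"],
        selected_feature=meta["selected_feature"],
        final_classifiers=classifiers,
        namespace=meta["namespace"],
        seed=meta["seed"],
        skipped_features=meta["skipped_features"],
    )
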