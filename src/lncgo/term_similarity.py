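"""Within-term profile similarity and its permutation significance.

For a GO term, the similarity of its member genes under one feature is the
mean Pearson correlation over all unordered gene pairs. Significance is
empirical: the same statistic is recomputed for ``n_perm`` random gene sets
of the same size drawn from the full profile universe, and the p-value is
the proportion of random similarities strictly higher than the observed
one. With ``n_perm=100`` the p-values live on the grid {0, 0.01, ..., 1}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from lncgo.io_normalize import SignalMatrix


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityResult:
    term_id: str
    feature_label: str
    observed_mean_r: float
    perm_values: np.ndarray
    p_empirical: float
    q_bh: float = float("nan")

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.observed_mean_r <= 1.0 + 1e-12:
            raise SimilarityError("mean correlation outside [-1, 1]")
        if not 0.0 <= self.p_empirical <= 1.0:
            raise SimilarityError("p-value outside [0, 1]")


def mean_pairwise_pearson(profiles: np.ndarray) -> float:
    """Mean Pearson r over all C(n, 2) unordered row pairs.

    ``profiles`` is an (n_genes, n_samples) array; rows must not be
    constant (their correlation is undefined).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise SimilarityError("need at least 2 gene rows")
    if profiles.shape[1] < 3:
        raise SimilarityError("need at least 3 samples")
    if (profiles.std(axis=1) == 0).any():
        bad = int(np.argmin(profiles.std(axis=1)))
        raise SimilarityError(f"constant profile at row {bad} (r undefined)")
    r = np.corrcoef(profiles)
    iu = np.triu_indices(profiles.shape[0], k=1)
    return float(r[iu].mean())


def permutation_significance(
    term_genes: list[str],
    all_profiles: SignalMatrix,
    n_perm: int = 100,
    seed: int = 0,
    feature_label: str | None = None,
    smoothing: bool = False,
) -> SimilarityResult:
    """Empirical significance of a term's within-group similarity.

    ``p = #{permuted mean_r > observed} / n_perm`` (strictly greater). With
    ``smoothing=True`` the add-one estimate ``(#+1)/(n_perm+1)`` is used
    instead, which cannot return exactly 0.
    """
    missing = [g for g in term_genes if g not in all_profiles.data.index]
    if missing:
        raise SimilarityError(f"term genes missing from profiles: {missing[:5]}")
    n = len(term_genes)
    if n > all_profiles.n_entities:
        raise SimilarityError("term larger than profile universe")
    observed = mean_pairwise_pearson(all_profiles.subset(term_genes))

    rng = np.random.default_rng(seed)
    vals = all_profiles.values
    perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(vals.shape[0], size=n, replace=False)
        perm[i] = mean_pairwise_pearson(vals[idx])
    higher = int((perm > observed).sum())
    if smoothing:
        p = (higher + 1) / (n_perm + 1)
    else:
        p = higher / n_perm
    return SimilarityResult(
        term_id="",
        feature_label=feature_label or all_profiles.feature_label,
        observed_mean_r=observed,
        perm_values=perm,
        p_empirical=p,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise SimilarityError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
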