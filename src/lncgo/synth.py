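"""Synthetic fixtures with the statistical structure the method assumes.

The generator emulates the data model of the real study: groups of genes
(one per GO term) whose per-feature profiles share a common centroid plus
Gaussian noise, a background population with an unrelated (zero) centroid,
and lncRNAs drawn from either population. Signal is planted only in the
``signal_features``; the remaining features are pure noise, which is what
makes feature-selection recovery testable.

Profiles are generated in standardized (log2/Z-like) space and emitted as
strictly positive RPM/FPKM-scale matrices via x = 2^(g + 8), so the
io-normalization path (log2(x+1) then per-row Z-score) approximately
recovers the planted structure. A small hand-laid BED fixture with known
bin counts exercises the TSS-profile path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from lncgo.io_normalize import (
    CHROMATIN_FEATURES,
    EXPRESSION_FEATURE,
    SignalMatrix,
    write_signal_matrix,
)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    ``separation_delta`` is the distance between a term's centroid and the
    background centroid in units of the within-class noise sd; δ=0 is the
    null (no signal), δ≈2–3 a well-separated term.
    """

    n_terms: int = 2
    genes_per_term: int = 30
    n_background_genes: int = 200
    n_samples_chromatin: int = 13
    n_samples_expression: int = 9
    n_features: int = 10  # 9 chromatin marks + expression
    separation_delta: float = 3.0
    signal_features: tuple[str, ...] = ("H3K9ac",)
    n_lncrnas_pos: int = 20
    n_lncrnas_neg: int = 20
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_terms",
            "genes_per_term",
            "n_background_genes",
            "n_samples_chromatin",
            "n_samples_expression",
            "n_features",
            "n_lncrnas_pos",
            "n_lncrnas_neg",
        ):
            if getattr(self, name) <= 0:
                raise FixtureError(f"{name} must be positive")
        if self.separation_delta < 0:
            raise FixtureError("separation_delta must be ≥ 0")
        if not self.signal_features:
            raise FixtureError("signal_features must be non-empty")
        if self.n_features < 1 or self.n_features > 10:
            raise FixtureError("n_features must be in 1..10")
        bad = set(self.signal_features) - set(self.feature_labels)
        if bad:
            raise FixtureError(f"signal_features not among features: {bad}")
        if self.n_terms * self.genes_per_term > self.n_background_genes * 10:
            raise FixtureError("term genes dwarf the background pool")

    @property
    def feature_labels(self) -> list[str]:
        labels = list(CHROMATIN_FEATURES) + [EXPRESSION_FEATURE]
        if self.n_features == 10:
            return labels
        # keep expression last so a chromatin-only study is the prefix
        return list(CHROMATIN_FEATURES[: self.n_features])


@dataclass
class Fixture:
    """In-memory fixture plus deterministic file serialization."""

    spec: FixtureSpec
    matrices: dict[str, SignalMatrix]
    lnc_matrices: dict[str, SignalMatrix]
    annotations: dict[str, set[str]]
    namespaces: dict[str, str]
    dag_edges: list[tuple[str, str]]
    truth: pd.DataFrame  # columns: lncrna_id, term_id
    reads_bed: pd.DataFrame
    tss_bed: pd.DataFrame
    expected_bins: dict[str, dict[int, int]]
    term_centroids: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "chromatin").mkdir(parents=True, exist_ok=True)
        (out / "lnc_chromatin").mkdir(parents=True, exist_ok=True)
        for fname, m in self.matrices.items():
            sub = "chromatin" if fname != EXPRESSION_FEATURE else "."
            write_signal_matrix(m, out / sub / f"{fname}.tsv")
        for fname, m in self.lnc_matrices.items():
            sub = "lnc_chromatin" if fname != EXPRESSION_FEATURE else "."
            name = f"{fname}.tsv" if fname != EXPRESSION_FEATURE else "lnc_expression.tsv"
            write_signal_matrix(m, out / sub / name)
        with open(out / "annotations.tsv", "w") as fh:
            for term in sorted(self.annotations):
                for gene in sorted(self.annotations[term]):
                    fh.write(f"{gene}\t{term}\t{self.namespaces[term]}\n")
        with open(out / "dag.tsv", "w") as fh:
            for parent, child in self.dag_edges:
                fh.write(f"{parent}\t{child}\n")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.reads_bed.to_csv(out / "reads.bed", sep="\t", index=False, header=False)
        self.tss_bed.to_csv(out / "tss.bed", sep="\t", index=False, header=False)
        (out / "expected_bins.json").write_text(
            json.dumps(
                {k: {str(b): c for b, c in v.items()} for k, v in self.expected_bins.items()},
                indent=1,
                sort_keys=True,
            )
        )
        (out / "spec.json").write_text(json.dumps(asdict(self.spec), indent=1))


def sphere_direction(dim: int, rng: np.random.Generator, center: bool = False) -> np.ndarray:
    """Uniform direction on the (dim−1)-sphere.

    With ``center=True`` the direction is drawn orthogonal to the all-ones
    vector: per-entity row-centering erases any mean component, so signal
    planted along the mean would be invisible downstream.
    """
    v = rng.standard_normal(dim)
    if center:
        v = v - v.mean()
    return v / np.linalg.norm(v)


def make_class_profiles(
    n_pos: int,
    n_neg: int,
    dim: int,
    delta: float,
    noise_sd: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two Gaussian classes with centroids ``delta·noise_sd`` apart.

    Returns (positive profiles, negative profiles, positive centroid); the
    negative centroid is the origin. This is the direct profile-space
    fixture used for classifier calibration studies.
    """
    rng = rng or np.random.default_rng(0)
    centroid = sphere_direction(dim, rng) * delta * noise_sd
    pos = centroid + rng.normal(0, noise_sd, size=(n_pos, dim))
    neg = rng.normal(0, noise_sd, size=(n_neg, dim))
    return pos, neg, centroid


def _to_rpm_scale(g: np.ndarray) -> np.ndarray:
    """Standardized space → strictly positive RPM-like values.

    log2(2^(g+8) + 1) = g + 8 + O(2^-8), so downstream log2/Z-scoring
    approximately inverts this map.
    """
    return np.exp2(g + 8.0)


def _toy_bed() -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[int, int]]]:
    """Hand-placed reads with known bin counts (bins numbered 1..200).

    Plus-strand TSS at chr1:10000 (window [8000, 12000)) and minus-strand
    TSS at chr1:20000–20001 (oriented window covering (18000, 22001)).
    """
    reads = pd.DataFrame(
        [
            ("chr1", 10000, 10020),  # + : exactly bin 101
            ("chr1", 9990, 10010),   # + : spans bins 100–101
            ("chr1", 8000, 8005),    # + : first bin (bin 1)
            ("chr1", 19900, 19920),  # − : 81–100 bp downstream → bins 105–106
            ("chr1", 20100, 20101),  # − : 100 bp upstream → bin 96
            ("chr2", 100, 200),      # different chromosome: ignored
        ],
        columns=["chrom", "start", "end"],
    )
    tss = pd.DataFrame(
        [
            ("chr1", 10000, 10001, "tss_plus", 0, "+"),
            ("chr1", 20000, 20001, "tss_minus", 0, "-"),
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    expected = {
        "tss_plus": {101: 2, 100: 1, 1: 1},
        "tss_minus": {105: 1, 106: 1, 96: 1},
    }
    return reads, tss, expected


def generate(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Build a complete synthetic study, optionally writing it to disk.

    Per term, member genes share one centroid per signal feature (norm δ
    from the zero background centroid, direction uniform on the sphere);
    non-signal features are pure noise. Positive lncRNAs are drawn from
    the term centroids (round-robin over terms), negatives from the
    background. The same seed always yields byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    features = spec.feature_labels
    genes = [f"G{i:04d}" for i in range(spec.n_background_genes)]
    term_ids = [f"GO:{7000000 + i}" for i in range(spec.n_terms)]
    term_genes: dict[str, list[str]] = {}
    pool = list(genes)
    for t in term_ids:
        if len(pool) < spec.genes_per_term:
            raise FixtureError("genes_per_term exceeds the background pool")
        idx = rng.choice(len(pool), size=spec.genes_per_term, replace=False)
        term_genes[t] = sorted(pool[i] for i in idx)
        pool = [g for i, g in enumerate(pool) if i not in set(idx.tolist())]

    lnc_pos = [f"LNC_P{i:03d}" for i in range(spec.n_lncrnas_pos)]
    lnc_neg = [f"LNC_N{i:03d}" for i in range(spec.n_lncrnas_neg)]
    lnc_term = {l: term_ids[i % spec.n_terms] for i, l in enumerate(lnc_pos)}

    # per-(term, feature) centroids in standardized space
    centroids: dict[str, dict[str, np.ndarray]] = {t: {} for t in term_ids}
    dims = {
        f: (spec.n_samples_expression if f == EXPRESSION_FEATURE else spec.n_samples_chromatin)
        for f in features
    }
    for t in term_ids:
        for f in spec.signal_features:
            centroids[t][f] = (
                sphere_direction(dims[f], rng, center=True)
                * spec.separation_delta
                * spec.noise_sd
            )

    matrices: dict[str, SignalMatrix] = {}
    lnc_matrices: dict[str, SignalMatrix] = {}
    for f in features:
        d = dims[f]
        samples = [f"cell{j + 1:02d}" for j in range(d)]
        g_rows = np.zeros((len(genes), d))
        gene_index = {g: i for i, g in enumerate(genes)}
        g_rows += rng.normal(0, spec.noise_sd, size=g_rows.shape)
        for t in term_ids:
            c = centroids[t].get(f)
            if c is not None:
                for g in term_genes[t]:
                    g_rows[gene_index[g]] += c
        state = "fpkm" if f == EXPRESSION_FEATURE else "rpm"
        matrices[f] = SignalMatrix(
            feature_label=f,
            data=pd.DataFrame(_to_rpm_scale(g_rows), index=genes, columns=samples),
            state=state,
        )
        l_rows = rng.normal(0, spec.noise_sd, size=(len(lnc_pos) + len(lnc_neg), d))
        for i, l in enumerate(lnc_pos):
            c = centroids[lnc_term[l]].get(f)
            if c is not None:
                l_rows[i] += c
        lnc_matrices[f] = SignalMatrix(
            feature_label=f,
            data=pd.DataFrame(
                _to_rpm_scale(l_rows), index=lnc_pos + lnc_neg, columns=samples
            ),
            state=state,
        )

    annotations = {t: set(term_genes[t]) for t in term_ids}
    namespaces = {t: "BP" for t in term_ids}
    namespaces["GO:ROOT"] = "BP"
    dag_edges = [("GO:ROOT", t) for t in term_ids]
    truth = pd.DataFrame(
        [(l, lnc_term[l]) for l in lnc_pos], columns=["lncrna_id", "term_id"]
    )
    reads, tss, expected = _toy_bed()
    fixture = Fixture(
        spec=spec,
        matrices=matrices,
        lnc_matrices=lnc_matrices,
        annotations=annotations,
        namespaces=namespaces,
        dag_edges=dag_edges,
        truth=truth,
        reads_bed=reads,
        tss_bed=tss,
        expected_bins=expected,
        term_centroids=centroids,
    )
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture
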