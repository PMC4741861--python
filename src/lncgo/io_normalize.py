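"""Signal-matrix I/O, RPM normalization, transcript aggregation and log2/Z-scoring.

A :class:`SignalMatrix` holds one feature's signal (a histone mark's
promoter-region read level, or expression) for a set of entities
(genes/lncRNAs, or their transcripts) across cell-line samples, together
with a ``state`` flag recording which normalization stage the values are in:

``raw_counts`` → ``rpm`` (reads per million mapped reads) → ``log2z``
(log2(x+1) then per-entity Z-score), with ``fpkm`` accepted as an
expression-side entry point equivalent to ``rpm``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Normalization states a SignalMatrix can be in. "profile" marks
#: already-standardized (or simulated) profile space with no constraints.
VALID_STATES = ("raw_counts", "rpm", "fpkm", "log2z", "profile")

#: The nine chromatin marks of the reference study, plus expression.
CHROMATIN_FEATURES = (
    "H2A.Z",
    "H3K4me1",
    "H3K4me2",
    "H3K4me3",
    "H3K9ac",
    "H3K9me3",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
)
EXPRESSION_FEATURE = "expression"

#: Presentation grouping of marks by regulatory direction.
ACTIVE_MARKS = frozenset(
    {"H2A.Z", "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K36me3", "H3K9ac"}
)
REPRESSIVE_MARKS = frozenset({"H3K9me3", "H3K27me3"})


class SignalMatrixError(ValueError):
    """Raised on malformed input or an invariant violation."""


@dataclass
class SignalMatrix:
    """One feature's values over entities × samples.

    Parameters
    ----------
    feature_label
        Name of the feature, e.g. ``"H3K4me3"`` or ``"expression"``.
    data
        DataFrame indexed by entity id, columns are sample ids, numeric body.
    state
        One of ``raw_counts``, ``rpm``, ``fpkm``, ``log2z``.
    """

    feature_label: str
    data: pd.DataFrame
    state: str
    dropped_constant: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise SignalMatrixError(
                f"unknown state {self.state!r}; expected one of {VALID_STATES}"
            )
        self.validate()

    # -- views -------------------------------------------------------------
    @property
    def entity_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_entities(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def profile(self, entity_id: str) -> np.ndarray:
        """The sample-space profile p(i) of one entity."""
        return self.data.loc[entity_id].to_numpy(dtype=float)

    def subset(self, entity_ids) -> np.ndarray:
        """Row-subset as an array, preserving the requested order."""
        return self.data.loc[list(entity_ids)].to_numpy(dtype=float)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise SignalMatrixError(f"duplicate entity id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise SignalMatrixError(f"duplicate sample id {dup!r}")
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise SignalMatrixError(
                f"non-finite value at entity {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if self.state in ("rpm", "fpkm") and vals.size and (vals < 0).any():
            raise SignalMatrixError(f"negative value in {self.state} matrix")
        if self.state == "log2z" and vals.size:
            mean = vals.mean(axis=1)
            sd = vals.std(axis=1, ddof=1)
            if np.abs(mean).max() > 1e-9 or np.abs(sd - 1).max() > 1e-9:
                raise SignalMatrixError("log2z rows must have mean 0 and sd 1")


@dataclass
class TranscriptMap:
    """Many-to-one transcript→gene mapping."""

    transcript_to_gene: dict[str, str]

    @classmethod
    def read(cls, path: str | Path) -> "TranscriptMap":
        """Read a two-column TSV ``transcript_id<TAB>gene_id``."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if df.shape[1] != 2:
            raise SignalMatrixError(
                f"transcript map must have 2 columns, found {df.shape[1]}"
            )
        if df[0].duplicated().any():
            dup = df.loc[df[0].duplicated(), 0].iloc[0]
            raise SignalMatrixError(f"transcript {dup!r} mapped more than once")
        return cls(dict(zip(df[0], df[1])))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t, g in self.transcript_to_gene.items():
                fh.write(f"{t}\t{g}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_signal_matrix(
    path: str | Path, feature_label: str, state: str = "raw_counts"
) -> SignalMatrix:
    """Read a TSV signal matrix (header = sample ids, first column = entity ids).

    The normalization ``state`` is not inferable from the file body, so it is
    a required declaration by the caller (CLI option ``--state``).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SignalMatrixError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0:
        raise SignalMatrixError(f"{path}: no entities (empty body)")
    if df.shape[1] == 0:
        raise SignalMatrixError(f"{path}: malformed header (no sample columns)")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SignalMatrixError(f"{path}: duplicate entity id {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise SignalMatrixError(
                f"{path}: non-numeric or missing cell at entity {row!r}, sample {col!r}"
            )
        df[col] = coerced.astype(float)
    df.index = df.index.astype(str)
    return SignalMatrix(feature_label=feature_label, data=df, state=state)


def write_signal_matrix(m: SignalMatrix, path: str | Path) -> None:
    """Write the matrix as a TSV with an ``id`` first column."""
    out = m.data.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", float_format="%.12g")


def rpm_normalize(
    m: SignalMatrix, mapped_reads_per_sample: Mapping[str, float]
) -> SignalMatrix:
    """Reads-per-million normalization: raw[i,k] / (mapped_reads[k] / 1e6).

    Each sample's raw counts are divided by the total number of million
    mapped reads in that sample.
    """
    if m.state != "raw_counts":
        raise SignalMatrixError(f"rpm_normalize expects raw_counts, got {m.state}")
    missing = [s for s in m.sample_ids if s not in mapped_reads_per_sample]
    if missing:
        raise SignalMatrixError(f"missing mapped-read totals for samples {missing}")
    totals = np.array([float(mapped_reads_per_sample[s]) for s in m.sample_ids])
    if (totals <= 0).any():
        bad = m.sample_ids[int(np.argmin(totals))]
        raise SignalMatrixError(f"non-positive mapped-read total for sample {bad!r}")
    data = m.data / (totals / 1e6)
    return SignalMatrix(feature_label=m.feature_label, data=data, state="rpm")


def aggregate_transcripts(m: SignalMatrix, tm: TranscriptMap) -> SignalMatrix:
    """Collapse transcript rows to gene rows by the per-sample maximum.

    The gene-level signal is the highest value observed across all
    transcripts of the gene, independently in every sample.
    """
    orphans = [t for t in m.entity_ids if t not in tm.transcript_to_gene]
    if orphans:
        raise SignalMatrixError(
            f"{len(orphans)} transcripts absent from transcript map: "
            f"{orphans[:10]}"
        )
    genes = pd.Index([tm.transcript_to_gene[t] for t in m.entity_ids], name=None)
    data = m.data.groupby(genes, sort=True).max()
    data.index = data.index.astype(str)
    return SignalMatrix(feature_label=m.feature_label, data=data, state=m.state)


def filter_and_log2z(
    m: SignalMatrix, mode: str, ddof: int = 1
) -> SignalMatrix:
    """Entity filtering followed by log2(x+1) and per-row Z-scoring.

    mode="chromatin"
        keep entities with at least one strictly positive value in any
        sample (detectable mark in at least one cell type);
    mode="expression"
        keep entities strictly positive in ALL samples (expressed in all
        cell types).

    Rows that are constant after the log2 transform have an undefined
    Z-score; they are dropped and recorded on ``dropped_constant``.
    """
    if m.state not in ("rpm", "fpkm"):
        raise SignalMatrixError(f"filter_and_log2z expects rpm/fpkm, got {m.state}")
    if m.n_samples < 2:
        raise SignalMatrixError("Z-score undefined with fewer than 2 samples")
    if mode not in ("chromatin", "expression"):
        raise SignalMatrixError(f"unknown mode {mode!r}")

    vals = m.values
    if mode == "chromatin":
        keep = (vals > 0).any(axis=1)
    else:
        keep = (vals > 0).all(axis=1)
    df = m.data.loc[keep]

    logx = np.log2(df.to_numpy(dtype=float) + 1.0)
    sd = logx.std(axis=1, ddof=ddof)
    constant = sd == 0
    dropped = [str(e) for e in df.index[constant]]
    if dropped:
        logger.warning(
            "%s: dropping %d constant row(s) after log2: %s",
            m.feature_label,
            len(dropped),
            dropped[:5],
        )
    logx = logx[~constant]
    z = (logx - logx.mean(axis=1, keepdims=True)) / sd[~constant][:, None]
    out = pd.DataFrame(z, index=df.index[~constant], columns=df.columns)
    return SignalMatrix(
        feature_label=m.feature_label,
        data=out,
        state="log2z",
        dropped_constant=dropped,
    )


def read_mapped_totals(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV ``sample_id<TAB>mapped_reads``."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    if df.shape[1] != 2:
        raise SignalMatrixError("mapped-reads file must have 2 columns")
    return dict(zip(df[0], df[1].astype(float)))
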