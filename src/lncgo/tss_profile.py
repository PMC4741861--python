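"""Strand-aware binned read density around transcription start sites.

The ±2 kb window around each TSS is divided into 200 bins of 20 bp in
transcript orientation (bin 1 is 2 kb upstream; the TSS sits at the start
of bin 101). A read increments every bin it overlaps by at least one base
(``count="overlap"``) or only the bin holding its 5' end
(``count="fiveprime"``). Group profiles are per-bin means over the member
TSSs, and two groups are compared by the Pearson correlation of their
200-bin average densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

WINDOW = 2000
BIN_WIDTH = 20
N_BINS = 2 * WINDOW // BIN_WIDTH  # 200


class TssProfileError(ValueError):
    pass


@dataclass
class TssProfile:
    """Average read density per 20 bp bin over a group of TSSs."""

    group_label: str
    densities: np.ndarray
    bin_width: int = BIN_WIDTH
    window: tuple[int, int] = (-WINDOW, WINDOW)
    truncated: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        n = (self.window[1] - self.window[0]) // self.bin_width
        if self.densities.shape != (n,):
            raise TssProfileError(f"expected {n} bins, got {self.densities.shape}")
        if (self.densities < 0).any():
            raise TssProfileError("densities must be non-negative")


def read_bed(path: str | Path, min_cols: int = 3) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < min_cols:
        raise TssProfileError(
            f"{path}: BED needs ≥ {min_cols} columns, found {df.shape[1]}"
        )
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise TssProfileError(f"{path}: interval with end ≤ start")
    return df


def _tss_position(row) -> int:
    """TSS base of a BED6 record: start on +, end−1 on − strand."""
    return int(row.start) if row.strand == "+" else int(row.end) - 1


def bin_read_density(
    reads: pd.DataFrame,
    tss_list: pd.DataFrame,
    window: int = WINDOW,
    bin_width: int = BIN_WIDTH,
    count: str = "overlap",
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Per-TSS binned read counts in transcript orientation.

    Returns (tss name → bin-count vector, names of window-truncated TSSs).
    Minus-strand windows are reversed so bin 1 is always upstream; windows
    running past a chromosome start are kept with the missing bins at 0 and
    the TSS flagged.
    """
    if count not in ("overlap", "fiveprime"):
        raise TssProfileError(f"unknown count mode {count!r}")
    if "strand" not in tss_list.columns:
        raise TssProfileError("TSS records must be BED6 (strand required)")
    n_bins = 2 * window // bin_width
    by_chrom = {
        str(c): (g["start"].to_numpy(), g["end"].to_numpy(), g)
        for c, g in reads.groupby("chrom")
    }
    profiles: dict[str, np.ndarray] = {}
    truncated: list[str] = []
    for i, row in enumerate(tss_list.itertuples(index=False)):
        name = getattr(row, "name", None) or f"tss_{i}"
        t = _tss_position(row)
        minus = row.strand == "-"
        # genomic half-open span covered by the oriented window [-w, +w)
        lo, hi = (t - window + 1, t + window + 1) if minus else (t - window, t + window)
        vec = np.zeros(n_bins)
        if lo < 0:
            truncated.append(str(name))
        chrom = str(row.chrom)
        if chrom in by_chrom:
            starts, ends, g = by_chrom[chrom]
            hit = np.flatnonzero((starts < hi) & (ends > lo))
            for j in hit:
                s, e = int(starts[j]), int(ends[j])
                if count == "fiveprime":
                    if "strand" in g.columns and g["strand"].iloc[j] == "-":
                        s, e = e - 1, e
                    else:
                        s, e = s, s + 1
                    if not (lo <= s < hi):
                        continue
                a, b = max(s, lo, 0), min(e, hi)
                if a >= b:
                    continue
                if minus:
                    b_lo = (t - (b - 1) + window) // bin_width
                    b_hi = (t - a + window) // bin_width
                else:
                    b_lo = (a - t + window) // bin_width
                    b_hi = (b - 1 - t + window) // bin_width
                vec[int(b_lo) : int(b_hi) + 1] += 1
        profiles[str(name)] = vec
    return profiles, truncated


def average_profile(
    per_tss_vectors: dict[str, np.ndarray],
    group_members: list[str],
    group_label: str = "group",
) -> TssProfile:
    """Per-bin arithmetic mean over the group's member TSS vectors."""
    missing = [m for m in group_members if m not in per_tss_vectors]
    if missing:
        raise TssProfileError(f"members without profiles: {missing[:5]}")
    if not group_members:
        raise TssProfileError("empty group")
    stack = np.stack([per_tss_vectors[m] for m in group_members])
    return TssProfile(group_label=group_label, densities=stack.mean(axis=0))


def profile_correlation(a: TssProfile, b: TssProfile) -> float:
    """Pearson r between two average profiles over their paired bins."""
    if a.densities.shape != b.densities.shape:
        raise TssProfileError("profiles have different bin counts")
    if a.densities.std() == 0 or b.densities.std() == 0:
        raise TssProfileError("constant profile (correlation undefined)")
    return float(pearsonr(a.densities, b.densities).statistic)


def write_profiles(profiles: list[TssProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {p.group_label: p.densities for p in profiles},
        index=[f"bin_{i + 1}" for i in range(len(profiles[0].densities))],
    )
    df.index.name = "bin"
    df.to_csv(path, sep="\t", float_format="%.10g")
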