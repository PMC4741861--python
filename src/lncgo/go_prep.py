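"""GO annotation propagation, term-size filtering and gold-standard sampling.

Per-term gene memberships are built from direct gene→term annotations plus
the ontology DAG: a term's propagated set is the union of its own direct
genes and those of all its descendants (the true-path rule). Terms are
retained only at intermediate sizes (more than ``min_genes``, fewer than
``max_genes`` annotated genes in the analysis universe); very small terms
are statistically unstable and very large ones uninformative.

For each retained term a gold standard is sampled: the gold-standard
positives (GSP) are the term's propagated genes restricted to the universe
of genes present in both the chromatin and expression profiles, and each of
``n_gsn`` gold-standard negative sets (GSN) is a size-matched uniform sample
without replacement from the remaining universe.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

NAMESPACES = ("BP", "CC", "MF")

#: Default strict term-size bounds: keep n with 20 < n < 2000.
MIN_GENES_EXCLUSIVE = 20
MAX_GENES_EXCLUSIVE = 2000


class GoPrepError(ValueError):
    """Raised on DAG or gold-standard construction failures."""


@dataclass
class GoTermSet:
    """A GO term with direct and DAG-propagated gene membership."""

    term_id: str
    namespace: str
    direct_genes: frozenset[str]
    propagated_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise GoPrepError(
                f"{self.term_id}: namespace {self.namespace!r} not in {NAMESPACES}"
            )
        if not self.direct_genes <= self.propagated_genes:
            raise GoPrepError(f"{self.term_id}: direct genes not ⊆ propagated genes")


@dataclass
class GoldStandard:
    """Per-term GSP plus size-matched GSN replicates.

    Every GSN replicate has exactly ``len(gsp)`` genes, is disjoint from the
    GSP, and is reconstructible in isolation from ``(rng_seed, term_id,
    replicate index)``.
    """

    term_id: str
    gsp: list[str]
    gsn_replicates: list[list[str]]
    rng_seed: int

    def __post_init__(self) -> None:
        gsp_set = set(self.gsp)
        for r, gsn in enumerate(self.gsn_replicates):
            if len(gsn) != len(self.gsp):
                raise GoPrepError(
                    f"{self.term_id}: GSN replicate {r} has {len(gsn)} genes, "
                    f"expected {len(self.gsp)}"
                )
            if gsp_set & set(gsn):
                raise GoPrepError(f"{self.term_id}: GSN replicate {r} overlaps GSP")

    @property
    def n_gsn(self) -> int:
        return len(self.gsn_replicates)


def replicate_seed(master_seed: int, term_id: str, replicate: int) -> int:
    """Deterministic per-(seed, term, replicate) RNG seed below 2^31."""
    h = zlib.crc32(term_id.encode("utf-8"))
    return (master_seed * 1_000_003 + h * 7919 + replicate) % (2**31 - 1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def propagate_annotations(
    direct: Mapping[str, Iterable[str]],
    dag: Iterable[tuple[str, str]],
    namespaces: Mapping[str, str] | None = None,
    propagation: str = "full",
) -> dict[str, GoTermSet]:
    """Union each term's direct genes with its descendants' direct genes.

    Parameters
    ----------
    direct
        term → iterable of directly annotated gene ids.
    dag
        parent→child edge list. Terms annotated but absent from the DAG are
        treated as isolated leaves.
    namespaces
        optional term → namespace map; defaults to "BP".
    propagation
        "full" unions over all DAG descendants; "one_level" only over
        immediate children.
    """
    if propagation not in ("full", "one_level"):
        raise GoPrepError(f"unknown propagation mode {propagation!r}")
    g = nx.DiGraph()
    g.add_edges_from(dag)
    g.add_nodes_from(direct.keys())
    if not nx.is_directed_acyclic_graph(g):
        cycle_term = next(iter(nx.find_cycle(g)))[0]
        raise GoPrepError(f"ontology graph has a cycle through {cycle_term!r}")

    direct_sets = {t: frozenset(gs) for t, gs in direct.items()}
    out: dict[str, GoTermSet] = {}
    for term in g.nodes:
        if propagation == "full":
            below = nx.descendants(g, term)
        else:
            below = set(g.successors(term))
        genes = set(direct_sets.get(term, frozenset()))
        for d in below:
            genes |= direct_sets.get(d, frozenset())
        ns = namespaces.get(term, "BP") if namespaces else "BP"
        out[term] = GoTermSet(
            term_id=term,
            namespace=ns,
            direct_genes=direct_sets.get(term, frozenset()),
            propagated_genes=frozenset(genes),
        )
    return out


def size_filter(
    terms: Mapping[str, GoTermSet],
    universe: set[str],
    min_genes: int = MIN_GENES_EXCLUSIVE,
    max_genes: int = MAX_GENES_EXCLUSIVE,
) -> list[str]:
    """Terms whose in-universe propagated size n satisfies min < n < max.

    Both bounds are strict: with the defaults a term is kept only for
    n in 21..1999.
    """
    kept = []
    for term_id, ts in terms.items():
        n = len(ts.propagated_genes & universe)
        if min_genes < n < max_genes:
            kept.append(term_id)
    return sorted(kept)


def build_gold_standard(
    term: GoTermSet,
    universe: set[str],
    n_gsn: int = 100,
    seed: int = 0,
) -> GoldStandard:
    """Sample ``n_gsn`` size-matched negative gene sets for one term.

    The GSP is the term's propagated membership restricted to ``universe``
    (genes with both chromatin and expression profiles). Each GSN replicate
    is drawn uniformly without replacement from ``universe \\ GSP`` with a
    deterministic seed derived from ``(seed, term_id, replicate)``.
    """
    gsp = sorted(term.propagated_genes & universe)
    if not gsp:
        raise GoPrepError(f"{term.term_id}: no GSP genes in universe")
    remaining = sorted(universe - set(gsp))
    if len(remaining) < len(gsp):
        raise GoPrepError(
            f"{term.term_id}: need {len(gsp)} genes for each GSN but only "
            f"{len(remaining)} remain in the universe"
        )
    remaining_arr = np.array(remaining, dtype=object)
    replicates = []
    for r in range(n_gsn):
        rng = np.random.default_rng(replicate_seed(seed, term.term_id, r))
        picked = rng.choice(len(remaining_arr), size=len(gsp), replace=False)
        replicates.append([str(x) for x in remaining_arr[picked]])
    return GoldStandard(
        term_id=term.term_id, gsp=gsp, gsn_replicates=replicates, rng_seed=seed
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a gene2go-style TSV ``gene_id<TAB>term_id[<TAB>namespace]``.

    Returns (term → direct gene set, term → namespace).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise GoPrepError("annotation file needs at least 2 columns")
    direct: dict[str, set[str]] = {}
    namespaces: dict[str, str] = {}
    for row in df.itertuples(index=False):
        gene, term = row[0], row[1]
        direct.setdefault(term, set()).add(gene)
        if len(row) > 2 and isinstance(row[2], str):
            namespaces[term] = row[2]
    return direct, namespaces


def read_dag(path: str | Path) -> list[tuple[str, str]]:
    """Read DAG edges from a two-column TSV (parent, child) or an OBO file.

    OBO parsing keeps only ``is_a`` edges; obonet orients edges child→parent,
    so they are reversed here to parent→child.
    """
    path = Path(path)
    if path.suffix == ".obo":
        import obonet

        g = obonet.read_obo(path)
        edges = []
        for child, parent, key in g.edges(keys=True):
            if key == "is_a":
                edges.append((parent, child))
        return edges
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise GoPrepError("DAG TSV must have exactly 2 columns (parent, child)")
    return list(df.itertuples(index=False, name=None))


def write_gold_standard(gs: GoldStandard, path: str | Path) -> None:
    """One TSV per term: column 0 is the set label (gsp / gsn_<r>)."""
    with open(path, "w") as fh:
        fh.write(f"# term={gs.term_id}\tseed={gs.rng_seed}\n")
        fh.write("gsp\t" + "\t".join(gs.gsp) + "\n")
        for r, gsn in enumerate(gs.gsn_replicates):
            fh.write(f"gsn_{r}\t" + "\t".join(gsn) + "\n")


def read_gold_standard(path: str | Path) -> GoldStandard:
    term_id, seed = "", 0
    gsp: list[str] = []
    gsns: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].strip().split("\t"):
                    k, _, v = part.partition("=")
                    if k == "term":
                        term_id = v
                    elif k == "seed":
                        seed = int(v)
                continue
            fields = line.split("\t")
            if fields[0] == "gsp":
                gsp = fields[1:]
            elif fields[0].startswith("gsn_"):
                gsns.append(fields[1:])
    return GoldStandard(term_id=term_id, gsp=gsp, gsn_replicates=gsns, rng_seed=seed)
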