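"""Multilocus genotype calling and clonal-diversity summaries from
microsatellite (SSR) allele sets.

Polyploid SSR profiles are treated as dominant presence/absence markers:
allele dosage cannot be resolved in a dodecaploid, so a sample's state
at a locus is simply the set of fragment sizes observed.  Samples with
identical allele sets at every locus form one multilocus genotype
(a putative clone).  Dissimilarity between samples is the number of
alleles present in exactly one of the two (symmetric-difference count,
summed over loci), and clonal structure is displayed as a minimum
spanning network: a minimum spanning tree over genotype dissimilarities
augmented with every non-tree edge that could replace a tree edge of
equal weight (the union of all minimum spanning trees).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

#: table columns that are not locus columns
METADATA_COLUMNS = ("sample_id", "cytotype", "origin")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (table-formatting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def parse_alleles(value) -> frozenset[float]:
    """Parse a slash-separated allele string; '' or NaN is an empty set
    (failed amplification)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    if isinstance(value, (set, frozenset)):
        return frozenset(value)
    s = str(value).strip()
    if not s:
        return frozenset()
    return frozenset(float(tok) for tok in s.split("/"))


def serialize_alleles(alleles: Iterable[float]) -> str:
    def fmt(a: float) -> str:
        return str(int(a)) if float(a).is_integer() else repr(float(a))
    return "/".join(fmt(a) for a in sorted(alleles))


def locus_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in METADATA_COLUMNS]


def _allele_sets(df: pd.DataFrame) -> dict[str, list[frozenset[float]]]:
    return {locus: [parse_alleles(v) for v in df[locus]]
            for locus in locus_columns(df)}


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_alleles(df: pd.DataFrame, bin_width: float = 1.0,
                exclusions: Sequence[tuple[str, float]] = ()) -> pd.DataFrame:
    """Collapse fragment sizes into binning classes and drop excluded alleles.

    Sizes at a locus whose distance from the start of a bin is strictly
    less than ``bin_width`` collapse to one allele, represented by the
    count-weighted mean of its members rounded to the nearest integer
    bp.  Integer sizes at the default ``bin_width=1`` therefore pass
    through unchanged.  ``exclusions`` lists ``(locus, binned_size)``
    pairs removed from every sample, e.g. suspected indel artefacts.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    df = df.copy()
    excluded = {(locus, float(size)) for locus, size in exclusions}
    for locus in locus_columns(df):
        sets = [parse_alleles(v) for v in df[locus]]
        counts: dict[float, int] = {}
        for s in sets:
            for a in s:
                if a < 0:
                    raise ValueError(f"negative fragment size {a} at {locus}")
                counts[a] = counts.get(a, 0) + 1
        mapping: dict[float, float] = {}
        cluster: list[float] = []
        for size in sorted(counts):
            if cluster and size - cluster[0] >= bin_width:
                _assign_bin(cluster, counts, mapping)
                cluster = []
            cluster.append(size)
        if cluster:
            _assign_bin(cluster, counts, mapping)
        binned = []
        for s in sets:
            out = {mapping[a] for a in s}
            out = {a for a in out if (locus, a) not in excluded}
            binned.append(serialize_alleles(out))
        df[locus] = binned
    return df


def _assign_bin(cluster: list[float], counts: Mapping[float, int],
                mapping: dict[float, float]) -> None:
    total = sum(counts[a] for a in cluster)
    wmean = sum(a * counts[a] for a in cluster) / total
    rep = float(round_half_up(wmean, 0))
    for a in cluster:
        mapping[a] = rep


# ---------------------------------------------------------------------------
# genotype calling
# ---------------------------------------------------------------------------

def _label_sequence():
    for r in itertools.count(1):
        for letters in itertools.product(string.ascii_uppercase, repeat=r):
            yield "".join(letters)


@dataclass
class GenotypeTable:
    """Multilocus genotype assignments and frequency summary.

    ``summary`` has one row per genotype label (descending count) with
    overall and per-cytotype counts and percentages (half-up rounded to
    one decimal).  ``alleles`` maps label -> locus -> allele set.
    """

    assignments: pd.Series
    summary: pd.DataFrame
    alleles: dict[str, dict[str, frozenset[float]]]
    loci: tuple[str, ...]
    n_distinct_alleles: int
    modal_allele_count: int

    @property
    def n_genotypes(self) -> int:
        return len(self.summary)

    def to_frame(self) -> pd.DataFrame:
        """One representative row per genotype, in the SSR table format."""
        rows = []
        for label in self.summary.index:
            row = {"sample_id": label, "cytotype": "", "origin": ""}
            for locus in self.loci:
                row[locus] = serialize_alleles(self.alleles[label][locus])
            rows.append(row)
        return pd.DataFrame.from_records(rows)


def call_multilocus_genotypes(df: pd.DataFrame) -> GenotypeTable:
    """Group samples with identical allele sets at every locus.

    Labels are assigned A, B, C, ... in descending count order; count
    ties are broken lexicographically on the serialized multilocus
    allele string so that labelling is invariant to sample order.
    """
    if len(df) == 0:
        raise ValueError("at least one sample is required")
    loci = tuple(locus_columns(df))
    if not loci:
        raise ValueError("no locus columns found")
    sets = _allele_sets(df)
    keys = ["|".join(serialize_alleles(sets[locus][i]) for locus in loci)
            for i in range(len(df))]
    df = df.reset_index(drop=True)
    key_series = pd.Series(keys)
    counts = key_series.value_counts()
    ordered = sorted(counts.index, key=lambda k: (-counts[k], k))
    labels = {key: lab for key, lab in zip(ordered, _label_sequence())}
    assignments = pd.Series([labels[k] for k in keys],
                            index=df["sample_id"], name="genotype")

    strata = [c for c in ("hybrid", "allopolyploid")
              if (df["cytotype"] == c).any()] if "cytotype" in df else []
    n_total = len(df)
    rows = {}
    for key in ordered:
        lab = labels[key]
        mask = key_series == key
        row = {"count": int(mask.sum()),
               "frequency": round_half_up(100.0 * mask.sum() / n_total)}
        for stratum in strata:
            smask = (df["cytotype"] == stratum).to_numpy()
            size = int(smask.sum())
            c = int((mask.to_numpy() & smask).sum())
            row[f"{stratum}_count"] = c
            row[f"{stratum}_frequency"] = (
                round_half_up(100.0 * c / size) if size else np.nan)
        rows[lab] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "genotype"

    alleles: dict[str, dict[str, frozenset[float]]] = {}
    for key in ordered:
        i = keys.index(key)
        alleles[labels[key]] = {locus: sets[locus][i] for locus in loci}

    distinct = {(locus, a) for locus in loci
                for s in sets[locus] for a in s}
    modal = sum(len(alleles[summary.index[0]][locus]) for locus in loci)
    return GenotypeTable(assignments=assignments, summary=summary,
                         alleles=alleles, loci=loci,
                         n_distinct_alleles=len(distinct),
                         modal_allele_count=modal)


def frequency_table(df: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Per-locus genotype-class frequencies (carrier percentages by
    cytotype and overall), one row per distinct allele set at ``locus``."""
    if locus not in df.columns or locus in METADATA_COLUMNS:
        raise KeyError(f"unknown locus {locus!r}")
    classes = [serialize_alleles(parse_alleles(v)) for v in df[locus]]
    cls = pd.Series(classes)
    cytos = df["cytotype"].reset_index(drop=True)
    n_total = len(df)
    strata = [c for c in ("hybrid", "allopolyploid") if (cytos == c).any()]
    counts = cls.value_counts()
    ordered = sorted(counts.index, key=lambda k: (-counts[k], k))
    rows = []
    for key in ordered:
        mask = (cls == key).to_numpy()
        row = {"alleles": key}
        for stratum in strata:
            smask = (cytos == stratum).to_numpy()
            size = int(smask.sum())
            c = int((mask & smask).sum())
            row[f"{stratum}_count"] = c
            row[f"{stratum}_pct"] = round_half_up(100.0 * c / size) if size else np.nan
        row["total_count"] = int(mask.sum())
        row["total_pct"] = round_half_up(100.0 * mask.sum() / n_total)
        rows.append(row)
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# dissimilarity and minimum spanning network
# ---------------------------------------------------------------------------

def dissimilarity_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise allele-difference counts (symmetric difference summed
    over loci).

    A locus with an empty allele set in either sample (failed
    amplification) is treated as missing for that pair and contributes
    zero, so amplification failures do not inflate divergence.
    """
    ids = list(df["sample_id"]) if "sample_id" in df else list(df.index)
    sets = _allele_sets(df)
    n = len(df)
    D = np.zeros((n, n))
    for locus, locus_sets in sets.items():
        alleles = sorted({a for s in locus_sets for a in s})
        if not alleles:
            continue
        idx = {a: j for j, a in enumerate(alleles)}
        P = np.zeros((n, len(alleles)))
        for i, s in enumerate(locus_sets):
            for a in s:
                P[i, idx[a]] = 1.0
        sizes = P.sum(axis=1)
        inter = P @ P.T
        symdiff = sizes[:, None] + sizes[None, :] - 2.0 * inter
        present = sizes > 0
        valid = present[:, None] & present[None, :]
        D += np.where(valid, symdiff, 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class MSNetwork:
    """Minimum spanning network over genotype dissimilarities.

    ``graph`` is the complete weighted graph with a boolean ``in_msn``
    attribute per edge; MSN edges are the union of all minimum spanning
    trees (a Kruskal tree plus every tied alternative edge).
    """

    graph: nx.Graph
    tree_weight: float

    def msn_subgraph(self) -> nx.Graph:
        keep = [(u, v) for u, v, d in self.graph.edges(data=True) if d["in_msn"]]
        return self.graph.edge_subgraph(keep).copy()

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["weight"], d["in_msn"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "in_msn"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.msn_subgraph(), path)

    def write_edgelist(self, path) -> None:
        self.edge_table().to_csv(path, index=False)


def minimum_spanning_network(d, node_sizes: Mapping[str, int] | None = None
                             ) -> MSNetwork:
    """Build the tie-retaining minimum spanning network.

    ``d`` is a symmetric non-negative dissimilarity matrix (DataFrame
    with labels, or array).  A non-tree edge is retained whenever its
    weight equals the maximum edge weight on the tree path between its
    endpoints — exactly the condition for it to belong to *some*
    minimum spanning tree.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        M = d.to_numpy(dtype=float)
    else:
        M = np.asarray(d, dtype=float)
        labels = list(range(M.shape[0]))
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if np.isnan(M).any():
        raise ValueError("dissimilarity matrix contains NaN weights")
    if not np.allclose(M, M.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if (np.diag(M) != 0).any():
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    if (M < 0).any():
        raise ValueError("dissimilarity matrix must be non-negative")

    G = nx.Graph()
    for i, lab in enumerate(labels):
        size = 1 if node_sizes is None else int(node_sizes.get(lab, 1))
        G.add_node(lab, size=size)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            G.add_edge(labels[i], labels[j], weight=float(M[i, j]), in_msn=False)

    if n == 1:
        return MSNetwork(graph=G, tree_weight=0.0)

    T = nx.minimum_spanning_tree(G, algorithm="kruskal")
    tree_weight = float(sum(d["weight"] for _, _, d in T.edges(data=True)))
    for u, v in T.edges():
        G[u][v]["in_msn"] = True
    for u, v, data in G.edges(data=True):
        if data["in_msn"]:
            continue
        path = nx.shortest_path(T, u, v)
        max_w = max(T[a][b]["weight"] for a, b in zip(path, path[1:]))
        if abs(data["weight"] - max_w) <= 1e-9 * max(1.0, abs(max_w)):
            data["in_msn"] = True
    return MSNetwork(graph=G, tree_weight=tree_weight)
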