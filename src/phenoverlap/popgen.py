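"""Barcode and dominant-marker diversity statistics and haplotype networks.

Sequence statistics operate on pre-aligned CO1 barcode fragments.  Sites
containing a gap or an ambiguous base (``N``) in *any* sequence are
excluded before every computation (complete deletion, the default of the
classic desktop tools); per-pair deletion is available behind a flag for
nucleotide diversity.

Haplotype diversity uses Nei's unbiased estimator
``Hd = n (1 - sum p_i^2) / (n - 1)``; nucleotide diversity is the mean
pairwise proportion of differing analyzed sites.  Dominant (band
presence/absence) markers get the percentage of variable markers and a
band-state gene diversity; a Hardy-Weinberg square-root allele-frequency
variant is exposed behind a flag since dominant-marker tools differ here.

The haplotype network is a median-joining construction: a minimum
spanning network over observed haplotypes, augmented with consensus
("median") vectors of connected triplets whenever that strictly reduces
the total number of mutational steps, then pruned of obsolete medians.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, UndefinedStatisticError, ValidationError

_ALPHABET = set("ACGTN-")


@dataclass
class Alignment:
    """A set of equal-length aligned sequences over {A, C, G, T, N, -}."""

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValidationError("ids and sequences differ in length")
        if not self.sequences:
            raise ValidationError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValidationError(f"sequences have differing lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - _ALPHABET
        if bad:
            raise ValidationError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def analyzed_sites(self) -> list[int]:
        """Site indices free of gaps and Ns in every sequence (complete deletion)."""
        cols = np.array([list(s) for s in self.sequences])
        keep = ~np.isin(cols, ["N", "-"]).any(axis=0)
        return [int(i) for i in np.flatnonzero(keep)]

    def analyzed_matrix(self) -> np.ndarray:
        """Character matrix restricted to analyzed sites (n × L_analyzed)."""
        cols = np.array([list(s) for s in self.sequences])
        return cols[:, self.analyzed_sites()]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in zip(self.ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class HaplotypeSet:
    """Distinct haplotypes (on analyzed sites) with their sample counts."""

    haplotypes: list[str]
    counts: list[int]
    assignment: Mapping[str, int]
    n: int
    analyzed_length: int = 0

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n


def collapse_haplotypes(aln: Alignment) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes after complete deletion.

    Haplotypes are ordered by decreasing count, ties by first appearance.
    """
    mat = aln.analyzed_matrix()
    strings = ["".join(row) for row in mat]
    order: dict[str, int] = {}
    counts: dict[str, int] = {}
    for s in strings:
        if s not in order:
            order[s] = len(order)
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts, key=lambda s: (-counts[s], order[s]))
    index = {s: i for i, s in enumerate(ordered)}
    assignment = {sid: index[s] for sid, s in zip(aln.ids, strings)}
    return HaplotypeSet(
        haplotypes=ordered,
        counts=[counts[s] for s in ordered],
        assignment=assignment,
        n=aln.n,
        analyzed_length=mat.shape[1],
    )


def haplotype_diversity(hs: HaplotypeSet) -> float:
    """Nei's unbiased haplotype diversity ``n (1 - sum p_i^2) / (n - 1)``."""
    if hs.n < 2:
        raise UndefinedStatisticError("haplotype diversity undefined for n < 2")
    p = hs.frequencies
    return hs.n / (hs.n - 1) * (1.0 - float((p ** 2).sum()))


def nucleotide_diversity(aln: Alignment, deletion: str = "complete") -> float:
    """Mean pairwise proportion of differing sites.

    ``deletion="complete"`` (default) drops every site with a gap/N in
    any sequence and divides by the analyzed length; ``"pairwise"``
    compares each pair over its own ungapped sites.
    """
    if aln.n < 2:
        raise UndefinedStatisticError("nucleotide diversity undefined for n < 2")
    if deletion == "complete":
        mat = aln.analyzed_matrix()
        L = mat.shape[1]
        if L == 0:
            return 0.0
        total = 0
        for i, j in itertools.combinations(range(aln.n), 2):
            total += int((mat[i] != mat[j]).sum())
        n_pairs = aln.n * (aln.n - 1) // 2
        return total / n_pairs / L
    if deletion == "pairwise":
        cols = np.array([list(s) for s in aln.sequences])
        valid = ~np.isin(cols, ["N", "-"])
        vals = []
        for i, j in itertools.combinations(range(aln.n), 2):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L:
                vals.append(int((cols[i][both] != cols[j][both]).sum()) / L)
        if not vals:
            raise UndefinedStatisticError("no comparable sites in any pair")
        return float(np.mean(vals))
    raise ContractError(f"unknown deletion mode {deletion!r}")


def site_classes(aln: Alignment) -> tuple[int, int]:
    """(segregating sites, parsimony-informative sites) over analyzed sites.

    A site is segregating when it carries >= 2 states; parsimony
    informative when >= 2 states are each carried by >= 2 sequences.
    """
    mat = aln.analyzed_matrix()
    s = pis = 0
    for col in mat.T:
        _, counts = np.unique(col, return_counts=True)
        if len(counts) >= 2:
            s += 1
            if (counts >= 2).sum() >= 2:
                pis += 1
    return s, pis


@dataclass(frozen=True)
class DiversityStats:
    """Per-sample sequence diversity summary (one table row per grouping)."""

    n: int
    n_haplotypes: int
    segregating_sites: int
    parsimony_informative: int
    haplotype_diversity: float | None
    nucleotide_diversity: float | None
    analyzed_length: int


def diversity_stats(aln: Alignment) -> DiversityStats:
    """All sequence diversity statistics for one alignment."""
    hs = collapse_haplotypes(aln)
    s, pis = site_classes(aln)
    hd = pi = None
    if aln.n >= 2:
        hd = haplotype_diversity(hs)
        pi = nucleotide_diversity(aln)
    return DiversityStats(
        n=aln.n,
        n_haplotypes=len(hs.haplotypes),
        segregating_sites=s,
        parsimony_informative=pis,
        haplotype_diversity=hd,
        nucleotide_diversity=pi,
        analyzed_length=hs.analyzed_length,
    )


@dataclass
class AFLPMatrix:
    """Individuals × loci dominant-marker matrix (1 band, 0 none, NaN missing)."""

    data: np.ndarray
    locus_ids: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("AFLP data must be 2-D (individuals × loci)")
        vals = self.data[~np.isnan(self.data)]
        if not np.isin(vals, [0.0, 1.0]).all():
            raise ValidationError("AFLP values must be 0, 1 or missing")
        if not self.locus_ids:
            self.locus_ids = [f"L{i+1}" for i in range(self.data.shape[1])]
        if not self.individual_ids:
            self.individual_ids = [f"ind{i+1}" for i in range(self.data.shape[0])]


def aflp_stats(m: AFLPMatrix, estimator: str = "band") -> tuple[float, float]:
    """(percentage of variable markers, gene diversity) for dominant markers.

    VM% is the percentage of loci with both band states observed among
    non-missing individuals.  With ``estimator="band"`` (default), gene
    diversity per locus is ``1 - f1^2 - f0^2`` on the observed band-state
    frequencies; ``estimator="hw"`` first reconstructs the null-allele
    frequency as ``q = sqrt(f0)`` assuming Hardy-Weinberg proportions and
    returns ``2 q (1 - q)`` per locus.  Loci with all values missing are
    excluded with a warning.
    """
    import warnings as _warnings

    if m.data.shape[0] < 1:
        raise ContractError("need at least one individual")
    gdivs = []
    variable = 0
    total = 0
    for j in range(m.data.shape[1]):
        col = m.data[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            _warnings.warn(f"locus {m.locus_ids[j]} entirely missing; excluded", stacklevel=2)
            continue
        total += 1
        f1 = float(obs.mean())
        f0 = 1.0 - f1
        if 0.0 < f1 < 1.0:
            variable += 1
        if estimator == "band":
            gdivs.append(1.0 - f1 ** 2 - f0 ** 2)
        elif estimator == "hw":
            q = float(np.sqrt(f0))
            gdivs.append(2.0 * q * (1.0 - q))
        else:
            raise ContractError(f"unknown estimator {estimator!r}")
    if total == 0:
        raise ContractError("no scorable loci")
    return 100.0 * variable / total, float(np.mean(gdivs))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def minimum_spanning_network(
    nodes: Sequence[str],
) -> nx.Graph:
    """Union of all minimum spanning trees under Hamming distance.

    Kruskal by distance level: edges of each successive distance are
    added together whenever they join components as they stood before
    that level, so every tie is kept.
    """
    nodes = list(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) < 2:
        return g
    edges = sorted(
        (hamming(u, v), u, v)
        for u, v in itertools.combinations(nodes, 2)
    )
    comp = {n: i for i, n in enumerate(nodes)}
    for dist, group in itertools.groupby(edges, key=lambda e: e[0]):
        batch = [(u, v) for _, u, v in group if comp[u] != comp[v]]
        for u, v in batch:
            g.add_edge(u, v, weight=dist)
        # merge components only after the whole level, keeping ties
        for u, v in batch:
            cu, cv = comp[u], comp[v]
            if cu != cv:
                for n, c in comp.items():
                    if c == cv:
                        comp[n] = cu
        if len(set(comp.values())) == 1:
            break
    return g


def _mst_cost(nodes: Sequence[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=hamming(u, v))
    return int(sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True)))


def _majority_median(u: str, v: str, w: str) -> str:
    """Site-wise majority consensus; ties (3 distinct states) keep ``u``'s state."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(a)
    return "".join(out)


@dataclass
class HaploNetwork:
    """Median-joining haplotype network.

    ``graph`` is an undirected networkx graph whose nodes are haplotype
    strings; node attributes carry ``count`` (0 for inferred median
    vectors), ``observed``, and optional annotations.  Edge attribute
    ``weight`` is the number of mutational steps.
    """

    graph: nx.Graph
    observed: list[str]
    medians: list[str]

    @property
    def total_cost(self) -> int:
        """Minimum total mutational steps connecting all network nodes.

        The display graph keeps every tied minimum-spanning link, so the
        cost is the minimum spanning cost over the node set (observed
        haplotypes plus inferred medians), i.e. the Steiner-style length
        the median vectors were added to reduce.
        """
        return _mst_cost(list(self.graph.nodes))

    def diameter_steps(self) -> int:
        """Longest shortest path (in mutational steps) between observed nodes."""
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="weight"))
        return max(
            lengths[u][v] for u in self.observed for v in self.observed
        )

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a,node_b,steps\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u},{v},{d['weight']}\n")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))


def median_joining_network(
    hs: HaplotypeSet,
    epsilon: int = 0,
    annotations: Mapping[str, Mapping] | None = None,
    max_rounds: int = 20,
) -> HaploNetwork:
    """Build a median-joining network over a haplotype set.

    Starts from the minimum spanning network of the observed haplotypes,
    then repeatedly considers triplets that are mutually connected
    through the network and adds their site-wise majority consensus when
    doing so strictly reduces the minimum-spanning cost of the node set.
    Median vectors of degree <= 2 whose removal does not increase that
    cost are pruned.  Deterministic for a fixed haplotype order;
    ``epsilon`` is kept at 0 (only cost-reducing medians are added).

    A single haplotype yields a single-node network.
    """
    if epsilon != 0:
        raise ContractError("only epsilon = 0 is supported")
    observed = list(hs.haplotypes)
    nodes = list(observed)
    for _ in range(max_rounds):
        msn = minimum_spanning_network(nodes)
        best = None
        current_cost = _mst_cost(nodes)
        candidates = set()
        for center in msn.nodes:
            nbrs = sorted(msn.neighbors(center))
            for a, b in itertools.combinations(nbrs, 2):
                candidates.add(tuple(sorted((center, a, b))))
        for trip in sorted(candidates):
            med = _majority_median(*trip)
            if med in nodes:
                continue
            cost = _mst_cost(nodes + [med])
            if cost < current_cost and (best is None or cost < best[0] or
                                        (cost == best[0] and med < best[1])):
                best = (cost, med)
        if best is None:
            break
        nodes.append(best[1])
    # prune obsolete medians
    changed = True
    while changed:
        changed = False
        msn = minimum_spanning_network(nodes)
        base = _mst_cost(nodes)
        for med in sorted(set(nodes) - set(observed)):
            if msn.degree(med) <= 2:
                without = [n for n in nodes if n != med]
                if _mst_cost(without) <= base:
                    nodes = without
                    changed = True
                    break
    graph = minimum_spanning_network(nodes)
    counts = dict(zip(hs.haplotypes, hs.counts))
    for node in graph.nodes:
        graph.nodes[node]["count"] = counts.get(node, 0)
        graph.nodes[node]["observed"] = node in counts
        if annotations and node in annotations:
            graph.nodes[node].update(annotations[node])
    return HaploNetwork(
        graph=graph,
        observed=observed,
        medians=sorted(set(nodes) - set(observed)),
    )
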