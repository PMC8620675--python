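"""Repeat discovery from raw reads by dense biclustering of the k-mer/read
incidence graph.

The bipartite graph G{V1, V2, E} has k-mers as V1, reads as V2, and an edge
whenever the k-mer (or its reverse complement, in canonical mode) occurs in
the read.  The density of a bipartite subgraph on (Vs, Vt) is
|Est| / (|Vs| * |Vt|); it is 1 exactly for bicliques.  Dense biclusters are
found by a deterministic greedy seed-and-grow with a prune phase, their
k-mers are assembled over exact (k-1)-overlaps into consensus chains
("kChains"), and the chains are the putative repetitive elements handed to
quantification.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import Read, revcomp

__all__ = [
    "IncidenceGraph",
    "Bicluster",
    "KChain",
    "DiscoveryParams",
    "extract_kmers",
    "graph_density",
    "find_biclusters",
    "assemble_kchains",
    "discover",
    "canonical",
]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class IncidenceGraph:
    """Bipartite k-mer x read incidence structure with both-way adjacency.

    ``kmer_reads[m]`` is the set of read indices containing m; ``read_kmers``
    the inverse.  Edge multiplicity within one read is collapsed.
    """

    k: int
    canonical: bool
    read_ids: list[str]
    kmer_reads: dict[str, set[int]]
    read_kmers: dict[int, set[str]] = field(repr=False)

    @property
    def kmers(self) -> set[str]:
        return set(self.kmer_reads)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.kmer_reads.values())

    def degree(self, kmer: str) -> int:
        return len(self.kmer_reads[kmer])


@dataclass
class Bicluster:
    """A dense bipartite subgraph: k-mer subset Vs, read subset Vt."""

    Vs: set[str]
    Vt: set[int]
    Est: int

    @property
    def density(self) -> float:
        return self.Est / (len(self.Vs) * len(self.Vt))

    @property
    def objective(self) -> float:
        # |Vs| * |Vt| * density == Est; kept explicit for the ordering contract
        return len(self.Vs) * len(self.Vt) * self.density


@dataclass(frozen=True)
class KChain:
    """A putative repetitive element assembled from a bicluster's k-mers."""

    id: str
    seq: str
    source_bicluster: int

    @property
    def length(self) -> int:
        return len(self.seq)


def _read_kmer_set(seq: str, k: int, use_canonical: bool) -> set[str]:
    n = len(seq)
    if n < k:
        return set()
    if use_canonical:
        rc = revcomp(seq)
        out = set()
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            if "N" in fwd:
                continue
            bwd = rc[n - k - i : n - i]
            out.add(fwd if fwd <= bwd else bwd)
        return out
    return {seq[i : i + k] for i in range(n - k + 1) if "N" not in seq[i : i + k]}


# --- 2-bit integer k-mer encoding (A=0 C=1 G=2 T=3, so integer order equals
# lexicographic order and canonicalization commutes with encoding) ---

_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode_kmers(seq: str, k: int, use_canonical: bool) -> np.ndarray:
    """Unique (canonical) k-mers of one sequence as int64 codes; windows
    containing non-ACGT characters are dropped."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    codes = _CODE_LUT[arr]
    bad = codes > 3
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64) @ pow4
    if bad.any():
        invalid = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    else:
        invalid = np.zeros(n - k + 1, dtype=bool)
    if use_canonical:
        rc_codes = (3 - codes[::-1]) & 3  # garbage at N positions, masked below
        rcw = np.lib.stride_tricks.sliding_window_view(rc_codes, k).astype(np.int64) @ pow4
        fwd = np.minimum(fwd, rcw[::-1])
    return np.unique(fwd[~invalid])


def _decode_kmer(code: int, k: int) -> str:
    digits = (int(code) >> (2 * np.arange(k - 1, -1, -1))) & 3
    return _DECODE[digits].tobytes().decode()


def extract_kmers(
    reads: Sequence[Read],
    k: int,
    canonical: bool = True,
    min_kmer_reads: int = 2,
) -> IncidenceGraph:
    """Build the k-mer x read incidence graph.

    V1 keeps only N-free (canonical) k-mers occurring in at least
    ``min_kmer_reads`` distinct reads; singleton k-mers carry no repeat
    signal and dominate memory otherwise.
    """
    if not 4 <= k <= 31:
        raise ValueError("k must lie in [4, 31]")
    if not reads:
        raise ValueError("reads must be non-empty")
    if k > max(len(r.seq) for r in reads):
        warnings.warn(f"k={k} exceeds the longest read; incidence graph is empty")
        return IncidenceGraph(k, canonical, [r.id for r in reads], {}, {})
    per_read = [_encode_kmers(r.seq, k, canonical) for r in reads]
    if per_read:
        codes, counts = np.unique(np.concatenate(per_read), return_counts=True)
        keep_codes = codes[counts >= min_kmer_reads]
    else:
        keep_codes = np.empty(0, dtype=np.int64)
    decoded = {int(c): _decode_kmer(c, k) for c in keep_codes}
    kmer_reads: dict[str, set[int]] = {decoded[int(c)]: set() for c in keep_codes}
    read_kmers: dict[int, set[str]] = {}
    for i, kms in enumerate(per_read):
        if not len(kms):
            continue
        # keep_codes is sorted (np.unique); membership via binary search
        if not len(keep_codes):
            continue
        pos = np.minimum(np.searchsorted(keep_codes, kms), len(keep_codes) - 1)
        hits = kms[keep_codes[pos] == kms]
        if not len(hits):
            continue
        ms = {decoded[int(c)] for c in hits}
        read_kmers[i] = ms
        for m in ms:
            kmer_reads[m].add(i)
    return IncidenceGraph(k, canonical, [r.id for r in reads], kmer_reads, read_kmers)


def graph_density(graph: IncidenceGraph, Vs: Iterable[str], Vt: Iterable[int]) -> float:
    """Density |Est| / (|Vs| * |Vt|) of the subgraph induced by (Vs, Vt)."""
    Vs, Vt = set(Vs), set(Vt)
    if not Vs or not Vt:
        raise ValueError("Vs and Vt must be non-empty")
    missing = Vs - set(graph.kmer_reads)
    if missing:
        raise ValueError(f"k-mers not in the graph: {sorted(missing)[:3]}...")
    est = sum(len(graph.kmer_reads[m] & Vt) for m in Vs)
    return est / (len(Vs) * len(Vt))


def _grow_cluster(
    graph: IncidenceGraph,
    seed_kmer: str,
    adj: dict[str, set[int]],
    min_density: float,
    used: set[str] = frozenset(),  # type: ignore[assignment]
    max_sweeps: int = 20,
) -> tuple[set[str], set[int], int]:
    """Batch seed-and-grow: Vt starts as the seed's reads, then alternating
    sweeps add, in one step, every k-mer whose edge count into Vt is at
    least min_density * |Vt|, and every read whose edge count into Vs is at
    least min_density * |Vs|, until a fixed point.

    The per-candidate threshold keeps the overall density >= min_density by
    induction (est' >= est + c_min * n_added >= min_density * |Vs'| * |Vt|),
    and because the threshold is evaluated against the whole current
    cluster, growth cannot drift stepwise along a chromosome the way
    one-vertex-at-a-time admission does.  The result is independent of
    iteration order, hence deterministic.
    """
    Vs = {seed_kmer}
    Vt = set(adj[seed_kmer])
    kc: dict[str, int] = {}  # candidate k-mer -> live edges into Vt
    rc: dict[int, int] = {}  # candidate read -> edges into Vs
    fresh_reads: set[int] = set(Vt)
    fresh_kmers: set[str] = {seed_kmer}
    read_kmers = graph.read_kmers
    for _ in range(max_sweeps):
        # fold newly admitted reads into the candidate k-mer counts; k-mers
        # already examined in earlier rounds are not re-absorbed, keeping
        # clusters k-mer-disjoint and the search near-linear in graph size
        for r in fresh_reads:
            for m in read_kmers.get(r, ()):
                if m not in Vs and m not in used:
                    am = adj.get(m)
                    if am is not None and r in am:
                        kc[m] = kc.get(m, 0) + 1
        thr = min_density * len(Vt)
        add_k = {m for m, c in kc.items() if c >= thr}
        for m in add_k:
            del kc[m]
        Vs |= add_k
        fresh_kmers |= add_k
        # fold newly admitted k-mers into the candidate read counts
        for m in fresh_kmers:
            for r in adj[m]:
                if r not in Vt:
                    rc[r] = rc.get(r, 0) + 1
        fresh_kmers = set()
        thr = min_density * len(Vs)
        add_r = {r for r, c in rc.items() if c >= thr}
        for r in add_r:
            del rc[r]
        Vt |= add_r
        fresh_reads = add_r
        if not add_k and not add_r:
            break
    est = sum(len(adj[m] & Vt) for m in Vs)
    return Vs, Vt, est


def _prune_cluster(
    adj: dict[str, set[int]], Vs: set[str], Vt: set[int], est: int, min_density: float
) -> tuple[set[str], set[int], int]:
    """Batch-remove vertices whose in-cluster connectivity falls below the
    growth criterion (edge count < min_density * opposite side), until every
    remaining vertex meets it.

    This is the dual of the grow sweep: each removal of a weakly connected
    vertex raises the cluster's density, and at the fixed point every k-mer
    sits in at least min_density of the reads and vice versa, which implies
    overall density >= min_density.  Unlike pruning to a strict local
    density maximum, it does not collapse a broad quasi-biclique (a repeat
    family sampled by partially overlapping, slightly divergent reads) into
    a tiny perfect biclique.
    """
    kdeg = {m: len(adj[m] & Vt) for m in Vs}
    rdeg: dict[int, int] = {r: 0 for r in Vt}
    radj: dict[int, set[str]] = {r: set() for r in Vt}
    for m in Vs:
        for r in adj[m] & Vt:
            rdeg[r] += 1
            radj[r].add(m)

    while Vs and Vt:
        thr_k = min_density * len(Vt)
        bad_k = {m for m in Vs if kdeg[m] < thr_k}
        if bad_k:
            for m in bad_k:
                Vs.discard(m)
                est -= kdeg.pop(m)
                for r in adj[m] & Vt:
                    rdeg[r] -= 1
                    radj[r].discard(m)
        thr_r = min_density * len(Vs) if Vs else 0.0
        bad_r = {r for r in Vt if rdeg[r] < thr_r}
        if bad_r:
            for r in bad_r:
                Vt.discard(r)
                est -= rdeg.pop(r)
                for m in radj.pop(r):
                    if m in Vs:
                        kdeg[m] -= 1
        if not bad_k and not bad_r:
            break
    return Vs, Vt, est


def find_biclusters(
    graph: IncidenceGraph,
    min_density: float = 0.5,
    min_kmers: int = 5,
    min_reads: int = 10,
    max_clusters: int = 10_000,
    seed: int = 0,
) -> list[Bicluster]:
    """Deterministic greedy bicluster search on the incidence graph.

    Each round seeds at the highest-degree unused k-mer (ties by
    lexicographic order), grows under the per-candidate connectivity rule
    (which keeps density >= ``min_density`` throughout), prunes
    below-average vertices, and accepts the cluster if the size minima are
    met.  Edges of accepted clusters are removed before the next round, so
    clusters are edge-disjoint.  Rounds stop once the maximum remaining
    k-mer degree falls below ceil(min_density * min_reads): any acceptable
    cluster must contain a k-mer of at least that degree, so nothing
    findable remains.  The search itself is deterministic; ``seed`` is
    accepted for interface stability.
    """
    if not 0.0 < min_density <= 1.0:
        raise ValueError("min_density must lie in (0, 1]")
    adj = {m: set(rs) for m, rs in graph.kmer_reads.items()}
    used: set[str] = set()
    clusters: list[Bicluster] = []
    degree_floor = max(1, int(np.ceil(min_density * min_reads)))
    # lazy max-heap over (degree, kmer); degrees only fall as edges are
    # removed, so a stale popped entry is re-pushed at its current degree
    seed_heap = [(-len(rs), m) for m, rs in adj.items() if len(rs) >= degree_floor]
    heapq.heapify(seed_heap)
    while len(clusters) < max_clusters:
        best_seed = None
        while seed_heap:
            negd, m = heapq.heappop(seed_heap)
            if m in used or m not in adj:
                continue
            d = len(adj[m])
            if d < degree_floor:
                continue
            if d != -negd:
                heapq.heappush(seed_heap, (-d, m))
                continue
            best_seed = m
            break
        if best_seed is None:
            break
        used.add(best_seed)
        Vs, Vt, est = _grow_cluster(graph, best_seed, adj, min_density, used)
        if len(Vs) < min_kmers or len(Vt) < min_reads:
            # pruning only shrinks; every examined k-mer is marked used so
            # the same undersized neighborhood is not regrown from each of
            # its members in later rounds
            used |= Vs
            continue
        grown_Vs = set(Vs)
        Vs, Vt, est = _prune_cluster(adj, Vs, Vt, est, min_density)
        if len(Vs) < min_kmers or len(Vt) < min_reads:
            used |= grown_Vs
            continue
        if est / (len(Vs) * len(Vt)) < min_density:
            used |= grown_Vs
            continue
        clusters.append(Bicluster(Vs, Vt, est))
        # every k-mer examined during this growth has had its neighborhood
        # explored; re-seeding from it would regrow the same region
        used |= grown_Vs
        for m in Vs:
            adj[m] -= Vt
            if not adj[m]:
                del adj[m]
    clusters.sort(key=lambda c: (-c.objective, sorted(c.Vs)[0]))
    return clusters


def assemble_kchains(
    bicluster: Bicluster,
    graph: IncidenceGraph,
    min_length: int = 30,
    source: int = 0,
) -> list[KChain]:
    """Assemble a bicluster's k-mers into consensus chains.

    Builds the directed (k-1)-overlap graph over both orientations of the
    member k-mers (plain orientation only for non-canonical graphs) and
    emits every maximal non-branching path; strand duplicates (a path and
    its reverse complement) are collapsed.  Chains shorter than
    ``min_length`` are discarded.  Divergent variants branch the graph and
    therefore yield separate chains rather than an IUPAC consensus.
    """
    k = graph.k
    members = set(bicluster.Vs)
    if graph.canonical:
        nodes = members | {revcomp(m) for m in members}

        def is_member(x: str) -> bool:
            return canonical(x) in members

    else:
        nodes = set(members)

        def is_member(x: str) -> bool:
            return x in members

    def _oriented_successors(node: str, _members=None) -> list[str]:
        suffix = node[1:]
        return [suffix + b for b in "ACGT" if is_member(suffix + b)]

    def _oriented_predecessors(node: str) -> list[str]:
        prefix = node[:-1]
        return [b + prefix for b in "ACGT" if is_member(b + prefix)]

    def out_deg(v: str) -> int:
        return len(_oriented_successors(v))

    def in_deg(v: str) -> int:
        return len(_oriented_predecessors(v))

    chains: set[str] = set()
    visited: set[str] = set()
    # maximal non-branching paths starting at non-1-in-1-out nodes
    for v in sorted(nodes):
        if in_deg(v) == 1 and out_deg(v) == 1:
            continue
        for nxt in _oriented_successors(v):
            path = v
            cur = nxt
            seen_local = {v}
            while in_deg(cur) == 1 and out_deg(cur) == 1 and cur not in seen_local:
                path += cur[-1]
                visited.add(cur)
                seen_local.add(cur)
                cur = _oriented_successors(cur)[0]
            path += cur[-1]
            visited.add(cur)
            visited.add(v)
            chains.add(min(path, revcomp(path)))
        if out_deg(v) == 0:
            visited.add(v)
    # isolated cycles: every node 1-in-1-out and unvisited
    for v in sorted(nodes):
        if v in visited:
            continue
        if in_deg(v) == 1 and out_deg(v) == 1:
            path = v
            cur = _oriented_successors(v)[0]
            visited.add(v)
            visited.add(revcomp(v))
            while cur != v and cur not in visited:
                path += cur[-1]
                visited.add(cur)
                visited.add(revcomp(cur))
                cur = _oriented_successors(cur)[0]
            chains.add(min(path, revcomp(path)))
    out = [
        KChain(f"kchain_{k}_{i}", seq, source)
        for i, seq in enumerate(sorted(c for c in chains if len(c) >= min_length))
    ]
    return out


@dataclass(frozen=True)
class DiscoveryParams:
    """Knobs for end-to-end discovery; defaults are the pipeline's study
    conditions (10% of pooled reads, k = 12 and 15, density >= 0.5)."""

    k_values: tuple[int, ...] = (12, 15)
    discovery_fraction: float = 0.10
    min_density: float = 0.5
    min_kmers: int = 5
    min_reads: int = 10
    max_clusters: int = 10_000
    min_kmer_reads: int = 2
    min_length: int = 30
    seed: int = 0


def discover(reads: Sequence[Read], params: DiscoveryParams = DiscoveryParams()) -> list[KChain]:
    """Full discovery: subsample pooled reads, bicluster at each k, assemble,
    and deduplicate chains identical up to reverse complement."""
    reads = list(reads)
    rng = np.random.default_rng([params.seed, 17])
    n_pick = int(len(reads) * params.discovery_fraction)
    if 0 < params.discovery_fraction < 1.0 and n_pick >= 1:
        idx = np.sort(rng.choice(len(reads), size=n_pick, replace=False))
        pool = [reads[i] for i in idx]
    else:
        pool = reads
    seen: set[str] = set()
    out: list[KChain] = []
    for k in params.k_values:
        graph = extract_kmers(pool, k, canonical=True, min_kmer_reads=params.min_kmer_reads)
        clusters = find_biclusters(
            graph,
            min_density=params.min_density,
            min_kmers=params.min_kmers,
            min_reads=params.min_reads,
            max_clusters=params.max_clusters,
            seed=params.seed,
        )
        serial = 0
        for ci, cluster in enumerate(clusters):
            for chain in assemble_kchains(cluster, graph, params.min_length, source=ci):
                key = min(chain.seq, revcomp(chain.seq))
                if key in seen:
                    continue
                seen.add(key)
                out.append(KChain(f"kchain_{k}_{serial}", chain.seq, ci))
                serial += 1
    return out
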