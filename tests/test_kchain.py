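"""The discovery kernel: incidence graph construction, bipartite density,
greedy biclustering against a brute-force oracle, and chain assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatome.io import Read, revcomp
from repeatome.kchain import (
    Bicluster,
    DiscoveryParams,
    IncidenceGraph,
    assemble_kchains,
    canonical,
    discover,
    extract_kmers,
    find_biclusters,
    graph_density,
)


class TestExtractKmers:
    def test_single_read_plain_kmers(self):
        g = extract_kmers([Read("r1", "ACGTAC")], 4, canonical=False, min_kmer_reads=1)
        assert g.kmers == {"ACGT", "CGTA", "GTAC"}
        assert g.n_edges == 3

    def test_canonical_collapses_strand(self):
        g = extract_kmers([Read("r1", "TTTT")], 4, canonical=True, min_kmer_reads=1)
        assert g.kmers == {"AAAA"}

    def test_short_read_contributes_nothing(self):
        g = extract_kmers(
            [Read("r1", "ACG"), Read("r2", "ACGTACGT")], 4, canonical=False, min_kmer_reads=1
        )
        assert 0 not in g.read_kmers

    def test_k_above_read_length_warns_empty(self):
        with pytest.warns(UserWarning):
            g = extract_kmers([Read("r1", "ACGT")], 8)
        assert g.kmers == set()

    def test_n_kmers_excluded(self):
        g = extract_kmers([Read("r1", "ACGNACGT")], 4, canonical=False, min_kmer_reads=1)
        assert all("N" not in m for m in g.kmers)
        assert g.kmers == {"ACGT"}

    def test_min_kmer_reads_filter(self):
        reads = [Read("r1", "ACGTA"), Read("r2", "ACGTC"), Read("r3", "TTTTT")]
        g = extract_kmers(reads, 4, canonical=False, min_kmer_reads=2)
        assert g.kmers == {"ACGT"}
        assert g.kmer_reads["ACGT"] == {0, 1}

    def test_edge_iff_substring(self, rng):
        # definitional invariant of the incidence graph
        reads = [
            Read(f"r{i}", "".join(rng.choice(list("ACGT"), size=30))) for i in range(20)
        ]
        g = extract_kmers(reads, 5, canonical=True, min_kmer_reads=1)
        for m, rs in g.kmer_reads.items():
            for i, read in enumerate(reads):
                expected = m in read.seq or revcomp(m) in read.seq
                assert (i in rs) == expected


class TestGraphDensity:
    def _complete_graph(self, n_kmers=4, n_reads=5):
        kmers = [f"KM{i}" for i in range(n_kmers)]
        kmer_reads = {m: set(range(n_reads)) for m in kmers}
        read_kmers = {r: set(kmers) for r in range(n_reads)}
        return IncidenceGraph(4, False, [f"r{i}" for i in range(n_reads)], kmer_reads, read_kmers)

    def test_biclique_density_is_one(self):
        g = self._complete_graph(4, 5)
        assert graph_density(g, g.kmers, range(5)) == 1.0

    def test_zero_edges(self):
        g = self._complete_graph(2, 2)
        g.kmer_reads["KM0"] = {0}
        g.kmer_reads["KM1"] = {0}
        assert graph_density(g, {"KM0", "KM1"}, {1}) == 0.0

    def test_half_density(self):
        g = self._complete_graph(2, 2)
        g.kmer_reads["KM0"] = {0}
        g.kmer_reads["KM1"] = {1}
        assert graph_density(g, {"KM0", "KM1"}, {0, 1}) == 0.5

    def test_empty_subset_rejected(self):
        g = self._complete_graph()
        with pytest.raises(ValueError):
            graph_density(g, set(), {0})

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_density_bounds_random_subgraphs(self, seed):
        rng = np.random.default_rng(seed)
        n_k, n_r = 8, 10
        kmers = [f"KM{i}" for i in range(n_k)]
        kmer_reads = {
            m: set(np.flatnonzero(rng.random(n_r) < 0.4).tolist()) for m in kmers
        }
        read_kmers = {}
        for m, rs in kmer_reads.items():
            for r in rs:
                read_kmers.setdefault(r, set()).add(m)
        g = IncidenceGraph(4, False, [f"r{i}" for i in range(n_r)], kmer_reads, read_kmers)
        vs = set(rng.choice(kmers, size=rng.integers(1, n_k + 1), replace=False).tolist())
        vt = set(rng.choice(n_r, size=rng.integers(1, n_r + 1), replace=False).tolist())
        d = graph_density(g, vs, vt)
        assert 0.0 <= d <= 1.0
        # brute-force edge count agrees
        brute = sum(1 for m in vs for r in vt if r in kmer_reads[m])
        assert d == brute / (len(vs) * len(vt))


def _graph_from_edges(n_kmers, n_reads, edges):
    kmers = [f"KM{i:02d}" for i in range(n_kmers)]
    kmer_reads = {m: set() for m in kmers}
    read_kmers = {}
    for a, b in edges:
        kmer_reads[kmers[a]].add(b)
        read_kmers.setdefault(b, set()).add(kmers[a])
    return IncidenceGraph(4, False, [f"r{i}" for i in range(n_reads)], kmer_reads, read_kmers)


def _brute_force_best(graph, min_density, min_kmers, min_reads):
    """Exhaustive best bicluster (max |Vs|*|Vt|*density = edge count) over
    all subset pairs meeting the size minima."""
    kmers = sorted(graph.kmer_reads)
    reads = sorted({r for rs in graph.kmer_reads.values() for r in rs})
    best = 0.0
    for ks in range(min_kmers, len(kmers) + 1):
        for vs in itertools.combinations(kmers, ks):
            for rs_n in range(min_reads, len(reads) + 1):
                for vt in itertools.combinations(reads, rs_n):
                    est = sum(len(graph.kmer_reads[m] & set(vt)) for m in vs)
                    if est / (ks * rs_n) >= min_density:
                        best = max(best, float(est))
    return best


class TestFindBiclusters:
    def test_planted_biclique_recovered(self, rng):
        n_k, n_r = 100, 200
        planted_k, planted_r = set(range(10)), set(range(20))
        edges = {(a, b) for a in planted_k for b in planted_r}
        noise = rng.random((n_k, n_r)) < 0.01
        edges |= {(a, b) for a, b in np.argwhere(noise).tolist()}
        g = _graph_from_edges(n_k, n_r, edges)
        clusters = find_biclusters(g, min_density=0.5, min_kmers=5, min_reads=10)
        assert clusters
        top = clusters[0]
        got_k = {int(m[2:]) for m in top.Vs}
        overlap_k = len(got_k & planted_k) / len(planted_k)
        overlap_r = len(top.Vt & planted_r) / len(planted_r)
        assert overlap_k >= 0.9
        assert overlap_r >= 0.9
        # no single-vertex perturbation improves the returned density
        assert top.density >= 0.9

    def test_graph_below_minima_returns_empty(self):
        g = _graph_from_edges(3, 4, {(a, b) for a in range(3) for b in range(4)})
        assert find_biclusters(g, min_kmers=5, min_reads=10) == []

    def test_two_disjoint_bicliques(self):
        edges = {(a, b) for a in range(6) for b in range(12)}
        edges |= {(a + 6, b + 12) for a in range(6) for b in range(12)}
        g = _graph_from_edges(12, 24, edges)
        clusters = find_biclusters(g, min_density=0.5, min_kmers=5, min_reads=10)
        assert len(clusters) == 2
        assert clusters[0].Vs.isdisjoint(clusters[1].Vs)
        assert all(c.density == 1.0 for c in clusters)

    def test_oracle_equivalence_small_graph(self, rng):
        # on graphs <= 12+12 vertices the greedy's best cluster is compared
        # with the exhaustive optimum; the greedy result is pinned.
        edges = {(a, b) for a in range(4) for b in range(4)}  # 4x4 biclique
        extra = {(a, b) for a, b in zip(rng.integers(0, 8, 20), rng.integers(0, 8, 20))}
        g = _graph_from_edges(8, 8, edges | extra)
        clusters = find_biclusters(g, min_density=0.5, min_kmers=2, min_reads=2)
        optimum = _brute_force_best(g, 0.5, 2, 2)
        assert clusters
        greedy_best = max(c.Est for c in clusters)
        # greedy is a heuristic: it must find a qualifying cluster and come
        # within a factor of two of the exhaustive optimum on these graphs
        assert greedy_best >= optimum / 2
        assert greedy_best >= 16  # the planted 4x4 biclique is found in full

    def test_density_threshold_respected_and_tightens(self, rng):
        # every returned cluster meets its threshold, and the weakest
        # returned density rises (weakly) with the threshold
        edges = {(a, b) for a, b in zip(rng.integers(0, 10, 120), rng.integers(0, 15, 120))}
        edges |= {(a, b) for a in range(5) for b in range(8)}
        g = _graph_from_edges(10, 15, edges)
        prev_min = 0.0
        for d in (0.3, 0.5, 0.7, 0.9):
            clusters = find_biclusters(g, min_density=d, min_kmers=2, min_reads=2)
            if not clusters:
                continue
            weakest = min(c.density for c in clusters)
            assert weakest >= d
            assert weakest >= prev_min - 1e-12
            prev_min = weakest

    def test_all_clusters_meet_contract(self, rng):
        edges = {(a, b) for a, b in zip(rng.integers(0, 12, 200), rng.integers(0, 20, 200))}
        edges |= {(a, b) for a in range(6) for b in range(10)}
        g = _graph_from_edges(12, 20, edges)
        clusters = find_biclusters(g, min_density=0.6, min_kmers=3, min_reads=4)
        for c in clusters:
            assert c.density >= 0.6
            assert len(c.Vs) >= 3
            assert len(c.Vt) >= 4
            # density recomputed from the full graph is >= the edge-disjoint
            # residual estimate used during the search
            assert graph_density(g, c.Vs, c.Vt) >= c.density - 1e-12

    def test_deterministic(self, rng):
        edges = {(a, b) for a, b in zip(rng.integers(0, 12, 150), rng.integers(0, 20, 150))}
        edges |= {(a, b) for a in range(5) for b in range(10)}
        g = _graph_from_edges(12, 20, edges)
        a = find_biclusters(g, min_kmers=2, min_reads=2)
        b = find_biclusters(g, min_kmers=2, min_reads=2)
        assert [(sorted(c.Vs), sorted(c.Vt), c.Est) for c in a] == [
            (sorted(c.Vs), sorted(c.Vt), c.Est) for c in b
        ]


class TestAssembleKChains:
    def _bicluster_graph(self, kmers, k=4, use_canonical=False):
        g = IncidenceGraph(k, use_canonical, ["r0"], {m: {0} for m in kmers}, {0: set(kmers)})
        return Bicluster(set(kmers), {0}, len(kmers)), g

    def test_unique_overlap_path(self):
        b, g = self._bicluster_graph({"ACGT", "CGTA", "GTAC"})
        chains = assemble_kchains(b, g, min_length=4)
        assert [c.seq for c in chains] == ["ACGTAC"]

    def test_branching_splits_chains(self):
        # TACG -> ACGT branches into CGTA and CGTC
        b, g = self._bicluster_graph({"TACG", "ACGT", "CGTA", "CGTC"})
        chains = {c.seq for c in assemble_kchains(b, g, min_length=4)}
        assert any(s.startswith("TACGT") or revcomp(s).startswith("TACGT") for s in chains)
        joined = "".join(sorted(chains))
        assert len(chains) >= 2  # each branch continues as its own chain

    def test_min_length_discards(self):
        b, g = self._bicluster_graph({"ACGT", "CGTA", "GTAC"})
        assert assemble_kchains(b, g, min_length=30) == []

    def test_canonical_mode_collapses_strands(self):
        # all canonical 5-mers distinct and non-palindromic: clean path
        seq = "GTTGTTTACGCCGTGA"
        k = 5
        kmers = {canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)}
        g = IncidenceGraph(k, True, ["r0"], {m: {0} for m in kmers}, {0: set(kmers)})
        chains = assemble_kchains(Bicluster(kmers, {0}, len(kmers)), g, min_length=5)
        assert len(chains) == 1
        got = chains[0].seq
        assert got in (seq, revcomp(seq))

    def test_chain_reconstructible_from_member_kmers(self):
        seq = "ACGTTGCAAGGTCCAT"
        k = 5
        kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        b, g = self._bicluster_graph(kmers, k=k)
        (chain,) = assemble_kchains(b, g, min_length=6)
        for i in range(len(chain.seq) - k + 1):
            assert chain.seq[i : i + k] in kmers or revcomp(chain.seq[i : i + k]) in kmers


class TestDiscover:
    def test_recovers_planted_family(self, tiny_study):
        pooled = [r for e in tiny_study.manifest.entries for r in tiny_study.reads[e.sample_id]]
        chains = discover(pooled, DiscoveryParams(seed=3))
        from repeatome.evaluate import family_recovery

        report = family_recovery(chains, tiny_study.consensi)
        assert bool(report.loc["fam1", "recovered"])

    def test_no_repeats_no_kchains(self, rng):
        # random reads from a repeat-free genome: dense clusters meeting the
        # defaults are vanishingly unlikely at this scale
        genome = "".join(rng.choice(list("ACGT"), size=30_000))
        reads = [Read(f"r{i}", genome[p : p + 100]) for i, p in
                 enumerate(rng.integers(0, len(genome) - 100, 200))]
        chains = discover(reads, DiscoveryParams(discovery_fraction=1.0, seed=5))
        assert chains == []

    def test_deterministic(self, tiny_study):
        pooled = [r for e in tiny_study.manifest.entries for r in tiny_study.reads[e.sample_id]]
        a = discover(pooled, DiscoveryParams(seed=3))
        b = discover(pooled, DiscoveryParams(seed=3))
        assert [(c.id, c.seq) for c in a] == [(c.id, c.seq) for c in b]

    def test_dedup_reverse_complement(self, tiny_study):
        pooled = [r for e in tiny_study.manifest.entries for r in tiny_study.reads[e.sample_id]]
        chains = discover(pooled, DiscoveryParams(seed=3))
        keys = [min(c.seq, revcomp(c.seq)) for c in chains]
        assert len(keys) == len(set(keys))
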