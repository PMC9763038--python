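"""p-distances, neighbor joining, bootstrap and UA/CY host-range typing."""

import numpy as np
import pytest

from capsidpcr.phylo import (
    DistanceMatrix,
    Tree,
    TreeNode,
    assign_host_range_type,
    bootstrap_support,
    masked_newick,
    neighbor_joining,
    p_distance_matrix,
)
from capsidpcr.seqcore import SequenceError, SequenceRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# random additive trees as an oracle for NJ
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves, rng):
    """Random binary topology with positive branch lengths; returns the leaf
    labels and the path-length (additive) distance matrix."""
    labels = [f"t{i}" for i in range(n_leaves)]
    # start from a 3-star, attach remaining leaves to random edges
    nodes = {0: {}, }  # adjacency: node -> {nbr: length}
    adj = {}

    def add_edge(a, b, ln):
        adj.setdefault(a, {})[b] = ln
        adj.setdefault(b, {})[a] = ln

    def blen():
        return float(rng.uniform(0.1, 1.0))

    center = "c0"
    for lb in labels[:3]:
        add_edge(center, lb, blen())
    next_internal = 1
    for lb in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(len(edges))]
        ln = adj[a].pop(b)
        adj[b].pop(a)
        mid = f"c{next_internal}"
        next_internal += 1
        cut = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, ln * cut)
        add_edge(mid, b, ln * (1 - cut))
        add_edge(mid, lb, blen())
    # all-pairs path lengths between leaves
    import heapq

    d = np.zeros((n_leaves, n_leaves))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > dist.get(u, np.inf):
                continue
            for v, ln in adj[u].items():
                nd = dd + ln
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    d = (d + d.T) / 2  # exact symmetry despite float path sums
    bips = set()
    # bipartitions of the true tree: remove each internal edge
    anchor = min(labels)
    for a in adj:
        for b in adj[a]:
            if str(a) < str(b) and not (
                str(a).startswith("t") or str(b).startswith("t")
            ):
                side = _component(adj, a, without=b)
                side_leaves = frozenset(x for x in side if str(x).startswith("t"))
                if 1 < len(side_leaves) < n_leaves - 1:
                    canon = (side_leaves if anchor not in side_leaves
                             else frozenset(labels) - side_leaves)
                    bips.add(canon)
    return labels, d, bips


def _component(adj, start, without):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v == without or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def tree_path_lengths(tree: Tree):
    """Leaf-to-leaf path lengths of an inferred tree."""
    adj = {}

    def walk(node, name_of):
        my = name_of[id(node)]
        for c, ln in node.children:
            name_of[id(c)] = c.label if c.is_leaf() else f"i{id(c)}"
            adj.setdefault(my, {})[name_of[id(c)]] = ln
            adj.setdefault(name_of[id(c)], {})[my] = ln
            walk(c, name_of)

    name_of = {id(tree.root): "root"}
    walk(tree.root, name_of)
    leaves = sorted(tree.leaf_set)
    import heapq

    out = {}
    for src in leaves:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > dist.get(u, np.inf):
                continue
            for v, ln in adj[u].items():
                nd = dd + ln
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for dst in leaves:
            out[(src, dst)] = dist[dst]
    return out


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = [SequenceRecord(f"s{i}", "MKTAY", "aa") for i in range(3)]
        assert np.all(p_distance_matrix(aln).d == 0)

    def test_quarter(self):
        aln = [
            SequenceRecord("a", "AAAA", "aa"),
            SequenceRecord("b", "AAAT", "aa"),
            SequenceRecord("c", "TTTT", "aa"),
        ]
        D = p_distance_matrix(aln)
        assert D.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_skipped_vs_counting_oracle(self, rng):
        rows = []
        for i in range(4):
            rows.append(
                SequenceRecord(
                    f"s{i}",
                    "".join(rng.choice(AA[:3] + ["-"], size=30)),
                    "aa",
                )
            )
        D = p_distance_matrix(rows)
        for i in range(4):
            for j in range(4):
                comp = diff = 0
                for x, y in zip(rows[i].residues, rows[j].residues):
                    if "-" in (x, y):
                        continue
                    comp += 1
                    diff += x != y
                assert D.d[i, j] == pytest.approx(diff / comp if comp else 0)

    def test_unequal_lengths_error(self):
        with pytest.raises(SequenceError):
            p_distance_matrix(
                [SequenceRecord("a", "AA", "aa"), SequenceRecord("b", "AAA", "aa"),
                 SequenceRecord("c", "AA", "aa")]
            )


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = DistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 2, 3], [2, 0, 4], [3, 4, 0.0]]),
        )
        tree = neighbor_joining(D)
        lens = {c.label: ln for c, ln in tree.root.children}
        assert lens == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_recovery_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        labels, d, true_bips = random_additive_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(tuple(labels), d))
        assert tree.bipartitions() == true_bips
        paths = tree_path_lengths(tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert paths[(a, b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_equidistant_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        D = DistanceMatrix(("a", "b", "c", "d"), d)
        t1 = neighbor_joining(D)
        t2 = neighbor_joining(D)
        assert t1.newick() == t2.newick()
        # the lexicographically smallest pair (a, b) joins first
        assert frozenset(["c", "d"]) in t1.bipartitions()

    def test_total_length_invariant_to_label_permutation(self, rng):
        labels, d, _ = random_additive_tree(6, rng)
        t_ref = neighbor_joining(DistanceMatrix(tuple(labels), d))
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        t_perm = neighbor_joining(
            DistanceMatrix(tuple(labels[i] for i in perm), d2)
        )
        assert t_perm.total_length() == pytest.approx(t_ref.total_length())

    def test_negative_branch_clamped(self):
        d = np.array(
            [[0.0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0.0]]
        )
        tree = neighbor_joining(DistanceMatrix(("a", "b", "c", "d"), d))
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for c, ln in node.children:
                assert ln >= 0
                stack.append(c)


class TestBootstrap:
    def _split_alignment(self, n_diag=30, n_const=10):
        """Two 4-leaf clades separated by ``n_diag`` diagnostic columns."""
        rng = np.random.default_rng(5)
        left = "".join(rng.choice(AA, size=n_diag))
        right = "".join(
            AA[(AA.index(c) + 1) % 20] for c in left
        )
        const = "".join(rng.choice(AA, size=n_const))
        rows = []
        for i in range(4):
            noise = list(const)
            noise[i % n_const] = AA[i]
            rows.append(SequenceRecord(f"L{i}", left + "".join(noise), "aa"))
        for i in range(4):
            noise = list(const)
            noise[i % n_const] = AA[10 + i]
            rows.append(SequenceRecord(f"R{i}", right + "".join(noise), "aa"))
        return rows

    def test_central_split_full_support(self):
        rows = self._split_alignment()
        tree = bootstrap_support(rows, n_replicates=200, seed=3)
        central = frozenset(f"R{i}" for i in range(4))
        found = {
            frozenset(c.leaves()): c.support
            for c in _internal_children(tree)
        }
        assert any(
            s == 100.0 for side, s in found.items()
            if side in (central, frozenset(f"L{i}" for i in range(4)))
        )

    def test_same_seed_identical_supports(self):
        rows = self._split_alignment()
        t1 = bootstrap_support(rows, 50, seed=9)
        t2 = bootstrap_support(rows, 50, seed=9)
        assert masked_newick(t1, 0) == masked_newick(t2, 0)

    def test_single_replicate_supports_binary(self):
        rows = self._split_alignment()
        tree = bootstrap_support(rows, n_replicates=1, seed=1)
        sups = [c.support for c in _internal_children(tree) if c.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_masking_hides_low_supports(self):
        rows = self._split_alignment()
        tree = bootstrap_support(rows, 100, seed=2)
        full = masked_newick(tree, min_support=0)
        masked = masked_newick(tree, min_support=50)
        assert len(masked) <= len(full)


def _internal_children(tree):
    out = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for c, _ in node.children:
            if not c.is_leaf():
                out.append(c)
                stack.append(c)
    return out


class TestAgainstScikitBio:
    def test_matches_skbio_nj_topology(self, rng):
        """Independent cross-check: same topology as scikit-bio's NJ on
        random additive matrices."""
        skbio = pytest.importorskip("skbio")
        from io import StringIO

        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            labels, d, true_bips = random_additive_tree(int(r.integers(4, 8)), r)
            ours = neighbor_joining(DistanceMatrix(tuple(labels), d))
            dm = skbio.DistanceMatrix(d, ids=labels)
            theirs = skbio.tree.nj(dm)
            their_bips = set()
            anchor = min(labels)
            for node in theirs.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    canon = (side if anchor not in side
                             else frozenset(labels) - side)
                    their_bips.add(canon)
            assert ours.bipartitions() == their_bips == true_bips


class TestHostTyping:
    def test_identical_to_cy_reference_is_cy(self, clean_model):
        from capsidpcr.pipeline import PipelineConfig, run_pipeline
        from capsidpcr.simulate import simulate_reads

        panel = clean_model.panel
        # construct a tiny typing tree: refs plus an ASV equal to the CY ref
        from capsidpcr.pipeline import panel_insert_translations

        inserts = panel_insert_translations(
            panel, clean_model.panel_nt, clean_model.primer_pair
        )
        from capsidpcr.classify import PanelEntry, ReferencePanel

        insert_panel = ReferencePanel(
            tuple(
                PanelEntry(SequenceRecord(e.record.id, inserts[e.record.id], "aa"),
                           e.group, e.host_range_type, e.accession)
                for e in panel.entries
            )
        )
        cy = next(e for e in insert_panel.entries if e.host_range_type == "CY")
        asv = SequenceRecord("asv1", cy.record.residues, "aa")
        hc = [e.record for e in insert_panel.entries if e.group == "HcRNAV"]
        aln = hc + [asv]
        tree = neighbor_joining(p_distance_matrix(aln))
        assert assign_host_range_type(asv, insert_panel, tree) == "CY"

    def test_below_identity_floor_is_unknown(self):
        from capsidpcr.classify import PanelEntry, ReferencePanel

        refs = [
            PanelEntry(SequenceRecord("ua", "A" * 20, "aa"), "HcRNAV", "UA", "U1"),
            PanelEntry(SequenceRecord("cy", "C" * 20, "aa"), "HcRNAV", "CY", "C1"),
        ]
        panel = ReferencePanel(tuple(refs))
        asv = SequenceRecord("asv1", "W" * 20, "aa")
        aln = [r.record for r in refs] + [asv]
        tree = neighbor_joining(p_distance_matrix(aln))
        assert assign_host_range_type(asv, panel, tree) == "unknown"

    def test_missing_leaf_errors(self):
        from capsidpcr.classify import PanelEntry, ReferencePanel

        refs = [
            PanelEntry(SequenceRecord("ua", "A" * 20, "aa"), "HcRNAV", "UA", "U1"),
            PanelEntry(SequenceRecord("cy", "C" * 20, "aa"), "HcRNAV", "CY", "C1"),
            PanelEntry(SequenceRecord("x", "G" * 20, "aa"), "HcRNAV", "UA", "U2"),
        ]
        panel = ReferencePanel(tuple(refs))
        tree = neighbor_joining(p_distance_matrix([r.record for r in refs]))
        with pytest.raises(SequenceError):
            assign_host_range_type(
                SequenceRecord("nope", "A" * 20, "aa"), panel, tree
            )
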