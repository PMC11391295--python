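"""Proximity graph, shortest paths (vs Floyd-Warshall oracle), pair categories."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ritualsync import (
    CATEGORIES,
    ConfigurationError,
    DataIntegrityError,
    RitualConfig,
    build_graph,
    categorize_pairs,
    generate_session,
    nearest_neighbour_distances,
    shortest_path_distances,
)


def make_tables(coords: dict, groups: dict, roles: dict = None):
    ids = list(coords)
    prox = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for a in ids:
        prox.loc[a, a] = 0.0
    for a, b in combinations(ids, 2):
        if groups[a] == groups[b]:
            d = float(np.hypot(*(np.array(coords[a]) - np.array(coords[b]))))
            prox.loc[a, b] = prox.loc[b, a] = d
    meta = pd.DataFrame(
        {
            "id": ids,
            "role": [(roles or {}).get(i, "worshipper") for i in ids],
            "group": [groups[i] for i in ids],
            "row": 0,
            "col": 0,
        }
    ).set_index("id")
    return prox, meta


class TestGraph:
    def test_edge_within_range(self):
        prox, meta = make_tables({"a": (0, 0), "b": (1.22, 0)}, {"a": "g", "b": "g"})
        assert build_graph(prox, meta).has_edge("a", "b")

    def test_no_cross_group_edge_even_when_close(self):
        prox, meta = make_tables({"a": (0, 0), "b": (0.5, 0)}, {"a": "g1", "b": "g2"})
        assert not build_graph(prox, meta).has_edge("a", "b")

    def test_threshold_boundary_closed(self):
        prox, meta = make_tables({"a": (0, 0), "b": (2.0, 0)}, {"a": "g", "b": "g"})
        assert build_graph(prox, meta).has_edge("a", "b")
        prox.loc["a", "b"] = prox.loc["b", "a"] = 2.0001
        assert not build_graph(prox, meta).has_edge("a", "b")

    def test_asymmetric_table_rejected(self):
        prox, meta = make_tables({"a": (0, 0), "b": (1, 0)}, {"a": "g", "b": "g"})
        prox.loc["a", "b"] = 1.5
        with pytest.raises(DataIntegrityError):
            build_graph(prox, meta)


class TestShortestPaths:
    def test_adjacent_and_two_step(self):
        coords = {"a": (0, 0), "b": (1.5, 0), "c": (3.0, 0)}
        prox, meta = make_tables(coords, {k: "g" for k in coords})
        table = shortest_path_distances(build_graph(prox, meta))
        assert table.loc["a", "b"] == 1
        assert table.loc["a", "c"] == 2  # 3.0 m apart: linked through b

    def test_matches_floyd_warshall_on_random_graphs(self):
        for seed in range(8):
            g = nx.gnp_random_graph(12, 0.25, seed=seed)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            bfs = shortest_path_distances(g)
            # independent all-pairs oracle
            n = list(g.nodes)
            dist = {(a, b): (0.0 if a == b else (1.0 if g.has_edge(a, b) else math.inf))
                    for a in n for b in n}
            for k in n:
                for i in n:
                    for j in n:
                        if dist[(i, k)] + dist[(k, j)] < dist[(i, j)]:
                            dist[(i, j)] = dist[(i, k)] + dist[(k, j)]
            for a in n:
                for b in n:
                    assert bfs.loc[a, b] == dist[(a, b)]


@pytest.fixture(scope="module")
def study_layout():
    """27 worshippers + imam on the default two-grid layout."""
    session = generate_session(RitualConfig(proximity_noise_sd_m=0.0))
    meta = session.metadata
    graph = build_graph(session.proximity, meta)
    return session, graph, categorize_pairs(graph, meta, session.proximity)


class TestCategories:
    def test_partition_is_complete_and_exclusive(self, study_layout):
        session, _, records = study_layout
        n = len(session.participants)
        assert len(records) == n * (n - 1) // 2  # 378 for the 28-person default
        counts = pd.Series([r.category for r in records]).value_counts()
        assert set(counts.index) <= set(CATEGORIES)
        assert counts.sum() == len(records)

    def test_expected_counts_on_default_layout(self, study_layout):
        _, _, records = study_layout
        counts = pd.Series([r.category for r in records]).value_counts()
        assert counts["imam_colocated"] == 13
        assert counts["imam_noncolocated"] == 14
        assert counts["separated"] == 13 * 14
        assert counts["neighbours"] + counts["distant"] == 78 + 91

    def test_imam_pairs_never_worshipper_categories(self, study_layout):
        _, _, records = study_layout
        for r in records:
            if "imam" in (r.id_a, r.id_b):
                assert r.category.startswith("imam_")
                assert r.id_a == "imam"  # imam listed first for lag sign convention

    def test_adjacency_iff_node_distance_one(self, study_layout):
        _, _, records = study_layout
        for r in records:
            if r.category in ("neighbours", "distant"):
                assert r.adjacency == (r.node_distance == 1)

    def test_separated_pairs_unreachable(self, study_layout):
        _, _, records = study_layout
        for r in records:
            if r.category == "separated":
                assert math.isinf(r.node_distance)

    def test_compact_grid_diameter_two(self):
        """A 3x3 cluster at 1.22 m spacing is at most two steps across."""
        cfg = RitualConfig(grid_rows=3, grid_cols=3, n_colocated=9, n_separated=9,
                           proximity_noise_sd_m=0.0)
        session = generate_session(cfg)
        graph = build_graph(session.proximity, session.metadata)
        colocated = [p.id for p in session.participants if p.group == "colocated" and p.role == "worshipper"]
        sub = graph.subgraph(colocated)
        assert nx.diameter(sub) == 2

    def test_two_imams_rejected(self):
        prox, meta = make_tables(
            {"a": (0, 0), "b": (1, 0)}, {"a": "g", "b": "g"}, {"a": "imam", "b": "imam"}
        )
        with pytest.raises(ConfigurationError):
            categorize_pairs(build_graph(prox, meta), meta)


class TestGradient:
    def test_synchrony_decays_with_node_distance(self):
        """With local coupling on, posture %REC correlates negatively with
        network distance (Spearman, p < 0.05) in at least 80% of 20 seeded
        default-size sessions."""
        from scipy.stats import spearmanr

        from ritualsync import (
            calibrate_global_radius,
            cross_recurrence_matrix,
            embed,
            recurrence_rate,
            select_embedding_params,
            unify_pair_params,
        )
        from ritualsync.preprocess import preprocess_series

        significant = 0
        n_seeds = 20
        for seed in range(1, n_seeds + 1):
            session = generate_session(RitualConfig(seed=seed))
            clean = {p.id: preprocess_series(p.posture).values for p in session.participants}
            params = {pid: select_embedding_params(v) for pid, v in clean.items()}
            meta = session.metadata
            records = categorize_pairs(build_graph(session.proximity, meta), meta,
                                       session.proximity)
            trajs = []
            for r in records:
                up = unify_pair_params(params[r.id_a], params[r.id_b])
                trajs.append((embed(clean[r.id_a], up), embed(clean[r.id_b], up)))
            radius = calibrate_global_radius(trajs)
            recs = np.array([
                recurrence_rate(cross_recurrence_matrix(a, b, radius)) for a, b in trajs
            ])
            nds = np.array([r.node_distance for r in records])
            finite = np.isfinite(nds)
            rho, p = spearmanr(nds[finite], recs[finite])
            significant += (rho < 0) and (p < 0.05)
        assert significant / n_seeds >= 0.80


class TestSpacing:
    def test_nearest_neighbour_distances_on_clean_grid(self):
        session = generate_session(RitualConfig(proximity_noise_sd_m=0.0))
        nn = nearest_neighbour_distances(session.proximity, session.metadata, "separated")
        assert np.allclose(nn.to_numpy(), 1.22)
        assert len(nn) == 14
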