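"""Correlation matrix, bootstrap pruning, concept lattice, graph build."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trimodal as tm
from trimodal.network import (
    Concept,
    FormalContext,
    SignedCorrelationMatrix,
    _pair_frame,
    bootstrap_filter,
    build_network,
    correlation_matrix,
    export_edge_table,
    extract_concepts,
    formal_context,
    to_networkx,
    write_dot,
    write_graphml,
)

from conftest import make_tables


# ---------------------------------------------------------------------------
# correlation_matrix
# ---------------------------------------------------------------------------


def test_duplicated_and_negated_variables(default_tables):
    t = default_tables
    dup = t.histology.copy()
    # overwrite one marker with a duplicate / negation of another
    gfap = dup[(dup.marker == "GFAP")].set_index(
        ["animal_id", "distance_bin"])["value"]
    for idx, row in dup.iterrows():
        if row.marker == "CD68":
            dup.loc[idx, "value"] = gfap.loc[(row.animal_id,
                                              row.distance_bin)]
        if row.marker == "IgG":
            dup.loc[idx, "value"] = -gfap.loc[(row.animal_id,
                                               row.distance_bin)]
    t2 = tm.assemble(t.config, t.recording_channel, t.recording_weekly,
                     t.behavior, dup)
    m = correlation_matrix(t2)
    i, j, k = (m.index("gfap_0_50"), m.index("cd68_0_50"),
               m.index("igg_0_50"))
    assert m.C[i, j] == pytest.approx(1.0)
    assert m.C[i, k] == pytest.approx(-1.0)


def test_planted_correlation_within_fisher_z_interval():
    C = np.eye(16)
    i = tm.variable_index("gfap_0_50")
    j = tm.variable_index("cd68_0_50")
    C[i, j] = C[j, i] = 0.8
    ccs = []
    for seed in range(8):
        tables = make_tables(tm.StudyConfig(
            n_animals=6, rng_seed=400 + seed, latent_correlation=C))
        m = correlation_matrix(tables)
        ccs.append(m.C[i, j])
    # Fisher-z 95% band for rho = 0.8 at n = 6: z in 1.0986 +/- 1.96/sqrt(3)
    lo, hi = np.tanh(np.arctanh(0.8) + 1.96 / np.sqrt(3) * np.array([-1, 1]))
    inside = sum(lo <= c <= hi for c in ccs)
    assert inside >= 6   # histology link curvature costs a little


def test_constant_variable_flagged_missing(default_tables):
    t = default_tables
    hist = t.histology.copy()
    hist.loc[hist.marker == "IgG", "value"] = 5.0
    t2 = tm.assemble(t.config, t.recording_channel, t.recording_weekly,
                     t.behavior, hist)
    with pytest.warns(UserWarning, match="constant"):
        m = correlation_matrix(t2)
    k = m.index("igg_0_50")
    off_diag = np.delete(m.C[k], k)
    assert np.isnan(off_diag).all()
    assert not m.retained[k].any()


def test_pair_granularity(default_tables):
    t = default_tables
    assert len(_pair_frame(t, "pct_channels_active", "ladder_time")) == 48
    assert len(_pair_frame(t, "ladder_time", "grip_force")) == 48
    assert len(_pair_frame(t, "gfap_0_50", "ladder_time")) == 6
    assert len(_pair_frame(t, "gfap_0_50", "cd68_0_50")) == 6


# ---------------------------------------------------------------------------
# bootstrap_filter
# ---------------------------------------------------------------------------


def test_planted_strong_pair_retained(default_tables):
    C = np.eye(16)
    i = tm.variable_index("ladder_time")
    j = tm.variable_index("grid_distance")
    C[i, j] = C[j, i] = 0.99
    tables = make_tables(tm.StudyConfig(rng_seed=55, latent_correlation=C))
    m = correlation_matrix(tables)
    bootstrap_filter(m, tables, B=500, alpha=0.05, seed=1)
    assert m.retained[i, j]


def test_alpha_one_retains_nothing(default_tables):
    m = correlation_matrix(default_tables)
    retained = bootstrap_filter(m, default_tables, B=200, alpha=1.0, seed=0)
    assert not retained.any()


def test_bootstrap_is_deterministic_given_seed(default_tables):
    m1 = correlation_matrix(default_tables)
    m2 = correlation_matrix(default_tables)
    r1 = bootstrap_filter(m1, default_tables, B=300, seed=9)
    r2 = bootstrap_filter(m2, default_tables, B=300, seed=9)
    assert np.array_equal(r1, r2)


def test_too_few_resamples_rejected(default_tables):
    m = correlation_matrix(default_tables)
    with pytest.raises(ValueError, match="200"):
        bootstrap_filter(m, default_tables, B=50)


def test_null_retention_close_to_alpha():
    """Independent pairs are retained at about the nominal rate."""
    from trimodal.network import _null_cc_samples

    rng = np.random.default_rng(0)
    kept = 0
    reps = 100
    for _ in range(reps):
        X = rng.normal(size=(6, 8))
        Y = rng.normal(size=(6, 8))
        obs = np.corrcoef(X.ravel(), Y.ravel())[0, 1]
        cc = _null_cc_samples(X, Y, 500, rng)
        cc = cc[~np.isnan(cc)]
        kept += abs(obs) > np.quantile(np.abs(cc), 0.95)
    assert 0.0 <= kept / reps <= 0.12


# ---------------------------------------------------------------------------
# extract_concepts
# ---------------------------------------------------------------------------


def _ctx(inc, objs=None):
    p = inc.shape[1]
    return FormalContext(threshold=0.5,
                         variables=tuple(f"v{k}" for k in range(p)),
                         incidence=np.asarray(inc, dtype=bool),
                         objects=objs)


def test_empty_incidence_has_two_concepts():
    got = extract_concepts(_ctx(np.zeros((4, 4))))
    assert len(got) == 2
    tops = {(len(c.extent), len(c.intent)) for c in got}
    assert tops == {(4, 0), (0, 4)}


def test_full_incidence_has_single_concept():
    got = extract_concepts(_ctx(np.ones((3, 3))))
    assert len(got) == 1
    assert got[0].extent == frozenset({"v0", "v1", "v2"})
    assert got[0].intent == frozenset({"v0", "v1", "v2"})


def _brute_force_concepts(inc, objs, attrs):
    n_obj, p = inc.shape
    out = set()
    for mask in range(1 << p):
        attr_set = {k for k in range(p) if mask & (1 << k)}
        extent = [g for g in range(n_obj)
                  if all(inc[g, a] for a in attr_set)]
        intent = {a for a in range(p)
                  if all(inc[g, a] for g in extent)}
        out.add(Concept(
            extent=frozenset(objs[g] for g in extent),
            intent=frozenset(attrs[a] for a in intent)))
    return out


@settings(derandomize=True, max_examples=40)
@given(seed=st.integers(0, 100_000))
def test_concepts_equal_powerset_closure_oracle(seed):
    rng = np.random.default_rng(seed)
    n_obj = int(rng.integers(1, 8))
    p = int(rng.integers(1, 8))
    inc = rng.random((n_obj, p)) < rng.uniform(0.2, 0.8)
    objs = tuple(f"o{k}" for k in range(n_obj))
    ctx = _ctx(inc, objs)
    got = set(extract_concepts(ctx))
    assert got == _brute_force_concepts(inc, objs, ctx.variables)


def test_incidence_monotone_in_threshold(default_tables):
    m = correlation_matrix(default_tables)
    b_lo = formal_context(m, 0.2).incidence
    b_hi = formal_context(m, 0.6).incidence
    assert not np.any(b_hi & ~b_lo)


# ---------------------------------------------------------------------------
# build_network
# ---------------------------------------------------------------------------


def _matrix(names, entries):
    p = len(names)
    C = np.eye(p)
    for (a, b), v in entries.items():
        i, j = names.index(a), names.index(b)
        C[i, j] = C[j, i] = v
    retained = ~np.eye(p, dtype=bool)
    return SignedCorrelationMatrix(variables=tuple(names), C=C,
                                   n_eff=np.full((p, p), 48),
                                   retained=retained)


def test_symmetric_pair_forms_single_bi_edge():
    m = _matrix(["pct", "upc"], {("pct", "upc"): 0.964})
    g = build_network(m, with_concepts=False)
    assert len(g.edges) == 1
    e = g.edges[0]
    assert (e.strength, e.direction, e.sign) == (0.964, "BI", "positive")


def test_three_node_hand_example():
    """ab 0.9, bc 0.8, ac 0.3: hierarchy ab+bc, influence ac; dominance
    a 1.2, b 1.7, c 1.1; b->a, b->c, a->c."""
    m = _matrix(["a", "b", "c"], {("a", "b"): 0.9, ("b", "c"): 0.8,
                                  ("a", "c"): 0.3})
    g = build_network(m, tau=0.25, epsilon=0.05, with_concepts=False)
    assert g.dominance == pytest.approx({"a": 1.2, "b": 1.7, "c": 1.1})
    by_pair = {frozenset((e.var_a, e.var_b)): e for e in g.edges}
    ab = by_pair[frozenset(("a", "b"))]
    assert (ab.layer, ab.direction, ab.var_a) == ("hierarchy", "UNI", "b")
    bc = by_pair[frozenset(("b", "c"))]
    assert (bc.layer, bc.direction, bc.var_a) == ("hierarchy", "UNI", "b")
    ac = by_pair[frozenset(("a", "c"))]
    assert (ac.layer, ac.direction, ac.var_a) == ("influence", "UNI", "a")


def test_negative_sign_kept_on_edges():
    m = _matrix(["a", "b"], {("a", "b"): -0.7})
    g = build_network(m, with_concepts=False)
    assert g.edges[0].sign == "negative"
    assert g.edges[0].strength == pytest.approx(0.7)


def test_tie_break_is_deterministic():
    m1 = _matrix(["a", "b", "c", "d"],
                 {("a", "b"): 0.5, ("c", "d"): 0.5, ("a", "c"): 0.5})
    g1 = build_network(m1, with_concepts=False)
    g2 = build_network(m1, with_concepts=False)
    assert [(e.var_a, e.var_b, e.layer) for e in g1.edges] == \
           [(e.var_a, e.var_b, e.layer) for e in g2.edges]


def test_hierarchy_is_spanning_forest():
    rng = np.random.default_rng(2)
    names = [f"v{k}" for k in range(8)]
    entries = {}
    for i in range(8):
        for j in range(i + 1, 8):
            entries[(names[i], names[j])] = float(rng.uniform(0.3, 0.99))
    g = build_network(_matrix(names, entries), with_concepts=False)
    hier = [e for e in g.edges if e.layer == "hierarchy"]
    assert len(hier) <= 7
    seen = set()
    for e in g.edges:
        key = frozenset((e.var_a, e.var_b))
        assert key not in seen
        seen.add(key)


@settings(derandomize=True, max_examples=20)
@given(seed=st.integers(0, 1000))
def test_raising_tau_never_adds_edges(seed):
    rng = np.random.default_rng(seed)
    names = [f"v{k}" for k in range(6)]
    entries = {(names[i], names[j]): float(rng.uniform(-1, 1))
               for i in range(6) for j in range(i + 1, 6)}
    m = _matrix(names, entries)
    lo = {(e.var_a, e.var_b) for e in
          build_network(m, tau=0.2, with_concepts=False).edges}
    hi = {(e.var_a, e.var_b) for e in
          build_network(m, tau=0.5, with_concepts=False).edges}
    assert hi <= lo


def test_all_below_tau_gives_empty_graph_with_warning():
    m = _matrix(["a", "b"], {("a", "b"): 0.1})
    m.retained = np.zeros((2, 2), dtype=bool)
    with pytest.warns(UserWarning, match="empty graph"):
        g = build_network(m, tau=0.25, with_concepts=False)
    assert g.edges == []


def test_concept_diagnostics_track_merging():
    m = _matrix(["a", "b", "c"], {("a", "b"): 0.9, ("b", "c"): 0.8,
                                  ("a", "c"): 0.3})
    g = build_network(m, tau=0.25, epsilon=0.05, with_concepts=True)
    levels = [d["threshold"] for d in g.concept_diagnostics]
    assert levels == sorted(levels, reverse=True)
    assert all(d["n_concepts"] >= 1 for d in g.concept_diagnostics)


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------


def test_edge_table_layout_and_rounding():
    m = _matrix(["pct", "upc"], {("pct", "upc"): 0.9639})
    df = export_edge_table(build_network(m, with_concepts=False))
    row = df.iloc[0]
    assert row.relationship == "Positive"
    assert row.strength == 0.964
    assert row.direction == "BI"


def test_empty_graph_exports_header_only():
    m = _matrix(["a", "b"], {("a", "b"): 0.1})
    m.retained = np.zeros((2, 2), dtype=bool)
    with pytest.warns(UserWarning):
        df = export_edge_table(build_network(m, tau=0.25,
                                             with_concepts=False))
    assert len(df) == 0
    assert list(df.columns)[:3] == ["variable", "relationship",
                                    "network_variable"]


def test_graphml_round_trip_preserves_edges(tmp_path):
    import networkx as nx

    m = _matrix(["a", "b", "c"], {("a", "b"): 0.9, ("b", "c"): 0.8,
                                  ("a", "c"): 0.3})
    g = build_network(m, with_concepts=False)
    path = tmp_path / "net.graphml"
    write_graphml(g, path)
    back = nx.read_graphml(path)
    expect = to_networkx(g)
    assert set(back.edges) == set(expect.edges)
    for u, v in expect.edges:
        assert back[u][v]["strength"] == pytest.approx(
            expect[u][v]["strength"])


def test_dot_export_contains_edges(tmp_path):
    m = _matrix(["a", "b"], {("a", "b"): -0.6})
    g = build_network(m, with_concepts=False)
    path = tmp_path / "net.dot"
    write_dot(g, path)
    text = path.read_text()
    assert '"a" -> "b"' in text or '"b" -> "a"' in text
    assert 'sign="negative"' in text
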