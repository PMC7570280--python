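"""Signed correlation network via numerical formal concept analysis (nFCA).

The sixteen analysis variables are correlated pairwise (Pearson, signed,
pairwise-complete, at the finest granularity both variables share),
spurious pairs are pruned by an independent bootstrap test that
resamples animals, and the surviving associations are organised into a
two-layer graph:

* a *hierarchy* layer — a maximum spanning forest over |cc|, the
  strongest associations that first connect the variable clusters
  (the clustering hierarchy a concept lattice lifts out of the
  thresholded incidence relation); and
* an *influence* layer — every remaining retained pair with |cc| at or
  above a strength floor.

Each edge keeps the correlation sign and strength; arrows point from the
*dominant* variable (larger total retained association mass) to the
weaker one, double-headed when the two masses are within tolerance.
Formal concept lattices of the thresholded incidence relation are
enumerated (NextClosure) on a grid of thresholds as a diagnostic showing
when clusters merge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import AnalysisTables
from .config import VARIABLES

DEFAULT_TAU = 0.25        # influence-layer strength floor
DEFAULT_EPSILON = 0.05    # dominance tolerance for bidirectional edges
DEFAULT_B = 1000          # bootstrap resamples
DEFAULT_ALPHA = 0.05
MIN_PAIR_N = 3


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class SignedCorrelationMatrix:
    variables: tuple[str, ...]
    C: np.ndarray                 # signed Pearson correlations, NaN = undefined
    n_eff: np.ndarray             # observation units used per pair
    retained: np.ndarray          # bootstrap mask (all True before filtering)

    def index(self, var: str) -> int:
        return self.variables.index(var)


@dataclass(frozen=True)
class FormalContext:
    """Thresholded incidence relation: B(i,j) = [|C(i,j)| retained >= t].

    In the nFCA setting objects and attributes are both the analysis
    variables; ``objects`` may name a distinct object set for general
    (rectangular) contexts.
    """

    threshold: float
    variables: tuple[str, ...]    # attributes
    incidence: np.ndarray         # boolean; False diagonal when square
    objects: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.objects is None:
            object.__setattr__(self, "objects", self.variables)


@dataclass(frozen=True)
class Concept:
    """A formal concept: extent and intent each the other's derivation."""

    extent: frozenset
    intent: frozenset


@dataclass
class NfcaEdge:
    var_a: str                    # tail for UNI edges
    var_b: str
    strength: float               # |cc|
    sign: str                     # "positive" / "negative"
    direction: str                # "UNI" / "BI"
    layer: str                    # "hierarchy" / "influence"


@dataclass
class NfcaGraph:
    variables: tuple[str, ...]
    edges: list[NfcaEdge]
    dominance: dict[str, float]
    tau: float
    epsilon: float
    concept_diagnostics: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pairwise signed correlations
# ---------------------------------------------------------------------------


def _pair_frame(tables: AnalysisTables, va: str, vb: str) -> pd.DataFrame:
    """Aligned (animal, x, y) rows for one pair at its shared granularity.

    Two longitudinal variables align on (animal, week); any pair
    involving an endpoint histology variable aligns on per-animal values
    (means over post-implant weeks for the longitudinal member).
    """
    if tables.is_longitudinal(va) and tables.is_longitudinal(vb):
        df = pd.concat([tables.longitudinal_series(va),
                        tables.longitudinal_series(vb)], axis=1).dropna()
        # post-implant weeks only: the presurgery baseline week is a
        # different condition (it normalizes behavior, it is not an
        # observation of the implanted state) and would otherwise inject
        # a shared injury-effect cluster into every behavior pair
        df = df[df.index.get_level_values("week") >= 1].reset_index()
        return df.rename(columns={va: "x", vb: "y"})[["animal_id", "x", "y"]]
    df = pd.concat([tables.animal_series(va),
                    tables.animal_series(vb)], axis=1).dropna().reset_index()
    return df.rename(columns={va: "x", vb: "y"})[["animal_id", "x", "y"]]


def correlation_matrix(tables: AnalysisTables,
                       variables=VARIABLES) -> SignedCorrelationMatrix:
    """Signed Pearson correlations over all registry variable pairs."""
    variables = tuple(variables)
    p = len(variables)
    C = np.eye(p)
    n_eff = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i + 1, p):
            df = _pair_frame(tables, variables[i], variables[j])
            n = len(df)
            n_eff[i, j] = n_eff[j, i] = n
            if n < MIN_PAIR_N or df.x.std() == 0 or df.y.std() == 0:
                if n >= MIN_PAIR_N:
                    warnings.warn(
                        f"constant variable in pair "
                        f"({variables[i]}, {variables[j]}); correlation "
                        "flagged missing")
                C[i, j] = C[j, i] = np.nan
                continue
            C[i, j] = C[j, i] = float(np.corrcoef(df.x, df.y)[0, 1])
    retained = ~np.isnan(C)
    np.fill_diagonal(retained, False)
    return SignedCorrelationMatrix(variables=variables, C=C, n_eff=n_eff,
                                   retained=retained)


# ---------------------------------------------------------------------------
# Bootstrap pruning
# ---------------------------------------------------------------------------


def _animal_matrices(df: pd.DataFrame):
    """Stack one pair's rows into per-animal aligned (x, y) row blocks."""
    groups = [g[["x", "y"]].to_numpy() for _, g in df.groupby("animal_id")]
    k = max(len(g) for g in groups)
    X = np.full((len(groups), k), np.nan)
    Y = np.full((len(groups), k), np.nan)
    for i, g in enumerate(groups):
        X[i, : len(g)] = g[:, 0]
        Y[i, : len(g)] = g[:, 1]
    return X, Y


def _corr_from_stats(Sx, Sy, Sxx, Syy, Sxy, N):
    num = Sxy - Sx * Sy / N
    den2 = (Sxx - Sx ** 2 / N) * (Syy - Sy ** 2 / N)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den2 > 0, num / np.sqrt(np.maximum(den2, 1e-300)),
                        np.nan)


def _null_cc_samples(X, Y, B, rng):
    """Bootstrap |cc| under independence: x-animals and y-animals resampled
    independently, week slots kept aligned within each animal."""
    G = X.shape[0]
    Xz = np.nan_to_num(X)
    Yz = np.nan_to_num(Y)
    mask = ~np.isnan(X) & ~np.isnan(Y)   # same missingness pattern per pair
    ix = rng.integers(0, G, size=(B, G))
    iy = rng.integers(0, G, size=(B, G))
    # per-(animal_x, animal_y) cross moments over aligned slots
    cross = (Xz * mask) @ (Yz * mask).T
    nmat = (mask.astype(float)) @ (mask.astype(float).T)
    sx_pair = (Xz * mask) @ mask.astype(float).T
    sy_pair = mask.astype(float) @ (Yz * mask).T
    sxx_pair = (Xz ** 2 * mask) @ mask.astype(float).T
    syy_pair = mask.astype(float) @ (Yz ** 2 * mask).T
    Sxy = cross[ix, iy].sum(axis=1)
    N = nmat[ix, iy].sum(axis=1)
    Sx = sx_pair[ix, iy].sum(axis=1)
    Sy = sy_pair[ix, iy].sum(axis=1)
    Sxx = sxx_pair[ix, iy].sum(axis=1)
    Syy = syy_pair[ix, iy].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = _corr_from_stats(Sx, Sy, Sxx, Syy, Sxy, np.maximum(N, 1))
    return cc


def _cluster_cc_samples(X, Y, B, rng):
    """Plain cluster-bootstrap cc: animals resampled jointly."""
    G = X.shape[0]
    mask = ~np.isnan(X) & ~np.isnan(Y)
    Xz = np.nan_to_num(X) * mask
    Yz = np.nan_to_num(Y) * mask
    n_a = mask.sum(axis=1).astype(float)
    sx, sy = Xz.sum(axis=1), Yz.sum(axis=1)
    sxx, syy = (Xz ** 2).sum(axis=1), (Yz ** 2).sum(axis=1)
    sxy = (Xz * Yz).sum(axis=1)
    idx = rng.integers(0, G, size=(B, G))
    N = n_a[idx].sum(axis=1)
    return _corr_from_stats(sx[idx].sum(1), sy[idx].sum(1),
                            sxx[idx].sum(1), syy[idx].sum(1),
                            sxy[idx].sum(1), np.maximum(N, 1))


def bootstrap_filter(matrix: SignedCorrelationMatrix, tables: AnalysisTables,
                     B: int = DEFAULT_B, alpha: float = DEFAULT_ALPHA,
                     seed: int = 0, method: str = "independent") -> np.ndarray:
    """Bootstrap test per pair; returns (and installs) the retained mask.

    ``method='independent'`` (default): the two variables' animals are
    resampled independently, giving the null distribution of |cc| under
    no cross-variable association while preserving each variable's
    within-animal dependence; a pair is retained iff its observed |cc|
    exceeds the (1 - alpha) null quantile. ``method='percentile'``: the
    animals are resampled jointly and the pair is retained iff the
    (1 - alpha) percentile interval of cc excludes zero. Degenerate
    resamples (constant columns) are skipped. At confidence level
    1 - alpha <= 0 nothing can be demonstrated, so nothing is retained.
    """
    if B < 200:
        raise ValueError("need at least 200 bootstrap resamples")
    if method not in ("independent", "percentile"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    p = len(matrix.variables)
    retained = np.zeros((p, p), dtype=bool)
    if 1.0 - alpha <= 0:
        matrix.retained = retained
        return retained
    rng = np.random.default_rng(seed)
    for i in range(p):
        for j in range(i + 1, p):
            obs = matrix.C[i, j]
            if np.isnan(obs) or matrix.n_eff[i, j] < MIN_PAIR_N:
                continue
            df = _pair_frame(tables, matrix.variables[i], matrix.variables[j])
            X, Y = _animal_matrices(df)
            if method == "independent":
                cc = _null_cc_samples(X, Y, B, rng)
                cc = cc[~np.isnan(cc)]
                if cc.size == 0:
                    continue
                keep = abs(obs) > np.quantile(np.abs(cc), 1.0 - alpha)
            else:
                cc = _cluster_cc_samples(X, Y, B, rng)
                cc = cc[~np.isnan(cc)]
                if cc.size == 0:
                    continue
                lo, hi = np.quantile(cc, [alpha / 2, 1.0 - alpha / 2])
                keep = lo > 0 or hi < 0
            retained[i, j] = retained[j, i] = keep
    matrix.retained = retained
    return retained


# ---------------------------------------------------------------------------
# Formal concept analysis (NextClosure)
# ---------------------------------------------------------------------------


def formal_context(matrix: SignedCorrelationMatrix,
                   threshold: float) -> FormalContext:
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    A = np.abs(np.nan_to_num(matrix.C)) * matrix.retained
    incidence = A >= threshold
    np.fill_diagonal(incidence, False)
    return FormalContext(threshold=threshold, variables=matrix.variables,
                         incidence=incidence)


def extract_concepts(context: FormalContext,
                     max_concepts: int | None = None) -> list[Concept]:
    """All formal concepts of the context, by NextClosure over attributes.

    Attribute sets are enumerated in lectic order; each closed intent is
    paired with its extent. Output is canonically ordered by descending
    extent size, then lexicographically.
    """
    inc = np.asarray(context.incidence, dtype=bool)
    n_obj, p = inc.shape
    if p > 64:
        raise ValueError("context too large (more than 64 attributes)")
    rows = [int.from_bytes(
        np.packbits(inc[g], bitorder="little").tobytes(), "little")
        for g in range(n_obj)]
    full = (1 << p) - 1

    def closure(mask: int) -> tuple[int, int]:
        intent = full
        extent = 0
        for g, row in enumerate(rows):
            if row & mask == mask:
                extent |= 1 << g
                intent &= row
        return intent, extent

    concepts = []
    intent, extent = closure(0)
    concepts.append((intent, extent))
    A = intent
    while A != full:
        nxt = None
        for i in range(p - 1, -1, -1):
            if A & (1 << i):
                continue
            below = (1 << i) - 1
            cand = (A & below) | (1 << i)
            c_int, c_ext = closure(cand)
            # lectic condition: no new attribute smaller than i
            if (c_int & below) == (A & below):
                nxt = (c_int, c_ext)
                break
        if nxt is None:  # defensive: closure of the full set always closes
            break
        A = nxt[0]
        concepts.append(nxt)
        if max_concepts is not None and len(concepts) >= max_concepts:
            break

    def unpack(mask, universe):
        return frozenset(universe[k] for k in range(len(universe))
                         if mask & (1 << k))

    out = [Concept(extent=unpack(e, context.objects),
                   intent=unpack(i, context.variables))
           for i, e in concepts]
    out.sort(key=lambda c: (-len(c.extent), tuple(sorted(c.extent)),
                            tuple(sorted(c.intent))))
    return out


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_network(matrix: SignedCorrelationMatrix,
                  tau: float = DEFAULT_TAU,
                  epsilon: float = DEFAULT_EPSILON,
                  with_concepts: bool = True,
                  max_concepts: int = 20000) -> NfcaGraph:
    """Construct the two-layer nFCA graph from a pruned correlation matrix.

    Retained pairs are scanned in descending |cc| (ties broken by
    lexicographic variable order, so the graph is deterministic); a pair
    joins the hierarchy layer iff it connects two previously disconnected
    components (maximum spanning forest), and the influence layer
    otherwise when |cc| >= tau. The dominance score of a variable is its
    total retained |cc| mass; an edge is bidirectional when the two
    endpoint scores differ by at most epsilon x the larger, else it
    points from the larger-score variable to the smaller.
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    p = len(matrix.variables)
    A = np.abs(np.nan_to_num(matrix.C)) * matrix.retained
    dominance = {v: float(A[i].sum()) for i, v in enumerate(matrix.variables)}

    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)
             if matrix.retained[i, j]]
    pairs.sort(key=lambda ij: (-A[ij], matrix.variables[ij[0]],
                               matrix.variables[ij[1]]))
    uf = _UnionFind(p)
    edges = []
    for i, j in pairs:
        layer = "hierarchy" if uf.union(i, j) else "influence"
        if layer == "influence" and A[i, j] < tau:
            continue
        va, vb = matrix.variables[i], matrix.variables[j]
        sa, sb = dominance[va], dominance[vb]
        if abs(sa - sb) <= epsilon * max(sa, sb):
            direction = "BI"
            a, b = sorted((va, vb))
        else:
            direction = "UNI"
            a, b = (va, vb) if sa > sb else (vb, va)
        edges.append(NfcaEdge(
            var_a=a, var_b=b, strength=float(A[i, j]),
            sign="positive" if matrix.C[i, j] >= 0 else "negative",
            direction=direction, layer=layer))
    if not edges:
        warnings.warn("no retained pair reaches the strength floor; "
                      "empty graph returned")

    diagnostics = []
    if with_concepts:
        levels = sorted({round(float(A[i, j]), 6) for i, j in pairs
                         if A[i, j] >= tau}, reverse=True)
        for t in levels:
            ctx = formal_context(matrix, t)
            concepts = extract_concepts(ctx, max_concepts=max_concepts)
            diagnostics.append({
                "threshold": t,
                "n_concepts": len(concepts),
                "concepts": [
                    {"extent": sorted(c.extent), "intent": sorted(c.intent)}
                    for c in concepts],
            })
    return NfcaGraph(variables=matrix.variables, edges=edges,
                     dominance=dominance, tau=tau, epsilon=epsilon,
                     concept_diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def export_edge_table(graph: NfcaGraph) -> pd.DataFrame:
    """One row per edge: variable, relationship, network variable,
    strength (3 decimals), direction, layer."""
    rows = [(e.var_a, e.sign.capitalize(), e.var_b,
             round(e.strength, 3), e.direction, e.layer)
            for e in graph.edges]
    return pd.DataFrame(rows, columns=[
        "variable", "relationship", "network_variable", "strength",
        "direction", "layer"])


def to_networkx(graph: NfcaGraph):
    import networkx as nx

    g = nx.DiGraph()
    for v in graph.variables:
        g.add_node(v, dominance=graph.dominance.get(v, 0.0))
    for e in graph.edges:
        g.add_edge(e.var_a, e.var_b, strength=e.strength, sign=e.sign,
                   direction=e.direction, layer=e.layer)
        if e.direction == "BI":
            g.add_edge(e.var_b, e.var_a, strength=e.strength, sign=e.sign,
                       direction=e.direction, layer=e.layer)
    return g


def write_graphml(graph: NfcaGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(graph), str(path))


def write_dot(graph: NfcaGraph, path: str | Path) -> None:
    lines = ["digraph nfca {"]
    for v in graph.variables:
        lines.append(f'  "{v}" [dominance={graph.dominance.get(v, 0.0):.4f}];')
    for e in graph.edges:
        attrs = (f'label="{e.strength:.3f}", sign="{e.sign}", '
                 f'layer="{e.layer}"')
        if e.direction == "BI":
            attrs += ', dir="both"'
        lines.append(f'  "{e.var_a}" -> "{e.var_b}" [{attrs}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_concepts(graph: NfcaGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph.concept_diagnostics, indent=2))


def run_network(tables: AnalysisTables, tau: float = DEFAULT_TAU,
                epsilon: float = DEFAULT_EPSILON, B: int = DEFAULT_B,
                alpha: float = DEFAULT_ALPHA, seed: int = 0,
                method: str = "independent",
                with_concepts: bool = True) -> tuple[SignedCorrelationMatrix,
                                                     NfcaGraph]:
    """Correlations -> bootstrap pruning -> nFCA graph, in one call."""
    matrix = correlation_matrix(tables)
    bootstrap_filter(matrix, tables, B=B, alpha=alpha, seed=seed,
                     method=method)
    graph = build_network(matrix, tau=tau, epsilon=epsilon,
                          with_concepts=with_concepts)
    return matrix, graph
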