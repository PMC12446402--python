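"""Spatial weights and Moran's I statistics (global, bivariate, local) with
permutation inference.

Global Moran's I for mean-deviated values z on weights W with total weight S0:

    I = (n / S0) * (z' W z) / (z' z)

and its bivariate analogue uses unit-variance z-scores of two variables,
I_xy = (zx' W zy) / S0, which reduces to the univariate statistic when y = x.
Local statistics decompose the global one: on row-standardized weights the
per-tract values sum to n * I_global.  Inference is by random permutation
(conditional permutation for the local statistics, holding the focal value
fixed and drawing its neighborhood from the remaining tracts).  The default
p-value is two-sided (twice the smaller pseudo-count tail), which is uniform
under the null and flags both positive (HH/LL) and negative (HL/LH) local
association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

QUADRANTS = ("HH", "LL", "HL", "LH", "not_significant")
_ALTERNATIVES = ("two-sided", "greater", "less")


class SpatialWeights:
    """Contiguity (or supplied) neighbor weights over a fixed set of tract ids.

    Neighbors are stored as index arrays into ``ids``; weights are uniform
    per edge before row standardization.  Isolated tracts (no neighbors) are
    recorded explicitly and excluded from the statistics.
    """

    def __init__(self, ids, neighbors, scheme="supplied", row_standardized=True):
        self.ids = list(ids)
        self._pos = {t: i for i, t in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise ValueError("duplicate tract ids")
        self.scheme = scheme
        self.row_standardized = bool(row_standardized)
        nb = [np.asarray(sorted(neighbors.get(i, ())), dtype=int) for i in range(len(self.ids))]
        for i, arr in enumerate(nb):
            if np.any(arr == i):
                raise ValueError(f"self-neighbor at tract {self.ids[i]!r}")
        # adjacency must be symmetric before standardization
        edges = {(i, j) for i, arr in enumerate(nb) for j in arr}
        for i, j in edges:
            if (j, i) not in edges:
                raise ValueError(f"asymmetric adjacency: {self.ids[i]!r} -> {self.ids[j]!r}")
        self.neighbors = nb
        self.weights = [
            (np.full(len(a), 1.0 / len(a)) if self.row_standardized and len(a) else np.ones(len(a)))
            for a in nb
        ]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_grid(cls, n_rows, n_cols, scheme="queen", row_standardize=True, ids=None):
        """Contiguity weights on a regular grid of cells (row-major ids)."""
        if scheme not in ("queen", "rook"):
            raise ValueError("scheme must be 'queen' or 'rook'")
        if ids is None:
            ids = [f"T{r * n_cols + c:05d}" for r in range(n_rows) for c in range(n_cols)]
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if scheme == "queen":
            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        nb = {}
        for r in range(n_rows):
            for c in range(n_cols):
                i = r * n_cols + c
                nb[i] = [
                    (r + dr) * n_cols + (c + dc)
                    for dr, dc in steps
                    if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
                ]
        return cls(ids, nb, scheme=scheme, row_standardized=row_standardize)

    @classmethod
    def from_geojson(cls, geo, scheme="queen", row_standardize=True, id_property="tract_id"):
        """Polygon contiguity from a GeoJSON FeatureCollection.

        Queen contiguity joins polygons sharing at least a point; rook
        requires a shared edge of positive length.
        """
        from shapely.geometry import shape
        from shapely.strtree import STRtree

        feats = geo.get("features", [])
        if not feats:
            raise ValueError("empty geometry")
        ids = [f["properties"][id_property] for f in feats]
        geoms = [shape(f["geometry"]) for f in feats]
        tree = STRtree(geoms)
        nb = {i: [] for i in range(len(ids))}
        for i, g in enumerate(geoms):
            for j in tree.query(g):
                j = int(j)
                if j <= i:
                    continue
                inter = g.intersection(geoms[j])
                if inter.is_empty:
                    continue
                touch = inter.length > 0 if scheme == "rook" else True
                if touch:
                    nb[i].append(j)
                    nb[j].append(i)
        return cls(ids, nb, scheme=scheme, row_standardized=row_standardize)

    @classmethod
    def from_adjacency(cls, edges, ids=None, row_standardize=True):
        """Explicit undirected edge list of (tract_id, tract_id) pairs."""
        if ids is None:
            ids = sorted({t for e in edges for t in e})
        pos = {t: i for i, t in enumerate(ids)}
        nb = {i: set() for i in range(len(ids))}
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-neighbor at {a!r}")
            nb[pos[a]].add(pos[b])
            nb[pos[b]].add(pos[a])
        return cls(ids, {i: sorted(s) for i, s in nb.items()}, scheme="supplied",
                   row_standardized=row_standardize)

    # -- views -------------------------------------------------------------
    @property
    def n(self):
        return len(self.ids)

    @property
    def isolates(self):
        return [self.ids[i] for i, a in enumerate(self.neighbors) if len(a) == 0]

    @property
    def s0(self):
        return float(sum(w.sum() for w in self.weights))

    def neighbors_of(self, tract_id):
        return [self.ids[j] for j in self.neighbors[self._pos[tract_id]]]

    def edge_list(self):
        return [
            (self.ids[i], self.ids[j])
            for i, arr in enumerate(self.neighbors)
            for j in arr
            if i < j
        ]

    def sparse(self):
        rows, cols, vals = [], [], []
        for i, (arr, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(arr))
            cols.extend(arr.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def subset(self, keep_ids):
        """Weights restricted to ``keep_ids`` with only within-subset edges."""
        keep = [t for t in self.ids if t in set(keep_ids)]
        old = [self._pos[t] for t in keep]
        remap = {o: i for i, o in enumerate(old)}
        nb = {
            i: [remap[j] for j in self.neighbors[o] if j in remap]
            for i, o in enumerate(old)
        }
        return SpatialWeights(keep, nb, scheme=self.scheme,
                              row_standardized=self.row_standardized)


def build_weights(geometry=None, adjacency=None, scheme="queen", row_standardize=True,
                  grid=None, ids=None):
    """Dispatching constructor: GeoJSON polygons, an edge list, or grid dims."""
    if geometry is not None:
        return SpatialWeights.from_geojson(geometry, scheme=scheme,
                                           row_standardize=row_standardize)
    if adjacency is not None:
        return SpatialWeights.from_adjacency(adjacency, ids=ids,
                                             row_standardize=row_standardize)
    if grid is not None:
        return SpatialWeights.from_grid(*grid, scheme=scheme,
                                        row_standardize=row_standardize, ids=ids)
    raise ValueError("supply geometry, adjacency, or grid dimensions")


@dataclass
class MoranResult:
    I: float
    expected_I: float
    p_perm: float
    n_perm: int
    n: int
    labels: tuple = ("x",)


@dataclass
class LisaResult:
    table: pd.DataFrame  # local_I, p_perm, quadrant per tract
    alpha: float
    n_perm: int
    labels: tuple = ("x",)

    def cluster(self, quadrant: str) -> list:
        return list(self.table.index[self.table["quadrant"] == quadrant])


def _align(w: SpatialWeights, *series):
    """Listwise-drop missing values, returning a subset weights object + arrays."""
    vals = [pd.Series(s).reindex(w.ids).to_numpy(dtype=float) for s in series]
    ok = np.ones(w.n, dtype=bool)
    for v in vals:
        ok &= np.isfinite(v)
    if ok.all():
        return w, vals
    keep = [t for t, k in zip(w.ids, ok) if k]
    sub = w.subset(keep)
    return sub, [v[ok] for v in vals]


def _pseudo_p(obs, perms, alternative):
    m = len(perms)
    p_up = (1 + np.sum(perms >= obs)) / (m + 1)
    p_lo = (1 + np.sum(perms <= obs)) / (m + 1)
    if alternative == "greater":
        return p_up
    if alternative == "less":
        return p_lo
    return min(1.0, 2.0 * min(p_up, p_lo))


def global_moran(x, w: SpatialWeights, n_perm=999, seed=0, alternative="two-sided"):
    """Global univariate Moran's I with a permutation test."""
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    w2, (xv,) = _align(w, x)
    if w2.n < 3:
        raise ValueError("need at least 3 non-missing tracts")
    z = xv - xv.mean()
    zz = float(z @ z)
    if zz == 0.0:
        raise ValueError("constant surface: variance of x is zero")
    W = w2.sparse()
    s0 = w2.s0
    n = w2.n
    obs = (n / s0) * float(z @ (W @ z)) / zz
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        zp = z[rng.permutation(n)]
        perms[k] = (n / s0) * float(zp @ (W @ zp)) / zz
    return MoranResult(I=obs, expected_I=-1.0 / (n - 1),
                       p_perm=_pseudo_p(obs, perms, alternative),
                       n_perm=n_perm, n=n, labels=(getattr(x, "name", "x"),))


def bivariate_moran(x, y, w: SpatialWeights, n_perm=999, seed=0, alternative="two-sided"):
    """Global bivariate Moran's I: correlation of x with the spatial lag of y.

    Both variables are standardized to unit variance; the permutation test
    holds x fixed and permutes y.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    w2, (xv, yv) = _align(w, x, y)
    if w2.n < 3:
        raise ValueError("need at least 3 non-missing tracts")
    n = w2.n
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant surface: variance is zero")
    zx = (xv - xv.mean()) / sx
    zy = (yv - yv.mean()) / sy
    W = w2.sparse()
    s0 = w2.s0
    obs = float(zx @ (W @ zy)) / s0
    rng = np.random.default_rng(seed)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        perms[k] = float(zx @ (W @ zy[rng.permutation(n)])) / s0
    return MoranResult(I=obs, expected_I=-1.0 / (n - 1),
                       p_perm=_pseudo_p(obs, perms, alternative),
                       n_perm=n_perm, n=n,
                       labels=(getattr(x, "name", "x"), getattr(y, "name", "y")))


def _conditional_lisa(zfocal, zlag_source, w2, n_perm, seed, m2):
    """Per-tract conditional permutation distribution of z_i * lag_i / m2.

    ``zfocal`` supplies the fixed focal values, ``zlag_source`` the values
    permuted over each tract's neighborhood (equal to ``zfocal`` in the
    univariate case).
    """
    n = w2.n
    rng = np.random.default_rng(seed)
    local = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    lags = np.full(n, np.nan)
    for i in range(n):
        nbrs = w2.neighbors[i]
        if len(nbrs) == 0:
            continue  # isolates: missing, not zero
        wi = w2.weights[i]
        lag = float(zlag_source[nbrs] @ wi)
        lags[i] = lag
        obs = zfocal[i] * lag / m2
        local[i] = obs
        others = np.delete(zlag_source, i)
        idx = rng.integers(0, n - 1, size=(n_perm, len(nbrs)))
        perm_lags = others[idx] @ wi
        perms = zfocal[i] * perm_lags / m2
        pvals[i] = _pseudo_p(obs, perms, "two-sided")
    return local, pvals, lags


def _quadrants(zfocal, lags, pvals, alpha):
    quad = np.where(
        np.isnan(pvals) | (pvals > alpha),
        "not_significant",
        np.where(zfocal > 0, np.where(lags > 0, "HH", "HL"), np.where(lags > 0, "LH", "LL")),
    )
    return quad


def local_moran(x, w: SpatialWeights, n_perm=999, alpha=0.05, seed=0):
    """Univariate LISA with conditional permutation and HH/LL/HL/LH labels."""
    w2, (xv,) = _align(w, x)
    if w2.n < 3:
        raise ValueError("need at least 3 non-missing tracts")
    z = xv - xv.mean()
    m2 = float(z @ z) / w2.n
    if m2 == 0.0:
        raise ValueError("constant surface: variance of x is zero")
    local, pvals, lags = _conditional_lisa(z, z, w2, n_perm, seed, m2)
    table = pd.DataFrame(
        {"local_I": local, "p_perm": pvals, "quadrant": _quadrants(z, lags, pvals, alpha)},
        index=pd.Index(w2.ids, name="tract_id"),
    )
    return LisaResult(table=table, alpha=alpha, n_perm=n_perm, labels=(getattr(x, "name", "x"),))


def local_moran_bv(x, y, w: SpatialWeights, n_perm=999, alpha=0.05, seed=0):
    """Bivariate LISA: z-score of x against the spatial lag of y.

    The HL quadrant (high x surrounded by low y) is the one used to find
    high-exposure / low-SVI enclaves.
    """
    w2, (xv, yv) = _align(w, x, y)
    if w2.n < 3:
        raise ValueError("need at least 3 non-missing tracts")
    sx, sy = xv.std(), yv.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("constant surface: variance is zero")
    zx = (xv - xv.mean()) / sx
    zy = (yv - yv.mean()) / sy
    local, pvals, lags = _conditional_lisa(zx, zy, w2, n_perm, seed, m2=1.0)
    table = pd.DataFrame(
        {"local_I": local, "p_perm": pvals, "quadrant": _quadrants(zx, lags, pvals, alpha)},
        index=pd.Index(w2.ids, name="tract_id"),
    )
    return LisaResult(table=table, alpha=alpha, n_perm=n_perm,
                      labels=(getattr(x, "name", "x"), getattr(y, "name", "y")))


def per_group_moran(x, w: SpatialWeights, groups, n_perm=999, seed=0):
    """Global Moran's I within each group of tracts (e.g. per state).

    Weights are subset to within-group edges.  Groups with fewer than 3
    connected tracts, or a constant surface, are skipped with a reason
    rather than aborting the whole decomposition.
    """
    gs = pd.Series(groups).reindex(w.ids)
    results, skipped = {}, {}
    for g in sorted(gs.dropna().unique()):
        ids = list(gs.index[gs == g])
        sub = w.subset(ids)
        connected = [t for t in sub.ids if t not in set(sub.isolates)]
        if len(connected) < 3:
            skipped[g] = f"only {len(connected)} connected tracts"
            continue
        sub2 = sub.subset(connected)
        try:
            results[g] = global_moran(pd.Series(x).reindex(sub2.ids), sub2,
                                      n_perm=n_perm, seed=seed)
        except ValueError as e:
            skipped[g] = str(e)
    return results, skipped
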