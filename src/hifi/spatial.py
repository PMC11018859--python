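"""Spatial-organization analytics on annotated cell tables.

Inputs are tidy cell tables with columns ``image_id``, ``group``, ``x_um``,
``y_um``, ``cell_type`` (plus optional ``in__<region>`` membership flags).
Provided analytics:

* composition — counts/percents per image, region, and cell type;
* nn_distances — per-image mean nearest-neighbor distance for every ordered
  cell-type pair, compiled into group mean/SD matrices;
* build_network — proximity networks with edge width 100/SD, an edge-width
  threshold of median(SD) x 0.8, node sizes binned from 3 (<=1% of cells) to
  70 (>=25%), and Louvain node clusters at resolution 1.5;
* shannon_index — per-image H' = -sum p ln p and its group mean;
* neighborhoods — per-cell 30 µm composition vectors;
* cluster_neighborhoods — pooled k-means into k=15 cellular neighborhoods;
* test_interactions — classical permutation test (1000 label shuffles) for
  pairwise attraction/avoidance on the 30 µm connectivity graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

__all__ = [
    "composition",
    "nn_distances",
    "build_network",
    "shannon_index",
    "neighborhoods",
    "cluster_neighborhoods",
    "test_interactions",
    "ProximityNetwork",
]

_REQUIRED = ("image_id", "x_um", "y_um", "cell_type")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")


# ---------------------------------------------------------------------------
# composition and diversity


def composition(table: pd.DataFrame, region_cols: list[str] | None = None) -> pd.DataFrame:
    """Cell-type counts and percents per image, overall and per region.

    ``region_cols`` are boolean membership columns (``in__<region>``); the
    overall tally appears under region ``"all"``. Percents within each
    (image, region) sum to 100.
    """
    _check_table(table)
    if table.empty:
        raise ValueError("empty cell table")
    blocks = [("all", table)]
    for col in region_cols or []:
        name = col.removeprefix("in__")
        blocks.append((name, table[table[col]]))
    out = []
    for region, sub in blocks:
        if sub.empty:
            continue
        counts = (
            sub.groupby(["image_id", "cell_type"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        totals = counts.groupby("image_id")["count"].transform("sum")
        counts["percent"] = 100.0 * counts["count"] / totals
        counts.insert(1, "region", region)
        out.append(counts)
    return pd.concat(out, ignore_index=True)


def shannon_index(comp: pd.DataFrame, groups: pd.Series | dict | None = None) -> pd.DataFrame:
    """Shannon diversity H' = -sum p ln p per image (natural log, p > 0 terms),
    with the group mean µH' when a group mapping is given.

    ``comp`` is a composition table (region ``"all"`` rows are used if a
    region column is present).
    """
    df = comp
    if "region" in df.columns:
        df = df[df["region"] == "all"]
    if df.empty:
        raise ValueError("empty composition")
    rows = []
    for image_id, sub in df.groupby("image_id"):
        p = sub["count"].to_numpy(float)
        p = p / p.sum()
        p = p[p > 0]
        rows.append({"image_id": image_id, "shannon": float(-(p * np.log(p)).sum())})
    out = pd.DataFrame(rows)
    if groups is not None:
        out["group"] = out["image_id"].map(groups)
    return out


def mean_shannon(table: pd.DataFrame) -> pd.DataFrame:
    """µH' per treatment group straight from a cell table with a group column."""
    _check_table(table)
    comp = composition(table)
    groups = table.drop_duplicates("image_id").set_index("image_id")["group"]
    per_image = shannon_index(comp, groups)
    return per_image.groupby("group")["shannon"].mean().rename("mu_shannon").reset_index()


# ---------------------------------------------------------------------------
# nearest-neighbor distances


def nn_distances(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Directed mean nearest-neighbor distances, per image and per group.

    For every ordered pair (A, B) and image: the mean over A cells of the
    Euclidean distance to the nearest B cell (A == B uses the nearest
    *other* cell of the same type). Pairs with either type absent in an
    image are missing, not zero. Columns: group, image_id, type_a, type_b,
    mean_dist; group-level mean/SD are computed across per-image means by
    :func:`summarize_distances`.
    """
    _check_table(table)
    rows = []
    for image_id, sub in table.groupby("image_id"):
        group = sub[group_col].iloc[0] if group_col in sub.columns else "all"
        pts = {
            t: g[["y_um", "x_um"]].to_numpy(float)
            for t, g in sub.groupby("cell_type", observed=True)
        }
        trees = {t: cKDTree(p) for t, p in pts.items()}
        for ta, pa in pts.items():
            for tb, tree in trees.items():
                if ta == tb:
                    if len(pa) < 2:
                        continue
                    d, _ = tree.query(pa, k=2)
                    mean_d = float(d[:, 1].mean())
                else:
                    d, _ = tree.query(pa, k=1)
                    mean_d = float(d.mean())
                rows.append(
                    {
                        "group": group,
                        "image_id": image_id,
                        "type_a": ta,
                        "type_b": tb,
                        "mean_dist": mean_d,
                    }
                )
    return pd.DataFrame(rows)


def summarize_distances(per_image: pd.DataFrame) -> pd.DataFrame:
    """Compile per-image means into group mean and SD distance matrices."""
    return (
        per_image.groupby(["group", "type_a", "type_b"], observed=True)["mean_dist"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, n_images="size")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# proximity network


@dataclass
class ProximityNetwork:
    graph: nx.Graph
    width_threshold: float
    clusters: dict[str, int] = field(default_factory=dict)
    mu_shannon: float = float("nan")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"type_a": a, "type_b": b, **attrs} for a, b, attrs in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def node_size(percent: float, size_range=(3, 70), pct_range=(1.0, 25.0), n_bins: int = 8) -> int:
    """Map a percent-total population onto a binned node size.

    <= ``pct_range[0]`` percent -> smallest size; >= ``pct_range[1]`` ->
    largest; linear bins in between, monotone, ``n_bins`` steps.
    """
    lo, hi = size_range
    p0, p1 = pct_range
    if percent <= p0:
        return int(lo)
    if percent >= p1:
        return int(hi)
    edges = np.linspace(p0, p1, n_bins + 1)
    sizes = np.round(np.linspace(lo, hi, n_bins + 1)).astype(int)
    idx = int(np.searchsorted(edges, percent, side="right") - 1)
    return int(sizes[min(idx + 1, n_bins)])


def build_network(
    ds: pd.DataFrame,
    comp: pd.DataFrame,
    group: str | None = None,
    width_const: float = 100.0,
    cofactor: float = 0.8,
    size_range: tuple[int, int] = (3, 70),
    pct_range: tuple[float, float] = (1.0, 25.0),
    louvain_resolution: float = 1.5,
    seed: int = 0,
) -> ProximityNetwork:
    """Build the proximity network for one group.

    ``ds`` is the output of :func:`summarize_distances` (directed pairs);
    edges are symmetrized (mean of the two directed means, pooled SD), edge
    width = ``width_const`` / SD, and edges whose width falls below
    median(SD) x ``cofactor`` are removed. Node sizes are binned percents
    (:func:`node_size`); node clusters come from Louvain at
    ``louvain_resolution`` with a fixed seed. The result is invariant to the
    order of input rows.
    """
    if group is not None:
        ds = ds[ds["group"] == group]
        if "group" in comp.columns:
            comp = comp[comp["group"] == group]
    if "region" in comp.columns:
        comp = comp[comp["region"] == "all"]
    pct = (
        comp.groupby("cell_type", observed=True)["count"].sum()
        / comp["count"].sum()
        * 100.0
    ).sort_index()
    types = sorted(pct.index)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")

    sym: dict[tuple[str, str], tuple[float, float]] = {}
    ds_idx = ds.set_index(["type_a", "type_b"]).sort_index()
    for i, a in enumerate(types):
        for b in types[i:]:
            keys = [(a, b)] if a == b else [(a, b), (b, a)]
            means, variances = [], []
            for key in keys:
                if key in ds_idx.index:
                    row = ds_idx.loc[key]
                    means.append(float(row["mean"]))
                    variances.append(float(row["sd"]) ** 2)
            if not means:
                continue
            sym[(a, b)] = (float(np.mean(means)), float(np.sqrt(np.mean(variances))))

    sds = np.array([sd for _, sd in sym.values()])
    threshold = float(np.median(sds)) * cofactor

    G = nx.Graph()
    for t in types:
        G.add_node(
            t,
            percent_total=float(pct[t]),
            node_size=node_size(float(pct[t]), size_range, pct_range),
        )
    for (a, b), (mean_d, sd) in sorted(sym.items()):
        width = width_const / sd if sd > 0 else float("inf")
        if width < threshold:
            continue
        G.add_edge(a, b, mean_dist=mean_d, sd=sd, width=width)

    communities = nx.community.louvain_communities(
        G, weight="width", resolution=louvain_resolution, seed=seed
    )
    clusters = {}
    for ci, comm in enumerate(sorted(map(sorted, communities))):
        for node in comm:
            clusters[node] = ci
    nx.set_node_attributes(G, clusters, "cluster")
    return ProximityNetwork(graph=G, width_threshold=threshold, clusters=clusters)


def layout_network(net: ProximityNetwork, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded force-directed layout with target edge lengths proportional to
    mean nearest-neighbor distances. Cosmetic."""
    dists = nx.get_edge_attributes(net.graph, "mean_dist")
    scale = max(dists.values()) if dists else 1.0
    G = net.graph.copy()
    for e, d in dists.items():
        G.edges[e]["layout_weight"] = 1.0 - 0.9 * d / scale
    return nx.spring_layout(G, weight="layout_weight", seed=seed)


# ---------------------------------------------------------------------------
# cellular neighborhoods


def neighborhoods(
    table: pd.DataFrame, radius_um: float = 30.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per-cell composition of cell types within ``radius_um`` (self excluded).

    Returns (profiles, type order): ``profiles`` has one row per cell with
    ``image_id``, the row index of the cell in ``table``, ``n_neighbors``,
    ``isolated``, and one fraction column per cell type (fractions sum to 1
    for cells with >= 1 neighbor, 0 rows for isolated cells).
    """
    _check_table(table)
    types = sorted(table["cell_type"].unique())
    t_index = {t: i for i, t in enumerate(types)}
    frames = []
    for image_id, sub in table.groupby("image_id"):
        xy = sub[["y_um", "x_um"]].to_numpy(float)
        codes = sub["cell_type"].map(t_index).to_numpy()
        tree = cKDTree(xy)
        counts = np.zeros((len(sub), len(types)))
        pairs = tree.query_pairs(radius_um, output_type="ndarray")
        if len(pairs):
            np.add.at(counts, (pairs[:, 0], codes[pairs[:, 1]]), 1)
            np.add.at(counts, (pairs[:, 1], codes[pairs[:, 0]]), 1)
        totals = counts.sum(axis=1)
        frac = np.divide(counts, totals[:, None], out=np.zeros_like(counts), where=totals[:, None] > 0)
        df = pd.DataFrame(frac, columns=types)
        df.insert(0, "image_id", image_id)
        df.insert(1, "cell_index", sub.index.to_numpy())
        df["n_neighbors"] = totals.astype(int)
        df["isolated"] = totals == 0
        frames.append(df)
    return pd.concat(frames, ignore_index=True), types


def cluster_neighborhoods(
    profiles: pd.DataFrame,
    types: list[str],
    k: int = 15,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Pool composition profiles across images and k-means them into k CNs.

    Returns (cn ids 1..k per profile row, per-CN mean composition matrix,
    per-image CN percent-total table).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = profiles[types].to_numpy(float)
    # isolated cells carry no composition signal: centers are fitted on
    # cells with neighbors (every center then sums to 1), isolated cells
    # are assigned to the nearest center afterwards
    active = ~profiles["isolated"].to_numpy() if "isolated" in profiles else np.ones(len(X), bool)
    if active.sum() < k:
        raise ValueError(f"fewer profiles ({int(active.sum())}) than clusters ({k})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(X[active])
    cn = km.predict(X) + 1
    mean_comp = pd.DataFrame(km.cluster_centers_, columns=types)
    mean_comp.insert(0, "cn", np.arange(1, k + 1))
    per_image = (
        pd.DataFrame({"image_id": profiles["image_id"], "cn": cn})
        .groupby(["image_id", "cn"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = per_image.groupby("image_id")["count"].transform("sum")
    per_image["percent"] = 100.0 * per_image["count"] / totals
    return cn, mean_comp, per_image


# ---------------------------------------------------------------------------
# permutation interaction test


def _interaction_stats(A_nbrs: np.ndarray, codes: np.ndarray, n_types: int) -> np.ndarray:
    """Mean count of type-b neighbors per type-a cell; (n_types, n_types)."""
    onehot = np.zeros((len(codes), n_types))
    onehot[np.arange(len(codes)), codes] = 1.0
    nbr_counts = A_nbrs @ onehot  # cells x types
    sums = onehot.T @ nbr_counts  # types x types
    n_per = onehot.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / n_per[:, None]


def test_interactions(
    table: pd.DataFrame,
    radius_um: float = 30.0,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Classical permutation test for pairwise cell-type interactions.

    For each image and ordered type pair (A, B) the statistic is the mean
    number of B neighbors per A cell on the fixed ``radius_um`` connectivity
    graph. The null shuffles cell-type labels within the image (type counts
    preserved), ``n_perm`` times. p_gt = (1 + #{perm >= obs}) / (n_perm + 1)
    tests attraction, p_lt avoidance; sigval is +1 / -1 / 0 at level
    ``alpha``. Per-image RNG streams derive from ``seed`` so results are
    reproducible under any execution order. Pairs whose type is absent from
    an image are skipped.
    """
    _check_table(table)
    master = np.random.SeedSequence(seed)
    rows = []
    image_ids = list(dict.fromkeys(table["image_id"]))
    seeds = master.spawn(len(image_ids))
    for image_id, ss in zip(image_ids, seeds):
        sub = table[table["image_id"] == image_id]
        group = sub[group_col].iloc[0] if group_col in sub.columns else "all"
        types = sorted(sub["cell_type"].unique())
        if len(types) < 2:
            continue
        t_index = {t: i for i, t in enumerate(types)}
        codes = sub["cell_type"].map(t_index).to_numpy()
        xy = sub[["y_um", "x_um"]].to_numpy(float)
        n = len(sub)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(radius_um, output_type="ndarray")
        A = np.zeros((n, n))
        if len(pairs):
            A[pairs[:, 0], pairs[:, 1]] = 1.0
            A[pairs[:, 1], pairs[:, 0]] = 1.0
        T = len(types)
        obs = _interaction_stats(A, codes, T)
        rng = np.random.default_rng(ss)
        ge = np.zeros((T, T))
        le = np.zeros((T, T))
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            stat = _interaction_stats(A, perm, T)
            ge += stat >= obs
            le += stat <= obs
        p_gt = (1.0 + ge) / (n_perm + 1.0)
        p_lt = (1.0 + le) / (n_perm + 1.0)
        for a in types:
            for b in types:
                i, j = t_index[a], t_index[b]
                sig = 0
                if p_gt[i, j] <= alpha:
                    sig = 1
                elif p_lt[i, j] <= alpha:
                    sig = -1
                rows.append(
                    {
                        "group": group,
                        "image_id": image_id,
                        "type_a": a,
                        "type_b": b,
                        "observed": obs[i, j],
                        "p_gt": p_gt[i, j],
                        "p_lt": p_lt[i, j],
                        "sigval": sig,
                        "p_sum": p_gt[i, j] + p_lt[i, j],
                    }
                )
    return pd.DataFrame(rows)


def sum_sigval(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate interaction significance per group and type pair.

    ``sum_sigval`` is the signed sum of per-image significance indicators
    (attraction positive, avoidance negative); the companion ``sum_p`` is
    the sum of the two one-tailed p values, averaged over images. Both are
    exported because the field uses both conventions.
    """
    return (
        results.groupby(["group", "type_a", "type_b"], observed=True)
        .agg(sum_sigval=("sigval", "sum"), sum_p=("p_sum", "mean"), n_images=("sigval", "size"))
        .reset_index()
    )
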