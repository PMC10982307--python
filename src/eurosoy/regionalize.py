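"""Site summary statistics and spatially constrained Ward clustering.

Each site is summarised by 15 statistics — the mean rainfed yield and the
crop success rate for each of the seven maturity groups, plus the mean
planting day of year (shared across groups).  Sites are clustered with
bottom-up agglomerative Ward clustering on Euclidean distance after
min-max normalization of each variable, with merges allowed only between
sites connected in a great-circle distance-band graph (75 km by default),
so every cluster is spatially contiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import AgglomerativeClustering

from .phenology import MATURITY_GROUPS
from .synthetic import haversine_km

__all__ = [
    "ClusteringConfig",
    "summarize_site",
    "summarize_sites",
    "build_spatial_weights",
    "cluster_sites",
    "cluster_summary_table",
    "load_table1_fixture",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class ClusteringConfig:
    distance_band_km: float = 75.0
    n_clusters: int = 16
    normalization: str = "minmax"

    def __post_init__(self):
        if self.distance_band_km <= 0:
            raise ValueError("distance_band_km must be > 0")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.normalization != "minmax":
            raise ValueError("only min-max normalization is supported")


def summarize_site(results: pd.DataFrame, mgs: tuple = MATURITY_GROUPS) -> pd.Series:
    """The per-site summary used for clustering, from that site's
    long-format factorial results.

    Rainfed yield per maturity group averages all years and the three
    initial-moisture members, with failures contributing 0; success is the
    proportion of non-failed years; the planting day is the mean over
    years with a planting (NaN when the site never plants).  Potential
    yield means are carried as auxiliary columns (not clustering inputs).
    """
    present = set(results["maturity_group"].unique())
    if not set(mgs) <= present:
        raise ValueError(f"results missing maturity groups: {sorted(set(mgs) - present)}")
    rainfed = results[results["config"].str.startswith("rainfed")]
    potential = results[results["config"] == "potential"]
    out = {}
    for mg in mgs:
        rf = rainfed[rainfed["maturity_group"] == mg]
        out[f"yield_{mg}"] = rf["yield_t_ha"].mean()
        per_year = rf.groupby("year")["failed"].all()
        out[f"success_{mg}"] = 1.0 - per_year.mean()
        pot = potential[potential["maturity_group"] == mg]
        out[f"potential_{mg}"] = pot["yield_t_ha"].mean()
    planted = results.dropna(subset=["planting_doy"])
    out["planting_doy"] = (
        planted.groupby("year")["planting_doy"].first().mean()
        if len(planted) else np.nan
    )
    return pd.Series(out)


def summarize_sites(results: pd.DataFrame, mgs: tuple = MATURITY_GROUPS) -> pd.DataFrame:
    """Apply :func:`summarize_site` per site; index = site_id."""
    out = results.groupby("site_id", sort=True).apply(
        lambda df: summarize_site(df, mgs), include_groups=False
    )
    out.index.name = "site_id"
    return out


def clustering_feature_columns(mgs: tuple = MATURITY_GROUPS) -> list:
    """Names of the 15 clustering statistics."""
    return ([f"yield_{mg}" for mg in mgs]
            + [f"success_{mg}" for mg in mgs]
            + ["planting_doy"])


def build_spatial_weights(sites: pd.DataFrame,
                          cfg: ClusteringConfig | None = None) -> sparse.csr_matrix:
    """Symmetric binary adjacency: an edge iff the great-circle distance is
    within the band; self-edges excluded."""
    cfg = cfg or ClusteringConfig()
    n = len(sites)
    if n < 2:
        raise ValueError("need at least two sites")
    lat = sites["lat"].to_numpy()
    lon = sites["lon"].to_numpy()
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    adj = (d <= cfg.distance_band_km) & ~np.eye(n, dtype=bool)
    return sparse.csr_matrix(adj)


def _minmax(X: np.ndarray, col_names) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    keep = span > 0
    if not np.all(keep):
        dropped = [c for c, k in zip(col_names, keep) if not k]
        warnings.warn(f"dropping constant clustering variables: {dropped}")
    return (X[:, keep] - lo[keep]) / span[keep]


def cluster_sites(
    summaries: pd.DataFrame,
    weights: sparse.csr_matrix,
    cfg: ClusteringConfig | None = None,
) -> np.ndarray:
    """Connectivity-constrained Ward clustering of the site summaries.

    Variables are min-max normalized first (constant variables dropped
    with a warning).  Merging respects the adjacency graph: clusters are
    allocated to connected components proportionally to component size
    (each component at least one), and Ward runs within each component,
    so every resulting cluster is spatially connected.  If the graph has
    more components than requested clusters, each component becomes its
    own cluster and a warning is emitted.
    """
    cfg = cfg or ClusteringConfig()
    n = len(summaries)
    if n < cfg.n_clusters:
        raise ValueError("need at least n_clusters sites")
    cols = [c for c in clustering_feature_columns() if c in summaries.columns]
    X = summaries[cols].to_numpy(float)
    X = np.nan_to_num(X, nan=0.0)  # never-planted sites: absent-coded as 0
    Xn = _minmax(X, cols)

    n_comp, comp = connected_components(weights, directed=False)
    labels = np.empty(n, dtype=int)
    if n_comp > cfg.n_clusters:
        warnings.warn(
            f"{n_comp} spatial components exceed n_clusters={cfg.n_clusters}; "
            "each component becomes its own cluster"
        )
        return comp.astype(int)

    sizes = np.bincount(comp, minlength=n_comp)
    alloc = np.maximum(1, np.floor(cfg.n_clusters * sizes / n).astype(int))
    alloc = np.minimum(alloc, sizes)
    # largest-remainder style top-up to hit exactly n_clusters
    while alloc.sum() < cfg.n_clusters:
        room = sizes - alloc
        i = int(np.argmax(np.where(room > 0, sizes / np.maximum(alloc, 1), -1)))
        alloc[i] += 1
    while alloc.sum() > cfg.n_clusters:
        i = int(np.argmax(np.where(alloc > 1, alloc, -1)))
        alloc[i] -= 1

    offset = 0
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        k = int(alloc[c])
        if k == 1 or len(idx) == 1:
            labels[idx] = offset
            offset += 1
            continue
        sub = weights[idx][:, idx]
        model = AgglomerativeClustering(
            n_clusters=k, linkage="ward", connectivity=sub
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sub-graph is connected by construction
            sub_labels = model.fit_predict(Xn[idx])
        labels[idx] = offset + sub_labels
        offset += k
    return labels


def _best_mg(cluster_summaries: pd.DataFrame, prefix: str,
             mgs: tuple = MATURITY_GROUPS) -> str:
    """Maturity group with the largest median yield; ties broken toward the
    earlier (shorter-season, lower-risk) group; 'na' if everything is 0."""
    medians = {mg: cluster_summaries[f"{prefix}_{mg}"].median() for mg in mgs}
    best = max(mgs, key=lambda mg: (medians[mg], -mgs.index(mg)))
    return "na" if medians[best] <= 0 else best


def cluster_summary_table(
    labels: np.ndarray,
    summaries: pd.DataFrame,
    land_use: pd.DataFrame | None = None,
    mgs: tuple = MATURITY_GROUPS,
) -> pd.DataFrame:
    """Cluster-level summary table (per-cluster yields, success, best MG).

    For each cluster the best maturity group is identified by the largest
    median per-site mean yield; the table reports that group's pooled
    mean +/- sd over sites, and the median success rate (as a percentage).
    ``land_use``, if given, must carry per-site arable_ha (and optionally
    wheat_frac) aligned with the summaries index, and is aggregated per
    cluster.
    """
    if len(labels) != len(summaries):
        raise ValueError("labels and summaries must be aligned")
    rows = []
    for j, lab in enumerate(np.unique(labels)):
        sub = summaries.iloc[np.flatnonzero(labels == lab)]
        assert len(sub) > 0
        letter = CLUSTER_LABELS[j] if j < len(CLUSTER_LABELS) else str(j)
        mg_rf = _best_mg(sub, "yield", mgs)
        mg_pot = _best_mg(sub, "potential", mgs)
        row = {
            "cluster": letter,
            "n_sites": len(sub),
            "mg_rainfed": mg_rf,
            "mg_potential": mg_pot,
        }
        rf_col = f"yield_{mg_rf}" if mg_rf != "na" else f"yield_{mgs[0]}"
        pot_col = f"potential_{mg_pot}" if mg_pot != "na" else f"potential_{mgs[0]}"
        row["yield_rainfed_mean"] = sub[rf_col].mean()
        row["yield_rainfed_sd"] = sub[rf_col].std(ddof=0)
        row["yield_potential_mean"] = sub[pot_col].mean()
        row["yield_potential_sd"] = sub[pot_col].std(ddof=0)
        succ_col = f"success_{mg_rf}" if mg_rf != "na" else f"success_{mgs[0]}"
        row["success_pct"] = 100.0 * sub[succ_col].median()
        if land_use is not None:
            lu = land_use.loc[sub.index]
            row["arable_ha"] = lu["arable_ha"].sum()
            if "wheat_frac" in lu:
                row["wheat_frac"] = np.average(lu["wheat_frac"],
                                               weights=lu["arable_ha"])
        rows.append(row)
    return pd.DataFrame(rows)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged cluster table (areas, wheat fractions, yields, success)
    transcribed from the published regional summary."""
    with resources.files("eurosoy.data").joinpath("table1_clusters.csv").open() as fh:
        return pd.read_csv(fh)
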