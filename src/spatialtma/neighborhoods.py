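"""Cellular-neighborhood analysis from per-cell k-nearest-neighbor profiles.

For every cell we count the phenotypes of its k nearest neighbors (Euclidean
distance on the X/Y coordinates, within its own core only, self excluded) over
phenotype x compartment categories (``E_<phenotype>`` / ``S_<phenotype>``).
Profiles pooled over the whole cohort are clustered by k-means into n
"cellular neighborhoods"; downstream metrics are the neighborhood composition
(per-category enrichment z-scores), centroid cosine similarity, per-core and
per-patient coverage fractions, coverage ratios, and a phenotype
co-localization matrix. A grid diagnostic over (k, n) helps pick values where
no two neighborhoods are redundant and one fewer cluster would merge two
distinct ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans, MiniBatchKMeans
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

DEFAULT_K = 15          # neighbors per cell
DEFAULT_K_GRID = (5, 10, 15, 20)
DEFAULT_N_GRID = (5, 6, 7, 8, 9, 10)
SIMILARITY_THRESHOLD = 0.95

_COMPARTMENT_PREFIX = {"epithelium": "E", "stroma": "S"}

_META_COLS = ["cell_id", "core_id", "patient_id", "phenotype", "compartment"]


def categories_for(cells: pd.DataFrame, by_compartment: bool = True) -> list[str]:
    """Sorted feature categories for a cohort (phenotype x compartment)."""
    if by_compartment:
        pref = cells["compartment"].map(_COMPARTMENT_PREFIX)
        if pref.isna().any():
            bad = cells.loc[pref.isna(), "compartment"].iloc[0]
            raise ValueError(f"unknown compartment {bad!r}")
        cats = pref + "_" + cells["phenotype"].astype(str)
    else:
        cats = cells["phenotype"].astype(str)
    return sorted(cats.unique())


def _cell_categories(cells: pd.DataFrame, by_compartment: bool) -> pd.Series:
    if by_compartment:
        return (cells["compartment"].map(_COMPARTMENT_PREFIX) + "_"
                + cells["phenotype"].astype(str))
    return cells["phenotype"].astype(str)


def _knn_exact_row(xy: np.ndarray, id_rank: np.ndarray, i: int, k: int
                   ) -> np.ndarray:
    """One cell's k nearest neighbors by the exact (distance, id-rank) rule."""
    d_full = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
    order = np.lexsort((id_rank, d_full))
    order = order[order != i]
    return order[:k]


def _knn_sets(xy: np.ndarray, id_rank: np.ndarray, k: int) -> np.ndarray:
    """Indices (N x k) of each point's k nearest neighbors, self excluded.

    Ties at the k-th distance are broken by (distance, cell-id rank); rows
    with a boundary tie (or coincident points crowding out the self hit) are
    re-resolved against the full distance vector.
    """
    n = len(xy)
    n_query = min(n, k + 2)
    nn = NearestNeighbors(n_neighbors=n_query).fit(xy)
    dist, idx = nn.kneighbors(xy)
    rows = np.arange(n)

    keep = idx != rows[:, None]                 # drop the self hit
    clean = keep.sum(axis=1) == n_query - 1     # exactly one self hit
    out = np.empty((n, k), dtype=np.intp)
    if clean.any():
        sub = np.flatnonzero(clean)
        nb = idx[sub][keep[sub]].reshape(len(sub), n_query - 1)
        d = dist[sub][keep[sub]].reshape(len(sub), n_query - 1)
        out[sub] = nb[:, :k]
        if n_query - 1 > k:
            # ambiguous membership when the first excluded candidate ties
            # the last included one
            tied = sub[d[:, k] == d[:, k - 1]]
        else:
            tied = np.empty(0, dtype=np.intp)
    else:
        tied = np.empty(0, dtype=np.intp)
    exact_rows = np.union1d(np.flatnonzero(~clean), tied)
    for i in exact_rows:
        out[i] = _knn_exact_row(xy, id_rank, i, k)
    return out


@dataclass
class ProfileSet:
    """Per-cell neighbor-phenotype count profiles at a single k."""

    profiles: pd.DataFrame        # _META_COLS + one count column per category
    k: int
    categories: list[str]
    excluded_cores: list[str] = field(default_factory=list)

    @property
    def counts(self) -> np.ndarray:
        return self.profiles[self.categories].to_numpy(dtype=float)


def neighbor_profiles(cells: pd.DataFrame, k: int = DEFAULT_K,
                      categories: list[str] | None = None,
                      by_compartment: bool = True) -> ProfileSet:
    """Count the phenotypes of each cell's k nearest neighbors, per core.

    Neighbor search never crosses cores. Cores with fewer than k+1 cells are
    excluded entirely (a deflated neighbor count would bias clustering) and
    logged. Requires finite coordinates and unique cell ids within a core.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    required = {"cell_id", "core_id", "patient_id", "x_um", "y_um",
                "compartment", "phenotype"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    if not np.isfinite(cells[["x_um", "y_um"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite coordinates in cell table")
    if categories is None:
        categories = categories_for(cells, by_compartment)
    cells = cells.reset_index(drop=True)
    cat_codes = pd.Categorical(_cell_categories(cells, by_compartment),
                               categories=categories)
    if cat_codes.isna().any():
        raise ValueError("cell category outside the provided category list")

    rows, excluded = [], []
    codes_all = np.asarray(cat_codes.codes)
    for core_id, grp in cells.groupby("core_id", sort=True):
        if grp["cell_id"].duplicated().any():
            raise ValueError(f"duplicate cell_id within core {core_id!r}")
        if len(grp) < k + 1:
            excluded.append(core_id)
            continue
        xy = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        id_rank = np.argsort(np.argsort(grp["cell_id"].to_numpy()))
        nb_idx = _knn_sets(xy, id_rank, k)
        codes = codes_all[grp.index.to_numpy()]
        counts = np.zeros((len(grp), len(categories)), dtype=np.int64)
        np.add.at(counts, (np.repeat(np.arange(len(grp)), k).ravel(),
                           codes[nb_idx].ravel()), 1)
        block = grp[["cell_id", "core_id", "patient_id", "phenotype",
                     "compartment"]].reset_index(drop=True)
        rows.append(pd.concat(
            [block, pd.DataFrame(counts, columns=categories)], axis=1))
    if excluded:
        log.warning("excluded %d core(s) with < k+1 = %d cells: %s",
                    len(excluded), k + 1, excluded)
    profiles = (pd.concat(rows, ignore_index=True) if rows
                else pd.DataFrame(columns=_META_COLS + list(categories)))
    return ProfileSet(profiles, k=k, categories=list(categories),
                      excluded_cores=excluded)


def colocalization_matrix(pset: ProfileSet) -> pd.DataFrame:
    """Percent co-localization of each focal category with neighbor categories.

    For each focal phenotype x compartment category, neighbor counts are
    summed over all of its cells across all cores and the row is normalized
    to percent (rows sum to exactly 100). Categories with no profiled cells
    are absent (missing rows, not zeros).
    """
    if not len(pset.profiles):
        raise ValueError("no profiled cells")
    prof = pset.profiles
    focal = (prof["compartment"].map(_COMPARTMENT_PREFIX) + "_"
             + prof["phenotype"].astype(str))
    if not focal.isin(pset.categories).all():
        focal = prof["phenotype"].astype(str)   # phenotype-only mode
    sums = prof.groupby(focal.rename("focal"))[pset.categories].sum()
    totals = sums.sum(axis=1)
    sums = sums.loc[totals > 0]
    out = sums.div(sums.sum(axis=1), axis=0) * 100.0
    return out


@dataclass
class NeighborhoodModel:
    """Fitted cohort-level neighborhood clustering."""

    k: int
    n: int
    centroids: pd.DataFrame               # n x categories
    labels: pd.Series                     # neighborhood id, indexed by cell_id
    inertia: float
    seed: int
    names: dict[int, str] = field(default_factory=dict)
    degenerate: bool = False

    def name_of(self, i: int) -> str:
        return self.names.get(i, f"N{i}")


def cluster_neighborhoods(pset: ProfileSet, n: int, seed: int = 0,
                          n_init: int = 10, mini_batch: bool = False
                          ) -> NeighborhoodModel:
    """K-means on raw neighbor-count vectors pooled across the cohort.

    One model per cohort (labels comparable across patients). Best of
    ``n_init`` k-means++ restarts; deterministic given ``seed``. ``n < 2`` is
    permitted but flagged degenerate.
    """
    X = pset.counts
    if n > len(X):
        raise ValueError(f"n={n} exceeds number of profiles ({len(X)})")
    if n < 1:
        raise ValueError("n must be >= 1")
    cls = MiniBatchKMeans if mini_batch else KMeans
    km = cls(n_clusters=n, n_init=n_init, random_state=seed).fit(X)
    labels = pd.Series(km.labels_, index=pset.profiles["cell_id"],
                       name="neighborhood")
    centroids = pd.DataFrame(km.cluster_centers_, columns=pset.categories)
    model = NeighborhoodModel(k=pset.k, n=n, centroids=centroids,
                              labels=labels, inertia=float(km.inertia_),
                              seed=seed, degenerate=n < 2)
    if model.degenerate:
        log.warning("n=%d neighborhood model is degenerate", n)
    return model


@dataclass
class CompositionResult:
    """Neighborhood composition: mean neighbor counts and enrichment z-scores."""

    mean_counts: pd.DataFrame             # neighborhood x category
    zscores: pd.DataFrame | None          # None when n == 1 (degenerate)
    degenerate: bool = False


def neighborhood_composition(model: NeighborhoodModel, pset: ProfileSet
                             ) -> CompositionResult:
    """Mean neighbor count per category within each neighborhood, z-scored
    per category across neighborhoods. Empty neighborhoods yield missing rows."""
    prof = pset.profiles.set_index("cell_id")
    lab = model.labels.reindex(prof.index)
    means = prof[pset.categories].groupby(lab).mean()
    empty = sorted(set(range(model.n)) - set(means.index))
    if empty:
        log.warning("empty neighborhood(s) %s have no composition row", empty)
    if len(means) < 2:
        return CompositionResult(means, None, degenerate=True)
    std = means.std(axis=0, ddof=0)
    z = (means - means.mean(axis=0)).div(std.where(std > 0, 1.0), axis=1)
    return CompositionResult(means, z)


def neighborhood_similarity(model: NeighborhoodModel,
                            threshold: float = SIMILARITY_THRESHOLD):
    """Pairwise cosine similarity of centroids; pairs >= threshold flagged.

    Zero centroids have missing (NaN) similarities and are never flagged.
    """
    C = model.centroids.to_numpy(dtype=float)
    norms = np.linalg.norm(C, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (C @ C.T) / np.outer(norms, norms)
    sim[(norms == 0)[:, None] | (norms == 0)[None, :]] = np.nan
    sim_df = pd.DataFrame(sim, index=range(model.n), columns=range(model.n))
    flagged = [(i, j) for i in range(model.n) for j in range(i + 1, model.n)
               if np.isfinite(sim[i, j]) and sim[i, j] >= threshold]
    return sim_df, flagged


def _best_match_collision(model_n: NeighborhoodModel,
                          model_m: NeighborhoodModel) -> bool:
    """True if two of model_n's centroids share the same most-similar
    centroid in model_m (i.e. reducing n merged two distinct neighborhoods)."""
    A = model_n.centroids.to_numpy(float)
    B = model_m.centroids.to_numpy(float)
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (A @ B.T) / (na * nb.T)
    best = np.nanargmax(np.nan_to_num(sim, nan=-np.inf), axis=1)
    return len(np.unique(best)) < len(best)


def select_k_n(cells: pd.DataFrame | None = None,
               profiles_by_k: dict[int, ProfileSet] | None = None,
               k_grid=DEFAULT_K_GRID, n_grid=DEFAULT_N_GRID,
               seed: int = 0, threshold: float = SIMILARITY_THRESHOLD,
               n_init: int = 10, mini_batch: bool = False):
    """Grid diagnostic over (k, n) with an advisory recommendation.

    A candidate (k, n) qualifies when its model has no highly similar
    centroid pair and refitting at (k, n-1) merges two previously distinct
    neighborhoods (two centroids sharing one best match). Among candidates
    the largest n (then smallest k) is recommended — i.e. grow n until just
    before clusters start splitting into near-duplicates. The choice remains
    a config value; the recommendation is advisory.

    Returns ``(diagnostics DataFrame, recommendation (k, n) or None)``.
    """
    if profiles_by_k is None:
        if cells is None:
            raise ValueError("provide cells or profiles_by_k")
        profiles_by_k = {k: neighbor_profiles(cells, k=k) for k in k_grid}
    if not profiles_by_k or not len(n_grid):
        raise ValueError("empty k/n grid")
    rows = []
    candidates = []
    for k in sorted(profiles_by_k):
        pset = profiles_by_k[k]
        models = {}
        need = sorted(set(n_grid) | {n - 1 for n in n_grid if n - 1 >= 2})
        for n in need:
            if n <= len(pset.profiles):
                models[n] = cluster_neighborhoods(
                    pset, n, seed=seed, n_init=n_init, mini_batch=mini_batch)
        for n in sorted(n_grid):
            if n not in models:
                continue
            sim, flagged = neighborhood_similarity(models[n], threshold)
            finite = sim.to_numpy()[np.triu_indices(n, 1)] if n > 1 else np.array([])
            merged = (n - 1 in models
                      and _best_match_collision(models[n], models[n - 1]))
            rows.append({"k": k, "n": n, "inertia": models[n].inertia,
                         "n_flagged_pairs": len(flagged),
                         "max_similarity": (np.nanmax(finite) if finite.size
                                            else np.nan),
                         "merge_at_n_minus_1": merged})
            if not flagged and merged:
                candidates.append((k, n))
    diagnostics = pd.DataFrame(rows)
    recommendation = None
    if candidates:
        recommendation = sorted(candidates, key=lambda kn: (-kn[1], kn[0]))[0]
    else:
        log.warning("no (k, n) combination qualified; diagnostics only")
    diagnostics["recommended"] = [
        (r["k"], r["n"]) == recommendation for _, r in diagnostics.iterrows()]
    return diagnostics, recommendation


@dataclass
class CoverageTable:
    """Fraction of profiled cells per neighborhood, per core and per patient."""

    core: pd.DataFrame        # index core_id, one column per neighborhood id
    patient: pd.DataFrame     # index patient_id, mean over the patient's cores


def coverage(model: NeighborhoodModel, pset: ProfileSet,
             patients: pd.DataFrame | None = None) -> CoverageTable:
    """Per-core neighborhood fractions and their per-patient means.

    Patient values average over that patient's non-excluded cores (duplicate
    cores). Patients whose cores were all excluded are missing and logged.
    """
    prof = pset.profiles
    lab = model.labels.reindex(prof["cell_id"]).to_numpy()
    df = pd.DataFrame({"core_id": prof["core_id"].to_numpy(),
                       "patient_id": prof["patient_id"].to_numpy(),
                       "neighborhood": lab})
    core = (df.groupby("core_id")["neighborhood"]
              .value_counts(normalize=True).unstack(fill_value=0.0)
              .reindex(columns=range(model.n), fill_value=0.0))
    core.columns = [int(c) for c in core.columns]
    core_to_patient = df.drop_duplicates("core_id").set_index("core_id")["patient_id"]
    patient = core.groupby(core_to_patient).mean()
    patient.index.name = "patient_id"
    if patients is not None:
        missing = set(patients["patient_id"]) - set(patient.index)
        if missing:
            log.warning("%d patient(s) have no non-excluded cores: %s",
                        len(missing), sorted(missing))
    return CoverageTable(core=core, patient=patient)


def coverage_ratio(cov: CoverageTable, numerator: int, denominator: int
                   ) -> pd.Series:
    """Per-patient coverage ratio; zero denominators yield missing values."""
    for nid in (numerator, denominator):
        if nid not in cov.patient.columns:
            raise KeyError(f"unknown neighborhood id {nid}")
    num = cov.patient[numerator]
    den = cov.patient[denominator]
    ratio = num / den.where(den > 0)
    n_missing = int(ratio.isna().sum())
    if n_missing:
        log.warning("coverage ratio %s/%s missing for %d patient(s) "
                    "(zero denominator)", numerator, denominator, n_missing)
    return ratio.rename(f"ratio_{numerator}_{denominator}")


def annotate_neighborhoods(composition: CompositionResult,
                           immune_threshold: float = 0.2,
                           overrides: dict[int, str] | None = None
                           ) -> dict[int, str]:
    """Rule-based human-readable neighborhood names.

    A neighborhood whose immune fraction (non-PanCK, non-Other neighbor
    counts) is below ``immune_threshold`` is "cold epithelium" or
    "cold stroma" by dominant compartment; one whose top enriched category is
    a CD16a class is "CD16a enriched <compartment>"; the remaining ones are
    ranked by total immune enrichment into "immune-rich" (top) and
    "immune-moderate". Manual ``overrides`` always win; unresolvable
    neighborhoods keep the fallback name ``N<i>``.
    """
    overrides = overrides or {}
    means = composition.mean_counts
    basis = composition.zscores if composition.zscores is not None else means

    def _split(cat: str):
        if "_" in cat and cat.split("_", 1)[0] in ("E", "S"):
            comp, pheno = cat.split("_", 1)
            return comp, pheno
        return None, cat

    immune_cols = [c for c in means.columns
                   if _split(c)[1] not in ("PanCK", "Other")]
    e_cols = [c for c in means.columns if _split(c)[0] == "E"]
    s_cols = [c for c in means.columns if _split(c)[0] == "S"]

    names: dict[int, str] = {}
    pending = []
    for i in means.index:
        i = int(i)
        if i in overrides:
            names[i] = overrides[i]
            continue
        row = means.loc[i]
        total = row.sum()
        if total <= 0:
            names[i] = f"N{i}"
            continue
        dominant = ("epithelium" if (not e_cols and not s_cols)
                    or row[e_cols].sum() >= row[s_cols].sum() else "stroma")
        immune_frac = row[immune_cols].sum() / total if immune_cols else 0.0
        top_cat = basis.loc[i].idxmax()
        if immune_frac < immune_threshold:
            names[i] = f"cold {dominant}"
        elif "CD16a" in _split(top_cat)[1]:
            names[i] = f"CD16a enriched {dominant}"
        else:
            pending.append((i, float(basis.loc[i, immune_cols].sum())
                            if immune_cols else 0.0))
    if pending:
        pending.sort(key=lambda t: -t[1])
        names[pending[0][0]] = "immune-rich"
        for i, _ in pending[1:]:
            names[i] = "immune-moderate"
    # disambiguate duplicates deterministically
    seen: dict[str, int] = {}
    for i in sorted(names):
        base = names[i]
        if base in seen:
            seen[base] += 1
            names[i] = f"{base} ({seen[base]})"
        else:
            seen[base] = 1
    return names


def plot_cores(cells: pd.DataFrame, model: NeighborhoodModel, core_ids,
               path):
    """Reconstructed-core scatter plots colored by neighborhood (best-effort)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    core_ids = list(core_ids)
    fig, axes = plt.subplots(1, len(core_ids),
                             figsize=(4 * len(core_ids), 4), squeeze=False)
    lab = model.labels
    cmap = plt.get_cmap("tab10")
    for ax, core_id in zip(axes[0], core_ids):
        grp = cells[cells["core_id"] == core_id]
        ids = grp["cell_id"]
        colors = [cmap(int(lab.get(c, -1)) % 10) if c in lab.index else "grey"
                  for c in ids]
        ax.scatter(grp["x_um"], grp["y_um"], s=4, c=colors)
        ax.set_title(str(core_id))
        ax.set_aspect("equal")
        ax.invert_yaxis()       # image convention: y increases downward
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
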