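"""Cell phenotyping: marker normalization, expression clustering, gating.

Two routes produce the same per-cell phenotype labels:

1. *Gating route* — binary positivity calls (``pos_<marker>`` columns) are
   passed through an ordered, first-match-wins gating hierarchy.
2. *Clustering route* — continuous marker signals (``marker_<marker>``
   columns) are log-normalized, clustered by k-means (cluster count chosen at
   the knee of the inertia/elbow curve), each cluster's mean signal is
   thresholded to a binary vector, and that vector is gated through the same
   hierarchy; member cells inherit the cluster's phenotype.

The panel-1 hierarchy encodes epithelial dominance (panCK+ cells are
epithelial regardless of other markers), then myeloid (CD68), T (CD3),
NK (CD94) and single-positive CD16a classes, with CD16a splitting the
myeloid/T/NK classes and CD94 recorded as a modifier attribute on
myeloid/T cells; all-negative cells are "Other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class GatingRule:
    """One first-match-wins rule: all ``require`` markers positive."""

    label: str
    require: tuple[str, ...] = ()
    split_on: tuple[str, ...] = ()   # positive -> label suffix "_<marker>"
    record: tuple[str, ...] = ()     # positive -> boolean modifier column


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    markers: tuple[str, ...]
    hierarchy: tuple[GatingRule, ...]

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        if "panCK" not in self.markers:
            raise ValueError("panel must contain panCK (epithelial gate)")
        if not self.hierarchy or self.hierarchy[-1].require:
            raise ValueError("hierarchy must end with a catch-all rule")
        for rule in self.hierarchy:
            for m in rule.require + rule.split_on + rule.record:
                if m not in self.markers:
                    raise ValueError(f"rule {rule.label!r} uses unknown marker {m!r}")

    @property
    def labels(self) -> list[str]:
        """All phenotype labels the hierarchy can emit, in hierarchy order."""
        return list(dict.fromkeys(_canonical_split_labels(self)))


def _canonical_split_labels(panel: "MarkerPanel") -> list[str]:
    out = []
    for rule in panel.hierarchy:
        combos = [[]]
        for m in rule.split_on:
            combos = [c + [on] for c in combos for on in (False, True)]
        for c in combos:
            lab = rule.label + "".join(
                f"_{m}" for m, on in zip(rule.split_on, c) if on)
            out.append(lab)
    return out


PANEL1 = MarkerPanel(
    name="panel1",
    markers=("panCK", "CD68", "CD3", "CD94", "CD16a"),
    hierarchy=(
        GatingRule("PanCK", require=("panCK",)),
        GatingRule("CD68", require=("CD68",), split_on=("CD16a",), record=("CD94",)),
        GatingRule("CD3", require=("CD3",), split_on=("CD16a",), record=("CD94",)),
        GatingRule("CD94", require=("CD94",), split_on=("CD16a",)),
        GatingRule("CD16a", require=("CD16a",)),
        GatingRule("Other"),
    ),
)

# Panel 2 adds CD8 (T-cell modifier) and CD163 (myeloid modifier); the rule
# order for lineage markers matches panel 1, with CD163 and CD8 single
# positives gated after NK/CD16a classes (order is config-driven).
PANEL2 = MarkerPanel(
    name="panel2",
    markers=("panCK", "CD68", "CD3", "CD94", "CD16a", "CD8", "CD163"),
    hierarchy=(
        GatingRule("PanCK", require=("panCK",)),
        GatingRule("CD68", require=("CD68",), split_on=("CD163", "CD16a"),
                   record=("CD94",)),
        GatingRule("CD3", require=("CD3",), split_on=("CD8", "CD16a"),
                   record=("CD94",)),
        GatingRule("CD94", require=("CD94",), split_on=("CD16a",)),
        GatingRule("CD163", require=("CD163",), split_on=("CD16a",)),
        GatingRule("CD16a", require=("CD16a",)),
        GatingRule("CD8", require=("CD8",)),
        GatingRule("Other"),
    ),
)

PANELS = {"panel1": PANEL1, "panel2": PANEL2}


def log_normalize(signals: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``log(1 + x)``; rejects negative input naming the cell."""
    arr = signals.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = signals.index[np.isnan(arr).any(axis=1)][0]
        raise ValueError(f"missing marker signal for cell {bad!r}")
    if (arr < 0).any():
        bad = signals.index[(arr < 0).any(axis=1)][0]
        raise ValueError(f"negative marker signal for cell {bad!r}")
    return pd.DataFrame(np.log1p(arr), index=signals.index,
                        columns=signals.columns)


def assign_phenotypes(calls: pd.DataFrame, panel: MarkerPanel = PANEL1
                      ) -> pd.DataFrame:
    """Gate binary marker calls through the panel hierarchy.

    ``calls`` needs one ``pos_<marker>`` (or bare ``<marker>``) column in
    {0, 1} per panel marker. Returns a frame indexed like ``calls`` with a
    ``phenotype`` column and one boolean ``mod_<marker>`` column per recorded
    modifier. First match wins; the hierarchy is a total function.
    """
    cols = {}
    for m in panel.markers:
        for cand in (f"pos_{m}", m):
            if cand in calls.columns:
                cols[m] = calls[cand]
                break
        else:
            raise ValueError(f"missing positivity call for marker {m!r}")
    mat = pd.DataFrame(cols)
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)][0]
        raise ValueError(f"missing positivity call for cell {bad!r}")
    arr = mat.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("positivity calls must be 0/1")
    pos = {m: arr[:, i].astype(bool) for i, m in enumerate(panel.markers)}

    n = len(mat)
    labels = np.empty(n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    recorded = sorted({m for r in panel.hierarchy for m in r.record})
    mods = {m: np.zeros(n, dtype=bool) for m in recorded}
    for rule in panel.hierarchy:
        match = unassigned.copy()
        for m in rule.require:
            match &= pos[m]
        if not match.any():
            continue
        lab = np.full(match.sum(), rule.label, dtype=object)
        for m in rule.split_on:
            on = pos[m][match]
            lab = np.where(on, lab + f"_{m}", lab)
        labels[match] = lab
        for m in rule.record:
            mods[m][match] = pos[m][match]
        unassigned &= ~match
    assert not unassigned.any()   # guaranteed by the catch-all rule

    out = pd.DataFrame({"phenotype": labels}, index=calls.index)
    for m in recorded:
        out[f"mod_{m}"] = mods[m]
    return out


@dataclass
class ExpressionClusterModel:
    """Fitted k-means expression clustering with elbow diagnostics."""

    n_clusters: int
    cluster_means: pd.DataFrame          # clusters x markers (normalized scale)
    labels: np.ndarray                   # per-cell cluster id
    elbow_curve: dict[int, float]        # candidate count -> inertia
    seed: int


def _knee(counts: np.ndarray, inertias: np.ndarray) -> int:
    """Knee of the dispersion curve: max distance to the chord, both axes
    normalized to [0, 1]. Degenerate (flat) curves return the smallest count."""
    if len(counts) == 1:
        return int(counts[0])
    x = (counts - counts[0]) / max(counts[-1] - counts[0], 1)
    span = inertias[0] - inertias[-1]
    if span <= 0:
        return int(counts[0])
    y = (inertias - inertias[-1]) / span
    # distance from (x, y) to the chord from (0, 1) to (1, 0): |x + y - 1|/√2
    d = np.abs(x + y - 1.0)
    return int(counts[int(np.argmax(d))])


def cluster_expression(normalized: pd.DataFrame,
                       candidate_counts=tuple(range(1, 16)),
                       seed: int = 0, n_init: int = 10) -> ExpressionClusterModel:
    """K-means over candidate cluster counts; elbow picks the count.

    Runs on the unscaled normalized signals. Deterministic given ``seed``;
    best of ``n_init`` k-means++ restarts per count.
    """
    X = normalized.to_numpy(dtype=float)
    counts = np.array(sorted(set(int(c) for c in candidate_counts)))
    if len(X) < 2:
        raise ValueError("need at least 2 cells to cluster")
    if counts.min() < 1:
        raise ValueError("candidate cluster counts must be >= 1")
    if counts.max() > len(X):
        raise ValueError("more clusters than cells")
    fits, inertias = {}, []
    for c in counts:
        km = KMeans(n_clusters=int(c), n_init=n_init, random_state=seed).fit(X)
        fits[int(c)] = km
        inertias.append(km.inertia_)
    chosen = _knee(counts, np.asarray(inertias))
    km = fits[chosen]
    means = pd.DataFrame(km.cluster_centers_, columns=normalized.columns)
    return ExpressionClusterModel(
        n_clusters=chosen, cluster_means=means, labels=km.labels_.copy(),
        elbow_curve={int(c): float(i) for c, i in zip(counts, inertias)},
        seed=seed)


def otsu_thresholds(normalized: pd.DataFrame) -> dict[str, float]:
    """Default per-marker positivity thresholds (Otsu on normalized signal).

    When the two intensity components are separated by an empty gap, every
    cut inside the gap ties on the Otsu objective and the histogram argmax
    lands at the gap's lower edge; the threshold is therefore re-centred
    between the nearest samples on either side.
    """
    out = {}
    for c in normalized.columns:
        x = normalized[c].to_numpy(dtype=float)
        t = float(threshold_otsu(x))
        below, above = x[x <= t], x[x > t]
        if len(below) and len(above):
            t = (below.max() + above.min()) / 2.0
        out[c] = t
    return out


def cluster_to_phenotype(model: ExpressionClusterModel,
                         panel: MarkerPanel,
                         thresholds: dict[str, float]) -> dict[int, str]:
    """Map each expression cluster to a phenotype.

    Each cluster's mean normalized signal is thresholded to a binary marker
    vector and gated through the panel hierarchy.
    """
    calls = {}
    for m in panel.markers:
        col = f"marker_{m}" if f"marker_{m}" in model.cluster_means else m
        if col not in model.cluster_means:
            raise ValueError(f"cluster means lack marker {m!r}")
        if m not in thresholds:
            raise ValueError(f"missing positivity threshold for marker {m!r}")
        calls[m] = (model.cluster_means[col] > thresholds[m]).astype(int)
    gated = assign_phenotypes(pd.DataFrame(calls), panel)
    return dict(zip(model.cluster_means.index.astype(int), gated["phenotype"]))


def phenotype_by_clustering(signals: pd.DataFrame, panel: MarkerPanel = PANEL1,
                            candidate_counts=tuple(range(1, 16)),
                            thresholds: dict[str, float] | None = None,
                            seed: int = 0):
    """Full clustering route: normalize -> cluster -> threshold -> gate.

    ``signals`` holds raw ``marker_<name>`` columns. Returns
    ``(labels Series, ExpressionClusterModel, cluster->phenotype map)``.
    """
    cols = {m: f"marker_{m}" for m in panel.markers}
    missing = [c for c in cols.values() if c not in signals.columns]
    if missing:
        raise ValueError(f"missing marker signal columns: {missing}")
    norm = log_normalize(signals[list(cols.values())])
    model = cluster_expression(norm, candidate_counts, seed=seed)
    if thresholds is None:
        raw = otsu_thresholds(norm)
        thresholds = {m: raw[cols[m]] for m in panel.markers}
    norm_means = model.cluster_means.rename(
        columns={v: k for k, v in cols.items()})
    model.cluster_means = norm_means
    mapping = cluster_to_phenotype(model, panel, thresholds)
    labels = pd.Series([mapping[c] for c in model.labels],
                       index=signals.index, name="phenotype")
    return labels, model, mapping
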