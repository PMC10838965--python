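"""Synthetic tissue-microarray (TMA) cohort generator.

Emulates the structure of a digital-pathology cell-segmentation export for a
multi-patient ovarian-cancer TMA: each patient contributes duplicate circular
tissue cores; each core contains epithelial "tumor nests" embedded in stroma;
cells are placed as homogeneous Poisson processes per compartment with
compartment-specific phenotype mixtures; spatially aggregated "hotspots"
(e.g. CD16a+ aggregates at nest boundaries) plant ground-truth cellular
neighborhoods; and patient survival times follow an exponential
proportional-hazards model whose linear predictor can include the planted
neighborhood coverage.

All randomness flows from a single master seed through named substreams, so
cohorts are bit-reproducible and insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.ops import unary_union

PANEL1_MARKERS = ("panCK", "CD68", "CD3", "CD94", "CD16a")

#: canonical binary marker calls implied by each true phenotype (panel 1).
#: CD94 on myeloid/T cells is a modifier drawn separately (see _draw_calls).
_PHENOTYPE_CALLS = {
    "PanCK": {"panCK": 1},
    "CD68": {"CD68": 1},
    "CD68_CD16a": {"CD68": 1, "CD16a": 1},
    "CD3": {"CD3": 1},
    "CD3_CD16a": {"CD3": 1, "CD16a": 1},
    "CD94": {"CD94": 1},
    "CD94_CD16a": {"CD94": 1, "CD16a": 1},
    "CD16a": {"CD16a": 1},
    "Other": {},
}

#: phenotypes on which CD94 may additionally appear as a recorded modifier.
_CD94_MODIFIER_CLASSES = {"CD68", "CD68_CD16a", "CD3", "CD3_CD16a"}

DEFAULT_MIXTURE = {
    "epithelium": {
        "PanCK": 0.88, "CD16a": 0.04, "CD68": 0.03, "CD68_CD16a": 0.02,
        "CD3": 0.015, "CD3_CD16a": 0.005, "CD94": 0.003, "CD94_CD16a": 0.002,
        "Other": 0.005,
    },
    "stroma": {
        "Other": 0.45, "CD16a": 0.15, "CD68": 0.10, "CD68_CD16a": 0.07,
        "CD3": 0.09, "CD3_CD16a": 0.03, "CD94": 0.02, "CD94_CD16a": 0.01,
        "PanCK": 0.08,
    },
}

DEFAULT_HOTSPOT_COMPOSITION = {
    "CD16a": 0.50, "CD68_CD16a": 0.20, "CD94_CD16a": 0.15, "CD3_CD16a": 0.15,
}


@dataclass
class HotspotSpec:
    """A planted cellular aggregate (ground-truth neighborhood seed).

    ``anchor`` is one of ``"nest-boundary"``, ``"stroma"``, ``"epithelium"``,
    or a fixed ``(x, y)`` position in mm relative to the core centre.
    """

    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOT_COMPOSITION))
    anchor: object = "nest-boundary"
    radius: float = 0.05          # mm
    cell_count: int = 150


@dataclass
class CovariateSpec:
    """Clinical covariate distributions (per patient)."""

    age_mean: float = 60.0
    age_sd: float = 10.0
    p_high_stage: float = 0.75
    p_grade3: float = 0.85
    p_debulked: float = 0.60
    p_chemo_sensitive: float = 0.70


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards survival model.

    Hazard for a patient is ``baseline * exp(X @ beta)``; ``coefficients``
    maps patient-frame column names (e.g. ``age``, ``stage``,
    ``planted_coverage_high``) to log-hazard coefficients. Censoring is
    uniform on ``censoring_window`` (months).
    """

    baseline_hazard_os: float = 0.015     # events / month
    baseline_hazard_pfs: float = 0.030
    coefficients: dict[str, float] = field(default_factory=dict)
    censoring_window: tuple[float, float] = (0.0, 120.0)


@dataclass
class SimulationConfig:
    n_patients: int = 40
    cores_per_patient: int = 2
    core_radius: float = 0.3                       # mm
    n_nests: int = 3
    nest_radius_range: tuple[float, float] = (0.05, 0.12)   # mm
    cell_intensity_epithelium: float = 2500.0      # cells / mm^2
    cell_intensity_stroma: float = 1500.0
    phenotype_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {r: dict(m) for r, m in DEFAULT_MIXTURE.items()})
    hotspots: list[HotspotSpec] = field(
        default_factory=lambda: [HotspotSpec()])
    patient_hotspot_scale: tuple[float, float] = (1.0, 1.0)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.cores_per_patient < 1:
            raise ValueError("cores_per_patient must be >= 1")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be positive")
        if self.n_nests < 0:
            raise ValueError("n_nests must be >= 0")
        lo, hi = self.nest_radius_range
        if self.n_nests > 0:
            if lo <= 0 or hi < lo:
                raise ValueError("nest_radius_range must be a positive interval")
            if hi >= self.core_radius:
                raise ValueError("nest radii must be smaller than the core radius")
        if self.cell_intensity_epithelium < 0 or self.cell_intensity_stroma < 0:
            raise ValueError("cell intensities must be nonnegative")
        if self.cell_intensity_epithelium + self.cell_intensity_stroma <= 0 \
                and not self.hotspots:
            raise ValueError("zero total cell intensity and no hotspots")
        for region, mix in self.phenotype_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"phenotype mixture for {region!r} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"negative mixture probability in {region!r}")
        for h in self.hotspots:
            total = sum(h.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"hotspot composition sums to {total}, not 1")
            if h.radius <= 0:
                raise ValueError("hotspot radius must be positive")
            if h.cell_count < 0:
                raise ValueError("hotspot cell_count must be >= 0")
            if h.anchor in ("nest-boundary", "epithelium") and self.n_nests == 0:
                raise ValueError(
                    f"hotspot anchored at {h.anchor!r} requires n_nests >= 1")


@dataclass
class CohortData:
    """Simulated cohort: cell table, core areas, clinical table, ground truth."""

    cells: pd.DataFrame
    cores: pd.DataFrame
    patients: pd.DataFrame
    truth_cells: pd.DataFrame
    truth_patients: pd.DataFrame


def _rng(seed: int, *stream) -> np.random.Generator:
    """Named substream of the master seed (stable under reordering)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *stream]))


def _uniform_disc(rng, n, radius, centre=(0.0, 0.0)):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([centre[0] + r * np.cos(theta),
                            centre[1] + r * np.sin(theta)])


def _in_nests(xy, nests):
    """Boolean mask: point inside any nest disc (exact circle test)."""
    inside = np.zeros(len(xy), dtype=bool)
    for (cx, cy), r in nests:
        inside |= (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2 <= r * r
    return inside


def _sample_compartment(rng, n_target, core_radius, nests, want_epithelium):
    """Rejection-sample uniform points in one compartment of the core disc."""
    if n_target == 0:
        return np.empty((0, 2))
    out = []
    got = 0
    while got < n_target:
        batch = max(256, 4 * (n_target - got))
        xy = _uniform_disc(rng, batch, core_radius)
        mask = _in_nests(xy, nests)
        keep = xy[mask] if want_epithelium else xy[~mask]
        out.append(keep)
        got += len(keep)
    return np.concatenate(out)[:n_target]


def _draw_calls(rng, phenotypes):
    """Binary marker-call columns consistent with each true phenotype."""
    n = len(phenotypes)
    calls = {m: np.zeros(n, dtype=int) for m in PANEL1_MARKERS}
    for i, ph in enumerate(phenotypes):
        for m, v in _PHENOTYPE_CALLS[ph].items():
            calls[m][i] = v
    # CD94 modifier on myeloid / T classes (recorded attribute, not a class)
    mod = np.isin(phenotypes, list(_CD94_MODIFIER_CLASSES))
    calls["CD94"] = calls["CD94"] | (mod & (rng.random(n) < 0.3)).astype(int)
    return calls


def marker_intensities(calls: pd.DataFrame, rng,
                       pos_mu: float = 2.5, neg_mu: float = 0.3,
                       sigma: float = 0.25) -> pd.DataFrame:
    """Two-component lognormal intensities from binary calls.

    Used to exercise the expression-clustering phenotyping route: positive
    cells draw from ``LogNormal(pos_mu, sigma)``, negative from
    ``LogNormal(neg_mu, sigma)`` (well-separated components by default).
    """
    out = {}
    for m in calls.columns:
        mu = np.where(calls[m].to_numpy() > 0, pos_mu, neg_mu)
        out[f"marker_{m.removeprefix('pos_')}"] = rng.lognormal(mu, sigma)
    return pd.DataFrame(out, index=calls.index)


def simulate_core(config: SimulationConfig, patient_id: str, core_index: int,
                  rng: np.random.Generator | None = None,
                  hotspot_scale: float = 1.0):
    """Simulate one TMA core.

    Returns ``(cells, core_row, truth)``: the per-cell table, a dict with the
    analytic per-compartment areas, and the per-cell ground truth (true
    phenotype and planted-hotspot id, −1 for background cells).
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed, 1, abs(hash(patient_id)) & 0xFFFF, core_index)
    R = config.core_radius
    core_id = f"{patient_id}_c{core_index}"

    # --- geometry: epithelial nests inside the core disc -------------------
    nests = []
    for _ in range(config.n_nests):
        r = rng.uniform(*config.nest_radius_range)
        centre = _uniform_disc(rng, 1, R - r)[0]
        nests.append(((centre[0], centre[1]), r))
    disc_area = math.pi * R * R
    if nests:
        union = unary_union([Point(c).buffer(r, quad_segs=256) for c, r in nests])
        area_epi = union.area
    else:
        area_epi = 0.0
    area_stroma = disc_area - area_epi   # exact complement by construction

    # --- background cells: homogeneous Poisson per compartment -------------
    xs, ys, comps, phenos, planted = [], [], [], [], []
    for region, intensity, area, want_epi in (
            ("epithelium", config.cell_intensity_epithelium, area_epi, True),
            ("stroma", config.cell_intensity_stroma, area_stroma, False)):
        if area <= 0 or intensity <= 0:
            continue
        n = rng.poisson(intensity * area)
        xy = _sample_compartment(rng, n, R, nests, want_epi)
        mix = config.phenotype_mixture.get(region, {"Other": 1.0})
        labels = rng.choice(list(mix.keys()), size=n, p=list(mix.values()))
        xs.append(xy[:, 0]); ys.append(xy[:, 1])
        comps.append(np.full(n, region, dtype=object))
        phenos.append(labels.astype(object))
        planted.append(np.full(n, -1))

    # --- planted hotspots ---------------------------------------------------
    for j, h in enumerate(config.hotspots):
        n = int(round(h.cell_count * hotspot_scale))
        if n == 0:
            continue
        if isinstance(h.anchor, (tuple, list)):
            anchor = np.asarray(h.anchor, dtype=float)
        elif h.anchor == "nest-boundary":
            (cx, cy), r = nests[rng.integers(len(nests))]
            theta = rng.random() * 2 * np.pi
            anchor = np.array([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        elif h.anchor == "stroma":
            anchor = _sample_compartment(rng, 1, R, nests, False)[0]
        elif h.anchor == "epithelium":
            anchor = _sample_compartment(rng, 1, R, nests, True)[0]
        else:
            raise ValueError(f"unknown hotspot anchor {h.anchor!r}")
        # uniform in the hotspot disc, clipped to the core
        pts = []
        got = 0
        while got < n:
            cand = _uniform_disc(rng, max(64, 2 * (n - got)), h.radius, anchor)
            cand = cand[cand[:, 0] ** 2 + cand[:, 1] ** 2 <= R * R]
            pts.append(cand)
            got += len(cand)
        xy = np.concatenate(pts)[:n]
        labels = rng.choice(list(h.composition.keys()), size=n,
                            p=list(h.composition.values()))
        xs.append(xy[:, 0]); ys.append(xy[:, 1])
        # compartment is purely geometric, regardless of hotspot membership
        comps.append(np.where(_in_nests(xy, nests), "epithelium", "stroma").astype(object))
        phenos.append(labels.astype(object))
        planted.append(np.full(n, j))

    if xs:
        x = np.concatenate(xs); y = np.concatenate(ys)
        comp = np.concatenate(comps); pheno = np.concatenate(phenos)
        plant = np.concatenate(planted)
    else:
        x = y = np.empty(0)
        comp = pheno = np.empty(0, dtype=object)
        plant = np.empty(0, dtype=int)

    n_cells = len(x)
    cell_ids = [f"{core_id}-{i}" for i in range(n_cells)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "core_id": core_id,
        "patient_id": patient_id,
        "x_um": x * 1000.0,           # canonical coordinates in micrometres
        "y_um": y * 1000.0,
        "compartment": comp,
    })
    calls = _draw_calls(rng, pheno)
    for m in PANEL1_MARKERS:
        cells[f"pos_{m}"] = calls[m]

    core_row = {"core_id": core_id, "patient_id": patient_id,
                "area_epithelium_mm2": area_epi, "area_stroma_mm2": area_stroma}
    truth = pd.DataFrame({"cell_id": cell_ids, "core_id": core_id,
                          "patient_id": patient_id,
                          "true_phenotype": pheno, "planted_id": plant})
    return cells, core_row, truth


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Simulate the full cohort: cells, core areas, clinical table, truth."""
    config.validate()
    cov_rng = _rng(config.seed, 2)
    cov = config.covariates
    n = config.n_patients
    width = max(4, len(str(max(n, 1))))
    patient_ids = [f"P{i:0{width}d}" for i in range(n)]
    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "age": np.clip(cov_rng.normal(cov.age_mean, cov.age_sd, n), 30, 90).round(1),
        "stage": (cov_rng.random(n) < cov.p_high_stage).astype(int),
        "grade": np.where(cov_rng.random(n) < cov.p_grade3, 3, 2),
        "debulking": (cov_rng.random(n) < cov.p_debulked).astype(int),
        "chemo_sensitivity": (cov_rng.random(n) < cov.p_chemo_sensitive).astype(int),
    })
    lo, hi = config.patient_hotspot_scale
    scales = cov_rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo)

    all_cells, all_cores, all_truth = [], [], []
    cov_rows = []
    n_hot = len(config.hotspots)
    for i, pid in enumerate(patient_ids):
        per_core_frac = np.zeros((config.cores_per_patient, max(n_hot, 1)))
        for c in range(config.cores_per_patient):
            rng = _rng(config.seed, 1, i, c)
            cells, core_row, truth = simulate_core(
                config, pid, c, rng=rng, hotspot_scale=scales[i])
            all_cells.append(cells); all_cores.append(core_row)
            all_truth.append(truth)
            if len(truth) and n_hot:
                counts = np.bincount(truth["planted_id"].to_numpy() + 1,
                                     minlength=n_hot + 1)[1:]
                per_core_frac[c, :n_hot] = counts / len(truth)
        row = {"patient_id": pid}
        for j in range(n_hot):
            row[f"planted_coverage_{j}"] = per_core_frac[:, j].mean()
        row["planted_coverage_total"] = per_core_frac.sum(axis=1).mean()
        cov_rows.append(row)

    cells = (pd.concat(all_cells, ignore_index=True) if all_cells
             else pd.DataFrame(columns=["cell_id", "core_id", "patient_id",
                                        "x_um", "y_um", "compartment"]))
    cores = pd.DataFrame(all_cores, columns=["core_id", "patient_id",
                                             "area_epithelium_mm2",
                                             "area_stroma_mm2"])
    truth_cells = (pd.concat(all_truth, ignore_index=True) if all_truth
                   else pd.DataFrame(columns=["cell_id", "core_id", "patient_id",
                                              "true_phenotype", "planted_id"]))
    truth_patients = pd.DataFrame(cov_rows, columns=(
        ["patient_id"] + [f"planted_coverage_{j}" for j in range(n_hot)]
        + ["planted_coverage_total"]))
    if n == 0:
        truth_patients = pd.DataFrame(
            columns=["patient_id", "planted_coverage_total"])

    patients, truth_patients = simulate_survival(
        patients, truth_patients, config.survival, _rng(config.seed, 3))
    return CohortData(cells, cores, patients, truth_cells, truth_patients)


def simulate_survival(patients: pd.DataFrame, truth_patients: pd.DataFrame,
                      spec: SurvivalSpec, rng: np.random.Generator):
    """Attach OS/PFS times and events drawn from ``h0 * exp(X beta)``.

    Returns updated ``(patients, truth_patients)``; the linear predictor is
    recorded in the ground truth. A zero-width censoring window is flagged
    degenerate (``censoring_degenerate`` attr on the returned frame).
    """
    if spec.baseline_hazard_os <= 0 or spec.baseline_hazard_pfs <= 0:
        raise ValueError("baseline hazards must be positive")
    frame = patients.merge(truth_patients, on="patient_id", how="left") \
        if len(truth_patients) else patients.copy()
    frame["grade3"] = ((frame["grade"] == 3).astype(int)
                       if "grade" in frame else 0)
    if "planted_coverage_total" in frame:
        total = frame["planted_coverage_total"].fillna(0.0)
        frame["planted_coverage_high"] = (total > total.mean()).astype(int)

    n = len(frame)
    lp = np.zeros(n)
    for name, beta in spec.coefficients.items():
        if name not in frame:
            raise ValueError(f"survival coefficient refers to unknown covariate {name!r}")
        lp += beta * frame[name].to_numpy(dtype=float)

    patients = patients.copy()
    c0, c1 = spec.censoring_window
    degenerate = c1 <= c0
    for endpoint, h0 in (("os", spec.baseline_hazard_os),
                         ("pfs", spec.baseline_hazard_pfs)):
        rate = h0 * np.exp(lp)
        t = rng.exponential(1.0 / rate) if n else np.empty(0)
        cens = np.full(n, c0) if degenerate else rng.uniform(c0, c1, n)
        patients[f"{endpoint}_months"] = np.minimum(t, cens)
        patients[f"{endpoint}_event"] = (t <= cens).astype(int)
    patients.attrs["censoring_degenerate"] = bool(degenerate)

    truth_patients = truth_patients.copy()
    if len(truth_patients):
        truth_patients["linear_predictor"] = lp
    return patients, truth_patients
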