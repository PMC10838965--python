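"""Shared fixtures: small synthetic cohorts and constructed cell tables."""

import numpy as np
import pandas as pd
import pytest

import spatialtma as s


def make_cells(xy, phenotypes, compartment="stroma", core_id="c0",
               patient_id="p0"):
    """Minimal cell table from explicit coordinates and phenotype labels."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return pd.DataFrame({
        "cell_id": [f"{core_id}-{i}" for i in range(n)],
        "core_id": core_id,
        "patient_id": patient_id,
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "compartment": compartment if isinstance(compartment, str)
        else list(compartment),
        "phenotype": phenotypes if not isinstance(phenotypes, str)
        else [phenotypes] * n,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-patient cohort with the default nest/hotspot structure."""
    cfg = s.SimulationConfig(n_patients=6, seed=7)
    return s.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_labeled(small_cohort):
    """Same cohort with gated phenotypes attached."""
    cells = pd.concat(
        [small_cohort.cells, s.assign_phenotypes(small_cohort.cells)], axis=1)
    return small_cohort, cells


def archetype_config(seed=0, n_patients=10):
    """Cohort whose cells form 3 spatially separated composition archetypes.

    Three distant aggregates with 80/20 phenotype mixtures produce three
    well-separated neighbor-profile archetypes: between-centroid distance
    ~ k * 0.8 * sqrt(2) ~ 17 counts versus a multinomial within-spread of
    ~ sqrt(k * 0.8 * 0.2) ~ 1.5 counts per category (> 5x separation).
    """
    anchors = [(0.18 * np.cos(a), 0.18 * np.sin(a))
               for a in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)]
    comps = [{"CD16a": 0.8, "Other": 0.2}, {"CD3": 0.8, "Other": 0.2},
             {"CD68": 0.8, "Other": 0.2}]
    return s.SimulationConfig(
        n_patients=n_patients, cores_per_patient=2, n_nests=0,
        cell_intensity_epithelium=0.0, cell_intensity_stroma=0.0,
        phenotype_mixture={"stroma": {"Other": 1.0}},
        hotspots=[s.HotspotSpec(composition=c, anchor=a, radius=0.05,
                                cell_count=120)
                  for a, c in zip(anchors, comps)],
        seed=seed)
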