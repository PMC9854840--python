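"""Shared fixtures.

The expensive simulation studies (20-seed parameter recovery, the
permutation-ANOVA null calibration, the no-signal negative control) run
once per session and are shared by the module property tests and the
acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from morphherit import gpa, shape_pca, symmetric_component
from morphherit import simulate as sim
from morphherit.animal_model import AnimalModel
from morphherit.heritability import summarize
from morphherit.morphometry import procrustes_anova

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


def _parent_columns(ped, ids):
    dam, sire = [], []
    for i in ids:
        k = ped.index[i]
        dam.append(ped.ids[ped.dam_idx[k]] if ped.dam_idx[k] >= 0 else None)
        sire.append(ped.ids[ped.sire_idx[k]] if ped.sire_idx[k] >= 0 else None)
    return dam, sire


def run_recovery_seed(seed: int, truth=None) -> dict:
    """Full pipeline on one synthetic recovery-design dataset.

    Landmarks -> GPA with sliding -> object symmetry -> 3-PC scores ->
    animal-model REML; returns true and estimated trace proportions and
    h2_max.
    """
    if truth is None:
        truth = sim.recovery_truth(t=3)
    ped = sim.recovery_pedigree(seed=seed)
    configs, _ = sim.simulate_dataset(truth, ped, phenotype_parents=True, seed=seed)
    scheme = truth.scheme
    aligned = gpa(configs, scheme=scheme, slide=True)
    symm = symmetric_component(aligned, scheme)
    space = shape_pca(symm, n_retained=truth.n_traits)
    dam, sire = _parent_columns(ped, symm.specimen_ids)
    model = AnimalModel(
        traits=space.scores,
        individual_ids=symm.specimen_ids,
        pedigree=ped,
        covariate=np.log(symm.centroid_sizes),
        dam_ids=dam,
        sire_ids=sire,
    )
    res = model.fit()
    truth_summary = summarize(
        {"G": truth.G, "Mat": truth.Mat, "Pat": truth.Pat, "R": truth.R}
    )
    est_summary = res.heritability()
    return {
        "seed": seed,
        "true_props": truth.proportions(),
        "est_props": res.variance_proportions(),
        "h2_max_true": truth_summary.h2_max,
        "h2_max_est": est_summary.h2_max,
        "gp_eigenvalues": est_summary.GPm_eigen.eigenvalues,
        "converged": res.converged,
        "components": res.components,
    }


@pytest.fixture(scope="session")
def recovery_study():
    """Twenty full-pipeline parameter-recovery replicates (study design:
    t=3, 40 dams, 30 sires, 800 offspring)."""
    return [run_recovery_seed(seed) for seed in range(1, 21)]


@pytest.fixture(scope="session")
def null_anova_pvalues():
    """Permutation-ANOVA p-values under a true null.

    200 datasets (n=40, 5-variate standard normal response, two balanced
    groups independent of the response), 500 permutations each.
    """
    pvals = []
    labels = np.repeat(["a", "b"], 20)
    for seed in range(1, 201):
        rng = np.random.default_rng(seed)
        Y = rng.standard_normal((40, 5))
        res = procrustes_anova(Y, labels, n_perm=500, seed=seed)
        pvals.append(res.p_value)
    return np.array(pvals)


@pytest.fixture(scope="session")
def null_reml_study():
    """Negative control: no heritable signal, uninformative parent labels.

    Traits are pure residual noise (true G = Mat = Pat = 0) and the dam /
    sire columns passed to the model are shuffled; estimated G, Mat and
    Pat trace proportions should all be near zero.
    """
    t = 3
    total = 1e-3
    truth = sim.SimulationTruth(
        G=np.zeros((t, t)), Mat=np.zeros((t, t)), Pat=np.zeros((t, t)),
        R=total / t * np.eye(t), beta=np.zeros(t),
        cs_mean=float(np.log(25.0)), cs_sd=0.15, asym_noise_sd=0.0,
    )
    out = []
    for seed in range(1, 21):
        ped = sim.simulate_pedigree(20, 15, 60, sim.family_sizes(300, 60), seed=seed)
        _, df = sim.simulate_dataset(truth, ped, phenotype_parents=True, seed=seed)
        rng = np.random.default_rng(1000 + seed)
        dam = list(rng.permutation([d if d else None for d in df["dam"]]))
        sire = list(rng.permutation([s if s else None for s in df["sire"]]))
        model = AnimalModel(
            traits=df[[f"s{i + 1}" for i in range(t)]].to_numpy(),
            individual_ids=df["id"],
            pedigree=ped,
            covariate=df["log_cs"].to_numpy(),
            dam_ids=dam,
            sire_ids=sire,
        )
        res = model.fit()
        out.append(res.variance_proportions())
    return out
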