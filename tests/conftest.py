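import numpy as np
import pandas as pd
import pytest

import wagep
from wagep import synthetic as syn


@pytest.fixture(scope="session")
def small_scenario():
    """A small but non-trivial class-structured cohort (4 classes)."""
    return syn.scenario(
        "easy", seed=11, n_classes=4, n_genes=80, markers_per_class=8, samples_per_class=12
    )


@pytest.fixture(scope="session")
def small_cohort(small_scenario):
    return syn.simulate_reference(small_scenario)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    em, annot, _ = small_cohort
    return wagep.build_reference(em, annot)


@pytest.fixture(scope="session")
def small_weights(small_model):
    return wagep.weight_matrix(small_model)


@pytest.fixture()
def separable_cohort():
    """Three classes whose values sit in disjoint ranges for every gene."""
    rng = np.random.default_rng(42)
    n, G = 10, 5
    blocks = [rng.normal(mu, 0.5, size=(G, n)) for mu in (0.0, 10.0, 20.0)]
    values = np.concatenate(blocks, axis=1)
    genes = [f"g{i}" for i in range(G)]
    samples = [f"{c}_s{i}" for c in "ABC" for i in range(n)]
    classes = {s: s.split("_")[0] for s in samples}
    return wagep.ExpressionMatrix(values, genes, samples), wagep.SampleAnnotation(classes=classes)


def normal_density(x, mu=0.0, sd=1.0):
    """Analytic normal pdf — the independent oracle for KDE checks."""
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def quadrature_weight(mu_a, mu_b, sd=1.0, *, lo=None, hi=None, n=51200):
    """Independent fine-grid quadrature of the uniqueness weight of class A
    against class B for two analytic Gaussians: the area by which the A
    density exceeds the B density, over the region where it is higher."""
    if lo is None:
        lo = min(mu_a, mu_b) - 8 * sd
    if hi is None:
        hi = max(mu_a, mu_b) + 8 * sd
    x = np.linspace(lo, hi, n)
    fa, fb = normal_density(x, mu_a, sd), normal_density(x, mu_b, sd)
    diff = np.where(fa > fb, fa - fb, 0.0)
    return float(np.trapezoid(diff, x))


def make_density_pair(mu_a, mu_b, sd=1.0, n_grid=512):
    """Two analytic Gaussian curves placed on one shared model grid."""
    lo, hi = min(mu_a, mu_b) - 5 * sd, max(mu_a, mu_b) + 5 * sd
    grid = np.linspace(lo, hi, n_grid)

    def de(mu):
        d = normal_density(grid, mu, sd)
        d = d / np.trapezoid(d, grid)
        return wagep.DensityEstimate(grid=grid, density=d, n_samples=1000)

    return {"A": de(mu_a), "B": de(mu_b)}


def tm_frame(rows, classes=("A", "B", "C")):
    """Helper: genes × classes tm DataFrame from a list of row tuples."""
    return pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"g{i}" for i in range(len(rows))],
        columns=list(classes),
    )
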