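"""Shared fixtures: a small simulated breeding program and its matrices.

The demo program is deliberately tiny (33 lines, 144 plots) so the full
simulate -> QC -> relationship-matrix -> REML chain stays fast; heavier
scenario fixtures live in the tests that need them.
"""

import numpy as np
import pandas as pd
import pytest

import epinoia as ep

DEMO_VARIANCES = {"line": 0.05, "additive": 0.2, "epistatic": 0.2,
                  "gxe": 0.1, "spatial": 0.01, "error": 0.2}


def make_program(seed=42, shared_founders=True, **overrides):
    kwargs = dict(
        n_founders=10, n_crosses=6, lines_per_cross=8, n_markers=200,
        n_cycles=2, locations_per_year=2, blocks_per_trial=2,
        lines_per_block=8, n_checks_per_block=1, random_seed=seed,
        shared_founders=shared_founders)
    kwargs.update(overrides)
    cfg = ep.BreedingProgramConfig(**kwargs)
    arch = ep.GeneticArchitecture(n_additive_qtl=80, n_epistatic_pairs=60,
                                  target_variances=dict(DEMO_VARIANCES))
    return ep.simulate_breeding_program(cfg, arch)


def matrices_from(result):
    filtered, _ = ep.qc_filter(result.genotypes_observed)
    imputed = ep.impute_missing_mean(filtered)
    freqs = ep.genotype_frequencies(filtered)
    G = ep.build_G_noia(ep.noia_additive_coefficients(imputed, freqs))
    return G, ep.build_H_noia(G)


@pytest.fixture(scope="session")
def demo_program():
    return make_program()


@pytest.fixture(scope="session")
def demo_matrices(demo_program):
    return matrices_from(demo_program)


@pytest.fixture(scope="session")
def demo_fit(demo_program, demo_matrices):
    """Full-data I+GA+GAA fit on the demo program."""
    G, H = demo_matrices
    spec = ep.ModelSpec("I+GA+GAA")
    bundle = ep.assemble_model(demo_program.plots, spec, G=G, H=H)
    vc = ep.ai_reml_estimate(bundle)
    sol = ep.solve_mme(bundle, vc)
    return {"spec": spec, "bundle": bundle, "vc": vc, "solution": sol,
            "G": G, "H": H}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_panel(n=20, m=50, seed=0, missing=0.0):
    """Random genotype panel containing all three genotype classes."""
    r = np.random.default_rng(seed)
    p = r.uniform(0.1, 0.9, m)
    vals = (r.random((n, m)) < p).astype(float) + (r.random((n, m)) < p)
    df = pd.DataFrame(vals, index=[f"L{i:03d}" for i in range(n)],
                      columns=[f"M{j:03d}" for j in range(m)])
    if missing > 0:
        df = df.mask(r.random((n, m)) < missing)
    return df


@pytest.fixture()
def random_panel():
    return make_panel
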