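import numpy as np
import pandas as pd
import pytest

import cnvjoint as cj


@pytest.fixture
def tiny_table() -> cj.GenotypeTable:
    """3 markers x 4 samples, hand-written: one diploid SNP, one marker with
    a deletion carrier, one with a duplication carrier."""
    markers = pd.DataFrame(
        {
            "marker_id": ["rs1", "rs2", "rs3"],
            "chrom": ["7", "7", "20"],
            "pos": [65255030, 65255100, 1888504],
            "allele_a": ["A", "A", "A"],
            "allele_b": ["B", "B", "B"],
        }
    )
    samples = ["I1", "I2", "I3", "I4"]
    a = np.array([[1, 2, 0, 1], [1, 0, 1, 1], [2, 1, 1, 2]])
    b = np.array([[1, 0, 2, 1], [0, 1, 1, 1], [1, 1, 1, 2]])
    conf = np.full((3, 4), 0.02)
    missing = np.zeros((3, 4), dtype=bool)
    missing[1, 3] = True
    return cj.GenotypeTable(markers, samples, a, b, conf, missing)


@pytest.fixture(scope="session")
def causal_study() -> cj.SimStudy:
    """Small seeded study with one strong causal SNP, reused by pipeline,
    report and CLI tests."""
    cfg = cj.SimConfig(
        n_markers=400,
        family_size_histogram={1: 40, 2: 55, 3: 20},
        n_causal=1,
        beta1=0.12,
        seed=42,
    )
    return cj.simulate_study(cfg)


@pytest.fixture(scope="session")
def causal_scan(causal_study) -> cj.TwoStageScan:
    study = causal_study
    return cj.TwoStageScan(k=60, seed=42).fit(study.genotypes, study.roster, study.pheno)


def dense_reml_loglik(y, X, families, s2f, s2e) -> float:
    """Independent dense-matrix restricted log-likelihood oracle."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    fam = pd.factorize(np.asarray(families))[0]
    n, p = X.shape
    Z = np.zeros((n, fam.max() + 1))
    Z[np.arange(n), fam] = 1.0
    V = s2f * Z @ Z.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_a = np.linalg.slogdet(A)
    return float(
        -0.5 * ((n - p) * np.log(2 * np.pi) + ld_v + ld_a + r @ Vi @ r)
    )
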