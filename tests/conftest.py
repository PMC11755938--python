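import numpy as np
import pytest

import rviskit as rk


@pytest.fixture(scope="session")
def small_config():
    return rk.SimConfig(
        n_genes=60,
        n_chromosomes=4,
        seed=3,
        set_specs=(rk.SetSpec("ASD", 12, 0.7), rk.SetSpec("ID", 15, 0.6)),
        n_disease_matches=3,
        n_disease_decoys=10,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    """One generated input bundle shared across tests (noise-free)."""
    out = tmp_path_factory.mktemp("bundle")
    return rk.generate_catalog(small_config, out)


@pytest.fixture(scope="session")
def small_scores(small_bundle):
    """RVIS scores fitted on the small bundle."""
    from rviskit.synthetic import read_gene_models

    records = list(rk.read_catalog(small_bundle.vcf))
    retained, _ = rk.qc_filter(records)
    gm = read_gene_models(small_bundle.gene_models)
    counts = rk.count_gene_variants(retained, gm)
    table = rk.remove_outliers(rk.compute_rvis(counts))
    return table.scores()


def loo_studentized_oracle(x, y):
    """Externally studentized residuals by literally refitting OLS n times.

    For each point i: fit on the other n-1 points, predict y_i, and
    scale the prediction error by its standard error.  Independent of
    the implementation under test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        X = np.column_stack([np.ones(n - 1), x[keep]])
        beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        resid = y[keep] - X @ beta
        s2 = resid @ resid / (n - 1 - 2)
        if s2 < 1e-10 * np.mean(y**2):  # remaining points fit exactly
            xi_resid = y[i] - np.array([1.0, x[i]]) @ beta
            out[i] = 0.0 if xi_resid == 0 else np.copysign(np.inf, xi_resid)
            continue
        xi = np.array([1.0, x[i]])
        var_pred = s2 * (1.0 + xi @ np.linalg.inv(X.T @ X) @ xi)
        out[i] = (y[i] - xi @ beta) / np.sqrt(var_pred)
    return out


def ks_running_sum_oracle(hit_flags):
    """Enumerate the KS running sum step by step; return signed extremum."""
    nh = sum(hit_flags)
    nm = len(hit_flags) - nh
    best, running = 0.0, 0.0
    for h in hit_flags:
        running += 1.0 / nh if h else -1.0 / nm
        if abs(running) > abs(best):
            best = running
    return best


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by direct combinatorial enumeration."""
    from math import comb

    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total
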