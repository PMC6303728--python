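import numpy as np
import pytest

from seascapegen.ocean_fields import GridSpec, make_synthetic_field
from seascapegen.popgen import GenotypeMatrix
from seascapegen.synthetic_data import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_bundle():
    """Small coherent synthetic world shared across tests (10-day field)."""
    return make_fixture_suite(seed=42, n_days=10)


@pytest.fixture()
def solid_body():
    """Solid-body-rotation field (10-day period) on a fine grid, plus metadata."""
    omega = 2 * np.pi / (10 * 86400.0)
    grid = GridSpec(
        lon_nodes=np.arange(33.0, 37.02, 0.05),
        lat_nodes=np.arange(-32.0, -27.98, 0.05),
        time_nodes=np.array([0.0, 40 * 86400.0]),
    )
    fld = make_synthetic_field(
        "solid_body_rotation", {"omega": omega, "lon0": 35.0, "lat0": -30.0}, grid
    )
    return fld, omega, (35.0, -30.0)


def toy_two_pop_genotypes():
    """2 populations x 1 locus toy table used by the FST hand oracle."""
    # pop A: 4x 1/1, 3x 1/2, 3x 2/2 ; pop B: 1x 1/1, 2x 1/2, 7x 2/2
    a = [(1, 1)] * 4 + [(1, 2)] * 3 + [(2, 2)] * 3
    b = [(1, 1)] * 1 + [(1, 2)] * 2 + [(2, 2)] * 7
    calls = np.array(a + b, dtype=int)[:, None, :]
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(20)],
        loci=["L1"],
        calls=calls,
        population=["A"] * 10 + ["B"] * 10,
        group={"A": "g", "B": "g"},
    )


def wc_theta_brute(calls_by_pop):
    """Independent brute-force Weir–Cockerham θ for one locus (direct formulas)."""
    r = len(calls_by_pop)
    n_i = np.array([c.shape[0] for c in calls_by_pop], float)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted(set(np.concatenate([c.ravel() for c in calls_by_pop]).tolist()))
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([np.mean(c.ravel() == al) for c in calls_by_pop])
        h_i = np.array(
            [np.mean((c[:, 0] != c[:, 1]) & ((c[:, 0] == al) | (c[:, 1] == al)))
             for c in calls_by_pop]
        )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        A += (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        B += (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        C += hbar / 2
    return A / (A + B + C)


def amova_brute(g):
    """Independent nested ANOVA on one-hot gene-copy vectors (toy-data oracle)."""
    pops = g.populations
    grp = np.array([g.group[p] for p in pops])
    sa = sb = sc = 0.0
    for l in range(len(g.loci)):
        X, plab = [], []
        for p in pops:
            idx = g.pop_indices(p)
            c = g.calls[idx, l, :]
            c = c[c[:, 0] != 0]
            for copy_ in c.ravel():
                X.append(copy_)
                plab.append(p)
        X, plab = np.array(X), np.array(plab)
        alleles = np.unique(X)
        # one-hot scaled so squared distance between distinct alleles is 1
        Y = (X[:, None] == alleles[None, :]).astype(float) / np.sqrt(2)
        N = len(X)
        ss_tot = ((Y - Y.mean(0)) ** 2).sum()
        ss_wp = sum(
            ((Y[plab == p] - Y[plab == p].mean(0)) ** 2).sum() for p in pops
        )
        glab = np.array([g.group[p] for p in plab])
        groups = sorted(set(grp))
        ss_wg = sum(
            ((Y[glab == gg] - Y[glab == gg].mean(0)) ** 2).sum() for gg in groups
        )
        N_p = np.array([np.sum(plab == p) for p in pops], float)
        N_g = np.array([np.sum(glab == gg) for gg in groups], float)
        G, P = len(groups), len(pops)
        S_g = np.array(
            [np.sum(N_p[grp == gg] ** 2) / N_g[gi] for gi, gg in enumerate(groups)]
        )
        n1 = (N - S_g.sum()) / (P - G)
        n2 = (S_g.sum() - (N_p**2).sum() / N) / (G - 1)
        n3 = (N - (N_g**2).sum() / N) / (G - 1)
        msd_c = ss_wp / (N - P)
        msd_b = (ss_wg - ss_wp) / (P - G)
        msd_a = (ss_tot - ss_wg) / (G - 1)
        c_ = msd_c
        b_ = (msd_b - c_) / n1
        a_ = (msd_a - c_ - n2 * b_) / n3
        sa, sb, sc = sa + a_, sb + b_, sc + c_
    return sa, sb, sc
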