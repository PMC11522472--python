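"""Ct preprocessing, hurdle-model marker testing, composition tests, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats
from sklearn.metrics import adjusted_rand_score

from clonotrack import genex


def make_ct(entries, cells=None, genes=("G1", "G2")):
    """entries: list of (cell, gene, replicate, ct)."""
    ct = pd.DataFrame(entries, columns=["cell_id", "gene", "replicate", "ct"])
    cell_ids = cells or sorted(ct["cell_id"].unique())
    meta = pd.DataFrame({"cell_id": cell_ids, "donor_id": "D1", "cohort": "HD",
                         "phenotype": "CM"}).set_index("cell_id")
    return genex.CtMatrix(ct=ct, cell_meta=meta)


def expr_from_et(et, meta=None, clusters=None):
    em = genex.ExpressionMatrix(
        et=et,
        cell_meta=meta if meta is not None else pd.DataFrame(
            {"donor_id": "D1", "cohort": "HD"}, index=et.index),
    )
    if clusters is not None:
        em = em.with_clusters(pd.Series(clusters, index=et.index))
    return em


def test_preprocess_min_of_duplicates():
    raw = make_ct([("c1", "G1", 1, 24.0), ("c1", "G1", 2, 25.0),
                   ("c1", "G2", 1, 30.0)])
    expr = genex.preprocess_ct(raw)
    assert expr.et.loc["c1", "G1"] == pytest.approx(8.0)
    assert expr.et.loc["c1", "G2"] == pytest.approx(2.0)


def test_preprocess_missing_duplicates_give_zero():
    raw = make_ct([("c1", "G1", 1, np.nan), ("c1", "G1", 2, np.nan),
                   ("c1", "G2", 1, 20.0)])
    expr = genex.preprocess_ct(raw)
    assert expr.et.loc["c1", "G1"] == 0.0


def test_preprocess_removes_all_zero_cells():
    raw = make_ct([("c1", "G1", 1, np.nan), ("c1", "G2", 1, np.nan),
                   ("c2", "G1", 1, 20.0), ("c2", "G2", 1, np.nan)],
                  cells=["c1", "c2"])
    expr = genex.preprocess_ct(raw)
    assert list(expr.et.index) == ["c2"]


def test_preprocess_ct_above_40_treated_missing():
    raw = make_ct([("c1", "G1", 1, 45.0), ("c1", "G1", 2, 28.0),
                   ("c1", "G2", 1, 20.0)])
    expr = genex.preprocess_ct(raw)
    assert expr.et.loc["c1", "G1"] == pytest.approx(4.0)


@given(st.lists(
    st.tuples(st.sampled_from(["c1", "c2", "c3"]), st.sampled_from(["G1", "G2"]),
              st.sampled_from([1, 2]),
              st.one_of(st.none(), st.floats(min_value=0.5, max_value=45.0))),
    min_size=1, max_size=20))
@settings(max_examples=80, deadline=None)
def test_et_bounds_property(entries):
    """Et always lies in [0, 32]; Et = 0 iff Ct missing or >= 32."""
    rows = [(c, g, r, np.nan if v is None else v) for (c, g, r, v) in entries]
    # keep at most one reading per (cell, gene, replicate)
    seen = {}
    for c, g, r, v in rows:
        seen[(c, g, r)] = (c, g, r, v)
    raw = make_ct(list(seen.values()), cells=sorted({c for c, _, _, _ in rows}))
    expr = genex.preprocess_ct(raw)
    assert ((expr.et >= 0) & (expr.et <= 32)).all().all()
    ct_min = raw.ct.assign(ct=raw.ct["ct"].mask(raw.ct["ct"] > 40)) \
        .groupby(["cell_id", "gene"])["ct"].min()
    for cell in expr.et.index:
        for gene in expr.et.columns:
            v = ct_min.get((cell, gene), np.nan)
            expected_zero = (pd.isna(v)) or (v >= 32)
            assert (expr.et.loc[cell, gene] == 0.0) == expected_zero


# ---------------------------------------------------------------------------
# Hurdle test
# ---------------------------------------------------------------------------

def hurdle_oracle(xi, xo):
    """Independent two-part likelihood maximisation (numerical optimisation)."""
    xi, xo = np.asarray(xi, float), np.asarray(xo, float)

    def bern_nll(p, k, n):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return -(k * np.log(p) + (n - k) * np.log(1 - p))

    def fit_bern(k, n):
        res = optimize.minimize_scalar(bern_nll, bounds=(1e-9, 1 - 1e-9),
                                       args=(k, n), method="bounded",
                                       options={"xatol": 1e-12})
        return -res.fun

    ki, ni = int((xi > 0).sum()), xi.size
    ko, no = int((xo > 0).sum()), xo.size
    dev_disc = 2 * (fit_bern(ki, ni) + fit_bern(ko, no) - fit_bern(ki + ko, ni + no))

    ei, eo = xi[xi > 0], xo[xo > 0]
    if ei.size >= 1 and eo.size >= 1:
        pooled = np.concatenate([ei, eo])

        def nll_one(theta):
            mu, logsd = theta
            return -stats.norm.logpdf(pooled, mu, np.exp(logsd)).sum()

        def nll_two(theta):
            mu1, mu2, logsd = theta
            sd = np.exp(logsd)
            return -(stats.norm.logpdf(ei, mu1, sd).sum()
                     + stats.norm.logpdf(eo, mu2, sd).sum())

        r1 = optimize.minimize(nll_one, [pooled.mean(), np.log(pooled.std() + 0.1)],
                               method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
        r2 = optimize.minimize(nll_two, [ei.mean(), eo.mean(),
                                         np.log(pooled.std() + 0.1)],
                               method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12})
        dev_cont = 2 * (r1.fun - r2.fun)
        df = 2
    else:
        dev_cont, df = 0.0, 1
    p_overall = stats.chi2.sf(dev_disc + dev_cont, df)
    return dev_disc, dev_cont, p_overall


@pytest.mark.parametrize("xi,xo", [
    ([0, 0, 5, 6, 7], [0, 0, 0, 4, 5, 6]),
    ([10, 11, 9, 0, 0, 12], [3, 4, 0, 0, 0, 5, 2]),
    ([0, 0, 0, 8], [7, 9, 0, 0, 6]),
    ([1, 2, 3, 4, 5], [2, 3, 4, 5, 6]),
])
def test_hurdle_matches_brute_force_oracle(xi, xo):
    """The closed-form deviances agree with direct likelihood maximisation."""
    et = pd.DataFrame({"g": list(xi) + list(xo)},
                      index=[f"c{i}" for i in range(len(xi) + len(xo))])
    clusters = [1] * len(xi) + [2] * len(xo)
    expr = expr_from_et(et.astype(float), clusters=clusters)
    res = genex.hurdle_test(expr, cluster=1, gene="g")
    _, _, p_oracle = hurdle_oracle(xi, xo)
    assert res.p_overall == pytest.approx(p_oracle, abs=1e-5)


def test_hurdle_null_case():
    xi = [0.0, 2.0, 4.0, 6.0] * 3
    et = pd.DataFrame({"g": xi + xi}, index=[f"c{i}" for i in range(2 * len(xi))])
    expr = expr_from_et(et, clusters=[1] * len(xi) + [2] * len(xi))
    res = genex.hurdle_test(expr, 1, "g")
    assert res.p_overall > 0.99
    assert res.avg_logFC == pytest.approx(0.0)


def test_hurdle_complete_separation():
    et = pd.DataFrame({"g": [10.0] * 8 + [0.0] * 8},
                      index=[f"c{i}" for i in range(16)])
    expr = expr_from_et(et, clusters=[1] * 8 + [2] * 8)
    res = genex.hurdle_test(expr, 1, "g")
    assert res.p_overall < 1e-4
    assert res.avg_logFC == pytest.approx(10.0)
    # continuous part undefined (no expressing cells out of cluster)
    assert res.p_continuous == 1.0


def test_hurdle_null_calibration_permuted_labels():
    """Fraction of p_overall < 0.05 under the null is 0.05 +/- 0.02."""
    rng = np.random.default_rng(7)
    n_genes, n_cells = 1000, 200
    labels = np.array([1] * 100 + [2] * 100)
    pvals = np.empty(n_genes)
    for g in range(n_genes):
        x = np.where(rng.random(n_cells) < 0.4, 0.0,
                     rng.normal(8.0, 2.0, n_cells).clip(0.1, 32))
        et = pd.DataFrame({"g": x}, index=[f"c{i}" for i in range(n_cells)])
        expr = expr_from_et(et, clusters=rng.permutation(labels))
        pvals[g] = genex.hurdle_test(expr, 1, "g").p_overall
    frac = (pvals < 0.05).mean()
    assert 0.03 <= frac <= 0.07
    # and the whole distribution is near-uniform
    ks = stats.kstest(pvals, "uniform").statistic
    assert ks < 0.06


def test_marker_filter_rules():
    def r(p, lfc):
        return genex.HurdleResult("g", 1, p, p, p_overall=p, avg_logFC=lfc)
    results = [r(0.001, 0.3)] + [r(0.5, 0.0)] * 8 + [r(0.001, 0.2)]
    kept = genex.marker_filter(results, alpha=0.05)
    assert results[0].p_adj == pytest.approx(0.01)
    assert kept == [results[0]]
    assert results[-1].is_marker is False  # significant but |logFC| <= 0.25

    results2 = [r(0.02, 1.0), r(0.2, 1.0)]
    kept2 = genex.marker_filter(results2, alpha=0.05)
    assert [x.is_marker for x in results2] == [True, False]

    # idempotence: re-filtering the retained list keeps it unchanged
    again = genex.marker_filter(kept2, alpha=0.05)
    assert again == kept2


def test_cluster_composition_exact_ranksum():
    """Complete separation at n=3 vs 3 gives the exact two-sided p of 2/20."""
    meta = pd.DataFrame({
        "donor_id": ["h1"] * 2 + ["h2"] * 2 + ["h3"] * 2
                    + ["t1"] * 2 + ["t2"] * 2 + ["t3"] * 2,
        "cohort": ["HD"] * 6 + ["T1D"] * 6,
    }, index=[f"c{i}" for i in range(12)])
    # per-donor fractions in cluster 1: HD 0.9/0.8/0.85 scaled to 20 cells
    fractions = {"h1": 0.9, "h2": 0.8, "h3": 0.85, "t1": 0.1, "t2": 0.2, "t3": 0.15}
    rows = []
    for donor, frac in fractions.items():
        n1 = int(round(frac * 20))
        rows += [(donor, 1)] * n1 + [(donor, 2)] * (20 - n1)
    meta = pd.DataFrame({
        "donor_id": [r[0] for r in rows],
        "cohort": ["HD" if r[0].startswith("h") else "T1D" for r in rows],
    }, index=[f"c{i}" for i in range(len(rows))])
    et = pd.DataFrame({"g": 1.0}, index=meta.index)
    expr = genex.ExpressionMatrix(et=et, cell_meta=meta)
    expr = expr.with_clusters(pd.Series([r[1] for r in rows], index=meta.index))
    res = genex.cluster_composition_test(expr)
    by_cluster = {r.cluster: r for r in res}
    assert by_cluster[1].p_wilcoxon == pytest.approx(2 / 20)
    # per-donor fractions across clusters sum to 1
    fracs = genex.donor_cluster_fractions(expr)
    assert np.allclose(fracs.sum(axis=1), 1.0)


def test_cluster_composition_identical_fractions_p_one():
    rows = [(d, cl) for d in ("h1", "h2", "t1", "t2") for cl in (1, 1, 2, 2)]
    meta = pd.DataFrame({
        "donor_id": [r[0] for r in rows],
        "cohort": ["HD" if r[0].startswith("h") else "T1D" for r in rows],
    }, index=[f"c{i}" for i in range(len(rows))])
    et = pd.DataFrame({"g": 1.0}, index=meta.index)
    expr = genex.ExpressionMatrix(et, meta).with_clusters(
        pd.Series([r[1] for r in rows], index=meta.index))
    for r in genex.cluster_composition_test(expr):
        assert r.p_wilcoxon == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def blob_matrix(seed=11, n_per=100, n_genes=48, shift=8.0, n_blobs=3):
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for b in range(n_blobs):
        mu = np.zeros(n_genes)
        mu[b * 10:(b + 1) * 10] = shift
        rows.append(rng.normal(mu, 1.0, size=(n_per, n_genes)))
        truth += [b] * n_per
    et = np.clip(np.vstack(rows), 0, 32)
    idx = [f"c{i}" for i in range(et.shape[0])]
    return pd.DataFrame(et, index=idx), np.array(truth)


def test_cluster_cells_recovers_blobs():
    et, truth = blob_matrix()
    expr = expr_from_et(et)
    labels = genex.cluster_cells(expr, n_pcs=10, resolution=1.0, seed=0)
    assert labels.nunique() == 3
    assert adjusted_rand_score(truth, labels.to_numpy()) > 0.95
    # labels are 1-based, ordered by decreasing size
    sizes = labels.value_counts()
    assert list(sizes.index) == sorted(sizes.index)


def test_cluster_cells_single_blob_low_resolution():
    rng = np.random.default_rng(5)
    et = pd.DataFrame(np.clip(rng.normal(8, 1, size=(120, 20)), 0, 32),
                      index=[f"c{i}" for i in range(120)])
    labels = genex.cluster_cells(expr_from_et(et), n_pcs=10, resolution=0.1, seed=0)
    assert labels.nunique() == 1


def test_cluster_cells_permutation_invariant():
    et, truth = blob_matrix(seed=21)
    labels = genex.cluster_cells(expr_from_et(et), seed=0)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(et))
    et2 = et.iloc[perm]
    labels2 = genex.cluster_cells(expr_from_et(et2), seed=0)
    # same partition up to renumbering
    assert adjusted_rand_score(labels.loc[et2.index].to_numpy(),
                               labels2.to_numpy()) == pytest.approx(1.0)


def test_cluster_cells_too_few_cells_raises():
    et, _ = blob_matrix(n_per=5, n_blobs=1)
    with pytest.raises(ValueError):
        genex.cluster_cells(expr_from_et(et), n_pcs=10, n_neighbors=20)
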