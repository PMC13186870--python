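"""Window construction, burden weights, FBAT scores, W and the filter."""

import numpy as np
import pandas as pd
import pytest

import trioknock as tk
from conftest import manual_cohort
from trioknock.scan import (
    FbatEngine,
    fit_burden_weights,
    knockoff_fdr_select,
    make_windows,
    window_statistic,
    z_to_p,
)

REGION_START = 30_820_506


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_windows_match_study_coordinates():
    pos = np.arange(REGION_START, REGION_START + 5000, 200)
    w500 = make_windows((REGION_START, REGION_START + 4999), (500,), pos)
    spans = {(w.start_bp, w.end_bp) for w in w500}
    assert (30_821_006, 30_821_505) in spans  # reference 500-bp window
    w1000 = make_windows((REGION_START, REGION_START + 4999), (1000,), pos)
    assert (w1000[0].start_bp, w1000[0].end_bp) == (30_820_506, 30_821_505)


def test_windows_overlap_half_and_cover():
    pos = np.arange(1000, 9000, 111)
    ws = make_windows((1000, 8999), (2000,), pos)
    starts = [w.start_bp for w in ws]
    assert np.all(np.diff(starts) == 1000)  # half-window step
    for p in pos:
        assert any(w.start_bp <= p <= w.end_bp for w in ws)


def test_window_exact_length_region_single():
    pos = np.array([120, 480])
    ws = make_windows((100, 599), (500,), pos)
    assert len(ws) == 1 and not ws[0].clipped


def test_window_region_shorter_than_size_clipped():
    pos = np.array([120, 180])
    ws = make_windows((100, 299), (500,), pos)
    assert len(ws) == 1 and ws[0].clipped
    assert (ws[0].start_bp, ws[0].end_bp) == (100, 299)


def test_empty_windows_dropped():
    pos = np.array([100, 4100])
    ws = make_windows((100, 4599), (500,), pos)
    assert all(w.members.size for w in ws)
    # only the windows overlapping the two variants survive
    assert len(ws) == 3
    assert {s for w in ws for s in range(w.start_bp, w.end_bp + 1)} >= {100, 4100}


# ---------------------------------------------------------------------------
# z_to_p: two-sided normal conversion against reference score/p pairs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "z,p",
    [(0.0, 1.0), (3.242, 0.001187887), (-2.887, 0.003892417), (2.828, 0.004677735)],
)
def test_z_to_p_two_sided_normal(z, p):
    assert z_to_p(z) == pytest.approx(p, rel=0.01)


# ---------------------------------------------------------------------------
# burden weights
# ---------------------------------------------------------------------------

def test_infinite_penalty_falls_back_to_equal_weights():
    rng = np.random.default_rng(0)
    X = rng.integers(0, 3, size=(40, 4)).astype(float)
    y = rng.random(40)
    bw = fit_burden_weights(X, y, lambda_policy="fixed", lam=1e9)
    assert bw.fallback
    assert np.allclose(bw.b, 0.5)  # 1/sqrt(4)


def test_constant_phenotype_falls_back():
    X = np.random.default_rng(1).integers(0, 3, size=(30, 3)).astype(float)
    with pytest.warns(UserWarning, match="constant"):
        bw = fit_burden_weights(X, np.ones(30))
    assert bw.fallback


def test_orthogonal_design_soft_threshold_closed_form():
    """On centred orthogonal columns the LASSO solution is the
    soft-threshold S(x_j . y, lam) / ||x_j||^2."""
    rng = np.random.default_rng(4)
    base = rng.normal(size=(64, 2))
    q, _ = np.linalg.qr(base - base.mean(0))
    X = q * 4.0  # ||x_j||^2 = 16, centred, orthogonal
    beta = np.array([0.9, -0.15])
    y = X @ beta + rng.normal(scale=0.3, size=64)
    y = y - y.mean()
    lam = 2.0
    bw = fit_burden_weights(X, y, lambda_policy="fixed", lam=lam)
    xy = X.T @ y
    oracle = np.sign(xy) * np.maximum(np.abs(xy) - lam, 0) / 16.0
    assert np.allclose(bw.b, oracle, atol=1e-5)


# ---------------------------------------------------------------------------
# FBAT score
# ---------------------------------------------------------------------------

def _het_father_trios(transmit_alt: list[int]):
    """Trios with het father (0,1), hom-ref mother; child paternal allele
    as given."""
    fathers = [((0,), (1,))] * len(transmit_alt)
    mothers = [((0,), (0,))] * len(transmit_alt)
    children = [((a,), (0,)) for a in transmit_alt]
    return manual_cohort(fathers, mothers, children)


def test_fbat_no_transmission_variance_is_undefined():
    cohort = manual_cohort(
        [((1,), (1,))], [((0,), (0,))], [((1,), (0,))],
    )
    eng = FbatEngine(cohort, offset_mu=0.0)
    z = eng.zstat(cohort.H, np.array([0]), np.array([1.0]))
    assert np.isnan(z)


def test_fbat_sign_single_transmission():
    cohort = _het_father_trios([1])
    eng = FbatEngine(cohort, offset_mu=0.0)
    z = eng.zstat(cohort.H, np.array([0]), np.array([1.0]))
    assert z > 0  # risk allele over-transmitted => Dir = +1


def test_fbat_four_trio_hand_enumeration():
    """3 of 4 het fathers transmit alt; weights 1, mu 0.
    U = sum(B - E) = 3*0.5 - 0.5 = 1; V = 4 * 0.25 = 1; Z = 1."""
    cohort = _het_father_trios([1, 1, 1, 0])
    eng = FbatEngine(cohort, offset_mu=0.0)
    z = eng.zstat(cohort.H, np.array([0]), np.array([1.0]))
    assert z == pytest.approx(1.0, abs=1e-12)


def test_fbat_weight_scale_invariance(study_null_cohort):
    cohort, _ = study_null_cohort
    eng = FbatEngine(cohort)
    cols = np.arange(5)
    b = np.array([0.3, -1.2, 0.8, 0.05, 2.0])
    z1 = eng.zstat(cohort.H, cols, b)
    z2 = eng.zstat(cohort.H, cols, 7.3 * b)
    assert z1 == pytest.approx(z2, rel=1e-12)


def test_fbat_missing_entries_contribute_nothing():
    cohort = _het_father_trios([1, 1, 0, 0])
    eng = FbatEngine(cohort, offset_mu=0.0)
    z_full = eng.zstat(cohort.H, np.array([0]), np.array([1.0]))
    H2 = cohort.H.copy()
    H2[0:2, 0] = -1  # father of trio 0 missing -> trio 0 drops out
    cohort2 = _het_father_trios([1, 0, 0])  # equivalent reduced cohort
    eng2 = FbatEngine(cohort2, offset_mu=0.0)
    z_masked = eng.zstat(H2, np.array([0]), np.array([1.0]))
    z_reduced = eng2.zstat(cohort2.H, np.array([0]), np.array([1.0]))
    assert z_masked == pytest.approx(z_reduced, abs=1e-12)
    assert z_masked != pytest.approx(z_full, abs=1e-6)


# ---------------------------------------------------------------------------
# W statistic and the knockoff filter
# ---------------------------------------------------------------------------

def test_window_statistic_self_ratio_and_median():
    w, p = window_statistic(2.5, np.full(10, 2.5))
    assert w == pytest.approx(1.0)
    w, _ = window_statistic(3.0, np.array([1.0, -1.5, 2.0]))
    assert w == pytest.approx(2.0)  # 3.0 / median(1, 1.5, 2)


def test_window_statistic_nan_handling():
    with pytest.warns(UserWarning):
        w, _ = window_statistic(3.0, np.array([np.nan, 1.0, 2.0]))
    assert w == pytest.approx(3.0 / 1.5)
    w, p = window_statistic(np.nan, np.array([1.0]))
    assert np.isnan(w) and np.isnan(p)
    w, _ = window_statistic(1.0, np.array([np.nan]))
    assert np.isnan(w)


def _results_frame(z, zstar):
    cols = {f"Zstar_{m + 1}": zstar[:, m] for m in range(zstar.shape[1])}
    return pd.DataFrame(dict(Z=z, **cols))


def test_filter_all_knockoff_wins_empty_selection():
    rng = np.random.default_rng(2)
    z = rng.normal(size=30) * 0.1
    zstar = np.abs(rng.normal(size=(30, 10))) + 1.0  # knockoffs always larger
    out = knockoff_fdr_select(_results_frame(z, zstar), q_target=0.2)
    assert not out["selected"].any()


def test_filter_single_strong_window_hand_trace():
    """One window with |Z| = 10 above all its knockoffs, the rest null:
    with the offset estimator a lone discovery has q = 1/M = 0.1, so it is
    selected at q = 0.10 (not at 0.05)."""
    rng = np.random.default_rng(3)
    n = 40
    z = rng.normal(size=n) * 0.05
    zstar = np.abs(rng.normal(size=(n, 10))) + 0.5
    z[7] = 10.0
    zstar[7] = rng.random(10)  # all <= 1
    out10 = knockoff_fdr_select(_results_frame(z, zstar), q_target=0.10)
    assert out10.loc[7, "selected"]
    assert out10.loc[7, "q"] == pytest.approx(0.1)
    assert out10["selected"].sum() == 1
    out05 = knockoff_fdr_select(_results_frame(z, zstar), q_target=0.05)
    assert not out05["selected"].any()


def test_filter_q_monotone_in_tau():
    """Among original-winning windows, larger margins never get larger q."""
    rng = np.random.default_rng(8)
    z = rng.normal(size=200, scale=2.0)
    zstar = rng.normal(size=(200, 10))
    out = knockoff_fdr_select(_results_frame(z, zstar), q_target=0.1)
    zc = np.abs(out["Z"].to_numpy())
    med = np.median(np.abs(zstar), axis=1)
    win = out["q"].notna()
    tau_like = zc - med
    sub = out[win]
    order = np.argsort(tau_like[win])
    qs = sub["q"].to_numpy()[order]
    assert np.all(np.diff(qs) <= 1e-12)


# ---------------------------------------------------------------------------
# calibration on the null study cohort (shared scan fixture)
# ---------------------------------------------------------------------------

def test_null_scan_z_standard_normal(study_null_scan):
    z = study_null_scan["Z"].to_numpy()
    z = z[~np.isnan(z)]
    assert len(z) >= 500
    assert abs(z.mean()) < 0.1
    assert 0.8 < z.var() < 1.2


def test_null_scan_results_schema(study_null_scan):
    res = study_null_scan
    need = {"chrom", "start", "end", "size", "n", "Dir", "W", "Z",
            "p_burden", "q", "selected"}
    assert need <= set(res.columns)
    ok = ~res["Z"].isna()
    assert (np.sign(res.loc[ok, "Z"]) == res.loc[ok, "Dir"]).all()
    p = res.loc[ok, "p_burden"]
    assert ((p > 0) & (p <= 1)).all()
    assert (res["n"] >= 1).all()
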