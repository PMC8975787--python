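import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chickadmix.genotype_io import MISSING
from chickadmix.hybrid_index import (
    classify_hybrid,
    estimate_h_mcmc,
    estimate_h_ml,
    estimates_to_frame,
    hybrid_summary,
    log_likelihood_h,
    rescale_hybrid_index,
)

# 5-locus worked fixture: arithmetic oracle evaluated independently below
FIX_PA = np.array([0.95, 0.80, 0.99, 0.70, 0.90])
FIX_PB = np.array([0.05, 0.30, 0.02, 0.20, 0.15])
FIX_G = np.array([2, 1, 2, 0, 1])


def loglik_reference(h, g, pa, pb):
    """Spreadsheet-style evaluation: explicit per-locus binomial terms."""
    total = 0.0
    for gi, pai, pbi in zip(g, pa, pb):
        phi = (1 - h) * pai + h * pbi
        coeff = {0: 1, 1: 2, 2: 1}[gi]
        total += math.log(coeff * phi**gi * (1 - phi) ** (2 - gi))
    return total


def test_loglik_closed_form_single_locus():
    assert log_likelihood_h(0.0, [2], [0.9], [0.1]) == pytest.approx(
        2 * math.log(0.9), abs=1e-12
    )
    assert log_likelihood_h(1.0, [2], [0.9], [0.1]) == pytest.approx(
        2 * math.log(0.1), abs=1e-12
    )


@pytest.mark.parametrize("h", [0.0, 0.17, 0.5, 0.83, 1.0])
def test_loglik_matches_arithmetic_oracle(h):
    assert log_likelihood_h(h, FIX_G, FIX_PA, FIX_PB) == pytest.approx(
        loglik_reference(h, FIX_G, FIX_PA, FIX_PB), abs=1e-10
    )


@pytest.mark.parametrize("h", [0.1, 0.35, 0.6])
def test_loglik_mirror_symmetry(h):
    """With p_B = 1 - p_A and genotypes complemented, L(h) = L(1-h) of the original."""
    pa = np.array([0.9, 0.7, 0.95])
    pb = 1 - pa
    g = np.array([2, 1, 0])
    orig = log_likelihood_h(h, g, pa, pb)
    mirrored = log_likelihood_h(1 - h, 2 - g, pa, pb)
    assert mirrored == pytest.approx(orig, abs=1e-12)


def test_loglik_reference_allele_relabeling_invariance():
    """Flipping which allele is 'reference' at any locus leaves estimates unchanged."""
    rng = np.random.default_rng(2)
    pa = rng.uniform(0.7, 0.99, 50)
    pb = rng.uniform(0.01, 0.3, 50)
    g = rng.integers(0, 3, 50)
    flip = rng.random(50) < 0.5
    pa2, pb2, g2 = pa.copy(), pb.copy(), g.copy()
    pa2[flip], pb2[flip], g2[flip] = 1 - pa[flip], 1 - pb[flip], 2 - g[flip]
    for h in (0.2, 0.5, 0.9):
        assert log_likelihood_h(h, g2, pa2, pb2) == pytest.approx(
            log_likelihood_h(h, g, pa, pb), abs=1e-10
        )
    assert estimate_h_ml(g2, pa2, pb2) == estimate_h_ml(g, pa, pb)


def test_loglik_all_missing_raises():
    with pytest.raises(ValueError, match="missing"):
        log_likelihood_h(0.5, [MISSING, MISSING], [0.9, 0.8], [0.1, 0.2])


def test_ml_boundary_cases():
    pa = np.full(50, 0.99)
    pb = np.full(50, 0.01)
    assert estimate_h_ml(np.zeros(50), pa, pb) == 1.0  # all-B homozygote
    assert estimate_h_ml(np.full(50, 2), pa, pb) == 0.0  # all-A homozygote
    assert estimate_h_ml(np.ones(50), pa, pb) == pytest.approx(0.5, abs=1e-9)


def test_ml_backcross_recovery(diagnostic_cohort):
    """BC1A individuals (h_true = 0.25) estimate inside [0.20, 0.30]."""
    freqs, mat, meta = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    idx = np.flatnonzero((meta["ancestry_class"] == "BC1A").to_numpy())
    for i in idx:
        assert 0.20 <= estimate_h_ml(mat.calls[i], pa, pb) <= 0.30


def test_mcmc_flat_likelihood_returns_prior():
    """p_A = p_B everywhere: posterior ~ uniform(0,1) prior."""
    pa = np.array([0.4, 0.6, 0.3, 0.7])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # acceptance 1.0 expected
        est = estimate_h_mcmc(
            np.array([1, 1, 0, 2]), pa, pa, proposal_sd=0.6, seed=5
        )
    assert est.h_posterior_mean == pytest.approx(0.5, abs=0.05)
    assert est.h_ci_high - est.h_ci_low >= 0.8


def test_mcmc_flat_likelihood_warns_on_acceptance_rate():
    pa = np.array([0.4, 0.6])
    with pytest.warns(UserWarning, match="acceptance rate"):
        estimate_h_mcmc(np.array([1, 0]), pa, pa, proposal_sd=0.05, seed=1)


def test_mcmc_is_deterministic_given_seed(diagnostic_cohort):
    freqs, mat, _ = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    a = estimate_h_mcmc(mat.calls[0], pa, pb, seed=123)
    b = estimate_h_mcmc(mat.calls[0], pa, pb, seed=123)
    assert a == b


def test_mcmc_agrees_with_grid_ml(diagnostic_cohort):
    """Posterior mean within 0.02 of the grid-ML point estimate."""
    freqs, mat, _ = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    for i in range(0, mat.n_individuals, 2):
        est = estimate_h_mcmc(mat.calls[i], pa, pb, seed=1000 + i)
        assert abs(est.h_posterior_mean - est.h_ml) <= 0.02


def test_mcmc_f1_interval_covers_half(diagnostic_cohort):
    freqs, mat, meta = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    idx = np.flatnonzero((meta["ancestry_class"] == "F1").to_numpy())
    covered = 0
    for i in idx[:5]:
        est = estimate_h_mcmc(mat.calls[i], pa, pb, seed=2000 + i)
        assert est.h_ci_low > 0.2 and est.h_ci_high < 0.8
        covered += est.h_ci_low <= 0.5 <= est.h_ci_high
    # a 95% interval may legitimately miss the truth for ~1 in 20 birds
    assert covered >= 4


def test_mcmc_estimate_invariants(diagnostic_cohort):
    freqs, mat, _ = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    est = estimate_h_mcmc(mat.calls[3], pa, pb, seed=9)
    assert 0.0 <= est.h_ci_low <= est.h_posterior_mean <= est.h_ci_high <= 1.0
    assert est.h_rescaled == 0.5 - abs(est.h_posterior_mean - 0.5)
    assert est.is_hybrid == (est.h_rescaled >= 0.20)
    assert est.n_loci_used == 500


def test_rescale_parental_and_f1_anchor_points():
    assert rescale_hybrid_index(0.5) == 0.5
    assert rescale_hybrid_index(0.0) == 0.0
    assert rescale_hybrid_index(1.0) == 0.0
    assert rescale_hybrid_index(0.9) == pytest.approx(0.1, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=0.0, max_value=1.0))
def test_rescale_symmetry_and_range(x):
    g = rescale_hybrid_index(x)
    assert g == pytest.approx(rescale_hybrid_index(1.0 - x), abs=1e-12)
    assert 0.0 <= g <= 0.5
    if x != 0.5:
        assert g < 0.5


def test_rescale_rejects_out_of_range():
    with pytest.raises(ValueError):
        rescale_hybrid_index(1.2)
    with pytest.raises(ValueError):
        rescale_hybrid_index(-0.1)


def test_classification_boundary_is_inclusive():
    assert classify_hybrid(0.43) is True
    assert classify_hybrid(0.20) is True
    assert classify_hybrid(0.13) is False
    with pytest.raises(ValueError):
        classify_hybrid(0.6)


def _summary_frames(n_hybrid, n_symp, n_allo=5):
    n = n_symp + n_allo
    est = pd.DataFrame(
        {
            "band": [f"b{i}" for i in range(n)],
            "h_rescaled": [0.3] * n_hybrid + [0.05] * (n - n_hybrid),
            "is_hybrid": [True] * n_hybrid + [False] * (n - n_hybrid),
        }
    )
    meta = pd.DataFrame(
        {
            "band": [f"b{i}" for i in range(n)],
            "species": ["A"] * n,
            "sympatry": ["sympatric"] * n_symp + ["allopatric"] * n_allo,
        }
    )
    return est, meta


def test_hybrid_summary_percentage_arithmetic():
    s = hybrid_summary(*_summary_frames(20, 170))
    assert s == {
        "n_hybrids": 20,
        "n_sympatric": 170,
        "percent_hybrid": 11.8,
        "rescaled_hi_range_by_species": {"A": (0.05, 0.3)},
    }
    assert hybrid_summary(*_summary_frames(3, 25))["percent_hybrid"] == 12.0
    assert hybrid_summary(*_summary_frames(0, 30))["percent_hybrid"] == 0.0


def test_hybrid_summary_excludes_allopatric_birds():
    est, meta = _summary_frames(2, 10, n_allo=50)
    s = hybrid_summary(est, meta)
    assert s["n_sympatric"] == 10


def test_estimates_to_frame_columns(diagnostic_cohort):
    freqs, mat, _ = diagnostic_cohort
    pa, pb = freqs["p_a"].to_numpy(), freqs["p_b"].to_numpy()
    est = estimate_h_mcmc(mat.calls[0], pa, pb, seed=4, band="x1")
    frame = estimates_to_frame([est])
    assert list(frame.columns) == [
        "band", "h_mean", "h_ci_low", "h_ci_high", "h_ml", "h_rescaled",
        "is_hybrid", "n_loci",
    ]
    assert frame["band"].iloc[0] == "x1"
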