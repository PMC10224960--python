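"""XP-CLR components: frequency estimation and clamping, drift-variance
moments, likelihood identities (normalisation, symmetry), window scores and
top-fraction extraction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

import desertscan as ds
from desertscan.core import MISSING
from desertscan.regions import GenomicRegion, RegionSet
from desertscan.xpclr import (
    XpclrParams,
    clamp_freqs,
    estimate_drift_variance,
    normalize_and_top,
    overlap_regions,
    pop_allele_freqs,
    snp_log_likelihood,
    window_xpclr_score,
)

from conftest import make_site_table


def test_pop_allele_freqs_and_clamp():
    codes = np.array(
        [
            [1] * 10,            # all het -> 0.5
            [0] * 10,            # all hom-ref -> 0 -> clamped to 1/20
            [MISSING] * 10,      # uncalled -> dropped
        ],
        dtype=np.int8,
    )
    gm = ds.GenotypeMatrix([f"s{i}" for i in range(10)], codes)
    sites = make_site_table("c", [0, 10, 20])
    freq, ok = pop_allele_freqs(gm, sites, gm.samples)
    assert freq[0] == 0.5
    assert freq[1] == 0.0
    assert ok.tolist() == [True, True, False]
    clamped = clamp_freqs(freq[:2], 10)
    assert clamped[1] == pytest.approx(0.05)  # 1/(2*10)
    with pytest.raises(ValueError, match="empty population"):
        pop_allele_freqs(gm, sites, [])


def test_drift_variance_zero_when_populations_agree():
    p = np.linspace(0.05, 0.95, 200)
    assert estimate_drift_variance(p, p) == 0.0


def test_drift_variance_needs_enough_polymorphic_sites():
    p = np.array([0.0, 1.0] * 40)  # nothing polymorphic in the reference
    with pytest.raises(ValueError, match="usable sites"):
        estimate_drift_variance(p, p)


def test_drift_variance_matches_independent_monte_carlo():
    """omega-hat on a simulated cohort agrees with an independent Monte-Carlo
    of the same moment under the generative model, within 3 combined SEs."""
    params = ds.SimParams(
        seed=41,
        chrom_lengths={"chr1": 400_000},
        n_samples={"cultivated": 60, "wild": 60},
        sweeps=[],
        blocus_region=("chr1", 380_000, 390_338),
        missing_rate=0.0,
        fst=0.1,
    )
    r = ds.simulate_cohort(params)
    keep = ~r.truth.blocus_site_mask
    sites = r.sites.subset(keep)
    gm = r.genotypes.subset_sites(keep)
    f_ref, _ = pop_allele_freqs(gm, sites, r.populations.samples_of("wild"))
    f_obj, _ = pop_allele_freqs(gm, sites, r.populations.samples_of("cultivated"))
    usable = (f_ref > 0) & (f_ref < 1)
    omega_hat = estimate_drift_variance(f_ref, f_obj)
    se_hat = np.std(
        (f_obj[usable] - f_ref[usable]) ** 2 / (f_ref[usable] * (1 - f_ref[usable])),
        ddof=1,
    ) / np.sqrt(usable.sum())

    # independent oracle: replay the generative model with plain numpy
    rng = np.random.default_rng(12345)
    n_sites, n = 40_000, 60
    p = np.clip(rng.beta(0.5, 0.5, n_sites), 1e-3, 1 - 1e-3)
    shape = (1 - 0.1) / 0.1
    q1 = rng.beta(p * shape, (1 - p) * shape)
    q2 = rng.beta(p * shape, (1 - p) * shape)
    p1 = rng.binomial(2 * n, q1) / (2 * n)
    p2 = rng.binomial(2 * n, q2) / (2 * n)
    ok = (p1 > 0) & (p1 < 1)
    vals = (p2[ok] - p1[ok]) ** 2 / (p1[ok] * (1 - p1[ok]))
    omega_mc = vals.mean()
    se_mc = vals.std(ddof=1) / np.sqrt(vals.size)
    tol = 3 * np.hypot(se_hat, se_mc)
    assert abs(omega_hat - omega_mc) < tol


def test_drift_variance_sampling_error_shrinks_with_site_count():
    """Doubling the number of sites roughly halves the estimator variance.

    Frequencies are discretised to 2n-allele sample estimates, as in real
    use, which bounds the per-site ratio away from the beta tails."""
    rng = np.random.default_rng(7)
    shape, n = 9.0, 50

    def omega_estimates(n_sites, reps=200):
        out = []
        for _ in range(reps):
            p = np.clip(rng.beta(0.5, 0.5, n_sites), 1e-3, 1 - 1e-3)
            q1 = rng.binomial(2 * n, rng.beta(p * shape, (1 - p) * shape)) / (2 * n)
            q2 = rng.binomial(2 * n, rng.beta(p * shape, (1 - p) * shape)) / (2 * n)
            out.append(estimate_drift_variance(q1, q2))
        return np.var(out)

    ratio = omega_estimates(400) / omega_estimates(800)
    assert 1.3 < ratio < 3.2


CLAMP = 0.02


def _total_mass(p1, omega, c):
    interior, _ = quad(
        lambda x: np.exp(
            snp_log_likelihood(np.array([x]), np.array([p1]), omega, c, CLAMP)[0]
        ),
        CLAMP + 1e-9,
        1 - CLAMP - 1e-9,
        limit=200,
    )
    atoms = sum(
        np.exp(snp_log_likelihood(np.array([x]), np.array([p1]), omega, c, CLAMP)[0])
        for x in (CLAMP, 1 - CLAMP)
    )
    return interior + atoms


@pytest.mark.parametrize("c", [1.0, 0.5, 0.0])
@pytest.mark.parametrize("p1", [0.1, 0.5, 0.9])
def test_snp_likelihood_integrates_to_one(c, p1):
    assert _total_mass(p1, 0.05, c) == pytest.approx(1.0, abs=1e-6)


def test_snp_likelihood_mixture_identities():
    p2 = np.array([0.3, CLAMP, 1 - CLAMP])
    p1 = np.array([0.4, 0.4, 0.4])
    full = snp_log_likelihood(p2, p1, 0.05, 1.0, CLAMP)
    half = snp_log_likelihood(p2, p1, 0.05, 0.5, CLAMP)
    # c=1 is the pure null; interior sweep density is zero so the c=0.5
    # mixture at an interior point is exactly half the null density
    assert np.exp(half[0]) == pytest.approx(0.5 * np.exp(full[0]))
    # at the upper boundary the sweep component adds mass p1
    assert np.exp(half[2]) == pytest.approx(
        0.5 * np.exp(full[2]) + 0.5 * 0.4
    )


def test_sweep_component_monotonic_in_p1_at_fixation():
    lo = snp_log_likelihood(
        np.array([1 - CLAMP]), np.array([0.1]), 0.05, 0.0, CLAMP
    )[0]
    hi = snp_log_likelihood(
        np.array([1 - CLAMP]), np.array([0.9]), 0.05, 0.0, CLAMP
    )[0]
    assert hi > lo
    assert np.exp(hi) == pytest.approx(0.9)


def test_snp_likelihood_domain_errors():
    with pytest.raises(ValueError, match="omega"):
        snp_log_likelihood(np.array([0.5]), np.array([0.5]), 0.0, 1.0, CLAMP)
    with pytest.raises(ValueError, match="p2"):
        snp_log_likelihood(np.array([0.001]), np.array([0.5]), 0.1, 1.0, CLAMP)


def test_window_score_zero_when_frequencies_agree():
    rng = np.random.default_rng(2)
    pos = np.sort(rng.integers(0, 50_000, 80))
    p = np.clip(rng.uniform(0.1, 0.9, 80), CLAMP, 1 - CLAMP)
    w = GenomicRegion("c", 0, 50_000)
    score = window_xpclr_score(w, pos, p, p, 0.05, XpclrParams(), CLAMP)
    assert score.raw == 0.0
    assert score.n_snps == 80


def test_window_score_detects_centre_clustered_fixation():
    pos = np.sort(np.random.default_rng(3).integers(22_000, 28_000, 20))
    p1 = np.full(20, 0.5)
    p2 = np.full(20, 1 - CLAMP)
    w = GenomicRegion("c", 0, 50_000)
    score = window_xpclr_score(w, pos, p1, p2, 0.05, XpclrParams(), CLAMP)
    assert score.raw > 0
    assert np.isfinite(score.sigma_hat)


def test_window_score_empty_window_is_nan():
    w = GenomicRegion("c", 0, 50_000)
    score = window_xpclr_score(
        w, np.array([60_000]), np.array([0.5]), np.array([0.5]),
        0.05, XpclrParams(), CLAMP,
    )
    assert np.isnan(score.raw) and score.n_snps == 0


def test_score_invariant_under_joint_allele_relabeling():
    rng = np.random.default_rng(4)
    pos = np.sort(rng.integers(0, 50_000, 60))
    p1 = np.clip(rng.uniform(CLAMP, 1 - CLAMP, 60), CLAMP, 1 - CLAMP)
    p2 = np.clip(p1 + rng.normal(0, 0.15, 60), CLAMP, 1 - CLAMP)
    w = GenomicRegion("c", 0, 50_000)
    params = XpclrParams()
    a = window_xpclr_score(w, pos, p1, p2, 0.08, params, CLAMP)
    b = window_xpclr_score(w, pos, 1 - p1, 1 - p2, 0.08, params, CLAMP)
    assert a.raw == pytest.approx(b.raw, rel=1e-9, abs=1e-9)


def _results_frame(raws):
    n = len(raws)
    return {
        "chrom": ["c"] * n,
        "start": np.arange(n) * 10_000,
        "end": np.arange(n) * 10_000 + 50_000,
        "raw": raws,
        "n_snps": [10] * n,
        "sigma_hat": [np.nan] * n,
    }


def test_normalize_and_top_extracts_exactly_five_percent():
    import pandas as pd

    rng = np.random.default_rng(5)
    raws = rng.permutation(np.arange(100, dtype=float))
    out, top, threshold = normalize_and_top(pd.DataFrame(_results_frame(raws)))
    assert len(top) == 5
    top_raws = sorted(out.loc[out["zscore"] >= threshold, "raw"])
    assert top_raws == [95.0, 96.0, 97.0, 98.0, 99.0]
    assert out["zscore"].mean() == pytest.approx(0.0, abs=1e-12)
    assert out["zscore"].std(ddof=0) == pytest.approx(1.0)


def test_normalize_includes_threshold_ties():
    import pandas as pd

    raws = [0.0] * 95 + [7.0] * 5
    raws[0] = 7.0  # six windows tie at the cut
    out, top, _ = normalize_and_top(pd.DataFrame(_results_frame(raws)))
    assert len(top) == 6


def test_normalize_degenerate_inputs_raise():
    import pandas as pd

    with pytest.raises(ValueError, match="constant"):
        normalize_and_top(pd.DataFrame(_results_frame([1.0] * 30)))
    with pytest.raises(ValueError, match="no scored windows"):
        normalize_and_top(pd.DataFrame(_results_frame([np.nan] * 30)))


def test_overlap_regions_trivial_cases():
    a = RegionSet([("c", 0, 1000)])
    b = RegionSet([("c", 5000, 6000)])
    assert overlap_regions(a, b)[0] == 0
    assert overlap_regions(a, a)[0] == 1000
    bp_ab, _ = overlap_regions(a, RegionSet([("c", 500, 700)]))
    assert bp_ab == 200
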