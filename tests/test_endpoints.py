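"""The 13 locomotor endpoints: worked values, invariants, and a naive oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfscreen.endpoints import (ENDPOINT_NAMES, EPS_DEN, bin_track,
                                compute_endpoints, endpoints_table)

from conftest import make_profile


# ---------------------------------------------------------------------------
# independent transcription of the endpoint formulas (no shared code)
def naive_endpoints(l, d):
    l, d = list(map(float, l)), list(map(float, d))
    m, n = len(l), len(d)
    mean = lambda v: sum(v) / len(v)
    trap = lambda v: sum((v[i] + v[i + 1]) / 2 for i in range(len(v) - 1))
    out = {}
    out["avgSL"] = mean(l)
    out["avgSD"] = mean(d)
    out["avgST"] = mean(l + d)
    out["hbt1L"] = (l[-1] - l[0]) / (m - 1)
    out["hbt1D"] = (d[-1] - d[0]) / (n - 1)
    out["hbt2L"] = (l[-1] - l[1]) / (m - 2) - (l[-2] - l[0]) / (m - 2)
    out["hbt2D"] = (d[-1] - d[1]) / (n - 2) - (d[-2] - d[0]) / (n - 2)
    out["RoAL"] = max(l) / (min(l) + 1.0)
    out["RoAD"] = max(d) / (min(d) + 1.0)
    out["strtlA"] = d[0] - l[-1]
    out["strtlAavg"] = d[0] - mean(l)
    out["strtlF"] = d[0] / max(l[-1], EPS_DEN)
    out["AUC_r"] = trap(d) / max(trap(l), EPS_DEN)
    return out
# ---------------------------------------------------------------------------


WORKED = {
    "avgSL": 2.5, "avgSD": 5.0, "avgST": 3.75,
    "hbt1L": 1.0, "hbt1D": -2.0, "hbt2L": 0.0, "hbt2D": 0.0,
    "RoAL": 2.0, "RoAD": 8.0 / 3.0,
    "strtlA": 4.0, "strtlAavg": 5.5, "strtlF": 2.0, "AUC_r": 2.0,
}


def test_worked_four_bin_fixture():
    ep = compute_endpoints(make_profile([1, 2, 3, 4], [8, 6, 4, 2]))
    assert set(ep) == set(ENDPOINT_NAMES)
    for name, want in WORKED.items():
        assert ep[name] == pytest.approx(want, abs=1e-12), name


def test_constant_profile():
    c = 3.0
    ep = compute_endpoints(make_profile([c] * 5, [c] * 5))
    for name in ("hbt1L", "hbt1D", "hbt2L", "hbt2D", "strtlA", "strtlAavg"):
        assert ep[name] == 0.0
    assert ep["strtlF"] == 1.0
    assert ep["AUC_r"] == 1.0
    assert ep["RoAL"] == ep["RoAD"] == pytest.approx(c / (c + 1))


def test_all_zero_profile():
    ep = compute_endpoints(make_profile([0] * 4, [0] * 4))
    assert all(v == 0.0 for v in ep.values())


def test_acclimation_bins_excluded():
    with_accl = compute_endpoints(
        make_profile([1, 2, 3, 4], [8, 6, 4, 2], accl=[99, 99, 99]))
    assert with_accl == compute_endpoints(make_profile([1, 2, 3, 4], [8, 6, 4, 2]))


@pytest.mark.parametrize("light,dark,phase", [([1, 2], [1, 2, 3], "light"),
                                              ([1, 2, 3], [5], "dark")])
def test_too_few_bins_names_phase(light, dark, phase):
    with pytest.raises(ValueError, match=phase):
        compute_endpoints(make_profile(light, dark))


def test_bin_track_filter_and_counts():
    # sub-threshold moves are zeroed before summation
    prof = bin_track([0.1, 0.5, 1.0, 1.5], [0.01, 0.05, 0.01, 0.10],
                     acclimation_min=0, light_min=2, dark_min=0)
    assert prof.distances[0] == pytest.approx(0.15)
    # min_move = 0 disables the filter
    prof = bin_track([0.1, 0.5, 1.0, 1.5], [0.01, 0.05, 0.01, 0.10], min_move=0,
                     acclimation_min=0, light_min=2, dark_min=0)
    assert prof.distances[0] == pytest.approx(0.17)
    # 60 min of samples at 2-min bins -> 30 bins
    t = np.arange(0, 60, 0.5)
    prof = bin_track(t, np.ones_like(t), acclimation_min=20, light_min=20, dark_min=20)
    assert len(prof.distances) == 30


def test_bin_track_half_open_boundaries():
    # a sample exactly at a bin edge belongs to the next bin
    prof = bin_track([0.0, 2.0], [1.0, 1.0],
                     acclimation_min=0, light_min=4, dark_min=0)
    assert prof.distances.tolist() == [1.0, 1.0]


def test_bin_track_errors():
    with pytest.raises(ValueError, match="no samples"):
        bin_track([], [])
    with pytest.raises(ValueError, match="monotone"):
        bin_track([1.0, 0.5], [0.1, 0.1])


def test_protocol_bin_count_contract():
    """40/40-min phases at 2-min bins give 20 light and 20 dark bins."""
    t = np.arange(0, 100, 1.0)
    prof = bin_track(t, np.full_like(t, 0.5))
    assert prof.n_light == 20 and prof.n_dark == 20


positive_bins = st.lists(
    st.floats(min_value=0.0, max_value=50.0, allow_nan=False), min_size=4, max_size=20)


@settings(max_examples=100, derandomize=True)
@given(light=positive_bins, dark=positive_bins)
def test_reversal_negates_hbt1_keeps_avg_and_roa(light, dark):
    ep = compute_endpoints(make_profile(light, dark))
    ep_rev = compute_endpoints(make_profile(light[::-1], dark))
    assert ep_rev["hbt1L"] == pytest.approx(-ep["hbt1L"], abs=1e-9)
    assert ep_rev["avgSL"] == pytest.approx(ep["avgSL"], abs=1e-9)
    assert ep_rev["RoAL"] == pytest.approx(ep["RoAL"], abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(light=positive_bins, dark=positive_bins,
       k=st.floats(min_value=0.1, max_value=10.0))
def test_scale_equivariance(light, dark, k):
    ep = compute_endpoints(make_profile(light, dark))
    ep_k = compute_endpoints(make_profile([k * v for v in light],
                                          [k * v for v in dark]))
    for name in ("avgSL", "avgSD", "avgST", "hbt1L", "hbt1D", "hbt2L", "hbt2D",
                 "strtlA", "strtlAavg"):
        assert ep_k[name] == pytest.approx(k * ep[name], rel=1e-9, abs=1e-9)
    # ratio endpoints are scale invariant away from the denominator floor
    if min(light) * k > EPS_DEN and min(light) > EPS_DEN:
        assert ep_k["strtlF"] == pytest.approx(ep["strtlF"], rel=1e-9)
        assert ep_k["AUC_r"] == pytest.approx(ep["AUC_r"], rel=1e-9)


def test_oracle_equivalence_on_random_profiles():
    """Independent formula transcription agrees to 1e-12 on 1,000 profiles."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        m = int(rng.integers(3, 21))
        n = int(rng.integers(3, 21))
        light = rng.gamma(2.0, 2.0, size=m)
        dark = rng.gamma(2.0, 3.0, size=n)
        ep = compute_endpoints(make_profile(light, dark))
        want = naive_endpoints(light, dark)
        for name in ENDPOINT_NAMES:
            assert ep[name] == pytest.approx(want[name], rel=1e-12, abs=1e-12), name


def test_avgst_between_phase_means_when_balanced():
    rng = np.random.default_rng(5)
    l, d = rng.gamma(2, 2, 10), rng.gamma(2, 3, 10)
    ep = compute_endpoints(make_profile(l, d))
    assert min(ep["avgSL"], ep["avgSD"]) <= ep["avgST"] <= max(ep["avgSL"], ep["avgSD"])


def test_endpoints_table_schema():
    tbl = endpoints_table([make_profile([1, 2, 3], [3, 2, 1], conc=5.0)])
    assert list(tbl.columns[:4]) == ["plate_id", "larva_id", "chemical", "conc_uM"]
    assert list(tbl.columns[4:]) == list(ENDPOINT_NAMES)
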