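"""Model suite, continuous hitcall, and BMC estimation."""

import numpy as np
import pandas as pd
import pytest

from zfscreen.concresp import (ConcRespInput, analyze_endpoint, bmc, fit_suite,
                               hitcall, pick_winner, screen_chemical)
from zfscreen.endpoints import endpoints_table
from zfscreen.models import MODEL_NAMES, fit_suite_arrays, pseudo_conc
from zfscreen.normalization import fit_reference
from zfscreen.simulate import HillEffect, SimulationConfig, simulate_plate

CONCS = np.array([0.01, 0.0316, 0.1, 0.316, 1.0, 3.16, 10.0])


def make_input(resp_fn, n_per=16, noise=0.0, seed=0, cutoff=1.0, concs=CONCS):
    rng = np.random.default_rng(seed)
    conc = np.concatenate([np.repeat(c, n_per) for c in [0.0, *concs]])
    resp = np.array([resp_fn(c) for c in conc]) + rng.normal(0, noise, len(conc))
    return ConcRespInput(endpoint="x", conc=conc, resp=resp, cutoff=cutoff)


def hill(c, top=5.0, ac50=1.0, h=2.0):
    return 0.0 if c == 0 else top / (1.0 + (ac50 / c) ** h)


def test_input_validation():
    with pytest.raises(ValueError, match="nonzero concentrations"):
        ConcRespInput("x", np.array([0.0, 1.0, 1.0]), np.zeros(3), 1.0)
    with pytest.raises(ValueError, match="cutoff"):
        ConcRespInput("x", np.array([0, 1, 2.0]), np.zeros(3), 0.0)


def test_pseudo_conc_half_log_step_below_lowest():
    out = pseudo_conc(np.array([0.0, 1.0, 10.0]))
    assert out[0] == pytest.approx(1.0 / 10**0.25)


def test_constant_wins_on_pure_noise():
    inp = make_input(lambda c: 0.0, noise=1.0, seed=11)
    fits = fit_suite(inp)
    assert min(fits, key=lambda f: f.aic).name == "cnst"


def test_aic_definition_on_all_fits():
    inp = make_input(hill, noise=0.3, seed=1)
    for f in fit_suite(inp):
        assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik, abs=1e-9)
        assert f.top >= 0


def test_hill_recovery_on_noiseless_data():
    """Noiseless Hill data: top within 1%, AC50 within 5%."""
    inp = make_input(lambda c: hill(c, top=5.0, ac50=1.0, h=2.0), noise=1e-3, seed=2)
    fits = {f.name: f for f in fit_suite(inp)}
    tp, ga, p = fits["hill"].params
    assert tp == pytest.approx(5.0, rel=0.01)
    assert ga == pytest.approx(1.0, rel=0.05)


def test_hitcall_bounds_and_null():
    inp = make_input(lambda c: 0.0, noise=1.0, seed=3)
    fits = fit_suite(inp)
    hc, w1, w2, w3 = hitcall(fits, inp)
    assert 0.0 <= hc <= 1.0
    assert all(0.0 <= w <= 1.0 for w in (w1, w2, w3))
    assert hc < 0.1


def test_hitcall_strong_signal():
    """Top at 5x cutoff with low noise: hitcall -> 1."""
    inp = make_input(lambda c: hill(c, top=5.0), noise=0.5, seed=4)
    fits = fit_suite(inp)
    hc, *_ = hitcall(fits, inp)
    assert hc > 0.99


def test_active_flag_at_exact_threshold():
    """A hitcall exactly at the activity threshold counts as active."""
    inp = make_input(lambda c: hill(c, top=5.0), noise=0.5, seed=5)
    res = analyze_endpoint(inp, n_boot=0)
    res_at = analyze_endpoint(inp, hit_threshold=res.hitcall, n_boot=0)
    assert res_at.active


def test_hitcall_zero_when_only_constant_fit():
    inp = make_input(lambda c: 0.0, noise=0.5, seed=6)
    fits = [f for f in fit_suite(inp) if f.name == "cnst"]
    hc, *_ = hitcall(fits, inp)
    assert hc == 0.0


def test_bmc_analytic_hill_inversion():
    """Hill top=5, AC50=1, h=1, BMR=1: BMC = AC50*BMR/(top-BMR) = 0.25 µM."""
    inp = make_input(lambda c: hill(c, top=5.0, ac50=1.0, h=1.0), noise=1e-3, seed=7)
    fits = {f.name: f for f in fit_suite(inp)}
    est, bl, bu, bmr, reason = bmc(fits["hill"], inp, bmr_multiplier=1.0, n_boot=0)
    assert est == pytest.approx(0.25, rel=0.01)


def test_bmc_absent_when_top_below_bmr():
    inp = make_input(lambda c: hill(c, top=0.5), noise=0.05, seed=8)
    fits = {f.name: f for f in fit_suite(inp)}
    est, bl, bu, bmr, reason = bmc(fits["hill"], inp, bmr_multiplier=1.349, n_boot=0)
    assert est is None
    assert reason == "no crossing in tested range"


def test_bootstrap_interval_brackets_estimate():
    for seed in (0, 1, 2):
        inp = make_input(lambda c: hill(c, top=4.0), noise=0.8, seed=seed)
        fits = {f.name: f for f in fit_suite(inp)}
        est, bl, bu, *_ = bmc(fits["hill"], inp, bmr_multiplier=1.0,
                              n_boot=100, seed=seed)
        assert bl <= est <= bu
        assert bl > 0


def test_hitcall_monotone_in_effect_size(reference):
    """Matched-seed simulations: bigger injected effects never lower the
    hitcall materially."""
    hcs = []
    for emax in (0.0, 0.2, 0.4, 0.6):
        cfg = SimulationConfig(
            effects={"dark_level": HillEffect(emax=emax, ac50=3.0)} if emax else {})
        profiles, *_ = simulate_plate(cfg, seed=99)
        ep = endpoints_table(profiles)
        resp = ep["avgSD"].to_numpy(float)
        from zfscreen.normalization import apply_reference
        r, _ = apply_reference(resp, reference["avgSD"])
        inp = ConcRespInput("avgSD", ep["conc_uM"].to_numpy(float), r,
                            reference["avgSD"].cutoff)
        hcs.append(analyze_endpoint(inp, n_boot=0).hitcall)
    for lo, hi in zip(hcs, hcs[1:]):
        assert hi >= lo - 0.05
    assert hcs[-1] > hcs[0]


def test_screen_null_chemical_mostly_inactive(reference):
    """Inactive chemical: 0 of 13 endpoints active on >= 90% of plates."""
    cfg = SimulationConfig()
    clean = 0
    n_plates = 8
    for seed in range(n_plates):
        profiles, *_ = simulate_plate(cfg, seed=2000 + seed)
        ep = endpoints_table(profiles)
        _, heat = screen_chemical(ep, reference, n_boot=0, seed=seed)
        clean += int(heat["active"].sum() == 0)
    assert clean >= int(0.9 * n_plates)


def test_screen_dark_suppression_hits_dark_endpoints(reference):
    """Dark suppression (Emax 0.6, AC50 3 µM): avgSD, avgST and strtlA are
    among the active endpoints in >= 90% of replicates (two pooled plates
    per replicate, honoring the >= 24 larvae/group design rule)."""
    cfg = SimulationConfig(effects={"dark_level": HillEffect(emax=0.6, ac50=3.0)})
    ok = 0
    n_rep = 5
    for seed in range(n_rep):
        eps = [
            endpoints_table(simulate_plate(cfg, 5000 + 10 * seed + k,
                                           plate_id=f"p{k}")[0])
            for k in range(2)
        ]
        ep = pd.concat(eps, ignore_index=True)
        _, heat = screen_chemical(ep, reference, n_boot=0, seed=seed)
        active = set(heat.loc[heat["active"], "endpoint"])
        ok += int({"avgSD", "avgST", "strtlA"} <= active)
    assert ok >= int(np.ceil(0.9 * n_rep))


def test_screen_reports_all_thirteen_endpoints(reference):
    cfg = SimulationConfig()
    profiles, *_ = simulate_plate(cfg, seed=42)
    ep = endpoints_table(profiles)
    results, heat = screen_chemical(ep, reference, n_boot=0, seed=0)
    assert len(results) == 13
    assert (heat["hitcall"].between(0, 1)).all()


def test_single_active_endpoint_marks_one_cell(reference):
    """Bookkeeping: a heatmap with one active endpoint has exactly one
    active cell (the selegiline-like pattern)."""
    rows = [{"chemical": "selegiline-like", "endpoint": e, "winning_model": "hill",
             "hitcall": 0.95 if e == "avgSL" else 0.1,
             "active": e == "avgSL", "bmc_uM": 89.7 if e == "avgSL" else None}
            for e in ("avgSL", "avgSD", "avgST")]
    heat = pd.DataFrame(rows)
    assert int(heat["active"].sum()) == 1
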