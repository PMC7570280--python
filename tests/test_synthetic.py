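"""Synthetic-study generator: copula, spike injection, image rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trimodal as tm
from trimodal.config import VARIABLES, variable_index
from trimodal.synthetic import (
    ACTIVITY_PROBIT,
    gaussian_copula,
    render_histology_image,
    depletion_profile,
    exponential_profile,
)


# ---------------------------------------------------------------------------
# StudyConfig validation
# ---------------------------------------------------------------------------


def test_config_rejects_bad_counts():
    with pytest.raises(ValueError, match="n_keep"):
        tm.StudyConfig(n_keep=20)
    with pytest.raises(ValueError, match="integer >= 1"):
        tm.StudyConfig(n_animals=0)


def test_config_rejects_non_psd_with_eigenvalue():
    C = np.eye(16)
    i, j, k = 0, 1, 2
    # rho(0,1)=rho(0,2)=0.9 but rho(1,2)=-0.9 is infeasible
    C[i, j] = C[j, i] = 0.9
    C[i, k] = C[k, i] = 0.9
    C[j, k] = C[k, j] = -0.9
    with pytest.raises(ValueError, match="eigenvalue"):
        tm.StudyConfig(latent_correlation=C)


def test_config_rejects_asymmetric_and_bad_diagonal():
    C = np.eye(16)
    C[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        tm.StudyConfig(latent_correlation=C)
    C = np.eye(16) * 1.5
    with pytest.raises(ValueError, match="diagonal"):
        tm.StudyConfig(latent_correlation=C)


# ---------------------------------------------------------------------------
# Copula
# ---------------------------------------------------------------------------


def test_copula_marginals_are_uniform_after_probit():
    C = tm.block_correlation(
        [["gfap_0_50", "cd68_0_50", "ladder_time"]], 0.8)
    z = gaussian_copula(np.random.default_rng(3), C, 1000)
    for col in (0, 5, 10, 15):
        u = stats.norm.cdf(z[:, col])
        p = stats.kstest(u, "uniform").pvalue
        assert p > 0.01


def test_copula_plants_cross_correlation():
    C = tm.block_correlation([["gfap_0_50", "cd68_0_50"]], 0.8)
    z = gaussian_copula(np.random.default_rng(4), C, 5000)
    i, j = variable_index("gfap_0_50"), variable_index("cd68_0_50")
    cc = np.corrcoef(z[:, i], z[:, j])[0, 1]
    assert cc == pytest.approx(0.8, abs=0.03)


def test_copula_ar1_preserves_cross_section():
    C = tm.block_correlation([["gfap_0_50", "cd68_0_50"]], 0.8)
    z = gaussian_copula(np.random.default_rng(5), C, 4000, ar1=0.6, n_weeks=8)
    i, j = variable_index("gfap_0_50"), variable_index("cd68_0_50")
    assert np.corrcoef(z[:, i], z[:, j])[0, 1] == pytest.approx(0.8, abs=0.04)
    zi = z[:, i].reshape(-1, 8)
    lag1 = np.corrcoef(zi[:, :-1].ravel(), zi[:, 1:].ravel())[0, 1]
    assert lag1 == pytest.approx(0.6, abs=0.05)


# ---------------------------------------------------------------------------
# Full-study generation
# ---------------------------------------------------------------------------


def test_same_seed_gives_identical_study(default_bundle):
    again = tm.generate_study(tm.StudyConfig(rng_seed=7))
    pd.testing.assert_frame_equal(default_bundle.latent, again.latent)
    pd.testing.assert_frame_equal(default_bundle.channel_units,
                                  again.channel_units)
    pd.testing.assert_frame_equal(default_bundle.behavior_trials,
                                  again.behavior_trials)
    t1 = default_bundle.trace("A1", 3, 2)
    t2 = again.trace("A1", 3, 2)
    assert t1.samples.tobytes() == t2.samples.tobytes()
    assert np.array_equal(t1.true_spike_times, t2.true_spike_times)
    i1 = default_bundle.histology_image("A2", "GFAP", 1)
    i2 = again.histology_image("A2", "GFAP", 1)
    assert i1.pixels.tobytes() == i2.pixels.tobytes()


def test_identity_latent_gives_near_zero_cross_correlations():
    """Cross-modal sample correlations stay small when nothing is planted."""
    probe_pairs = [
        ("pct_channels_active", "ladder_time"),
        ("units_per_channel", "grip_force"),
        ("grid_distance", "ladder_right_slips"),
        ("grid_max_velocity", "ladder_left_slips"),
    ]
    exceed = total = 0
    for seed in range(10):
        b = tm.generate_study(tm.StudyConfig(rng_seed=100 + seed))
        lat = b.latent
        cm, oc, _ = tm.recording_metrics(b.channel_units)
        bw = tm.behavior_weekly(b.behavior_trials)
        tables = tm.assemble(b.config, cm, oc, bw, b.histology_table)
        from trimodal.network import _pair_frame
        for a, c in probe_pairs:
            df = _pair_frame(tables, a, c)
            cc = np.corrcoef(df.x, df.y)[0, 1]
            total += 1
            exceed += abs(cc) > 0.3
    assert exceed / total <= 0.05


def test_planted_high_correlation_survives_links():
    """A 0.9 latent correlation comes through the observables strongly."""
    C = np.eye(16)
    i = variable_index("neun_0_50")
    j = variable_index("units_per_channel")
    C[i, j] = C[j, i] = 0.9
    b = tm.generate_study(tm.StudyConfig(rng_seed=17, latent_correlation=C))
    # weekly observable against its planted latent partner, n = 48
    cm, oc, _ = tm.recording_metrics(b.channel_units)
    lat = b.latent.set_index(["animal_id", "week"])
    upc = oc.set_index(["animal_id", "week"])["units_per_channel"].dropna()
    cc = np.corrcoef(lat.loc[upc.index, "neun_0_50"], upc)[0, 1]
    assert cc > 0.6
    # endpoint analytic value against the animal-mean observable
    h = b.histology_table
    neun = h[(h.marker == "NeuN") & (h.distance_bin == "0-50")]
    neun = neun.set_index("animal_id")["value"]
    upc_a = upc.groupby("animal_id").mean()
    assert np.corrcoef(neun, upc_a.loc[neun.index])[0, 1] > 0


def test_planted_correlation_recovery_battery():
    """Observable correlations track moderate planted values within 0.1.

    One pair per link family (proportion, count rate, lognormal time and
    grid scores, affine force, endpoint histology), planted at 0.4, mean
    |cc| over three seeds, about 1500 (weekly) / 500 (endpoint) units.
    """
    long_pairs = [
        ("pct_channels_active", "units_per_channel"),
        ("ladder_time", "grid_distance"),
        ("grip_force", "grid_max_velocity"),
        ("ladder_left_slips", "ladder_right_slips"),
    ]
    hist_pairs = [
        ("neun_0_50", "units_per_channel"),
        ("gfap_0_50", "cd68_0_50"),
        ("igg_50_100", "grid_distance"),
        ("cd68_50_100", "grip_force"),
    ]
    from trimodal.network import _pair_frame

    def measure(pairs, n_animals, seed0):
        C = np.eye(16)
        for a, c in pairs:
            i, j = variable_index(a), variable_index(c)
            C[i, j] = C[j, i] = 0.4
        acc = {p: [] for p in pairs}
        for seed in (seed0, seed0 + 1, seed0 + 2):
            cfg = tm.StudyConfig(n_animals=n_animals, rng_seed=seed,
                                 latent_correlation=C)
            b = tm.generate_study(cfg)
            cm, oc, _ = tm.recording_metrics(b.channel_units)
            bw = tm.behavior_weekly(b.behavior_trials)
            tables = tm.assemble(cfg, cm, oc, bw, b.histology_table)
            for p in pairs:
                df = _pair_frame(tables, *p)
                acc[p].append(abs(np.corrcoef(df.x, df.y)[0, 1]))
        return {p: np.mean(v) for p, v in acc.items()}

    got = measure(long_pairs, 63, 300)        # ~500 weekly units per seed
    got.update(measure(hist_pairs, 500, 310))  # 500 endpoint units
    for p, cc in got.items():
        assert abs(cc - 0.4) < 0.1, (p, cc)


# ---------------------------------------------------------------------------
# inject_spikes
# ---------------------------------------------------------------------------


def test_inject_rate_zero_is_pure_noise():
    tr = tm.inject_spikes(5.0, [tm.biphasic_template(100, 24414.0)], 0.0,
                          2.0, seed=1)
    assert tr.true_spike_times.size == 0
    assert np.std(tr.samples) == pytest.approx(5.0, rel=0.05)


def test_inject_event_count_in_poisson_band():
    tpl = tm.biphasic_template(100.0, 24414.0)
    counts = [len(tm.inject_spikes(10.0, [tpl], 5.0, 10.0,
                                   seed=s).true_spike_times)
              for s in range(20)]
    # Poisson(50): central 95% band is about [36, 64]
    assert np.mean(counts) == pytest.approx(50, abs=5)
    assert all(30 <= c <= 72 for c in counts)


def test_inject_noiseless_trace_is_sum_of_templates():
    fs = 24414.0
    tpl = tm.biphasic_template(80.0, fs)
    tr = tm.inject_spikes(0.0, [tpl], 3.0, 3.0, seed=2, fs=fs)
    recon = np.zeros_like(tr.samples, dtype=float)
    for t in tr.true_spike_times:
        end = min(t + tpl.size, recon.size)
        recon[t:end] += tpl[: end - t]
    assert np.allclose(tr.samples, recon, atol=1e-4)


def test_inject_respects_refractory_period():
    fs = 24414.0
    tr = tm.inject_spikes(1.0, [tm.biphasic_template(50, fs)], 200.0, 5.0,
                          seed=3, fs=fs)
    gaps = np.diff(tr.true_spike_times)
    assert gaps.min() >= int(round(1e-3 * fs))


def test_inject_rejects_unpackable_rate():
    with pytest.raises(ValueError, match="feasible maximum"):
        tm.inject_spikes(1.0, [tm.biphasic_template(50, 24414.0)], 2000.0,
                         1.0, seed=0)


def test_template_is_biphasic_with_requested_amplitude():
    tpl = tm.biphasic_template(120.0, 24414.0)
    assert tpl.max() - tpl.min() == pytest.approx(120.0)
    assert np.argmin(tpl) < np.argmax(tpl)  # negative peak leads


# ---------------------------------------------------------------------------
# render_histology_image
# ---------------------------------------------------------------------------


def test_flat_image_has_unit_normalized_profile():
    img = render_histology_image(intensity_profile=None, seed=5)
    prof = tm.normalize_profile(tm.bin_radial_intensity(img))
    assert np.nanmax(np.abs(prof.normalized - 1.0)) < 0.05


def test_rendered_image_is_deterministic():
    a = render_histology_image(
        intensity_profile=exponential_profile(1.0, 100.0), seed=9)
    b = render_histology_image(
        intensity_profile=exponential_profile(1.0, 100.0), seed=9)
    assert a.pixels.tobytes() == b.pixels.tobytes()


def test_planted_neuron_depletion_recovered():
    img = render_histology_image(
        neuron_density_profile=depletion_profile(1.0, 50.0),
        marker="NeuN", seed=11)
    prof = tm.neuron_density(img.neuron_points, img.implant_center,
                             img.pixels.shape, img.um_per_pixel)
    # d(r) = d_bg (1 - e^{-r/50}): the 0-50 um ring integrates well below
    # half of background
    assert prof.percent_of_background[0] < 50.0
    assert prof.percent_of_background[-2] == pytest.approx(100.0, abs=25)


def test_image_too_small_for_background_annulus_rejected():
    with pytest.raises(ValueError, match="1 mm"):
        render_histology_image(half_width_um=600.0, seed=1)


def test_study_images_carry_planted_band_targets(default_bundle):
    """Section images round-trip the per-animal histology targets."""
    b = default_bundle
    hp = b.histology_params
    # intensity markers have sub-percent pixel noise; NeuN inner-ring
    # percentages carry heavy counting noise (about 8 neurons in the
    # 0-50 um ring of one section), so only slice-averaged, looser checks
    # are meaningful there
    plan = {("GFAP", "0-50"): (3, 0.12), ("GFAP", "50-100"): (3, 0.12),
            ("NeuN", "0-50"): (6, 0.55), ("NeuN", "50-100"): (6, 0.25)}
    for (marker, dbin), (n_slices, rel_tol) in plan.items():
        vals = []
        for s in range(n_slices):
            img = b.histology_image("A1", marker, s)
            vals.append(tm.image_analysis_values(img, marker,
                                                 animal_id="A1")[dbin])
        target = float(hp[(hp.animal_id == "A1") & (hp.marker == marker)
                          & (hp.distance_bin == dbin)].target.iloc[0])
        expect = target if marker == "NeuN" else 50.0 * target
        assert np.mean(vals) == pytest.approx(expect, rel=rel_tol)
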