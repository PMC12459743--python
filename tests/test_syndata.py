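"""Generators: task design, behavior, nMVAR benchmark, mixing, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps
from scipy import stats as spstats

from eegconn import preprocess, syndata
from eegconn.syndata import ArtifactSpec


# ---------------------------------------------------------------------------
# task design
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_trials,go_frac,cong_frac,n_blocks",
    [(720, 0.7, 0.5, 6), (40, 0.5, 0.5, 2), (120, 0.7, 0.5, 1)],
)
def test_task_design_cell_counts_are_exact(n_trials, go_frac, cong_frac, n_blocks):
    design = syndata.generate_task_design(n_trials, go_frac, cong_frac, n_blocks,
                                          (1300, 1700), seed=3)
    counts = design.counts()
    assert sum(counts.values()) == n_trials
    expected = {
        ("go", "congruent"): n_trials * go_frac * cong_frac,
        ("go", "incongruent"): n_trials * go_frac * (1 - cong_frac),
        ("nogo", "congruent"): n_trials * (1 - go_frac) * cong_frac,
        ("nogo", "incongruent"): n_trials * (1 - go_frac) * (1 - cong_frac),
    }
    for cell, val in expected.items():
        assert counts[cell] == round(val)
    # exact per-block balance
    for b in range(1, n_blocks + 1):
        block = [t for t in design.trials if t.block == b]
        assert len(block) == n_trials // n_blocks
        for (ttype, cong), tot in expected.items():
            n_cell = sum(1 for t in block
                         if t.trial_type == ttype and t.congruency == cong)
            assert n_cell == round(tot) // n_blocks
    for t in design.trials:
        assert 1300 <= t.iti_ms <= 1700
        if t.trial_type == "nogo":
            assert t.correct_response == "none"


def test_default_design_matches_the_studied_paradigm():
    design = syndata.generate_task_design(seed=0)
    counts = design.counts()
    assert counts[("go", "congruent")] + counts[("go", "incongruent")] == 504
    assert counts[("nogo", "congruent")] + counts[("nogo", "incongruent")] == 216
    per_block = [sum(1 for t in design.trials if t.block == b) for b in range(1, 7)]
    assert per_block == [120] * 6


def test_empty_design():
    assert syndata.generate_task_design(0, 0.7, 0.5, 1, (1300, 1700), 0).trials == []


def test_non_integer_cell_count_is_rejected_with_cell_name():
    with pytest.raises(ValueError, match="congruent"):
        syndata.generate_task_design(10, 0.7, 0.5, 1, (1300, 1700), 0)


def test_design_reproducible_and_seed_sensitive():
    a = syndata.generate_task_design(n_trials=120, n_blocks=2, seed=9)
    b = syndata.generate_task_design(n_trials=120, n_blocks=2, seed=9)
    c = syndata.generate_task_design(n_trials=120, n_blocks=2, seed=10)
    assert a.to_frame().equals(b.to_frame())
    assert not a.to_frame().equals(c.to_frame())


def test_design_csv_round_trip(tmp_path):
    design = syndata.generate_task_design(n_trials=40, n_blocks=2, seed=1)
    path = tmp_path / "design.csv"
    design.to_csv(path)
    assert syndata.TaskDesign.from_csv(path).to_frame().equals(design.to_frame())


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _full_p(p_nogo_cong=0.85):
    return {"go_congruent": 0.95, "go_incongruent": 0.90,
            "nogo_congruent": p_nogo_cong, "nogo_incongruent": 0.90}


def test_certain_nogo_condition_yields_zero_false_alarms():
    design = syndata.generate_task_design(seed=2)
    records = syndata.simulate_behavior(design, _full_p(1.0), seed=4)
    by_index = {t.index: t for t in design.trials}
    for r in records:
        t = by_index[r.trial_index]
        if t.trial_type == "nogo" and t.congruency == "congruent":
            assert r.outcome == "correct_omission"


def test_nogo_accuracy_within_exact_binomial_interval():
    design = syndata.generate_task_design(seed=2)  # 108 Nogo-congruent trials
    records = syndata.simulate_behavior(design, _full_p(0.85), seed=11)
    by_index = {t.index: t for t in design.trials}
    n_corr = sum(1 for r in records
                 if by_index[r.trial_index].trial_type == "nogo"
                 and by_index[r.trial_index].congruency == "congruent"
                 and r.outcome == "correct_omission")
    lo = spstats.binom.ppf(0.005, 108, 0.85)
    hi = spstats.binom.ppf(0.995, 108, 0.85)
    assert lo <= n_corr <= hi


def test_simon_shift_moves_incongruent_go_reaction_times():
    design = syndata.generate_task_design(seed=2)
    records = syndata.simulate_behavior(
        design, _full_p(),
        rt_model={"mean_ms": 450.0, "sd_ms": 90.0, "simon_shift_ms": 30.0},
        seed=6,
    )
    by_index = {t.index: t for t in design.trials}
    rts = {"congruent": [], "incongruent": []}
    for r in records:
        t = by_index[r.trial_index]
        if t.trial_type == "go" and r.outcome == "hit":
            rts[t.congruency].append(r.rt_ms)
    diff = np.mean(rts["incongruent"]) - np.mean(rts["congruent"])
    se = 90.0 * np.sqrt(1 / len(rts["congruent"]) + 1 / len(rts["incongruent"]))
    assert abs(diff - 30.0) < 3 * se


def test_unknown_condition_key_rejected():
    design = syndata.generate_task_design(n_trials=40, n_blocks=1, seed=0)
    with pytest.raises(ValueError, match="unknown condition"):
        syndata.simulate_behavior(design, {"nogo_sideways": 0.5}, seed=0)


def test_behavior_reproducible():
    design = syndata.generate_task_design(n_trials=120, n_blocks=1, seed=0)
    a = syndata.simulate_behavior(design, _full_p(), seed=5)
    b = syndata.simulate_behavior(design, _full_p(), seed=5)
    assert a == b


# ---------------------------------------------------------------------------
# AR(2) carriers and the nMVAR generator
# ---------------------------------------------------------------------------

def test_ar2_closed_form_and_degenerate_cases():
    a1, a2 = syndata.ar2_coefficients(10.0, 256.0, 0.95)
    assert a1 == pytest.approx(1.8431, abs=5e-5)
    assert a2 == pytest.approx(-0.9025, abs=5e-5)
    assert syndata.ar2_coefficients(10.0, 256.0, 0.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        syndata.ar2_coefficients(10.0, 256.0, 1.0)
    with pytest.raises(ValueError):
        syndata.ar2_coefficients(200.0, 256.0, 0.5)


@pytest.mark.parametrize("peak_hz", [6.0, 10.0])
def test_ar2_spectral_peak_location(peak_hz):
    fs, L = 256.0, 2**14
    a1, a2 = syndata.ar2_coefficients(peak_hz, fs, 0.95)
    rng = np.random.default_rng(0)
    x = sps.lfilter([1.0], [1.0, -a1, -a2], rng.normal(size=L + 500))[500:]
    f, pxx = sps.welch(x, fs=fs, nperseg=2048)  # averaged periodogram
    assert abs(f[np.argmax(pxx)] - peak_hz) <= 0.5


def test_b1_linear_subsystem_is_stable(b1_system):
    assert b1_system.companion_spectral_radius() < 1.0


def test_decoupled_b1_channels_are_independent(b1_system):
    system = syndata.benchmark_b1()
    system.linear_coeffs[0, 1, 0] = 0.0
    system.nonlinear_terms = []
    L = 10_000
    src, edges = syndata.simulate_nmvar(system, L, seed=3)
    assert edges["linear"] == set() and edges["nonlinear"] == set()
    z = (src - src.mean(1, keepdims=True)) / src.std(1, keepdims=True)
    bound = 4.0 / np.sqrt(L)
    for i in range(3):
        for j in range(i + 1, 3):
            for lag in range(0, 4):
                r = np.mean(z[i, lag:] * z[j, : L - lag])
                assert abs(r) <= bound


def test_b1_ar2_variance_matches_closed_form(b1_system):
    src, _ = syndata.simulate_nmvar(b1_system, 10_000, seed=1)
    a1, a2 = 1.8431, -0.9025
    expected = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    assert np.var(src[0]) == pytest.approx(expected, rel=0.15)


def test_b1_nonlinear_edge_is_purely_even(b1_system):
    src, _ = syndata.simulate_nmvar(b1_system, 10_000, seed=1)
    z1 = (src[0] - src[0].mean()) / src[0].std()
    x3 = src[2]
    r_lin = np.corrcoef(x3[1:], z1[:-1])[0, 1]
    r_sq = np.corrcoef(x3[1:], z1[:-1] ** 2)[0, 1]
    assert abs(r_lin) < 0.1
    assert r_sq > 0.3


def test_unstable_system_rejected():
    coeffs = np.zeros((1, 2, 2))
    coeffs[0, 0, 0] = 1.05
    coeffs[0, 1, 1] = 0.5
    system = syndata.GroundTruthSystem(2, 1, coeffs)
    with pytest.raises(ValueError, match="unstable"):
        syndata.simulate_nmvar(system, 1000, seed=0)


def test_true_edge_lists_returned(b1_system):
    _, edges = syndata.simulate_nmvar(b1_system, 2000, seed=0)
    assert edges["linear"] == {(0, 1)}
    assert edges["nonlinear"] == {(0, 2)}


# ---------------------------------------------------------------------------
# mixing and artifacts
# ---------------------------------------------------------------------------

def test_identity_mixing_zero_noise_passes_sources_through():
    src = np.random.default_rng(0).normal(size=(3, 200))
    ep = syndata.mix_to_sensors(src, np.eye(3), 0.0, seed=0)
    assert np.allclose(ep.data[0], src)


def test_single_source_covariance_has_rank_one():
    src = np.random.default_rng(1).normal(size=(1, 2000))
    mixing = np.random.default_rng(2).normal(size=(8, 1))
    ep = syndata.mix_to_sensors(src, mixing, 0.0, seed=0)
    eigvals = np.linalg.eigvalsh(np.cov(ep.data[0]))
    assert eigvals[-1] > 1e-6
    assert np.all(eigvals[:-1] < 1e-10 * eigvals[-1])


def test_pseudoinverse_unmixing_recovers_sources():
    rng = np.random.default_rng(3)
    src = rng.normal(size=(3, 4000))
    mixing = rng.normal(size=(8, 3))
    ep = syndata.mix_to_sensors(src, mixing, 0.1, seed=4)
    rec = np.linalg.pinv(mixing) @ ep.data[0]
    for k in range(3):
        assert np.corrcoef(rec[k], src[k])[0, 1] > 0.95


def test_rank_deficient_mixing_warns():
    mixing = np.ones((4, 2))
    with pytest.warns(UserWarning, match="rank deficient"):
        syndata.mix_to_sensors(np.zeros((2, 50)), mixing, 0.0, seed=0)


def _clean_epochs(n_trials=10, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(1024) / 256.0
    data = 20.0 * np.sin(2 * np.pi * 10 * t)[None, None, :] * np.ones((n_trials, 4, 1))
    data = data + rng.normal(0, 2.0, size=(n_trials, 4, 1024))
    return syndata.EpochedSignal(data=data, fs_hz=256.0, t0_ms=-2000.0)


def test_empty_artifact_spec_is_a_bitwise_noop():
    epochs = _clean_epochs()
    out, bad = syndata.inject_artifacts(epochs, [], seed=0)
    assert bad == []
    assert np.array_equal(out.data, epochs.data)


def test_planted_spike_violates_amplitude_rule():
    epochs = _clean_epochs()
    out, bad = syndata.inject_artifacts(
        epochs, [ArtifactSpec(trial=3, kind="spike", amplitude_uv=300.0,
                              duration_ms=120.0)], seed=1)
    assert bad == [3]
    _, mask, report = preprocess.reject_epochs(out)
    assert not mask[3]
    assert report.loc[report.trial == out.trial_indices[3], "reason"].item() == "max-diff"


def test_rejection_recovers_exactly_the_planted_artifact_set():
    epochs = _clean_epochs(n_trials=10, seed=5)
    specs = [
        ArtifactSpec(trial=1, kind="spike", amplitude_uv=300.0, duration_ms=100.0),
        ArtifactSpec(trial=4, kind="flatline", duration_ms=150.0),
        ArtifactSpec(trial=8, kind="spike", amplitude_uv=400.0, duration_ms=80.0),
    ]
    out, bad = syndata.inject_artifacts(epochs, specs, seed=2)
    kept, mask, _ = preprocess.reject_epochs(out)
    assert bad == [1, 4, 8]
    assert sorted(np.flatnonzero(~mask).tolist()) == bad
    assert kept.n_trials == 7


def test_artifact_duration_longer_than_epoch_rejected():
    epochs = _clean_epochs(n_trials=2)
    with pytest.raises(ValueError, match="duration"):
        syndata.inject_artifacts(
            epochs, [ArtifactSpec(trial=0, kind="spike", duration_ms=9000.0)], seed=0)


# ---------------------------------------------------------------------------
# synthetic grid
# ---------------------------------------------------------------------------

def test_synthetic_grid_geometry_and_labels():
    grid = syndata.synthetic_source_grid(shape=(6, 6, 6), n_regions=4)
    assert grid.n_voxels == 216
    assert grid.leadfield.shape == (64, 216)
    assert set(grid.region_labels.astype(str)) == {f"region{k}" for k in range(4)}
    diffs = np.diff(np.unique(grid.voxel_positions[:, 0]))
    assert np.allclose(diffs, grid.voxel_edge_mm)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(1, 5), st.integers(1, 4))
def test_task_design_counts_closed_form_property(blocks, quarter_cells):
    # per-block cell count = quarter_cells for every cell -> all counts exact
    n = 4 * quarter_cells * blocks
    design = syndata.generate_task_design(n, 0.5, 0.5, blocks, (1300, 1700), seed=7)
    for count in design.counts().values():
        assert count == n // 4
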