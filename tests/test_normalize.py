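"""Spike-in normalization arithmetic, probe collapse, and measurement closed forms."""

import numpy as np
import pandas as pd
import pytest

from epiarray.arrayio import CY3, CY5, RawArraySet
from epiarray.errors import NormalizationError
from epiarray.normalize import (
    build_profile,
    expression_level,
    m6a_quantity,
    normalize_channel,
    read_profile,
    spikein_log2_mean,
    write_profile,
)
from epiarray.simdata import SimConfig, simulate_dataset

from conftest import make_raw


def spike_raw(spike_cy5_values, probe_cy5=(1024.0,)):
    """One sample per column; spike-ins share both channels for simplicity."""
    n_spike = len(spike_cy5_values)
    cy5 = np.array([[v] * 4 for v in list(probe_cy5) + list(spike_cy5_values)])
    return make_raw(cy5=cy5, cy3=cy5.copy(),
                    spikein=["none"] * len(probe_cy5) + ["pos"] * n_spike)


@pytest.mark.parametrize(
    "spikes, expected",
    [((1024.0, 1024.0), 10.0), ((512.0, 2048.0), 10.0), ((2.0,), 1.0)],
)
def test_spikein_log2_mean_is_mean_of_logs(spikes, expected):
    raw = spike_raw(spikes)
    assert spikein_log2_mean(raw, "s0", CY5) == pytest.approx(expected)


def test_spikein_mean_missing_spikes_is_error():
    raw = make_raw(cy5=[[1000.0] * 4], cy3=[[1000.0] * 4])  # no spike-in probes
    with pytest.raises(NormalizationError):
        spikein_log2_mean(raw, "s0", CY5)


def test_matched_policy_restricts_channels():
    cy5 = np.array([[1024.0] * 4, [4096.0] * 4, [256.0] * 4])
    raw = make_raw(cy5=cy5, cy3=cy5.copy(), spikein=["none", "pos", "neg"])
    assert spikein_log2_mean(raw, "s0", CY5, policy="matched") == pytest.approx(12.0)
    assert spikein_log2_mean(raw, "s0", CY3, policy="matched") == pytest.approx(8.0)
    assert spikein_log2_mean(raw, "s0", CY5, policy="all") == pytest.approx(10.0)


@pytest.mark.parametrize("raw_value, expected", [(1024.0, 0.0), (2048.0, 1.0)])
def test_normalize_channel_subtracts_anchor(raw_value, expected):
    raw = spike_raw((1024.0, 1024.0), probe_cy5=(raw_value,))
    norm = normalize_channel(raw, CY5)
    assert norm.loc["probe0", "s0"] == pytest.approx(expected)


def test_scaling_invariance_per_sample_per_channel(small_sim):
    """Multiplying every raw (spike-ins included) in one sample/channel leaves
    all normalized values unchanged."""
    _, raw, _ = small_sim
    scaled = RawArraySet(
        probes=raw.probes, samples=raw.samples,
        cy5=raw.cy5.assign(**{raw.sample_ids[0]: raw.cy5[raw.sample_ids[0]] * 4.0}),
        cy3=raw.cy3.assign(**{raw.sample_ids[2]: raw.cy3[raw.sample_ids[2]] * 7.5}),
        flags=raw.flags,
    )
    for channel in (CY5, CY3):
        a = normalize_channel(raw, channel)
        b = normalize_channel(scaled, channel)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12, equal_nan=True)


@pytest.mark.parametrize(
    "ip_values, expected_median",
    [((1.0, 3.0, 2.0), 2.0), ((1.0, 3.0), 2.0)],  # odd and even probe counts
)
def test_probe_collapse_by_median(ip_values, expected_median):
    n = len(ip_values)
    anchor = 1024.0
    cy5 = np.array([[anchor * 2.0**v] * 4 for v in ip_values] + [[anchor] * 4])
    raw = make_raw(cy5=cy5, cy3=np.full_like(cy5, anchor),
                   spikein=["none"] * n + ["pos"])
    raw.probes.loc[[f"probe{i}" for i in range(n)], "transcript_id"] = "tx_shared"
    profile = build_profile(raw)
    assert profile.m6a.loc["tx_shared", "s0"] == pytest.approx(expected_median)


def test_expression_is_channel_sum_and_symmetric():
    anchor = 1024.0
    cy5 = np.array([[anchor * 2.0**1.5] * 4, [anchor] * 4])
    cy3 = np.array([[anchor * 2.0**-0.5] * 4, [anchor] * 4])
    raw = make_raw(cy5=cy5, cy3=cy3, spikein=["none", "pos"])
    profile = build_profile(raw)
    assert expression_level(profile).loc["tx0", "s0"] == pytest.approx(1.0)
    assert m6a_quantity(profile).loc["tx0", "s0"] == pytest.approx(1.5)
    # swapping channels preserves the expression level but not the m6A quantity
    swapped = make_raw(cy5=cy3, cy3=cy5, spikein=["none", "pos"])
    sprof = build_profile(swapped)
    assert expression_level(sprof).loc["tx0", "s0"] == pytest.approx(1.0)
    assert m6a_quantity(sprof).loc["tx0", "s0"] == pytest.approx(-0.5)


def test_expression_missing_where_either_channel_missing():
    anchor = 1024.0
    cy5 = np.array([[anchor] * 4, [anchor] * 4])
    cy3 = np.array([[0.0, anchor, anchor, anchor], [anchor] * 4])  # 0 -> missing
    raw = make_raw(cy5=cy5, cy3=cy3, spikein=["none", "pos"])
    profile = build_profile(raw)
    assert np.isnan(expression_level(profile).loc["tx0", "s0"])
    assert m6a_quantity(profile).loc["tx0", "s0"] == pytest.approx(0.0)


def test_noise_free_group_differences_match_generative_closed_form():
    """In the low-noise limit the m6A-quantity group difference equals the
    planted log2 methylation-fraction change (plus any abundance shift), and
    the expression-level difference equals 2*de + log2(m2(1-m2)/(m1(1-m1)))."""
    cfg = SimConfig(n_transcripts={"mRNA": 60}, noise_sd=1e-9,
                    frac_dm_up=0.2, frac_dm_down=0.2, frac_de_up=0.1,
                    frac_de_down=0.1, frac_absent_flags=0.0, seed=13)
    raw, truth = simulate_dataset(cfg)
    profile = build_profile(raw)
    g1 = [s for s in profile.samples.index if profile.samples.loc[s, "group"] == cfg.group_names[0]]
    g2 = [s for s in profile.samples.index if profile.samples.loc[s, "group"] == cfg.group_names[1]]
    truth = truth.loc[profile.m6a.index]

    m6a_diff = profile.m6a[g2].mean(axis=1) - profile.m6a[g1].mean(axis=1)
    de = truth["abundance_log2_g2"] - truth["abundance_log2_g1"]
    expected_m6a = de + np.log2(truth["meth_frac_g2"] / truth["meth_frac_g1"])
    assert np.allclose(m6a_diff, expected_m6a, atol=1e-6)

    expr_diff = profile.expression[g2].mean(axis=1) - profile.expression[g1].mean(axis=1)
    expected_expr = 2.0 * de + np.log2(
        (truth["meth_frac_g2"] * (1 - truth["meth_frac_g2"]))
        / (truth["meth_frac_g1"] * (1 - truth["meth_frac_g1"]))
    )
    assert np.allclose(expr_diff, expected_expr, atol=1e-6)


def test_profile_round_trips_through_tsv(small_profile, tmp_path):
    write_profile(small_profile, tmp_path / "profile.tsv")
    back = read_profile(tmp_path / "profile.tsv", small_profile.samples)
    pd.testing.assert_frame_equal(back.m6a, small_profile.m6a)
    pd.testing.assert_frame_equal(back.expression, small_profile.expression)
    pd.testing.assert_frame_equal(back.transcripts, small_profile.transcripts)
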