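import numpy as np
import pandas as pd
import pytest

from dyadsync.dtw import dtw_align
from dyadsync.errors import TruncationError, ValidationError
from dyadsync.preprocess import HemoSeries
from dyadsync.schedule import SEQUENCES
from dyadsync.synchrony import (
    CHANNEL_ROI,
    aggregate_roi_condition,
    compute_dyad_synchrony,
    segment_blocks,
)

FS = 7.81


def _hemo(channels, n=9512, seed=0):
    rng = np.random.default_rng(seed)
    hbo = {ch: rng.normal(size=n) for ch in channels}
    hbr = {ch: -hbo[ch] / 3 for ch in channels}
    return HemoSeries(sampling_rate=FS, hbo=hbo, hbr=hbr)


def test_segment_arithmetic(schedule_a):
    hemo = _hemo([4, 13])
    seg = segment_blocks(hemo, schedule_a)
    assert seg.conditions == SEQUENCES["A"]
    for ch in (4, 13):
        assert seg.segments[ch].shape == (7, 890)  # floor(114 * 7.81)
    start = int(60 * FS)  # floor -> 468
    assert start == 468
    np.testing.assert_array_equal(seg.segments[4][0], hemo.hbo[4][468 : 468 + 890])


def test_segment_signal_choice(schedule_a):
    hemo = _hemo([4])
    hbr_seg = segment_blocks(hemo, schedule_a, signal="hbr")
    np.testing.assert_array_equal(hbr_seg.segments[4][0], hemo.hbr[4][468 : 468 + 890])
    with pytest.raises(ValidationError):
        segment_blocks(hemo, schedule_a, signal="both")


def test_segment_overrun(schedule_a):
    with pytest.raises(TruncationError, match="neutral"):
        segment_blocks(_hemo([4], n=9000), schedule_a)


def test_identical_subjects_zero_distance(schedule_a):
    hemo = _hemo([4, 6, 13])
    table = compute_dyad_synchrony(hemo, hemo, schedule_a, dyad_id="d0")
    assert len(table) == 3 * 7
    assert np.all(table["normalized_distance"] == 0)


def test_synchrony_matches_looped_alignments(schedule_a):
    hemo_a = _hemo([4, 13], seed=1)
    hemo_b = _hemo([4, 13], seed=2)
    table = compute_dyad_synchrony(hemo_a, hemo_b, schedule_a, dyad_id="d0")
    seg_a = segment_blocks(hemo_a, schedule_a)
    seg_b = segment_blocks(hemo_b, schedule_a)
    for _, row in table.iterrows():
        ref = dtw_align(
            seg_a.segments[row.channel][row.block_index],
            seg_b.segments[row.channel][row.block_index],
        ).normalized_distance
        assert row.normalized_distance == pytest.approx(ref, rel=1e-12)


def test_missing_channel_produces_no_rows(schedule_a):
    table = compute_dyad_synchrony(
        _hemo([4, 13], seed=1), _hemo([13], seed=2), schedule_a, dyad_id="d0"
    )
    assert set(table["channel"]) == {13}
    with pytest.warns(UserWarning, match="no common"):
        empty = compute_dyad_synchrony(
            _hemo([4], seed=1), _hemo([13], seed=2), schedule_a, dyad_id="d0"
        )
    assert empty.empty


# ---------------------------------------------------------------------------
# ROI x condition aggregation
# ---------------------------------------------------------------------------

def _toy_table(distances):
    """Build a synchrony table from {(channel, condition): distance}."""
    rows = []
    for k, ((ch, cond), d) in enumerate(distances.items()):
        rows.append(
            {
                "dyad_id": "d0",
                "channel": ch,
                "block_index": k,
                "condition": cond,
                "normalized_distance": d,
            }
        )
    return pd.DataFrame(rows)


def test_roi_membership():
    assert {ch for ch, roi in CHANNEL_ROI.items() if roi == "frontal_left"} == {4, 6, 7, 11}
    assert {ch for ch, roi in CHANNEL_ROI.items() if roi == "frontal_right"} == {13, 14, 16, 19}


def test_aggregate_constant_distances():
    table = _toy_table(
        {(ch, cond): 0.42 for ch in (4, 6, 13, 14) for cond in ("love", "fear", "neutral")}
    )
    out = aggregate_roi_condition(table)
    assert np.allclose(out["index"], 0.42)
    assert set(zip(out["roi"], out["condition"])) == {
        (roi, cond)
        for roi in ("frontal_left", "frontal_right")
        for cond in ("positive", "negative", "baseline")
    }


def test_right_index_uses_right_channels_only():
    """Hand-computed mean: left-channel distances cannot leak into the right ROI."""
    table = _toy_table(
        {
            (13, "love"): 0.2,
            (14, "love"): 0.4,
            (4, "love"): 99.0,
            (13, "fear"): 0.6,
        }
    )
    out = aggregate_roi_condition(table)
    right_pos = out[(out.roi == "frontal_right") & (out.condition == "positive")]["index"]
    assert right_pos.item() == pytest.approx(0.3)  # mean(0.2, 0.4)
    right_neg = out[(out.roi == "frontal_right") & (out.condition == "negative")]["index"]
    assert right_neg.item() == pytest.approx(0.6)
    # dropping a left channel leaves the right index unchanged
    out2 = aggregate_roi_condition(table[table.channel != 4])
    assert (
        out2[(out2.roi == "frontal_right") & (out2.condition == "positive")]["index"].item()
        == right_pos.item()
    )


def test_mean_of_means_order():
    """Channels average within block first, then blocks within condition."""
    table = pd.DataFrame(
        [
            # block 0 (love): channels 13, 14 -> mean 0.3
            {"dyad_id": "d0", "channel": 13, "block_index": 0, "condition": "love",
             "normalized_distance": 0.2},
            {"dyad_id": "d0", "channel": 14, "block_index": 0, "condition": "love",
             "normalized_distance": 0.4},
            # block 1 (pride): channel 13 only -> 0.8
            {"dyad_id": "d0", "channel": 13, "block_index": 1, "condition": "pride",
             "normalized_distance": 0.8},
        ]
    )
    out = aggregate_roi_condition(table)
    # mean of block means: (0.3 + 0.8) / 2, not pooled mean of 3 rows
    assert out["index"].item() == pytest.approx(0.55)


def test_aggregation_permutation_invariant(rng):
    table = _toy_table(
        {(ch, cond): rng.random() for ch in (4, 6, 13) for cond in ("love", "fear")}
    )
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = aggregate_roi_condition(table).sort_values(["roi", "condition"]).reset_index(drop=True)
    b = aggregate_roi_condition(shuffled).sort_values(["roi", "condition"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_satisfaction_column_attached():
    table = _toy_table({(13, "love"): 0.1, (13, "fear"): 0.2, (13, "neutral"): 0.3})
    out = aggregate_roi_condition(table, satisfaction_difference={"d0": 0.58})
    assert np.allclose(out["satisfaction_difference"], 0.58)


def test_empty_table_rejected():
    with pytest.raises(ValidationError):
        aggregate_roi_condition(pd.DataFrame(columns=["dyad_id"]))
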