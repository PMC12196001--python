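"""Per-block synchrony indexes and ROI x condition aggregation.

Each 114 s video block is cut out of both subjects' preprocessed series and
scored with the normalized DTW distance, channel by channel.  Channel
indexes are averaged into the two prefrontal regions of interest and block
indexes into the three emotion conditions (positive, negative, baseline),
giving one index per dyad x ROI x condition.  Throughout, a larger index
means less interpersonal synchrony.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dtw import batch_normalized_distance, normalized_distance
from .errors import TruncationError, ValidationError
from .preprocess import HemoSeries
from .schedule import CONDITION_CATEGORY, EventSchedule

logger = logging.getLogger(__name__)

#: Channel -> region-of-interest map of the ventral-PFC montage.
CHANNEL_ROI: dict[int, str] = {
    4: "frontal_left",
    6: "frontal_left",
    7: "frontal_left",
    11: "frontal_left",
    13: "frontal_right",
    14: "frontal_right",
    16: "frontal_right",
    19: "frontal_right",
}

#: Finer anatomical labels of the same channels.
CHANNEL_SUBREGION: dict[int, str] = {
    4: "VLPFC_left",
    19: "VLPFC_right",
    7: "VMPFC_left",
    14: "VMPFC_right",
    6: "OFC_left",
    11: "OFC_left",
    13: "OFC_right",
    16: "OFC_right",
}

ROIS = ("frontal_left", "frontal_right")
CONDITIONS = ("positive", "negative", "baseline")


@dataclass
class SegmentedBlocks:
    """Video-block segments of one subject: ``segments[ch][k]`` is block k."""

    conditions: tuple[str, ...]
    segments: dict[int, np.ndarray]  # channel -> (n_blocks, seg_len)
    sampling_rate: float


def segment_blocks(
    hemo: HemoSeries, schedule: EventSchedule, signal: str = "hbo"
) -> SegmentedBlocks:
    """Cut the video blocks out of a preprocessed series.

    Block k covers samples ``[floor(onset*fs), floor(onset*fs) + floor(114*fs))``
    (floor-aligned, half-open); fixation periods are not segmented.  The DTW
    input signal is dHbO by default (``signal`` may be ``"hbo"``, ``"hbr"``
    or ``"mean"`` for the average of both species).
    """
    fs = hemo.sampling_rate
    n = hemo.n_samples
    starts, lengths, conditions = [], [], []
    for block in schedule.video_blocks:
        start = int(math.floor(block.onset_s * fs))
        length = int(math.floor(block.duration_s * fs))
        if start + length > n:
            raise TruncationError(
                f"block {block.condition!r} at {block.onset_s} s needs samples "
                f"up to {start + length} but the series has {n}"
            )
        starts.append(start)
        lengths.append(length)
        conditions.append(block.condition)
    segments: dict[int, np.ndarray] = {}
    for ch in hemo.channels:
        if signal == "hbo":
            x = hemo.hbo[ch]
        elif signal == "hbr":
            x = hemo.hbr[ch]
        elif signal == "mean":
            x = 0.5 * (hemo.hbo[ch] + hemo.hbr[ch])
        else:
            raise ValidationError(f"unknown DTW input signal {signal!r}")
        segments[ch] = np.stack(
            [x[s : s + l] for s, l in zip(starts, lengths)], axis=0
        )
    return SegmentedBlocks(tuple(conditions), segments, fs)


def compute_dyad_synchrony(
    hemo_a: HemoSeries,
    hemo_b: HemoSeries,
    schedule: EventSchedule,
    dyad_id: str = "dyad",
    signal: str = "hbo",
    window: int | None = None,
) -> pd.DataFrame:
    """Normalized DTW distance per common channel and video block.

    Returns a long table with columns ``dyad_id, channel, block_index,
    condition, normalized_distance``.  Channels retained in only one subject
    produce no rows (missing, never zero).
    """
    common = sorted(set(hemo_a.channels) & set(hemo_b.channels))
    if not common:
        warnings.warn(f"dyad {dyad_id}: no common retained channels", stacklevel=2)
        return pd.DataFrame(
            columns=["dyad_id", "channel", "block_index", "condition", "normalized_distance"]
        )
    seg_a = segment_blocks(hemo_a, schedule, signal=signal)
    seg_b = segment_blocks(hemo_b, schedule, signal=signal)
    n_blocks = len(seg_a.conditions)
    X = np.concatenate([seg_a.segments[ch] for ch in common], axis=0)
    Y = np.concatenate([seg_b.segments[ch] for ch in common], axis=0)
    if window is None:
        dist = batch_normalized_distance(X, Y)
    else:
        dist = np.array(
            [normalized_distance(x, y, window=window) for x, y in zip(X, Y)]
        )
    rows = {
        "dyad_id": np.repeat(dyad_id, len(common) * n_blocks),
        "channel": np.repeat(common, n_blocks),
        "block_index": np.tile(np.arange(n_blocks), len(common)),
        "condition": np.tile(seg_a.conditions, len(common)),
        "normalized_distance": dist,
    }
    return pd.DataFrame(rows)


def aggregate_roi_condition(
    table: pd.DataFrame,
    roi_map: dict[int, str] | None = None,
    satisfaction_difference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate channel x block indexes to dyad x ROI x condition.

    Within each block the retained channels of an ROI are averaged with
    equal weight, then block indexes are averaged within each emotion
    condition (mean of means).  A (dyad, ROI) cell with no retained channel
    is absent from the output and logged.  Columns: ``dyad_id, roi,
    condition, index, n_channels_used`` plus ``satisfaction_difference``
    when a per-dyad mapping is given.
    """
    if table.empty:
        raise ValidationError("synchrony table is empty; nothing to aggregate")
    roi_map = CHANNEL_ROI if roi_map is None else roi_map
    df = table.copy()
    df["roi"] = df["channel"].map(roi_map)
    df["condition_category"] = df["condition"].map(CONDITION_CATEGORY)
    per_block = (
        df.groupby(["dyad_id", "roi", "condition_category", "block_index"], observed=True)
        .agg(index=("normalized_distance", "mean"), n_channels_used=("channel", "nunique"))
        .reset_index()
    )
    out = (
        per_block.groupby(["dyad_id", "roi", "condition_category"], observed=True)
        .agg(index=("index", "mean"), n_channels_used=("n_channels_used", "min"))
        .reset_index()
        .rename(columns={"condition_category": "condition"})
    )
    for dyad in out["dyad_id"].unique():
        present = set(out.loc[out["dyad_id"] == dyad, "roi"])
        for roi in ROIS:
            if roi not in present:
                logger.info("dyad %s: ROI %s has no retained channels; cell missing", dyad, roi)
    if satisfaction_difference is not None:
        out["satisfaction_difference"] = out["dyad_id"].map(satisfaction_difference)
    return out.sort_values(["dyad_id", "roi", "condition"]).reset_index(drop=True)
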