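"""In-memory containers for raw dyadic fNIRS recordings."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import MarkerMissingError, ValidationError
from .ras import RASResponse

#: The eight prefrontal channels entering the analysis (ventral PFC montage).
ANALYSIS_CHANNELS = (4, 6, 7, 11, 13, 14, 16, 19)
WAVELENGTHS_NM = (760, 850)


@dataclass
class SubjectRecording:
    """One subject's per-channel two-wavelength optical-density series.

    ``od[channel][wavelength_nm]`` is a 1-D float array; ``gain`` is the
    per-channel amplifier gain and ``cv[channel][wavelength_nm]`` the
    coefficient of variation (percent) reported for that channel.
    """

    label: str
    od: dict[int, dict[int, np.ndarray]]
    gain: dict[int, float]
    cv: dict[int, dict[int, float]]
    ras: Optional[RASResponse] = None

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted(self.od))


@dataclass
class RawDyadRecording:
    """Two subjects' simultaneous recordings plus markers and metadata."""

    dyad_id: str
    sequence_label: str
    sampling_rate: float
    subjects: tuple[SubjectRecording, SubjectRecording]
    video_onsets_s: tuple[float, ...]
    #: Simulator ground truth (e.g. drawn coupling strength); None for real data.
    sim_truth: Optional[dict] = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_samples(self) -> int:
        subj = self.subjects[0]
        ch = subj.channels[0]
        return int(next(iter(subj.od[ch].values())).size)

    def validate(self) -> None:
        if len(self.subjects) != 2:
            raise ValidationError(
                f"dyad {self.dyad_id}: expected 2 subjects, got {len(self.subjects)}"
            )
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if len(self.video_onsets_s) == 0:
            raise MarkerMissingError(
                f"dyad {self.dyad_id}: no video-onset markers present"
            )
        lengths = set()
        for subj in self.subjects:
            if not subj.od:
                raise ValidationError(f"subject {subj.label}: no channels present")
            for ch, by_wl in subj.od.items():
                for wl in WAVELENGTHS_NM:
                    if wl not in by_wl:
                        raise ValidationError(
                            f"subject {subj.label} channel {ch}: wavelength {wl} nm missing"
                        )
                    lengths.add(int(by_wl[wl].size))
        if len(lengths) != 1:
            raise ValidationError(
                f"dyad {self.dyad_id}: series lengths differ across "
                f"subjects/channels: {sorted(lengths)}"
            )


def recordings_equal(a: RawDyadRecording, b: RawDyadRecording) -> bool:
    """Exact equality of two recordings (arrays compared element-wise)."""
    if (
        a.dyad_id != b.dyad_id
        or a.sequence_label != b.sequence_label
        or a.sampling_rate != b.sampling_rate
        or a.video_onsets_s != b.video_onsets_s
    ):
        return False
    for sa, sb in zip(a.subjects, b.subjects):
        if sa.label != sb.label or sa.ras != sb.ras:
            return False
        if set(sa.od) != set(sb.od) or sa.gain != sb.gain or sa.cv != sb.cv:
            return False
        for ch in sa.od:
            for wl in WAVELENGTHS_NM:
                if not np.array_equal(sa.od[ch][wl], sb.od[ch][wl]):
                    return False
    return True
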