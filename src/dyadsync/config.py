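"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, (de)serialisable to YAML.

    ``input_source`` selects simulation (``synthetic``) or reading a cohort
    directory of the native CSV dialect (``files``).  Preprocessing and DTW
    parameters mirror :class:`~dyadsync.preprocess.PreprocessParams` and the
    DTW module; coupling parameters feed the simulator's satisfaction ->
    coupling link.
    """

    input_source: str = "synthetic"
    input_dir: Optional[str] = None
    seed: int = 0
    n_dyads: int = 15
    # preprocessing
    gain_max: float = 8.0
    cv_max: float = 7.5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.2
    filter_order: int = 3
    despike_window_s: float = 1.0
    despike_k: float = 5.0
    # DTW
    dtw_signal: str = "hbo"
    dtw_step_pattern: str = "symmetric2"
    dtw_window: Optional[int] = None
    # channel -> ROI map override; None uses the ventral-PFC default
    channel_roi_map: Optional[dict] = None
    # statistics
    kw_roi: str = "frontal_right"
    # simulator link (used when input_source == "synthetic")
    coupling_beta0: float = 0.2
    coupling_beta1: float = 0.35
    coupling_sigma: float = 0.05
    sampling_rate: float = 7.81
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.input_source not in ("synthetic", "files"):
            raise ParameterError(
                f"input_source must be 'synthetic' or 'files', got {self.input_source!r}"
            )
        if self.input_source == "files" and not self.input_dir:
            raise ParameterError("input_source 'files' requires input_dir")
        nyquist = self.sampling_rate / 2.0
        if not 0 < self.band_low_hz < self.band_high_hz < nyquist:
            raise ParameterError(
                f"band edges must satisfy 0 < low < high < Nyquist ({nyquist} Hz); "
                f"got ({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.gain_max <= 0 or self.cv_max <= 0:
            raise ParameterError("gain_max and cv_max must be > 0")
        if self.dtw_signal not in ("hbo", "hbr", "mean"):
            raise ParameterError(f"unknown dtw_signal {self.dtw_signal!r}")
        if self.dtw_step_pattern != "symmetric2":
            raise ParameterError(
                f"unsupported dtw_step_pattern {self.dtw_step_pattern!r}; "
                "only 'symmetric2' is implemented"
            )
        if self.channel_roi_map is not None:
            self.channel_roi_map = {int(k): str(v) for k, v in self.channel_roi_map.items()}

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
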