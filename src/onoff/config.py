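"""Pipeline configuration.

Every numeric constant of the detection pipeline lives here with its
default, so a single JSON file fully determines a run.  Unknown keys are
rejected; values are schema-validated by pydantic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

# Filter-bank edges (Hz) for the walk-classifier features: 8 roughly
# log-spaced bands covering 0-15 Hz.
DEFAULT_FEATBANK = [0.0, 0.5, 1.0, 2.0, 3.25, 5.0, 7.5, 10.5, 15.0]


class PipelineConfig(BaseModel):
    """All constants of the On/Off detection pipeline.

    The two band-power thresholds ``tau_pt`` and ``tau_dysk`` are global
    (identical for every patient); their defaults were calibrated once on
    the synthetic corpus by maximising Youden's J for their respective
    detection tasks and then frozen.
    """

    model_config = ConfigDict(extra="forbid")

    fs: float = Field(default=40.0, gt=0, description="sampling rate, Hz")
    window_s: float = Field(default=3.2, gt=0, description="segment length, s")
    featbank: list[float] = Field(default_factory=lambda: list(DEFAULT_FEATBANK))

    # stride / fluidity
    fluidity_band: tuple[float, float] = (0.0, 10.0)
    stride_min_s: float = 0.4
    stride_max_s: float = 2.4
    stride_lowpass_hz: float = 10.0
    contact_coincidence_s: float = 0.1
    contact_refractory_s: float = 0.4

    # bradykinesia thresholding / classification
    intermediate_halfwidth: float = 1.7  # m/s^2
    bimodal_min_mass: float = 0.15
    shoulder_density_ratio: float = 0.60
    min_strides_for_threshold: int = 30
    bradykinesia_low_fluidity: bool = True

    # dyskinesia
    pt_band: tuple[float, float] = (0.1, 0.6)
    tau_pt: float = 0.158  # (m/s^2)^2, frozen synthetic-corpus calibration
    dysk_band: tuple[float, float] = (1.0, 4.0)
    tau_dysk: float = 0.849  # (m/s^2)^2, frozen synthetic-corpus calibration
    minute_min_analyzable_ratio: float = 0.30
    minute_positive_ratio: float = 0.40
    period_undetermined_min: int = 8

    # motor-state fusion
    triple_stride: int = Field(default=1, description="gap-fill window stride (1 or 3)")

    # walk SVM
    svm_c: float = 1.0
    svm_gamma: str | float = "auto"  # 'auto' == 1/n_features

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if sorted(self.featbank) != list(self.featbank) or len(self.featbank) < 2:
            raise ValueError("featbank must be an increasing list of >= 2 edges")
        for name in ("fluidity_band", "pt_band", "dysk_band"):
            lo, hi = getattr(self, name)
            if not (0 <= lo < hi):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi")
        if self.triple_stride not in (1, 3):
            raise ValueError("triple_stride must be 1 or 3")
        return self

    @property
    def samples_per_segment(self) -> int:
        return int(self.fs * self.window_s)

    def feature_spec_hash(self) -> str:
        """Hash of everything that shapes the feature vector."""
        payload = json.dumps(
            {"fs": self.fs, "window_s": self.window_s, "featbank": self.featbank},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a JSON config; absent keys take the defaults above.

    An empty file or ``None`` yields the full default configuration.
    Unknown keys and out-of-range values raise with a key-level message.
    """
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text().strip()
    data = json.loads(raw) if raw else {}
    return PipelineConfig(**data)
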