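"""Study configuration: one structured document controlling every stage.

The configuration is validated before any computation and serialised next
to the outputs so a run can be reproduced exactly from its artefacts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .airway import AirwayConfig
from .phantom import CohortRanges, PhantomParams, ReconParams
from .segmentation import SegmentationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed for a simulate → reconstruct → measure → compare run.

    ``noise_sigma_hu`` is the full (FBP) image noise; the iterative
    reconstruction renders the same noise field scaled by
    ``1 - ir_noise_reduction``.
    """

    n_subjects: int = 30
    seed: int = 0
    base_phantom: PhantomParams = field(default_factory=PhantomParams)
    cohort_ranges: CohortRanges = field(default_factory=CohortRanges)
    noise_sigma_hu: float = 80.0
    ir_noise_reduction: float = 0.45
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    airway: AirwayConfig = field(default_factory=AirwayConfig)

    def recon_params(self) -> tuple[ReconParams, ReconParams]:
        return (
            ReconParams.fbp(self.noise_sigma_hu),
            ReconParams.idose(self.noise_sigma_hu, self.ir_noise_reduction),
        )

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        self.base_phantom.validate()
        self.cohort_ranges.validate()
        for recon in self.recon_params():
            recon.validate()

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def _tupled(d: dict) -> dict:
            return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}

        kwargs = dict(raw)
        if "base_phantom" in kwargs:
            kwargs["base_phantom"] = PhantomParams(**_tupled(kwargs["base_phantom"]))
        if "cohort_ranges" in kwargs:
            kwargs["cohort_ranges"] = CohortRanges(**_tupled(kwargs["cohort_ranges"]))
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationConfig(**kwargs["segmentation"])
        if "airway" in kwargs:
            kwargs["airway"] = AirwayConfig(**kwargs["airway"])
        config = cls(**kwargs)
        config.validate()
        return config
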