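"""Single-document JSON run configuration.

One :class:`RunConfig` describes a complete experiment: head model, source
space, ROI, simulation conditions, SNR grid, channel-optimization scenarios
and the classification protocol.  Unknown keys are rejected so a typo cannot
silently fall back to a default.  Every random draw in a run derives from
``seed`` through named spawn streams (see :mod:`esiopt.pipeline`).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HeadModelConfig(_Strict):
    montage_system: Literal["10-05", "10-10"] = "10-05"
    scalp_radius: float = 0.100
    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)
    conductivities: tuple[float, float, float] = (0.3, 0.006, 0.3)
    series_terms: int = 100
    n_per_hemisphere: int = 4098
    cortex_radius: float = 0.078
    z_min: float = -0.02


class RoiConfig(_Strict):
    k: int = 20
    markers: list[list[float]] | None = None  # None -> C3/C4 hand-knob stand-ins


class SimulationConfig(_Strict):
    duration: float = 2.0
    sfreq: float = 250.0
    epochs_per_source: int = 2
    background_ratio: float = 0.10
    background_min_dist: float = 0.03
    snr_grid: tuple[float, ...] = (10.0, 5.0, 0.0)


class GaRunConfig(_Strict):
    population_size: int = 100
    n_generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    esi_method: Literal["sloreta", "wmne"] = "sloreta"
    scenarios: tuple[str, ...] = ("ten10", "none", "symmetric")
    cascade_counts: tuple[int, ...] = (32, 16, 8)
    snr_db: float = 0.0  # dataset the optimization runs on


class ClassifyConfig(_Strict):
    n_trials_per_class: int = 60
    erd_depth: float = 0.5
    classifiers: tuple[str, ...] = ("rf", "svm", "lda")
    spaces: tuple[str, ...] = ("electrode", "source")
    n_csp_components: int = 6
    n_repeats: int = 10
    test_frac: float = 0.3


class RunConfig(_Strict):
    seed: int = 0
    headmodel: HeadModelConfig = Field(default_factory=HeadModelConfig)
    roi: RoiConfig = Field(default_factory=RoiConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    optimization: GaRunConfig = Field(default_factory=GaRunConfig)
    classification: ClassifyConfig = Field(default_factory=ClassifyConfig)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        """Load from a path, or parse directly when given JSON text."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        return cls.model_validate(json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
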