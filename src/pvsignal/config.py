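"""Configuration objects for the simulator and the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml


class ValidationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class DemographicSpec:
    """Marginal distributions for the simulated report demographics.

    Probabilities describe a spontaneous-reporting population: heavy
    missingness in age (~50%) and weight (~80%) is the norm, sex skews
    female for antidepressant cohorts.
    """

    p_sex: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.608, "M": 0.266, "": 0.126}
    )
    p_age_missing: float = 0.497
    age_mean_years: float = 45.0
    age_sd_years: float = 18.0
    p_weight_missing: float = 0.801
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 18.0
    p_reporter: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.499, "MD": 0.261, "OT": 0.070, "PH": 0.026, "": 0.144}
    )
    p_outcome: Mapping[str, float] = field(
        default_factory=lambda: {
            "CA": 0.001, "DE": 0.031, "DS": 0.015, "HO": 0.112, "LT": 0.016, "OT": 0.825,
        }
    )

    def validate(self) -> None:
        for name, dist in (("p_sex", self.p_sex), ("p_reporter", self.p_reporter),
                           ("p_outcome", self.p_outcome)):
            probs = np.asarray(list(dist.values()), dtype=float)
            if np.any(probs < 0) or np.any(probs > 1):
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1 (got {probs.sum():.6f})")
        for name, p in (("p_age_missing", self.p_age_missing),
                        ("p_weight_missing", self.p_weight_missing)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic spontaneous-report generator.

    ``planted_rr`` maps ``(drug_index, event_index)`` to the relative
    reporting rate of that event under that suspect drug; unlisted pairs
    default to 1 (no disproportionality). ``onset_shape``/``onset_scale_days``
    parameterise the Weibull time-to-onset distribution; the default shape
    0.58 gives the early-failure hazard typical of antidepressant adverse
    events, with a scale chosen so the median onset sits near two weeks.
    """

    n_reports: int = 20_000
    n_drugs: int = 20
    n_events: int = 30
    baseline_event_probs: tuple[float, ...] | None = None
    planted_rr: Mapping[tuple[int, int], float] = field(default_factory=dict)
    duplicate_rate: float = 0.10
    onset_shape: float = 0.58
    onset_scale_days: float = 30.0
    mean_events_per_report: float = 2.0
    demographic_spec: DemographicSpec = field(default_factory=DemographicSpec)
    quarters: tuple[str, ...] = ("2014Q1", "2014Q2", "2014Q3", "2014Q4")
    seed: int = 0

    def event_probs(self) -> np.ndarray:
        if self.baseline_event_probs is None:
            return np.full(self.n_events, 1.0 / self.n_events)
        return np.asarray(self.baseline_event_probs, dtype=float)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValidationError("n_reports must be non-negative")
        if self.n_drugs < 1 or self.n_events < 1:
            raise ValidationError("n_drugs and n_events must be positive")
        probs = self.event_probs()
        if len(probs) != self.n_events:
            raise ValidationError("baseline_event_probs length must equal n_events")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValidationError("baseline_event_probs must lie in [0, 1]")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValidationError(
                f"baseline_event_probs must sum to 1 (got {probs.sum():.9f})"
            )
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValidationError("duplicate_rate must lie in [0, 1]")
        if self.onset_shape <= 0 or self.onset_scale_days <= 0:
            raise ValidationError("Weibull onset shape and scale must be positive")
        for (drug, event), rr in self.planted_rr.items():
            if rr < 0:
                raise ValidationError(f"planted_rr[{(drug, event)}] must be >= 0")
            if not (0 <= drug < self.n_drugs and 0 <= event < self.n_events):
                raise ValidationError(f"planted_rr key {(drug, event)} out of range")
        self.demographic_spec.validate()


@dataclass(frozen=True)
class SignalThresholds:
    """Per-algorithm positivity criteria; the combined positive signal is
    the conjunction of all four."""

    min_count: int = 3          # a >= 3 gates ROR and PRR
    ror_lo95: float = 1.0       # lower 95% CI bound must exceed this
    prr_min: float = 2.0
    prr_chisq_min: float = 4.0
    ic025_min: float = 0.0      # strict: ic025 > 0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (mirrors the CLI/YAML surface)."""

    input_dir: Path
    output_dir: Path
    quarters: tuple[str, ...]
    synonyms: tuple[str, ...]
    pt_soc_map_path: Path | None = None
    suicide_pt_path: Path | None = None
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    zero_cell_policy: str = "undefined"     # or "haldane" (+0.5)
    yates_correction: bool = False
    tto_event_filter: tuple[str, ...] | None = None   # None = all PTs
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        required = ("input_dir", "output_dir", "quarters", "synonyms")
        for key in required:
            if key not in raw:
                raise ValidationError(f"pipeline config missing required key: {key!r}")
        thresholds = SignalThresholds(**raw.pop("thresholds", {}))
        kwargs: dict[str, Any] = {
            "input_dir": Path(raw.pop("input_dir")),
            "output_dir": Path(raw.pop("output_dir")),
            "quarters": tuple(raw.pop("quarters")),
            "synonyms": tuple(raw.pop("synonyms")),
            "thresholds": thresholds,
        }
        for key in ("pt_soc_map_path", "suicide_pt_path"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw.pop(key))
            else:
                raw.pop(key, None)
        if raw.get("tto_event_filter") is not None:
            kwargs["tto_event_filter"] = tuple(raw.pop("tto_event_filter"))
        else:
            raw.pop("tto_event_filter", None)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for key in ("input_dir", "output_dir", "pt_soc_map_path", "suicide_pt_path"):
            if d[key] is not None:
                d[key] = str(d[key])
        d["quarters"] = list(d["quarters"])
        d["synonyms"] = list(d["synonyms"])
        if d["tto_event_filter"] is not None:
            d["tto_event_filter"] = list(d["tto_event_filter"])
        return d
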