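"""Layered run configuration: defaults < YAML config file < CLI flags.

The flat key namespace mirrors the pipeline stages::

    filter.order, filter.low_hz, filter.high_hz, filter.zero_phase
    envelope.fir_length, envelope.backend
    emd.levels, emd.sd_threshold, emd.max_sift_iterations
    normalize.mode
    decimate.factor
    model.architecture, model.hidden_units, model.learning_rate,
    model.epochs, model.batch_size, model.train_fraction, model.max_steps
    window.seconds
    synth.*  (see :class:`pcgseg.synthetic.SynthConfig`)

Every run writes a manifest JSON capturing the fully resolved configuration,
the package version and the seed, so any output can be regenerated.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .emd import SiftConfig
from .models import ModelConfig
from .preprocess import EnvelopeSpec, FilterSpec, PreprocessConfig
from .synthetic import BurstSpec, SynthConfig

DEFAULTS: dict[str, Any] = {
    "filter.order": 4,
    "filter.low_hz": 60.0,
    "filter.high_hz": 150.0,
    "filter.zero_phase": True,
    "envelope.fir_length": 200,
    "envelope.backend": "fir",
    "emd.levels": 3,
    "emd.sd_threshold": 0.2,
    "emd.max_sift_iterations": 100,
    "normalize.mode": "symmetric",
    "decimate.factor": 1,
    "model.architecture": "bigru",
    "model.hidden_units": 200,
    "model.learning_rate": 0.001,
    "model.epochs": None,
    "model.batch_size": 16,
    "model.train_fraction": 0.7,
    "model.max_steps": None,
    "window.seconds": 2.0,
    "synth.rate_hz": 1000,
    "synth.duration_s": 20.0,
    "synth.heart_rate_bpm": 60.0,
    "synth.heart_rate_jitter": 0.05,
    "synth.s1_duration_ms": 120.0,
    "synth.s1_frequency_hz": 80.0,
    "synth.s1_amplitude": 1.0,
    "synth.s2_duration_ms": 90.0,
    "synth.s2_frequency_hz": 110.0,
    "synth.s2_amplitude": 0.8,
    "synth.systole_fraction": 0.35,
    "synth.murmur": "off",
    "synth.murmur_amplitude": 0.1,
    "synth.noise_snr_db": 20.0,
}


def _flatten(nested: dict, prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in nested.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{full}."))
        else:
            flat[full] = value
    return flat


class RunConfig:
    """Resolved key/value configuration for one command invocation."""

    def __init__(self, values: dict[str, Any], seed: int = 0):
        unknown = set(values) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        self.values = {**DEFAULTS, **values}
        self.seed = seed

    @classmethod
    def load(
        cls,
        config_path: str | Path | None = None,
        overrides: dict[str, Any] | None = None,
        seed: int = 0,
    ) -> "RunConfig":
        values: dict[str, Any] = {}
        if config_path is not None:
            nested = yaml.safe_load(Path(config_path).read_text()) or {}
            values.update(_flatten(nested))
        if overrides:
            values.update(overrides)
        return cls(values, seed=seed)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def preprocess_config(self) -> PreprocessConfig:
        v = self.values
        return PreprocessConfig(
            filter=FilterSpec(
                order=int(v["filter.order"]),
                low_cut_hz=float(v["filter.low_hz"]),
                high_cut_hz=float(v["filter.high_hz"]),
                zero_phase=bool(v["filter.zero_phase"]),
            ),
            envelope=EnvelopeSpec(fir_length=int(v["envelope.fir_length"])),
            emd=SiftConfig(
                max_sift_iterations=int(v["emd.max_sift_iterations"]),
                sd_threshold=float(v["emd.sd_threshold"]),
            ),
            emd_levels=int(v["emd.levels"]),
            normalize_mode=str(v["normalize.mode"]),
            envelope_backend=str(v["envelope.backend"]),
            decimate_factor=int(v["decimate.factor"]),
        )

    def model_config(self) -> ModelConfig:
        v = self.values
        return ModelConfig(
            architecture=str(v["model.architecture"]),
            hidden_units=int(v["model.hidden_units"]),
            learning_rate=float(v["model.learning_rate"]),
            epochs=None if v["model.epochs"] is None else int(v["model.epochs"]),
            batch_size=int(v["model.batch_size"]),
            train_fraction=float(v["model.train_fraction"]),
            seed=self.seed,
            max_steps=None if v["model.max_steps"] is None else int(v["model.max_steps"]),
        )

    def synth_config(self, seed: int | None = None) -> SynthConfig:
        v = self.values
        return SynthConfig(
            sampling_rate_hz=int(v["synth.rate_hz"]),
            duration_s=float(v["synth.duration_s"]),
            heart_rate_bpm=float(v["synth.heart_rate_bpm"]),
            heart_rate_jitter=float(v["synth.heart_rate_jitter"]),
            s1=BurstSpec(
                float(v["synth.s1_duration_ms"]),
                float(v["synth.s1_frequency_hz"]),
                float(v["synth.s1_amplitude"]),
            ),
            s2=BurstSpec(
                float(v["synth.s2_duration_ms"]),
                float(v["synth.s2_frequency_hz"]),
                float(v["synth.s2_amplitude"]),
            ),
            systole_fraction=float(v["synth.systole_fraction"]),
            murmur=str(v["synth.murmur"]),
            murmur_amplitude=float(v["synth.murmur_amplitude"]),
            noise_snr_db=float(v["synth.noise_snr_db"]),
            seed=self.seed if seed is None else seed,
        )

    def window_seconds(self) -> float:
        return float(self.values["window.seconds"])

    def manifest(self, command: str, extra: dict | None = None) -> dict:
        doc = {
            "package": "pcgseg",
            "version": __version__,
            "command": command,
            "seed": self.seed,
            "config": self.values,
        }
        if extra:
            doc.update(extra)
        return doc

    def write_manifest(self, out_dir: str | Path, command: str,
                       extra: dict | None = None) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"manifest-{command}.json"
        path.write_text(json.dumps(self.manifest(command, extra), indent=2, default=str))
        return path
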