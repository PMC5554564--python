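"""One-step design runner: YAML config in, STL + QA sidecar out.

``run_design`` ties the stages together the way a clinic workstation would
use them: load a scan and its marked landmarks, design the orthosis, write
a binary STL next to a JSON QA sidecar recording the package version, a
hash of the effective configuration, and every quality gate.  The exit
status encodes the outcome: 0 all gates pass, 1 validation problem,
2 geometry failure (including failed gates), 3 I/O problem.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .afo_template import TemplateSpec
from .errors import (
    AfogenError,
    GeometryError,
    InputValidationError,
    MeshIOError,
    ParameterError,
)
from .geometry_io import read_landmarks, read_mesh, write_stl
from .shell_builder import DesignResult, ShellParams, design_afo

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 1
EXIT_GEOMETRY = 2
EXIT_IO = 3


@dataclass
class DesignConfig:
    """Everything run_design needs, loadable from YAML."""

    scan_path: str = ""
    landmarks_path: str = ""
    output_stl: str = "afo.stl"
    qa_json: str = ""  # defaults to output_stl with .qa.json suffix
    template: TemplateSpec = field(default_factory=TemplateSpec)
    shell: ShellParams = field(default_factory=ShellParams)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.qa_json:
            self.qa_json = str(Path(self.output_stl).with_suffix(".qa.json"))

    def validate(self) -> None:
        self.template.validate()
        self.shell.validate()
        if not self.scan_path:
            raise ParameterError("scan_path is required")
        if not self.landmarks_path:
            raise ParameterError("landmarks_path is required")

    def to_dict(self) -> dict:
        return {
            "scan_path": self.scan_path,
            "landmarks_path": self.landmarks_path,
            "output_stl": self.output_stl,
            "qa_json": self.qa_json,
            "template": self.template.to_dict(),
            "shell": self.shell.to_dict(),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DesignConfig":
        data = dict(data)
        template = TemplateSpec.from_dict(data.pop("template", {}) or {})
        shell_data = data.pop("shell", {}) or {}
        shell = ShellParams.from_dict(shell_data)
        # the template carries clearance/thickness for the YAML surface; they
        # seed the shell parameters unless the shell section overrides them
        if "clearance_mm" not in shell_data:
            shell.clearance_mm = template.clearance_mm
        if "thickness_mm" not in shell_data:
            shell.thickness_mm = template.thickness_mm
        unknown = set(data) - {
            "scan_path", "landmarks_path", "output_stl", "qa_json", "seed",
            "log_level",
        }
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(template=template, shell=shell, **data)

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"{path} must hold a YAML mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_design(config: DesignConfig) -> int:
    """Execute the design pipeline for a config; returns the exit status."""
    try:
        config.validate()
        config.shell.rng_seed = config.seed
    except InputValidationError as exc:
        log.error("configuration invalid: %s", exc)
        return EXIT_VALIDATION

    try:
        scan = read_mesh(config.scan_path)
        landmarks = read_landmarks(config.landmarks_path)
    except MeshIOError as exc:
        log.error("%s", exc)
        return EXIT_IO
    except InputValidationError as exc:
        log.error("%s", exc)
        return EXIT_VALIDATION

    try:
        result: DesignResult = design_afo(
            scan, landmarks, config.template, config.shell
        )
    except InputValidationError as exc:
        log.error("validation failed: %s", exc)
        return EXIT_VALIDATION
    except (GeometryError, AfogenError) as exc:
        log.error("%s", exc)
        return EXIT_GEOMETRY

    try:
        write_stl(result.mesh, config.output_stl, binary=True)
        sidecar = {
            "afogen_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "qa": result.qa.to_dict(),
        }
        with open(config.qa_json, "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        log.error("cannot write outputs: %s", exc)
        return EXIT_IO

    if not result.qa.gates_pass():
        log.error(
            "QA gates failed (watertight=%s, thickness_ok=%.3f, relief_ok=%s)",
            result.qa.watertight,
            result.qa.thickness_within_tolerance_fraction,
            result.qa.relief_clearance_ok,
        )
        return EXIT_GEOMETRY
    log.info("AFO written to %s (QA sidecar %s)", config.output_stl, config.qa_json)
    return EXIT_OK
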