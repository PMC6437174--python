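"""End-to-end orchestration: network → flow → oxygen → maps → phenotype.

A :class:`RunConfig` (YAML-loadable) fully determines a run; rerunning
with the same config and seed reproduces per-segment outputs.  Every
emitted file is listed with a checksum in a provenance JSON that also
records the config hash, library versions and solver residuals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hemodynamics import FlowConfig, interior_mass_residual, simulate_hemodynamics
from .io import read_network, write_attributes, write_network
from .morphometry import MorphometryMaps, compute_morphometry, morphology_summary
from .oxygen import OxygenParams, solve_oxygen
from .phenotype import ClassThresholds, classify_vessels, mean_path_length
from .synth import TumorLikeParams, make_tumor_like

__all__ = ["RunConfig", "RunResult", "run_pipeline", "ConfigError"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run (schema version 1)."""

    out_dir: str
    network_path: str | None = None  # CSV directory; None → synthesize
    network_format: str = "csv"
    seed: int = 0
    synth: dict = field(default_factory=dict)  # TumorLikeParams overrides
    flow: dict = field(default_factory=dict)  # FlowConfig overrides
    oxygen: dict = field(default_factory=dict)  # OxygenParams fields (m_c required)
    thresholds: dict = field(default_factory=dict)  # ClassThresholds overrides
    morphometry_spacing_um: float = 8.0
    morphometry_kernel: int = 20
    write_maps: bool = True
    write_vtk: bool = False
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "out_dir" not in doc:
            raise ConfigError(f"{path}: out_dir is required")
        return cls(**doc)

    def validate(self) -> None:
        """Fail fast before any compute."""
        if "m_c" not in self.oxygen:
            raise ConfigError("oxygen.m_c (tissue O2 consumption, ml O2/g/s) is required")
        OxygenParams(**self.oxygen)  # field-level validation
        FlowConfig(**self.flow)
        ClassThresholds(**self.thresholds)
        if self.network_path is None:
            TumorLikeParams(**{"seed": self.seed, **self.synth})
        if self.morphometry_spacing_um <= 0 or self.morphometry_kernel < 1:
            raise ConfigError("morphometry grid settings must be positive")

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = asdict(self)
        doc.pop("out_dir", None)
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Outputs of one pipeline run."""

    network: object
    hemodynamics: object
    oxygen: object
    maps: MorphometryMaps
    classes: np.ndarray
    report: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages and write the result bundle + provenance manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if config.network_path is not None:
            net = read_network(config.network_path, config.network_format)
        else:
            net = make_tumor_like(TumorLikeParams(**{"seed": config.seed, **config.synth}))
            write_network(net, out / "network", format="csv")
    except Exception as e:
        raise RuntimeError(f"stage 'network': {e}") from e

    try:
        flow_cfg = FlowConfig(**config.flow)
        hemo = simulate_hemodynamics(net, flow_cfg)
    except Exception as e:
        raise RuntimeError(f"stage 'hemodynamics': {e}") from e

    try:
        oxy_params = OxygenParams(**config.oxygen)
        oxy = solve_oxygen(net, hemo, oxy_params)
    except Exception as e:
        raise RuntimeError(f"stage 'oxygen': {e}") from e

    try:
        maps = compute_morphometry(net, config.morphometry_spacing_um, config.morphometry_kernel)
    except Exception as e:
        raise RuntimeError(f"stage 'morphometry': {e}") from e

    try:
        thresholds = ClassThresholds(**config.thresholds)
        classes = classify_vessels(hemo, oxy, net.diameters, net.lengths, thresholds)
    except Exception as e:
        raise RuntimeError(f"stage 'phenotype': {e}") from e

    # -- outputs --------------------------------------------------------
    hemo.to_frame().to_csv(out / "flow.csv", index=False, float_format="%.12g")
    hemo.node_frame().to_csv(out / "pressures.csv", index=False, float_format="%.12g")
    oxy.to_frame().to_csv(out / "oxygen.csv", index=False, float_format="%.12g")
    pd.DataFrame({"segment_id": net.segment_ids, "vessel_class": classes}).to_csv(
        out / "classes.csv", index=False
    )
    summary = morphology_summary(net, maps)
    summary.to_csv(out / "morphology_summary.csv", float_format="%.10g")
    if config.write_maps:
        maps.dv.save_nifti(out / "dv_um.nii.gz")
        maps.lv.save_nifti(out / "lv_mm_mm3.nii.gz")
        maps.sv.save_nifti(out / "sv_mm2_mm3.nii.gz")
    if config.write_vtk:
        table = hemo.to_frame().drop(columns=["hd", "ht"]).set_index("segment_id")
        write_attributes(net, table, out / "flow.vtk", format="vtk_polyline")

    perf = hemo.perfused
    report = {
        "schema_version": config.schema_version,
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_nodes": int(net.n_nodes),
        "n_segments": int(net.n_segments),
        "hemodynamics": {
            "outer_iterations": hemo.iterations,
            "hematocrit_residual": hemo.residual,
            "interior_mass_residual_ul_s": interior_mass_residual(
                net, hemo.flow, list(net.boundary_conditions)
            ),
        },
        "oxygen": {
            "iterations": oxy.iterations,
            "residual_mmHg": oxy.residual,
            "eligible_fraction": float(np.mean(oxy.eligible)),
        },
        "phenotype": {
            "perfused_fraction": float(np.mean(perf)),
            "class_fractions": {
                str(c): float(np.mean(classes[perf] == c)) for c in (1, 2, 3, 4)
            },
            "mpl_um": mean_path_length(hemo.flow[perf], net.lengths[perf]) if perf.any() else None,
        },
        "median_po2_mmHg": float(np.median(oxy.segment_po2[perf])) if perf.any() else None,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    versions = {}
    for mod in ("numpy", "scipy", "pandas"):
        versions[mod] = __import__(mod).__version__
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "versions": {"vasculoscope": __version__, **versions},
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "provenance.json"
        },
    }
    (out / "provenance.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s (%d segments)", out, net.n_segments)
    return RunResult(net, hemo, oxy, maps, classes, report, out)
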