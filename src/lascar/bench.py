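"""End-to-end benchmark harness: cases -> methods -> metrics -> tables.

A benchmark runs a list of cases (phantom presets/specs or files on
disk) through a list of methods, evaluates every segmentation against
the case's reference scar with the full metric set, and aggregates
per-method medians and quartiles.  One failing (case, method) pair is
reported and skipped, never aborts the batch.  All randomness flows
from the single global seed through per-(case, method) derived seeds.
"""

from __future__ import annotations

import json
import logging
import traceback
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging_io, metrics, phantom, segmenters
from .imaging_io import BinaryMask, Volume3D
from .segmenters import ScarPrior

log = logging.getLogger("lascar.bench")

EXIT_OK, EXIT_CONFIG_ERROR, EXIT_PARTIAL = 0, 1, 2


def derived_seed(global_seed: int, case_id: str, method: str) -> int:
    """Stable per-(case, method) seed below 2**31."""
    key = f"{global_seed}:{case_id}:{method}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


@dataclass
class BenchmarkConfig:
    """Declarative description of a benchmark run."""

    cases: list
    methods: list                       # [{"name": ..., "params": {...}}, ...]
    seed: int = 0
    out_dir: str | None = None
    surface_label_radius_mm: float = 3.0

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(cases=list(raw["cases"]), methods=list(raw["methods"]),
                       seed=int(raw.get("seed", 0)),
                       out_dir=raw.get("out_dir"),
                       surface_label_radius_mm=float(
                           raw.get("surface_label_radius_mm", 3.0)))
        except (KeyError, TypeError, ValueError) as err:
            raise ValueError(f"invalid benchmark config: {err}") from err

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "cases": self.cases, "methods": self.methods, "seed": self.seed,
            "out_dir": self.out_dir,
            "surface_label_radius_mm": self.surface_label_radius_mm,
        }, sort_keys=True)


def yl_threshold(vol: Volume3D, enhanced: BinaryMask) -> float:
    """Threshold that includes an entire prominent enhanced region."""
    return float(vol.data[enhanced.data].min())


@dataclass
class CaseBundle:
    """Everything needed to run and score methods on one case."""

    case_id: str
    vol: Volume3D
    truth: BinaryMask
    inputs: dict
    regions: tuple = ()
    artefacts: dict = field(default_factory=dict)


def _load_case(case: dict, global_seed: int) -> CaseBundle:
    case_id = str(case.get("id", "case"))
    if "preset" in case or "spec" in case:
        overrides = dict(case.get("spec", {}))
        seed = derived_seed(global_seed, case_id, "phantom")
        if "preset" in case:
            spec = phantom.preset(case["preset"], seed=seed, **overrides)
        else:
            spec = phantom.PhantomSpec(seed=seed, **overrides)
        pc = phantom.generate_phantom(spec)
        prior_mean, prior_sd = phantom.scar_prior_for(spec)
        inputs = {
            "endo": pc.endo,
            "wall": pc.wall_manual,
            "healthy": pc.healthy_region,
            "enhanced": pc.enhanced_region,
            "prior": ScarPrior(prior_mean, prior_sd),
            "threshold": yl_threshold(pc.volume, pc.enhanced_region),
        }
        return CaseBundle(case_id, pc.volume, pc.scar_gt, inputs,
                          pc.region_masks, pc.artefacts)
    # file-based case
    vol = imaging_io.read_volume(case["image"])
    inputs = {}
    for key, role in (("endo", "endocardium"), ("wall", "wall"),
                      ("healthy", "region"), ("enhanced", "region")):
        if key in case:
            inputs[key] = imaging_io.read_mask(case[key], vol, role)
    if "prior" in case:
        inputs["prior"] = ScarPrior(**case["prior"])
    if "threshold" in case:
        inputs["threshold"] = float(case["threshold"])
    truth = imaging_io.read_mask(case["truth"], vol, "scar")
    regions = tuple(imaging_io.read_mask(p, vol, "region")
                    for p in case.get("regions", []))
    artefacts = {Path(p).stem: imaging_io.read_mask(p, vol, "artefact")
                 for p in case.get("artefacts", [])}
    return CaseBundle(case_id, vol, truth, inputs, regions, artefacts)


def evaluate_segmentation(seg: BinaryMask, bundle: CaseBundle, method: str,
                          params: dict, seed: int,
                          surface_label_radius_mm: float = 3.0,
                          anatomy: BinaryMask | None = None,
                          gt_mesh=None) -> metrics.MetricReport:
    """Score one segmentation against the case reference."""
    report = metrics.MetricReport(
        method=method,
        dice=metrics.dice(bundle.truth, seg),
        regional_dice=metrics.regional_dice(bundle.truth, seg, bundle.regions),
        delta_v_ml=metrics.volume_difference_ml(seg, bundle.truth),
        provenance={"case": bundle.case_id, "method": method,
                    "params": {k: repr(v) for k, v in params.items()},
                    "seed": seed},
    )
    anatomy = anatomy or bundle.inputs.get("endo")
    if anatomy is not None and bundle.truth.count:
        if gt_mesh is None:
            mesh = metrics.extract_isosurface(anatomy)
            gt_mesh = metrics.label_surface_scar(mesh, bundle.truth,
                                                 surface_label_radius_mm)
        test_mesh = metrics.label_surface_scar(gt_mesh, seg,
                                               surface_label_radius_mm)
        if gt_mesh.vertex_labels.any():
            report.rmse_mm = metrics.surface_rmse(gt_mesh, test_mesh)
    for name, artefact in bundle.artefacts.items():
        report.artefact_pct[name] = metrics.artefact_inclusion_pct(seg, artefact)
    return report


def run_benchmark(cfg: BenchmarkConfig):
    """Execute the benchmark; returns (reports, aggregate, failures).

    ``reports`` maps (case_id, method) -> MetricReport; ``aggregate`` is
    a per-method median/quartile table; ``failures`` lists isolated
    (case_id, method, error) tuples.
    """
    reports: dict = {}
    failures: list = []
    for case in cfg.cases:
        try:
            bundle = _load_case(dict(case), cfg.seed)
        except Exception as err:  # isolate a broken case
            log.error("case %s failed to load: %s", case, err)
            failures.append((str(case.get("id", case)), "<load>", repr(err)))
            continue
        anatomy = bundle.inputs.get("endo")
        gt_mesh = None
        if anatomy is not None and bundle.truth.count:
            mesh = metrics.extract_isosurface(anatomy)
            gt_mesh = metrics.label_surface_scar(
                mesh, bundle.truth, cfg.surface_label_radius_mm)
        for mspec in cfg.methods:
            mspec = dict(mspec)
            name = mspec["name"]
            params = dict(mspec.get("params", {}))
            seed = derived_seed(cfg.seed, bundle.case_id, name)
            try:
                seg = segmenters.run_method(name, bundle.vol, bundle.inputs,
                                            params, seed=seed)
                report = evaluate_segmentation(
                    seg, bundle, name, params, seed,
                    cfg.surface_label_radius_mm, anatomy, gt_mesh)
            except Exception as err:
                log.error("case %s / method %s failed: %s\n%s",
                          bundle.case_id, name, err, traceback.format_exc())
                failures.append((bundle.case_id, name, repr(err)))
                continue
            reports[(bundle.case_id, name)] = report
    aggregate = aggregate_reports(reports)
    if cfg.out_dir:
        write_outputs(cfg, reports, aggregate, failures)
    return reports, aggregate, failures


def aggregate_reports(reports: dict) -> pd.DataFrame:
    """Per-method median and quartiles of Dice, RMSE and volume error."""
    rows = []
    for (case_id, method), rep in sorted(reports.items()):
        rows.append({"case": case_id, "method": method, "dice": rep.dice,
                     "rmse_mm": rep.rmse_mm, "delta_v_ml": rep.delta_v_ml})
    if not rows:
        return pd.DataFrame(
            columns=["method", "n", "dice_median", "dice_q1", "dice_q3",
                     "rmse_median", "delta_v_median"])
    df = pd.DataFrame(rows)
    out = []
    for method, grp in df.groupby("method", sort=True):
        out.append({
            "method": method,
            "n": int(len(grp)),
            "dice_median": float(grp["dice"].median()),
            "dice_q1": float(grp["dice"].quantile(0.25)),
            "dice_q3": float(grp["dice"].quantile(0.75)),
            "rmse_median": float(grp["rmse_mm"].median()),
            "delta_v_median": float(grp["delta_v_ml"].median()),
        })
    return pd.DataFrame(out)


def write_outputs(cfg: BenchmarkConfig, reports: dict,
                  aggregate: pd.DataFrame, failures: list) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (case_id, method), rep in sorted(reports.items()):
        path = out / f"{case_id}_{method}.json"
        path.write_text(json.dumps(rep.to_dict(), indent=2, sort_keys=True))
    aggregate.to_csv(out / "aggregate.csv", index=False)
    run_log = {
        "config": yaml.safe_load(cfg.to_yaml()),
        "failures": failures,
        "n_reports": len(reports),
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True))
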