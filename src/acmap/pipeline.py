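"""Config-driven pipeline runner with reproducibility manifests.

A run config (YAML/JSON) names an output directory and an ordered list of
stages.  Each stage has an explicit seed where it is stochastic; the
manifest records the schema version, the full config, input checksums and
every produced output so any stage can be re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import __version__
from .acm import acm_precision, compute_acm
from .groupstats import welch_group_t
from .io import Volume, write_volume
from .multitensor import tensor_field_to_array
from .phantoms import CohortSpec, PhantomSpec, cohort_design_table, make_cohort, make_tensor_phantom, simulate_dwi, default_scheme
from .pico import build_calibration_table, build_fodf_field, fodf_field_to_array, fodf_from_tensor_field
from .tractography import TrackingParams

SCHEMA_VERSION = 1

_STAGES: dict[str, Callable[..., dict[str, Any]]] = {}


def _stage(name: str, requires: tuple[str, ...] = ()):  # registry decorator
    def wrap(fn):
        fn._requires = requires
        _STAGES[name] = fn
        return fn

    return wrap


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a mapping")
    if cfg.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise PipelineError("unsupported schema_version")
    if "out_dir" not in cfg:
        raise PipelineError("config missing out_dir")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        raise PipelineError("config needs a non-empty stage list")
    for st in stages:
        if not isinstance(st, dict) or "name" not in st:
            raise PipelineError("each stage needs a name")
        if st["name"] not in _STAGES:
            raise PipelineError(f"unknown stage {st['name']!r}")


@_stage("phantom")
def _run_phantom(params: dict, ws: dict, out: Path) -> dict:
    spec = PhantomSpec(
        geometry=params.get("geometry", "straight_tube"),
        dims=tuple(params.get("dims", (24, 16, 16))),
        radius=params.get("radius", 2.0),
    )
    field, mask = make_tensor_phantom(spec)
    ws["tensor_field"], ws["mask"] = field, mask
    tens_path = out / "tensors.nii"
    write_volume(Volume(tensor_field_to_array(field), field.affine), tens_path)
    write_volume(mask.as_volume(), out / "mask.nii")
    if params.get("simulate_snr"):
        dwi = simulate_dwi(field, default_scheme(), params["simulate_snr"], params.get("seed", 0))
        write_volume(dwi, out / "dwi.nii")
    return {"outputs": ["tensors.nii", "mask.nii"]}


@_stage("calibrate")
def _run_calibrate(params: dict, ws: dict, out: Path) -> dict:
    table = build_calibration_table(
        default_scheme(),
        snrs=tuple(params.get("snrs", (16.0,))),
        n_trials=params.get("trials", 500),
        seed=params.get("seed", 0),
    )
    ws["calibration"] = table
    table.to_json(out / "calibration.json")
    return {"outputs": ["calibration.json"]}


@_stage("fodf", requires=("tensor_field",))
def _run_fodf(params: dict, ws: dict, out: Path) -> dict:
    if "kappa" in params:
        ws["fodf"] = fodf_from_tensor_field(ws["tensor_field"], params["kappa"])
    else:
        if "calibration" not in ws:
            raise PipelineError("fodf stage needs a prior calibrate stage or a fixed kappa")
        ws["fodf"] = build_fodf_field(ws["tensor_field"], ws["calibration"], params.get("snr", 16.0))
    f = ws["fodf"]
    write_volume(Volume(fodf_field_to_array(f), f.affine), out / "fodf.nii")
    return {"outputs": ["fodf.nii"]}


@_stage("acm", requires=("fodf", "mask"))
def _run_acm(params: dict, ws: dict, out: Path) -> dict:
    tp = TrackingParams(
        step_fraction=params.get("step_fraction", 0.1),
        max_steps=params.get("max_steps", 2000),
    )
    vol = compute_acm(
        ws["fodf"], ws["mask"], params.get("n_per_seed", 500), tp,
        rng=params.get("seed", 0),
    )
    ws["acm"] = vol
    write_volume(vol.counts, out / "acm.nii")
    return {"outputs": ["acm.nii"]}


@_stage("acm_precision", requires=("fodf", "mask"))
def _run_precision(params: dict, ws: dict, out: Path) -> dict:
    tp = TrackingParams(step_fraction=params.get("step_fraction", 0.1))
    rep = acm_precision(
        ws["fodf"], ws["mask"],
        tuple(params.get("n_values", (10, 50, 150, 300, 500, 700))),
        repeats=params.get("repeats", 5),
        params=tp,
        rng=params.get("seed", 0),
    )
    rep.to_tsv(out / "precision.tsv")
    ws["precision"] = rep
    return {"outputs": ["precision.tsv"]}


@_stage("cohort_stats")
def _run_cohort_stats(params: dict, ws: dict, out: Path) -> dict:
    """Cohort generation -> per-subject ACM -> group contrast, end to end."""
    cspec = CohortSpec(
        n_healthy=params.get("n_healthy", 4),
        n_rr=params.get("n_rr", 4),
        n_sp=params.get("n_sp", 4),
        effect_rr=params.get("effect_rr", 0.3),
        effect_sp=params.get("effect_sp", 0.5),
        seed=params.get("seed", 0),
    )
    pspec = PhantomSpec(dims=tuple(params.get("dims", (16, 10, 10))), radius=1.5)
    subjects = make_cohort(cspec, pspec)
    cohort_design_table(subjects).to_csv(out / "design.tsv", sep="\t", index=False)
    tp = TrackingParams(step_fraction=params.get("step_fraction", 0.1))
    kappa = params.get("kappa", -60.0)
    rng = np.random.default_rng(cspec.seed + 1)
    acms = []
    for s in subjects:
        fodf = fodf_from_tensor_field(s.tensor_field, kappa)
        mask = s.tensor_field.mask
        acms.append(
            compute_acm(fodf, mask, params.get("n_per_seed", 10), tp, rng).data.reshape(-1)
        )
    y = np.stack(acms).astype(float)
    rr = np.array([s.group == "RR" for s in subjects])
    sp = np.array([s.group == "SP" for s in subjects])
    t, df = welch_group_t(y, rr, sp)
    np.savetxt(out / "rr_vs_sp_t.tsv", t.reshape(1, -1), delimiter="\t")
    ws["cohort"] = subjects
    return {"outputs": ["design.tsv", "rr_vs_sp_t.tsv"]}


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Execute stages in order and return (and write) the run manifest."""
    validate_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    ws: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "version": __version__,
        "config": cfg,
        "stages": [],
    }
    for st in cfg["stages"]:
        name = st["name"]
        fn = _STAGES[name]
        missing = [r for r in fn._requires if r not in ws]
        if missing:
            raise PipelineError(
                f"stage {name!r} requires upstream outputs {missing}; "
                "add the producing stage first"
            )
        params = {k: v for k, v in st.items() if k != "name"}
        record = fn(params, ws, out)
        record["name"] = name
        record["params"] = params
        record["checksums"] = {
            f: _sha256(out / f) for f in record.get("outputs", [])
        }
        manifest["stages"].append(record)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
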