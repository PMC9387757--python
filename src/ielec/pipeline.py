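"""One-command end-to-end run: register → snap → project → label → warp.

The pipeline wires the modules together exactly the way the interactive
workflow does, minus the GUI: contact seeds take the place of user clicks.
All stage parameters come from a validated JSON config whose materialized
defaults are written into the output manifest, so a run can be reproduced
bit-identically from its manifest alone (the registration is deterministic
and every stochastic input is seeded upstream).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from ._version import __version__
from .anatomy import labels_at_positions, read_lut
from .brainshift import project_sensors_onto_brain, read_off
from .errors import FormatError, SpecError
from .imagespace import FRAME_CT, FRAME_MR, FRAME_TEMPLATE, AffineTransform, read_volume
from .localization import mark_contact, read_electrodes_tsv, snap_to_center, write_electrodes_tsv
from .registration import (
    apply_point_registration,
    compute_affine_registration,
    compute_sdr_registration,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "paths": {
        "ct": None,
        "mr": None,
        "seeds": None,
        "seg": None,
        "lut": None,
        "lepto": None,
        "template": None,
        "initial": None,
        "out_dir": None,
    },
    "register": {"stages": ["translation", "rigid", "affine"],
                 "pyramid_factors": [4, 2, 1], "bins": 32, "max_evals": 200},
    "snap": {"radius": 5.0, "intensity_floor": 0.25, "max_region_radius": 5.0},
    "project": {"channels": []},
    "label": {"radius": 2.0},
    "sdr": {"level_iters": [10, 10, 5], "field_sigma": 2.0},
}


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in given:
            gval = given[key]
            if isinstance(dval, dict):
                if not isinstance(gval, dict):
                    raise FormatError(f"config key {path + key!r} must be an object")
                out[key] = _merge(dval, gval, path + key + ".")
            else:
                out[key] = gval
        else:
            out[key] = {k: v for k, v in dval.items()} if isinstance(dval, dict) else dval
    unknown = set(given) - set(defaults)
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(path + k for k in unknown))}")
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with defaults materialized."""

    config: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_merge(_DEFAULTS, d))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __getitem__(self, key):
        return self.config[key]


def _require(paths: dict, *keys):
    for key in keys:
        p = paths.get(key)
        if p is None:
            raise SpecError(f"pipeline requires paths.{key}")
        if not os.path.exists(p):
            raise FileNotFoundError(f"paths.{key}: no such file: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run register → snap → (project) → label → (warp) and write outputs.

    Returns a summary dict with the output paths and per-stage metrics.
    Any stage error aborts the run with the failing stage named.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.config
    paths = cfg["paths"]
    _require(paths, "ct", "mr", "seeds")
    out_dir = paths["out_dir"]
    if out_dir is None:
        raise SpecError("pipeline requires paths.out_dir")
    os.makedirs(out_dir, exist_ok=True)

    log_path = os.path.join(out_dir, "pipeline.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ielec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    outputs: dict[str, str] = {}
    metrics: dict[str, object] = {}
    stage = "setup"
    t_stage = {}
    try:
        # ---- register -----------------------------------------------------
        stage = "register"
        t0 = time.perf_counter()
        ct = read_volume(paths["ct"], frame=FRAME_CT)
        mr = read_volume(paths["mr"], frame=FRAME_MR)
        initial = None
        if paths["initial"]:
            with open(paths["initial"]) as fh:
                initial = AffineTransform.from_dict(json.load(fh))
        reg = compute_affine_registration(
            ct, mr, initial=initial,
            stages=tuple(cfg["register"]["stages"]),
            pyramid_factors=tuple(cfg["register"]["pyramid_factors"]),
            bins=cfg["register"]["bins"],
            max_evals=cfg["register"]["max_evals"],
        )
        reg_path = os.path.join(out_dir, "ct_to_mr.json")
        with open(reg_path, "w") as fh:
            json.dump(reg.affine.to_dict(), fh, indent=1)
        outputs["ct_to_mr.json"] = reg_path
        metrics["register_final_mi"] = reg.mi_trace[-1][2] if reg.mi_trace else None
        t_stage[stage] = time.perf_counter() - t0

        # ---- snap ---------------------------------------------------------
        stage = "snap"
        t0 = time.perf_counter()
        seeds = read_electrodes_tsv(paths["seeds"], frame=FRAME_CT)
        snapped_ct = seeds.copy()
        moved = []
        for contact in seeds.contacts:
            if contact.status != "located":
                continue
            res = snap_to_center(
                ct, contact.position,
                radius=cfg["snap"]["radius"],
                intensity_floor=cfg["snap"]["intensity_floor"],
                max_region_radius=cfg["snap"]["max_region_radius"],
            )
            mark_contact(snapped_ct, contact.name, res)
            moved.append(res.moved_mm)
        # to MR frame through the recovered registration
        snapped_mr = snapped_ct.copy()
        snapped_mr.frame = FRAME_MR
        located = [c for c in snapped_mr.contacts if c.status == "located"]
        pos_mr, _ = apply_point_registration(
            np.array([c.position for c in located]), reg.affine
        )
        for contact, p in zip(located, pos_mr):
            contact.position = p
        snapped_path = os.path.join(out_dir, "snapped.tsv")
        write_electrodes_tsv(snapped_mr, snapped_path)
        outputs["snapped.tsv"] = snapped_path
        metrics["snap_mean_moved_mm"] = float(np.mean(moved)) if moved else 0.0
        t_stage[stage] = time.perf_counter() - t0

        # ---- project (ECoG brain shift) ------------------------------------
        stage = "project"
        t0 = time.perf_counter()
        final = snapped_mr
        channels = list(cfg["project"]["channels"])
        if channels:
            if not paths["lepto"]:
                raise SpecError("project.channels given but paths.lepto missing")
            lepto = read_off(paths["lepto"], frame=FRAME_MR)
            final = project_sensors_onto_brain(final, lepto, channels)
            proj_path = os.path.join(out_dir, "projected.tsv")
            write_electrodes_tsv(final, proj_path)
            outputs["projected.tsv"] = proj_path
        t_stage[stage] = time.perf_counter() - t0

        # ---- label ---------------------------------------------------------
        stage = "label"
        t0 = time.perf_counter()
        if paths["seg"] and paths["lut"]:
            seg = read_volume(paths["seg"], frame=FRAME_MR, kind="label")
            lut = read_lut(paths["lut"])
            located = [c for c in final.contacts if c.status == "located"]
            labels = labels_at_positions(
                seg, lut, np.array([c.position for c in located]),
                radius=cfg["label"]["radius"], names=[c.name for c in located],
            )
            label_path = os.path.join(out_dir, "labels.tsv")
            with open(label_path, "w") as fh:
                fh.write("name\tlabel\tfraction\n")
                for name in [c.name for c in located]:
                    for lab, frac in labels.fractions[name]:
                        fh.write(f"{name}\t{lab}\t{frac:.6f}\n")
            outputs["labels.tsv"] = label_path
        t_stage[stage] = time.perf_counter() - t0

        # ---- warp to template ----------------------------------------------
        stage = "warp"
        t0 = time.perf_counter()
        if paths["template"]:
            template = read_volume(paths["template"], frame=FRAME_TEMPLATE)
            mr2t = compute_affine_registration(
                mr, template,
                stages=tuple(cfg["register"]["stages"]),
                pyramid_factors=tuple(cfg["register"]["pyramid_factors"]),
                bins=cfg["register"]["bins"],
                max_evals=cfg["register"]["max_evals"],
            )
            fld = compute_sdr_registration(
                mr, template, pre_affine=mr2t.affine,
                level_iters=tuple(cfg["sdr"]["level_iters"]),
                field_sigma=cfg["sdr"]["field_sigma"],
            )
            located = [c for c in final.contacts if c.status == "located"]
            warped, _ = apply_point_registration(
                np.array([c.position for c in located]), fld, direction="forward"
            )
            tmpl = final.copy()
            tmpl.frame = FRAME_TEMPLATE
            for contact, p in zip([tmpl[c.name] for c in located], warped):
                contact.position = p
            tmpl_path = os.path.join(out_dir, "template_space.tsv")
            write_electrodes_tsv(tmpl, tmpl_path)
            outputs["template_space.tsv"] = tmpl_path
        t_stage[stage] = time.perf_counter() - t0
    except Exception as exc:
        logger.exception("pipeline failed in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        if handler in root.handlers:
            root.removeHandler(handler)
            handler.close()

    for name, sec in t_stage.items():
        logger.info("stage %s: %.2f s", name, sec)

    manifest = {
        "ielec_version": __version__,
        "config": cfg,
        "inputs": {k: _sha256(v) for k, v in sorted(paths.items()) if v and os.path.isfile(v)},
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"outputs": outputs, "metrics": metrics, "manifest": manifest_path}
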