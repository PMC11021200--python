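"""End-to-end orchestration: simulate → label → measure → spatial summary.

A run is a pure function of (config, seed): every stage output is a file
in a documented format, every file's SHA-256 goes into the run manifest,
and rerunning with the same config reproduces the hashes bit-exactly
(wall-clock timings excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .components import label_components, measure_objects
from .grids import LabelVolume
from .io import write_table, write_volume
from .phantom import (
    CLASS_METASTASIS,
    CLASS_TLS,
    PhantomConfig,
    generate_object_phantom,
)
from .spatial import (
    density_correlation,
    distribution_summary,
    nn_distances,
    region_summary,
    volume_distance_join,
    volume_distance_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "DEFAULT_PIPELINE_OPTIONS"]

#: Pipeline-level options (phantom options live in PhantomConfig).
DEFAULT_PIPELINE_OPTIONS = {
    "connectivity": 26,
    "volume_cutoffs_mm3": [0.02],
    "nn_radius_um": 200.0,
}


def load_config(source: str | Path | dict) -> dict:
    """Load a run config from a JSON file or dict; unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        cfg = json.loads(Path(source).read_text())
    else:
        cfg = dict(source)
    allowed = set(DEFAULT_PIPELINE_OPTIONS) | set(PhantomConfig().__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(allowed)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _nn_summary(nntab, radius_um=None) -> dict:
    s = volume_distance_summary(nntab, radius_um=radius_um)
    for key in ("mean_distance_um", "median_distance_um"):
        s[key.replace("_um", "_mm")] = s[key] / 1000.0
    return s


def run_pipeline(config: str | Path | dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Run the full object pipeline and return the manifest dict.

    Parameters
    ----------
    config
        JSON file path or dict with PhantomConfig fields plus pipeline
        options (connectivity, volume_cutoffs_mm3, nn_radius_um).
    out_dir
        Output directory (created if needed); all stage outputs and the
        manifest land here.
    seed
        Overrides the config's seed when given.
    """
    cfg = load_config(config)
    opts = {k: cfg.pop(k, v) for k, v in DEFAULT_PIPELINE_OPTIONS.items()}
    if seed is not None:
        cfg["seed"] = int(seed)
    pconfig = PhantomConfig.from_dict(cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "bodyquant",
        "version": __version__,
        "seed": pconfig.seed,
        "config_echo": {**pconfig.as_dict(), **opts},
        "stages": [],
    }

    def stage(name: str):
        entry = {"name": name, "outputs": [], "wall_s": None}
        manifest["stages"].append(entry)
        return entry, time.perf_counter()

    def finish(entry, t0, paths):
        entry["wall_s"] = time.perf_counter() - t0
        for p in paths:
            entry["outputs"].append({"path": p.name, "sha256": _sha256(p)})

    try:
        # -- simulate -------------------------------------------------
        entry, t0 = stage("simulate")
        intensity, annotation, regions, truth = generate_object_phantom(pconfig)
        paths = []
        for cls, tag in ((CLASS_METASTASIS, "met"), (CLASS_TLS, "tls")):
            p = out / f"{tag}_intensity.tif"
            write_volume(intensity[cls], p)
            paths += [p, p.with_name(p.name + ".meta.json")]
            p = out / f"{tag}_annotation.tif"
            write_volume(annotation[cls], p)
            paths += [p, p.with_name(p.name + ".meta.json")]
        p = out / "regions.tif"
        write_volume(regions, p)
        paths += [p, p.with_name(p.name + ".meta.json")]
        p = out / "truth_objects.csv"
        write_table(truth.objects_frame(), p)
        paths.append(p)
        p = out / "config_echo.json"
        p.write_text(json.dumps(manifest["config_echo"], indent=1, sort_keys=True))
        paths.append(p)
        finish(entry, t0, paths)

        # -- label + measure ------------------------------------------
        tables = {}
        for cls, tag in ((CLASS_METASTASIS, "met"), (CLASS_TLS, "tls")):
            entry, t0 = stage(f"label_{tag}")
            binary = LabelVolume(
                (annotation[cls].data > 0).astype(np.uint8),
                annotation[cls].spacing_um,
                annotation[cls].origin_um,
            )
            labels, n = label_components(binary, connectivity=opts["connectivity"])
            p = out / f"{tag}_labels.tif"
            write_volume(labels, p)
            finish(entry, t0, [p, p.with_name(p.name + ".meta.json")])

            entry, t0 = stage(f"measure_{tag}")
            table = measure_objects(labels, class_name=cls, regions=regions)
            tables[cls] = table
            p = out / f"objects_{tag}.csv"
            write_table(table, p)
            finish(entry, t0, [p])

        # -- spatial statistics ---------------------------------------
        entry, t0 = stage("spatial")
        met, tls = tables[CLASS_METASTASIS], tables[CLASS_TLS]
        paths = []
        summary: dict = {
            "counts": {
                "n_metastases": int(len(met)),
                "n_tls": int(len(tls)),
                "n_metastases_truth": sum(
                    1 for o in truth.objects if o.class_name == CLASS_METASTASIS
                ),
                "n_tls_truth": sum(1 for o in truth.objects if o.class_name == CLASS_TLS),
            }
        }

        nn_specs = [
            ("tls_to_tls", tls, tls, True),
            ("met_to_met", met, met, True),
            ("tls_to_met", tls, met, False),
        ]
        for name, src, tgt, excl in nn_specs:
            if len(src) == 0:
                summary[name] = {"n_total": 0, "n_eligible": 0}
                continue
            tab = nn_distances(src, tgt, exclude_self=excl)
            p = out / f"nn_{name}.csv"
            write_table(tab, p)
            paths.append(p)
            summary[name] = _nn_summary(tab)

        join = volume_distance_join(met, tls)
        p = out / "nn_met_to_tls.csv"
        write_table(join, p)
        paths.append(p)
        summary["met_to_tls"] = _nn_summary(join, radius_um=opts["nn_radius_um"])

        cutoffs = [float(c) for c in opts["volume_cutoffs_mm3"]]
        for cls, tag, table in (
            (CLASS_METASTASIS, "metastasis", met),
            (CLASS_TLS, "tls", tls),
        ):
            if len(table):
                summary[f"volumes_{tag}"] = distribution_summary(
                    table["volume_mm3"], cutoffs=cutoffs
                )
            else:
                summary[f"volumes_{tag}"] = {"n": 0, "note": "no objects"}

        rtab = region_summary(_concat_tables(met, tls), regions)
        p = out / "region_table.csv"
        write_table(rtab, p)
        paths.append(p)
        summary["regions"] = rtab.to_dict(orient="records")

        try:
            r, pval = density_correlation(rtab, CLASS_METASTASIS, CLASS_TLS)
            summary["density_correlation"] = {
                "classes": [CLASS_METASTASIS, CLASS_TLS],
                "method": "pearson",
                "r": r,
                "p": pval,
            }
        except (ValueError, KeyError) as exc:
            summary["density_correlation"] = {"undefined": str(exc)}

        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
        paths.append(p)
        finish(entry, t0, paths)

    except Exception as exc:
        failed = manifest["stages"][-1]["name"] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _concat_tables(*tables):
    import pandas as pd

    nonempty = [t for t in tables if len(t)]
    if not nonempty:
        return tables[0]
    return pd.concat(nonempty, ignore_index=True)
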