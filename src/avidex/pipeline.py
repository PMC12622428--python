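"""End-to-end orchestration: config handling and the surface-comparison run.

``run_surface_comparison`` reproduces, fully in silico, the four-surface
nanomechanical comparison: it simulates a force-volume grid per calibrated
surface preset, scores every curve, aggregates per-surface summaries,
runs normality-gated pairwise tests on the maximum adhesion force, and
writes a JSON + CSV report bundle.  Every run is reproducible from its
config and root seed (per-surface substreams are derived from the root
seed), both of which are embedded in the report.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .biomarker_stats import compare_groups
from .fd_events import (
    EventConfig,
    SurfaceSummary,
    build_heatmaps,
    score_grid,
    summarize_surface,
)
from .fd_preprocess import PreprocessConfig
from .fd_sim import builtin_presets, simulate_grid

__all__ = ["PipelineConfig", "run_surface_comparison"]

log = logging.getLogger("avidex")


@dataclass
class PipelineConfig:
    """Configuration of the surface-comparison pipeline.

    ``presets`` lists the surface profiles to simulate; ``seed`` is the
    explicit root seed (wall-clock seeding is deliberately unsupported).
    """

    presets: list[str] = field(
        default_factory=lambda: ["G7-pPDL1", "aPD-L1", "pPDL1", "G7-pPDL1-scr"]
    )
    rows: int = 20
    cols: int = 20
    seed: int = 17
    alpha: float = 0.05
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    events: EventConfig = field(default_factory=EventConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        errors = []
        kwargs: dict = {}
        sim = raw.get("simulate", {})
        for key, target in (("rows", int), ("cols", int), ("seed", int)):
            if key in sim:
                kwargs[key] = target(sim[key])
        if "presets" in sim:
            kwargs["presets"] = list(sim["presets"])
        if "alpha" in raw.get("stats", {}):
            kwargs["alpha"] = float(raw["stats"]["alpha"])
        try:
            kwargs["preprocess"] = PreprocessConfig(**raw.get("preprocess", {}))
        except (TypeError, ValueError) as err:
            errors.append(f"preprocess: {err}")
        try:
            kwargs["events"] = EventConfig(**raw.get("events", {}))
        except (TypeError, ValueError) as err:
            errors.append(f"events: {err}")
        known = {p for p in builtin_presets()}
        for name in kwargs.get("presets", []):
            if name not in known:
                errors.append(f"unknown preset {name!r}")
        if "seed" in kwargs and not isinstance(kwargs["seed"], int):
            errors.append("seed must be an integer")
        if errors:
            raise ValueError("config validation failed: " + "; ".join(errors))
        return cls(**kwargs)


def _summary_dict(s: SurfaceSummary) -> dict:
    return dataclasses.asdict(s)


def run_surface_comparison(
    cfg: PipelineConfig, outdir: str | Path | None = None
) -> dict:
    """Simulate, score and compare all configured surfaces.

    Returns the report as a dict; when ``outdir`` is given, additionally
    writes ``report.json``, per-surface ``<name>_metrics.csv`` and heatmap
    CSV matrices.
    """
    presets = builtin_presets()
    unknown = [p for p in cfg.presets if p not in presets]
    if unknown:
        raise ValueError(f"unknown presets: {unknown}")

    report: dict = {
        "config": {
            "presets": cfg.presets,
            "rows": cfg.rows,
            "cols": cfg.cols,
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "preprocess": dataclasses.asdict(cfg.preprocess),
            "events": dataclasses.asdict(cfg.events),
        },
        "surfaces": {},
        "pairwise_f_max": {},
    }
    f_max_by_surface: dict[str, np.ndarray] = {}
    bundles = {}
    for i, name in enumerate(cfg.presets):
        # independent substream per surface derived from the root seed
        sub_seed = int(
            np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31)
        )
        grid = simulate_grid(presets[name], cfg.rows, cfg.cols, sub_seed)
        metrics = score_grid(grid, cfg.preprocess, cfg.events)
        summary = summarize_surface(grid, metrics)
        log.info(
            "surface %s: %d curves scored, prevalence_multiple=%.3f",
            name, len(metrics), summary.prevalence_multiple,
        )
        report["surfaces"][name] = {
            "seed": sub_seed,
            "summary": _summary_dict(summary),
        }
        f_max_by_surface[name] = np.array([m.f_max for m in metrics])
        bundles[name] = (grid, metrics)

    for a, b in itertools.combinations(cfg.presets, 2):
        res = compare_groups(f_max_by_surface[a], f_max_by_surface[b], cfg.alpha)
        report["pairwise_f_max"][f"{a}|{b}"] = {
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        for name, (grid, metrics) in bundles.items():
            stem = name.replace("/", "_")
            _write_metrics_csv(outdir / f"{stem}_metrics.csv", grid, metrics)
            f_map, e_map = build_heatmaps(grid, metrics)
            np.savetxt(outdir / f"{stem}_fmax_map.csv", f_map, delimiter=",", fmt="%.3f")
            np.savetxt(outdir / f"{stem}_eadh_map.csv", e_map, delimiter=",", fmt="%.3f")
    return report


def _write_metrics_csv(path: Path, grid, metrics) -> None:
    from .fd_model_io import curve_id_for

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("curve_id,n_events,binding_class,f_max_pN,e_adh_pN_nm,contact_nm\n")
        for curve, m in zip(grid.curves, metrics):
            contact = "" if m.contact_point is None else f"{m.contact_point:.3f}"
            fh.write(
                f"{curve_id_for(curve)},{m.n_events},{m.binding_class},"
                f"{m.f_max:.3f},{m.e_adh:.3f},{contact}\n"
            )
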