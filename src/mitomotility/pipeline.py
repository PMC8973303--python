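"""End-to-end pipeline driver: simulate → track → screen, or simulate →
track → kymograph, from a single config.

A single root seed drives every stage; per-well and per-stage generators are
spawned deterministically from it, so re-running an identical config
reproduces byte-identical tabular outputs.  Every run writes a provenance
JSON recording package and library versions, the seed, and all effective
parameters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .io_tables import traces_to_dataframe, write_axon_path_csv, write_csv
from .kymograph import axon_density, build_kymograph, extract_traces, trace_metrics
from .movie import write_movie
from .screening import WellSummary, call_hits, plate_summary
from .simulate import SimParams, simulate_axon_movie, simulate_field_movie
from .tracking import DetectionParams, summarize_field, track_movie

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``mode`` is 'screen' (simulated plate → tracking → hit calling) or
    'kymo' (simulated axon → kymograph → trace metrics).  ``sim`` and
    ``detection`` hold parameter overrides for SimParams / DetectionParams.
    """

    mode: str
    out_dir: str
    seed: int = 0
    sim: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    # screen mode
    n_vehicle_wells: int = 4
    compounds: list = field(default_factory=list)  # {name, fraction_motile, concentration_uM}
    n_replicates: int = 2
    hit_threshold: float = 2.0

    def __post_init__(self):
        if self.mode not in ("screen", "kymo"):
            raise ValueError("mode must be 'screen' or 'kymo'")
        if self.mode == "screen" and self.n_vehicle_wells < 2:
            raise ValueError("screen mode needs >= 2 vehicle wells")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _spawned_seeds(root_seed: int, n: int) -> list[int]:
    """Deterministic per-stage integer seeds below 2**31."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) % (2**31)]


def _write_provenance(out: Path, config: RunConfig, extra: dict | None = None):
    prov = {
        "package": "mitomotility",
        "version": _pkg_version,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
    }
    if extra:
        prov.update(extra)
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True))


def _run_screen(config: RunConfig, out: Path) -> dict:
    det = DetectionParams(**config.detection)
    base_sim = config.sim.copy()
    base_fraction = base_sim.pop("fraction_motile", 0.10)

    # well plan: vehicle wells, then one well per compound per replicate
    plan = []
    for i in range(config.n_vehicle_wells):
        plan.append(("VEH%02d" % (i + 1), "DMSO", float("nan"),
                     i % config.n_replicates, True, base_fraction))
    for j, comp in enumerate(config.compounds):
        for rep in range(config.n_replicates):
            plan.append(("C%02dR%d" % (j + 1, rep + 1), comp["name"],
                         float(comp.get("concentration_uM", float("nan"))),
                         rep, False,
                         float(comp.get("fraction_motile", base_fraction))))
    seeds = _spawned_seeds(config.seed, len(plan))

    wells = []
    rows = []
    for (well, compound, conc, rep, is_veh, fm), seed in zip(plan, seeds):
        params = SimParams.field_regime(**base_sim, fraction_motile=fm,
                                        seed=seed)
        movie, gt = simulate_field_movie(params)
        tracks = track_movie(movie, det)
        summary = summarize_field(tracks, det, movie.pixel_size,
                                  n_frames=movie.n_frames)
        wells.append(WellSummary(
            well=well, compound=compound, replicate=rep,
            distances_um=summary.distances_um, concentration_um=conc,
            is_vehicle=is_veh, percent_motile=summary.percent_motile,
            mean_integrated_distance_um=summary.mean_integrated_distance_um))
        rows.append({"well": well, "compound": compound, "replicate": rep,
                     "is_vehicle": is_veh, "seed": seed,
                     "true_fraction_motile": fm,
                     "true_percent_motile": gt.percent_motile,
                     "n_tracks": summary.n_tracks,
                     "percent_motile": summary.percent_motile,
                     "mean_integrated_distance_um":
                         summary.mean_integrated_distance_um})
    write_csv(pd.DataFrame(rows), out / "wells.csv")

    plate = plate_summary(wells)
    write_csv(plate, out / "plate_summary.csv")

    per_compound = {}
    treated = plate[~plate["is_vehicle"]]
    for compound, grp in treated.groupby("compound", sort=True):
        per_compound[compound] = grp.sort_values("replicate")["ks_z"].tolist()
    hits = call_hits(per_compound, threshold=config.hit_threshold)
    hits_df = pd.DataFrame([dataclasses.asdict(h) for h in hits])
    write_csv(hits_df, out / "hits.csv")
    return {"wells": str(out / "wells.csv"),
            "plate_summary": str(out / "plate_summary.csv"),
            "hits": str(out / "hits.csv"),
            "n_hits": int(hits_df["hit"].sum()) if len(hits_df) else 0}


def _run_kymo(config: RunConfig, out: Path) -> dict:
    det = DetectionParams(**config.detection)
    seed = _spawned_seeds(config.seed, 1)[0]
    params = SimParams(**config.sim, seed=seed)
    movie, gt = simulate_axon_movie(params)
    write_movie(movie, out / "movie.tif")
    path = gt.paths[0]
    write_axon_path_csv(path, out / "axon_path.csv")

    kymo = build_kymograph(movie, path)
    import tifffile
    tifffile.imwrite(out / "kymograph.tif", kymo.data.astype(np.float32))

    traces = extract_traces(movie, path, det)
    write_csv(traces_to_dataframe(traces), out / "traces.csv")
    metrics = trace_metrics(traces, movie.frame_interval)
    density = axon_density(traces, path, movie.pixel_size)
    mdf = pd.DataFrame([{
        "n_mitochondria": metrics.n,
        "percent_motile": metrics.percent_motile,
        "percent_anterograde": metrics.percent_anterograde,
        "percent_retrograde": metrics.percent_retrograde,
        "velocity_anterograde_um_s": metrics.velocity_anterograde_um_s,
        "velocity_retrograde_um_s": metrics.velocity_retrograde_um_s,
        "density_per_um": density,
        "true_percent_motile": gt.percent_motile,
    }])
    write_csv(mdf, out / "metrics.csv")
    return {"metrics": str(out / "metrics.csv"),
            "traces": str(out / "traces.csv")}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a dict of output paths.

    Any stage error aborts the run with the stage name; outputs written
    before the failure are left in place for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.mode == "screen":
            stage = "screen"
            result = _run_screen(config, out)
        else:
            stage = "kymo"
            result = _run_kymo(config, out)
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_provenance(out, config, {"outputs": result})
    result["provenance"] = str(out / "provenance.json")
    return result
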