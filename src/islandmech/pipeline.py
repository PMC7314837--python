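"""End-to-end orchestration: images → velocities → tractions → stresses.

``run_pipeline`` takes a flat configuration, runs image correlation on the
particle and cell stacks, inverts the substrate displacements to tractions,
corrects them to force/moment equilibrium, recovers monolayer stresses by
finite elements, integrates trajectories, evaluates the validation metrics,
and writes every product plus a run manifest (inputs, parameters, package
version) to the output folder. The pipeline is deterministic: replaying a
manifest reproduces the outputs bit for bit.
"""
from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np

from . import __version__
from .domain import IslandDomain, Monolayer, Substrate, domain_from_mask
from .dic import correlate_stack, DEFAULT_CELL_PARAMS, DEFAULT_PARTICLE_PARAMS
from .fields import GriddedVectorField
from .kinematics import compute_trajectories, default_seeds
from .msm import contractile_tension, mesh_from_node_mask, principal_stresses, \
    solve_stress
from .traction import enforce_equilibrium, fttc_inverse
from .validate import TensionSeries, island_report, normalize_tension
from . import io as iom

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = dict(
    pixel_size=0.65,          # µm/px
    dt=10.0,                  # min between frames
    youngs_modulus=6000.0,    # Pa
    poisson_ratio=0.45,
    regularization_lambda=0.0,
    # DIC fields are cropped by the subset margin, so the displacement is
    # not compactly supported on the analysis grid: pad the FFT to suppress
    # wrap-around (recorded in the output metadata)
    fttc_pad=2,
    monolayer_height=5.0,     # µm
    ratio_nu_m=0.5,
    cell_subset=DEFAULT_CELL_PARAMS["subset_size"],
    cell_spacing=DEFAULT_CELL_PARAMS["spacing"],
    particle_subset=DEFAULT_PARTICLE_PARAMS["subset_size"],
    particle_spacing=DEFAULT_PARTICLE_PARAMS["spacing"],
    trajectory_seed_stride=4,
    treatment_frame=None,
    seed=0,
)


def _as_stack(arr: np.ndarray) -> list[np.ndarray]:
    arr = np.asarray(arr, dtype=float)
    return [arr] if arr.ndim == 2 else [arr[t] for t in range(arr.shape[0])]


def run_pipeline(config: dict, out_dir: Optional[str] = None) -> dict:
    """Run the full island pipeline from a configuration dict.

    The config must name an input — either ``island_folder`` (an island
    record on disk) or ``synthetic`` (a parameter dict passed to
    :func:`islandmech.synthetic.synthesize_island`) — plus any overrides of
    :data:`DEFAULT_CONFIG`. Returns a result dict with the computed fields
    and the validation report; when ``out_dir`` (or config["out_dir"]) is
    set, all products and the run manifest are written there.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    out_dir = out_dir or cfg.get("out_dir")

    stage = "load-input"
    try:
        if "synthetic" in cfg and cfg["synthetic"] is not None:
            from .synthetic import synthesize_island, render_advected_stack
            syn_params = dict(cfg["synthetic"])
            syn_params.setdefault("seed", cfg["seed"])
            island = synthesize_island(**syn_params)
            domain = island.domain
            cfg["pixel_size"] = domain.pixel_size
            reference = island.speckle_reference.data
            particle_frames = [island.speckle_deformed.data]
            cells = render_advected_stack(island.velocity, 3, cfg["dt"],
                                          seed=syn_params["seed"] + 1)
            cell_frames = [c.data for c in cells]
            provenance = dict(kind="synthetic", **syn_params)
        elif "island_folder" in cfg:
            record = iom.read_island_record(
                cfg["island_folder"], dt=cfg["dt"],
                treatment_frame=cfg.get("treatment_frame"))
            mask = iom.read_mask_tiff(record.mask_image)
            domain = domain_from_mask(mask, cfg["pixel_size"])
            reference = iom.read_image_tiff(record.reference_image)
            particle_frames = _as_stack(iom.read_image_tiff(record.particle_stack))
            cell_frames = (_as_stack(iom.read_image_tiff(record.cell_stack))
                           if record.cell_stack else [])
            provenance = dict(kind="island_record", folder=record.folder)
        else:
            raise ValueError("config must provide 'island_folder' or "
                             "'synthetic'")

        substrate = Substrate(cfg["youngs_modulus"], cfg["poisson_ratio"])
        monolayer = Monolayer.from_nu(cfg["ratio_nu_m"],
                                      height_h=cfg["monolayer_height"])

        stage = "dic-substrate"
        displacements = correlate_stack(
            particle_frames, reference_mode="fixed", reference=reference,
            subset_size=cfg["particle_subset"],
            spacing=cfg["particle_spacing"], pixel_size=cfg["pixel_size"])

        stage = "dic-cells"
        velocities = []
        if len(cell_frames) >= 2:
            velocities = correlate_stack(
                cell_frames, reference_mode="consecutive",
                subset_size=cfg["cell_subset"], spacing=cfg["cell_spacing"],
                pixel_size=cfg["pixel_size"], dt=cfg["dt"])

        stage = "traction"
        tractions = []
        for disp in displacements:
            tr = fttc_inverse(disp, substrate,
                              regularization_lambda=cfg["regularization_lambda"],
                              pad=cfg["fttc_pad"])
            tr, _ = enforce_equilibrium(tr, domain)
            tr.time_index = disp.time_index
            tractions.append(tr)

        stage = "msm"
        t0 = tractions[0]
        mesh = mesh_from_node_mask(domain.mask_at(t0.x, t0.y), t0.x, t0.y)
        stresses, tensions = [], []
        for tr in tractions:
            st = principal_stresses(solve_stress(tr, mesh, monolayer,
                                                 ratio_nu_m=cfg["ratio_nu_m"]))
            _, avg = contractile_tension(st)
            stresses.append(st)
            tensions.append(avg)

        stage = "kinematics"
        trajectories = None
        if velocities:
            seeds = default_seeds(velocities[0], domain,
                                  stride=cfg["trajectory_seed_stride"])
            trajectories = compute_trajectories(velocities, seeds, cfg["dt"],
                                                domain=domain)

        stage = "validate"
        series = TensionSeries(np.arange(len(tensions)) * cfg["dt"],
                               np.asarray(tensions))
        if cfg.get("treatment_frame") is not None and len(tensions) > 1:
            k = cfg["treatment_frame"]
            series = TensionSeries(
                (np.arange(len(tensions)) - k) * cfg["dt"],
                np.asarray(tensions))
            series = normalize_tension(series, treatment_time=0.0)
        report = island_report(tractions[-1], domain, tensions[-1])
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed for input "
            f"{cfg.get('island_folder', cfg.get('synthetic'))}: {err}"
        ) from err

    result = dict(domain=domain, displacements=displacements,
                  velocities=velocities, tractions=tractions,
                  stresses=stresses, tension_series=series,
                  trajectories=trajectories, report=report, config=cfg,
                  provenance=provenance)

    if out_dir:
        _write_outputs(out_dir, result)
    return result


def _write_outputs(out_dir: str, result: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for t, f in enumerate(result["displacements"]):
        iom.write_field(os.path.join(out_dir, f"displacement_{t:03d}.tsv"), f)
    for t, f in enumerate(result["velocities"]):
        iom.write_field(os.path.join(out_dir, f"velocity_{t:03d}.tsv"), f)
    for t, f in enumerate(result["tractions"]):
        iom.write_field(os.path.join(out_dir, f"traction_{t:03d}.tsv"), f)
    for t, f in enumerate(result["stresses"]):
        iom.write_stress(os.path.join(out_dir, f"stress_{t:03d}.tsv"), f)
    if result["trajectories"] is not None:
        result["trajectories"].to_dataframe().to_csv(
            os.path.join(out_dir, "trajectories.tsv"), sep="\t", index=False)
    series = result["tension_series"]
    with open(os.path.join(out_dir, "tension_series.tsv"), "w") as fh:
        fh.write("t\ttension_Pa\tnormalized\n")
        norm = series.normalized if series.normalized is not None else \
            [float("nan")] * len(series.time)
        for t, s, n in zip(series.time, series.tension, norm):
            fh.write(f"{t:.6g}\t{s:.10g}\t{n:.10g}\n")
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(result["report"], fh, indent=2, sort_keys=True)

    manifest = {f"config.{k}": v for k, v in result["config"].items()
                if isinstance(v, (str, int, float, bool)) or v is None}
    manifest.update({f"input.{k}": v for k, v in result["provenance"].items()
                     if isinstance(v, (str, int, float, bool))})
    manifest["package_version"] = __version__
    manifest["sign_convention"] = ("T is cells-on-substrate; force balance "
                                   "div(sigma) = T/h; y increases downward")
    iom.write_metadata(os.path.join(out_dir, "manifest.txt"),
                       {k: manifest[k] for k in sorted(manifest)})
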