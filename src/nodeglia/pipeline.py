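"""End-to-end orchestration: simulate, analyze, and record provenance.

Every analysis parameter that affects a number lives in
:class:`RunConfig` and is echoed into the provenance JSON of each run,
together with the package version and a hash of the resolved
configuration, so that no numeric output can change without a
corresponding config difference.

Conventions: 0-based pixel indices, (t, z, y, x) axis order, half-open
ROI bounds; µm conversions happen only at the reporting layer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, contacts, dynamics, masks, morphodynamics
from .stacks import ChannelStack, write_stack
from .synthetic_microscopy import (
    CHANNEL_MICROGLIA,
    CHANNEL_NODES,
    ImagingParams,
    generate_scene,
    render,
    scene_to_json,
)


@dataclass
class RunConfig:
    """Resolved configuration of one simulate-then-analyze run."""

    # simulation
    n_conditions: dict[str, float] = field(
        default_factory=lambda: {"control": 0.25, "remyelination": 0.6}
    )  # condition -> planted contacted fraction
    n_animals: int = 4
    fields_per_animal: int = 4
    n_axons: int = 4
    n_nodes: int = 20
    movie_frames: int = 21
    attach: float = 0.3
    detach: float = 0.1
    tip_sigma: float = 1.5
    tip_kappa: float = 0.5
    n_free_tips: int = 2
    field_shape: tuple[int, int] = (256, 256)
    voxel_size_xy: float = 0.193
    frame_interval: float = 30.0
    psf_sigma: float = 1.0
    photon_gain: float | None = 200.0
    read_noise_sd: float = 0.01
    amplitude: float = 1.0
    # analysis
    threshold_method: str = "otsu"
    min_object_px: int = 4
    adjacency: str = "full"
    plane_mode: str = "middle_plane"
    connectivity: str = "full"
    perimeter_estimator: str = "crofton"
    marker_k: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "field_shape" in doc:
            doc["field_shape"] = tuple(doc["field_shape"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape"] = list(d["field_shape"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def imaging_params(self, n_frames: int = 1) -> ImagingParams:
        return ImagingParams(
            voxel_size_xy=self.voxel_size_xy,
            frame_interval=self.frame_interval,
            psf_sigma=self.psf_sigma,
            photon_gain=self.photon_gain,
            read_noise_sd=self.read_noise_sd,
            shape=(n_frames, 1, *self.field_shape),
        )


def _analyze_field(stacks: dict[str, ChannelStack], config: RunConfig, meta: dict):
    mg_mask = masks.binarize(
        stacks[CHANNEL_MICROGLIA], config.threshold_method, config.min_object_px
    )
    node_mask = masks.binarize(
        stacks[CHANNEL_NODES], config.threshold_method, config.min_object_px
    )
    return contacts.percent_contacted(
        mg_mask,
        node_mask,
        plane_mode=config.plane_mode,
        adjacency=config.adjacency,
        connectivity=config.connectivity,
        **meta,
    )


def run_pipeline(config: RunConfig, seed: int, outdir) -> dict:
    """Simulate fields and a movie per condition, analyze, write results.

    Writes per-node contact calls, per-field results, the per-condition
    mean-of-means summary, movie contact-stability metrics, tip motility
    metrics, rose-plot coordinates, single-cell morphodynamics, and a
    provenance JSON.  Fully deterministic for a fixed (config, seed).
    Returns the result tables as a dict of DataFrames.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)

    field_results = []
    node_rows = []
    movie_rows = []
    tip_rows = []
    rose_rows = []
    morpho_rows = []

    for cond, frac in sorted(config.n_conditions.items()):
        for animal in range(config.n_animals):
            animal_id = f"{cond}_animal{animal}"
            for fld in range(config.fields_per_animal):
                fseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                scene, truth = generate_scene(
                    seed=fseed,
                    n_axons=config.n_axons,
                    n_nodes=config.n_nodes,
                    params=config.imaging_params(1),
                    contacted_fraction=frac,
                    n_free_tips=config.n_free_tips,
                    tip_sigma=config.tip_sigma,
                    tip_kappa=config.tip_kappa,
                )
                stacks = render(scene, truth, seed=fseed, amplitude=config.amplitude)
                field_id = f"{animal_id}_field{fld}"
                result = _analyze_field(
                    stacks,
                    config,
                    {"field_id": field_id, "animal_id": animal_id, "condition": cond},
                )
                field_results.append(result)
                for node_id, contacted in result.node_calls:
                    node_rows.append(
                        {
                            "field_id": field_id,
                            "node_id": node_id,
                            "contacted": contacted,
                        }
                    )

        # one time-lapse movie per condition: contact stability + tips + morpho
        mseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        scene, truth = generate_scene(
            seed=mseed,
            n_axons=config.n_axons,
            n_nodes=max(4, config.n_nodes // 2),
            params=config.imaging_params(config.movie_frames),
            contacted_fraction=frac,
            n_frames=config.movie_frames,
            attach=config.attach,
            detach=config.detach,
            n_free_tips=config.n_free_tips,
            tip_sigma=config.tip_sigma,
            tip_kappa=config.tip_kappa,
        )
        mg_movie = truth.masks_clean[CHANNEL_MICROGLIA]
        for nd in scene.nodes:
            node_mask = np.zeros(scene.shape, dtype=bool)
            from skimage.draw import disk as _disk

            rr, cc = _disk(nd.center, nd.radius + 0.5, shape=scene.shape)
            node_mask[rr, cc] = True
            series = dynamics.contact_timecourse_from_masks(
                mg_movie,
                node_mask,
                frame_interval=config.frame_interval,
                adjacency=config.adjacency,
                pair_id=("cell0", f"node{nd.id}"),
            )
            movie_rows.append(
                {
                    "condition": cond,
                    "node_id": nd.id,
                    "percent_frames_with_contact": dynamics.percent_frames_with_contact(series),
                    "longest_contact_run": dynamics.longest_run(series, True),
                    "longest_gap_run": dynamics.longest_run(series, False),
                }
            )
        for i, plan in enumerate(scene.tip_plan):
            tip = dynamics.TrackedTip(
                coords=truth.tip_tracks[i][:, ::-1],  # (y,x) -> (x,y)
                voxel_size_xy=config.voxel_size_xy,
                frame_interval=config.frame_interval,
                tip_id=f"{cond}_tip{plan.tip_id}",
                initial_contact=plan.initial_contact,
            )
            summary = dynamics.motility_summary(tip)
            tip_rows.append(
                {"condition": cond, "tip_id": tip.tip_id, "regime": plan.regime, **summary}
            )
            rel = dynamics.relative_trajectory(tip) * tip._scale()
            for t, (x, y) in enumerate(rel):
                rose_rows.append(
                    {"tip_id": tip.tip_id, "frame": t, "x_um": x, "y_um": y}
                )
        surv = morphodynamics.surveillance_index(mg_movie)
        r_per_frame = [
            morphodynamics.ramification_index(mg_movie[t], config.perimeter_estimator)
            for t in range(mg_movie.shape[0])
        ]
        morpho_rows.append(
            {
                "condition": cond,
                "cell_id": "cell0",
                "S": surv.S,
                "S_per_pair": float(surv.per_pair.mean()),
                "R_mean": float(np.mean(r_per_frame)),
            }
        )

    tables = {
        "node_calls": pd.DataFrame(node_rows),
        "field_results": pd.DataFrame(
            [
                {
                    "field_id": f.field_id,
                    "animal_id": f.animal_id,
                    "condition": f.condition,
                    "n_nodes": f.n_nodes,
                    "n_contacted": f.n_contacted,
                    "percent_contacted": f.percent_contacted,
                    "excluded": f.excluded,
                }
                for f in field_results
            ]
        ),
        "condition_summary": contacts.aggregate_mean_of_means(field_results),
        "contact_stability": pd.DataFrame(movie_rows),
        "tip_motility": pd.DataFrame(tip_rows),
        "rose_coordinates": pd.DataFrame(rose_rows),
        "morphodynamics": pd.DataFrame(morpho_rows),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)

    provenance = {
        "package": "nodeglia",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return tables


def make_fixtures(seed: int, outdir) -> dict:
    """Generate a small synthetic dataset exercising every module.

    Writes, per SNR level (high / medium / degraded negative control):
    two-channel OME-TIFF stacks for three fields, one short movie with
    per-frame microglia masks, ground-truth contact and track CSVs, and
    the scene JSON sidecar.  Deterministic in ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snr_levels = {  # (photon gain, read noise sd, psf sigma px)
        "high": (500.0, 0.005, 0.8),
        "medium": (50.0, 0.02, 1.0),
        "degraded": (0.5, 0.4, 1.5),  # intentionally unusable: negative control
    }
    index = {"seed": seed, "fields": [], "movies": []}
    ss = np.random.SeedSequence(seed)
    for level, (gain, read_sd, psf) in snr_levels.items():
        for fld in range(3):
            fseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            params = ImagingParams(photon_gain=gain, read_noise_sd=read_sd, psf_sigma=psf)
            scene, truth = generate_scene(
                seed=fseed, n_nodes=10, params=params, contacted_fraction=0.4
            )
            stacks = render(scene, truth, seed=fseed)
            base = outdir / f"{level}_field{fld}"
            for ch, st in stacks.items():
                write_stack(f"{base}_{ch}.ome.tif", st)
            np.save(f"{base}_clean_microglia.npy", truth.masks_clean[CHANNEL_MICROGLIA][0])
            np.save(f"{base}_clean_nodes.npy", truth.masks_clean[CHANNEL_NODES][0])
            pd.DataFrame(
                {
                    "node_id": np.arange(truth.contact_state.shape[0]),
                    "frame": 0,
                    "contacted": truth.contact_state[:, 0],
                }
            ).to_csv(f"{base}_contacts.csv", index=False)
            with open(f"{base}_scene.json", "w") as fh:
                fh.write(scene_to_json(scene))
            index["fields"].append({"level": level, "field": fld, "seed": fseed})
    # one movie with tracks
    mseed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
    params = ImagingParams(photon_gain=500.0, read_noise_sd=0.005, shape=(12, 1, 256, 256))
    scene, truth = generate_scene(
        seed=mseed, n_nodes=6, params=params, contacted_fraction=0.5,
        n_frames=12, attach=0.3, detach=0.1,
    )
    stacks = render(scene, truth, seed=mseed)
    for ch, st in stacks.items():
        write_stack(outdir / f"movie_{ch}.ome.tif", st)
    rows = []
    for i, plan in enumerate(scene.tip_plan):
        for t in range(truth.tip_tracks.shape[1]):
            y, x = truth.tip_tracks[i, t]
            rows.append(
                {
                    "tip_id": plan.tip_id,
                    "frame": t,
                    "x": x,
                    "y": y,
                    "initial_contact": plan.initial_contact,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "movie_tracks.csv", index=False)
    n_nodes, n_frames = truth.contact_state.shape
    pd.DataFrame(
        {
            "node_id": np.repeat(np.arange(n_nodes), n_frames),
            "frame": np.tile(np.arange(n_frames), n_nodes),
            "contacted": truth.contact_state.ravel(),
        }
    ).to_csv(outdir / "movie_contacts.csv", index=False)
    index["movies"].append({"seed": mseed, "n_frames": n_frames})
    with open(outdir / "index.json", "w") as fh:
        json.dump(index, fh, indent=2)
    return index
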