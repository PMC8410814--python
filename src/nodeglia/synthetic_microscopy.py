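"""Synthetic two-channel fluorescence scenes with exact ground truth.

Emulates the data this pipeline analyses: sparse bright nodal puncta
(sodium-channel clusters) along tube-like axons, a ramified microglial
cell whose processes extend to and retract from individual nodes, and
time-lapse movies in which per-node contact follows a two-state Markov
chain (attach probability ``a``, detach probability ``q`` per frame).
Tracked process tips move either as free isotropic Gaussian random walks
or as confined walks (discrete Ornstein-Uhlenbeck pull toward an anchor,
emulating a tip held at a node).

Construction is deliberately *constructive*, not sampled: a node marked
"in contact" at a frame has a microglial process pixel overlapping its
raster, and a node marked "no contact" has every microglial pixel kept
at least CLEARANCE_PX pixels away, so ground truth is unambiguous even
after PSF blurring and noise.  Rasters are hard binary before the PSF
for the same reason.

All randomness flows from one explicit integer seed through a single
:class:`numpy.random.Generator`; there is no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, line

from .stacks import ChannelStack

CHANNEL_MICROGLIA = "microglia"
CHANNEL_NODES = "nodes"

#: minimum Euclidean distance (pixels) between any microglia pixel and the
#: *center* of a non-contacted node; with the default node radius this
#: leaves a >= 2-px background gap between the rasters, wide enough that
#: PSF blur and thresholding cannot close it at realistic SNR.
CLEARANCE_PX = 4.0

#: processes are drawn as lines thickened by one 8-neighbourhood dilation
#: (3 px wide, ~0.6 µm at the default pixel size)
PROCESS_DILATION = np.ones((3, 3), dtype=bool)


class GeometryError(ValueError):
    """Requested scene geometry does not fit in the field of view."""


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition parameters of the simulated microscope.

    Defaults follow spinning-disk time-lapse of cerebellar slices:
    ~0.19 µm lateral pixels, 0.5 µm z-step, one frame every 30 s.
    ``photon_gain`` is the expected photon count at unit intensity;
    ``photon_gain=None`` (with ``read_noise_sd=0``) gives a noise-free
    render.  ``shape`` is the (t, z, y, x) extent of the field.
    """

    voxel_size_xy: float = 0.193
    voxel_size_z: float = 0.5
    frame_interval: float = 30.0
    psf_sigma: float = 1.0
    photon_gain: float | None = 200.0
    read_noise_sd: float = 0.01
    shape: tuple[int, int, int, int] = (1, 1, 256, 256)

    def __post_init__(self) -> None:
        for name in ("voxel_size_xy", "voxel_size_z", "frame_interval", "psf_sigma"):
            if getattr(self, name) < 0 or (
                name.startswith("voxel") and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.photon_gain is not None and self.photon_gain <= 0:
            raise ValueError("photon_gain must be positive or None")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if len(self.shape) != 4 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be (t, z, y, x) with extents >= 1")


def high_snr_params(n_frames: int = 1, shape_yx: tuple[int, int] = (256, 256)) -> ImagingParams:
    """Validation preset: optics and SNR at which mask recovery is
    essentially lossless (tight PSF, 500 expected photons, low read
    noise).  Acquisition SNR is a free simulation parameter, not a claim
    about any particular instrument."""
    return ImagingParams(
        psf_sigma=0.8,
        photon_gain=500.0,
        read_noise_sd=0.005,
        shape=(n_frames, 1, *shape_yx),
    )


@dataclass
class Node:
    id: int
    axon_id: int
    center: tuple[int, int]  # (y, x) pixel
    radius: int = 2


@dataclass
class ContactPlan:
    """Two-state Markov persistence for one node: P(attach)=a, P(detach)=q."""

    node_id: int
    attach: float
    detach: float
    initial: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.attach <= 1.0 and 0.0 <= self.detach <= 1.0):
            raise ValueError("attach/detach probabilities must lie in [0, 1]")


@dataclass
class TipPlan:
    """Motion regime for one tracked process tip.

    ``free``: isotropic Gaussian walk with per-axis step sd ``sigma`` px.
    ``confined``: the same walk plus a pull of strength ``kappa`` per
    frame toward ``anchor`` (discrete Ornstein-Uhlenbeck).
    """

    tip_id: int
    regime: str
    sigma: float
    kappa: float
    start: tuple[float, float]
    anchor: tuple[float, float]
    initial_contact: bool = False

    def __post_init__(self) -> None:
        if self.regime not in ("free", "confined"):
            raise ValueError("regime must be 'free' or 'confined'")
        if self.sigma < 0 or self.kappa < 0:
            raise ValueError("sigma and kappa must be >= 0")


@dataclass
class Scene:
    """Geometric description of one synthetic field."""

    shape: tuple[int, int]  # (y, x)
    axons: list[np.ndarray]  # polyline vertices, (n, 2) float (y, x)
    nodes: list[Node]
    soma_center: tuple[int, int]
    soma_radius: int
    process_paths: dict[int, np.ndarray]  # node id -> (n, 2) int pixels
    decoy_paths: list[np.ndarray]
    contact_plan: list[ContactPlan]
    tip_plan: list[TipPlan]
    params: ImagingParams = field(default_factory=ImagingParams)


@dataclass
class GroundTruth:
    """Exact truth for one scene: contact states, tracks, clean rasters."""

    contact_state: np.ndarray  # (n_nodes, n_frames) bool
    tip_tracks: np.ndarray  # (n_tips, n_frames, 2) float (y, x)
    node_centroids: np.ndarray  # (n_nodes, 2) float (y, x)
    masks_clean: dict[str, np.ndarray]  # channel -> (t, y, x) bool


# ---------------------------------------------------------------------------
# scene construction


def _axon_polyline(y_row: float, width: int, amplitude: float, phase: float) -> np.ndarray:
    x = np.arange(width, dtype=float)
    y = y_row + amplitude * np.sin(2 * np.pi * x / max(width, 1) + phase)
    return np.column_stack([y, x])


def _node_disk(center: tuple[int, int], radius: int, shape: tuple[int, int]):
    return disk(center, radius + 0.5, shape=shape)


def _path_pixels(p0: tuple[int, int], p1: tuple[int, int]) -> np.ndarray:
    rr, cc = line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
    return np.column_stack([rr, cc])


def _carve_clearance(raster: np.ndarray, node: Node) -> None:
    """Remove raster pixels within radius + CLEARANCE_PX of the node center."""
    h, w = raster.shape
    reach = int(np.ceil(node.radius + CLEARANCE_PX)) + 1
    y0, y1 = max(0, node.center[0] - reach), min(h, node.center[0] + reach + 1)
    x0, x1 = max(0, node.center[1] - reach), min(w, node.center[1] + reach + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    close = np.hypot(yy - node.center[0], xx - node.center[1]) < node.radius + CLEARANCE_PX
    raster[y0:y1, x0:x1][close] = False


def generate_scene(
    seed: int,
    n_axons: int = 4,
    n_nodes: int = 8,
    params: ImagingParams | None = None,
    contacted_fraction: float = 0.4,
    n_frames: int = 1,
    attach: float = 0.0,
    detach: float = 0.0,
    node_radius: int = 3,
    soma_radius: int = 6,
    n_decoys: int = 3,
    n_free_tips: int = 2,
    tip_sigma: float = 1.5,
    tip_kappa: float = 0.5,
) -> tuple[Scene, GroundTruth]:
    """Build a synthetic field and its exact ground truth.

    Exactly ``round(contacted_fraction * n_nodes)`` nodes are contacted
    at the first frame (placement is constructive, not sampled).  For
    movies (``n_frames > 1``) per-node contact then evolves as a Markov
    chain with per-frame attach/detach probabilities.  One confined tip
    is planted per initially-contacted node (anchored at the contact
    point) and ``n_free_tips`` free tips per contacted node elsewhere in
    the field, mirroring the tracking protocol of one contacting tip
    plus randomly chosen non-contacting tips per movie.

    Raises
    ------
    GeometryError
        If the requested axons/nodes cannot be placed with the enforced
        spacing in the field of view.
    """
    if n_axons < 0 or n_nodes < 0:
        raise ValueError("counts must be >= 0")
    if not 0.0 <= contacted_fraction <= 1.0:
        raise ValueError("contacted_fraction must lie in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    params = params or ImagingParams()
    h, w = params.shape[2], params.shape[3]
    rng = np.random.default_rng(seed)

    if n_nodes > 0 and n_axons == 0:
        raise GeometryError("nodes require at least one axon")

    # axons: horizontal rows with a gentle sinusoidal wiggle, avoiding a
    # central exclusion zone reserved for the soma
    margin_y = max(12, soma_radius + node_radius + int(CLEARANCE_PX) + 4)
    rows: list[float] = []
    if n_axons > 0:
        usable = np.linspace(margin_y, h - margin_y, n_axons + 2)[1:-1]
        if len(usable) < n_axons or h < 2 * margin_y + n_axons:
            raise GeometryError(f"{n_axons} axons do not fit in height {h}")
        rows = list(usable)
    axons = [
        _axon_polyline(row, w, amplitude=2.0, phase=rng.uniform(0, 2 * np.pi))
        for row in rows
    ]

    soma_center = (h // 2, w // 2)
    # nodes: spread along axons with enforced spacing, away from soma
    margin_x = 12
    min_spacing = 4 * (node_radius + int(CLEARANCE_PX))
    nodes: list[Node] = []
    if n_nodes > 0:
        per_axon = int(np.ceil(n_nodes / n_axons))
        slots_per_axon = max(1, (w - 2 * margin_x) // min_spacing)
        if per_axon > slots_per_axon:
            raise GeometryError(
                f"{n_nodes} nodes do not fit on {n_axons} axons of width {w}"
            )
        nid = 0
        for ax_id in range(n_axons):
            if nid >= n_nodes:
                break
            n_here = min(per_axon, n_nodes - nid)
            xs = np.linspace(margin_x, w - margin_x, n_here + 2)[1:-1]
            xs = xs + rng.uniform(-2, 2, size=n_here)
            for x in xs:
                xi = int(round(float(np.clip(x, margin_x, w - margin_x - 1))))
                yi = int(round(float(axons[ax_id][xi, 0])))
                c = (yi, xi)
                if np.hypot(c[0] - soma_center[0], c[1] - soma_center[1]) < (
                    soma_radius + node_radius + CLEARANCE_PX + 2
                ):
                    # nudge out of the soma exclusion zone along the axon
                    xi = xi + min_spacing if xi < w // 2 else xi - min_spacing
                    xi = int(np.clip(xi, margin_x, w - margin_x - 1))
                    yi = int(round(float(axons[ax_id][xi, 0])))
                    c = (yi, xi)
                nodes.append(Node(id=nid, axon_id=ax_id, center=c, radius=node_radius))
                nid += 1

    # initial contact assignment: constructive, exact count
    n_contacted = int(round(contacted_fraction * n_nodes))
    contacted_ids = rng.choice(n_nodes, size=n_contacted, replace=False) if n_nodes else np.array([], int)
    initial = np.zeros(n_nodes, dtype=bool)
    initial[contacted_ids] = True

    contact_plan = [
        ContactPlan(node_id=nd.id, attach=attach, detach=detach, initial=bool(initial[nd.id]))
        for nd in nodes
    ]

    # one straight process per node from soma towards the node; the full
    # path ends with one pixel inside the node raster (overlap).  When a
    # node is out of contact, rendering carves every microglia pixel out
    # of its clearance zone, which truncates the process constructively.
    process_paths: dict[int, np.ndarray] = {}
    for nd in nodes:
        raw = _path_pixels(soma_center, nd.center)
        d = np.hypot(raw[:, 0] - nd.center[0], raw[:, 1] - nd.center[1])
        inside = np.nonzero(d <= nd.radius)[0]
        end = inside[0] + 1 if len(inside) else len(raw)
        process_paths[nd.id] = raw[:end]

    # decoy processes in random directions (clearance enforced at render)
    decoy_paths: list[np.ndarray] = []
    reach = 0.4 * min(h, w)
    for _ in range(n_decoys):
        ang = rng.uniform(0, 2 * np.pi)
        tip = (
            int(np.clip(soma_center[0] + reach * np.sin(ang), 1, h - 2)),
            int(np.clip(soma_center[1] + reach * np.cos(ang), 1, w - 2)),
        )
        decoy_paths.append(_path_pixels(soma_center, tip))

    # Markov evolution of per-node contact
    contact_state = np.zeros((n_nodes, n_frames), dtype=bool)
    if n_nodes:
        contact_state[:, 0] = initial
        for t in range(1, n_frames):
            u = rng.random(n_nodes)
            prev = contact_state[:, t - 1]
            contact_state[:, t] = np.where(prev, u >= detach, u < attach)

    # tracked tips: one confined per initially contacted node, plus free tips
    tip_plan: list[TipPlan] = []
    tid = 0
    for nd in nodes:
        if not initial[nd.id]:
            continue
        path = process_paths[nd.id]
        anchor = tuple(map(float, path[-1])) if len(path) else tuple(map(float, nd.center))
        tip_plan.append(
            TipPlan(tid, "confined", tip_sigma, tip_kappa, anchor, anchor, initial_contact=True)
        )
        tid += 1
    n_free = n_free_tips * int(initial.sum())
    for _ in range(n_free):
        start = (
            float(rng.uniform(margin_y, h - margin_y)),
            float(rng.uniform(margin_x, w - margin_x)),
        )
        tip_plan.append(TipPlan(tid, "free", tip_sigma, 0.0, start, start, initial_contact=False))
        tid += 1

    scene = Scene(
        shape=(h, w),
        axons=axons,
        nodes=nodes,
        soma_center=soma_center,
        soma_radius=soma_radius,
        process_paths=process_paths,
        decoy_paths=decoy_paths,
        contact_plan=contact_plan,
        tip_plan=tip_plan,
        params=params,
    )

    tip_tracks = simulate_tip_motion(scene, n_frames, seed=int(rng.integers(2**31)))
    masks_clean = {
        CHANNEL_NODES: np.broadcast_to(_render_node_raster(scene), (n_frames, h, w)).copy(),
        CHANNEL_MICROGLIA: np.stack(
            [_render_microglia_raster(scene, contact_state[:, t]) for t in range(n_frames)]
        ),
    }
    truth = GroundTruth(
        contact_state=contact_state,
        tip_tracks=tip_tracks,
        node_centroids=np.array([nd.center for nd in nodes], dtype=float).reshape(n_nodes, 2),
        masks_clean=masks_clean,
    )
    return scene, truth


def _render_node_raster(scene: Scene) -> np.ndarray:
    h, w = scene.shape
    raster = np.zeros((h, w), dtype=bool)
    for nd in scene.nodes:
        rr, cc = _node_disk(nd.center, nd.radius, (h, w))
        raster[rr, cc] = True
    return raster


def _render_microglia_raster(scene: Scene, contact: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    h, w = scene.shape
    raster = np.zeros((h, w), dtype=bool)
    rr, cc = disk(scene.soma_center, scene.soma_radius, shape=(h, w))
    raster[rr, cc] = True
    for decoy in scene.decoy_paths:
        if len(decoy):
            raster[decoy[:, 0], decoy[:, 1]] = True
    for nd in scene.nodes:
        path = scene.process_paths[nd.id]
        if len(path):
            raster[path[:, 0], path[:, 1]] = True
    raster = binary_dilation(raster, structure=PROCESS_DILATION)
    # constructive truth: carve the clearance zone of every node that is
    # out of contact this frame (truncates its process and any passer-by)
    for nd in scene.nodes:
        if not contact[nd.id]:
            _carve_clearance(raster, nd)
    return raster


# ---------------------------------------------------------------------------
# tip motion


def simulate_random_walks(
    n_tracks: int,
    n_frames: int,
    sigma: float,
    kappa: float = 0.0,
    seed: int = 0,
    start: tuple[float, float] = (0.0, 0.0),
    anchor: tuple[float, float] | None = None,
) -> np.ndarray:
    """Simulate 2D Gaussian walks, optionally confined (AR(1) toward anchor).

    Free walk (``kappa=0``): x_{t+1} = x_t + sigma * N(0, I).  Confined:
    x_{t+1} = x_t + sigma * N(0, I) - kappa * (x_t - anchor), whose
    per-axis deviation from the anchor is AR(1) with coefficient
    (1 - kappa) and stationary variance sigma^2 / (1 - (1-kappa)^2).

    Returns an array of shape ``(n_tracks, n_frames, 2)``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if sigma < 0 or kappa < 0:
        raise ValueError("sigma and kappa must be >= 0")
    rng = np.random.default_rng(seed)
    anchor_arr = np.asarray(anchor if anchor is not None else start, dtype=float)
    tracks = np.empty((n_tracks, n_frames, 2), dtype=float)
    tracks[:, 0] = np.asarray(start, dtype=float)
    steps = rng.normal(0.0, sigma if sigma > 0 else 0.0, size=(n_tracks, n_frames - 1, 2))
    if kappa == 0.0:
        tracks[:, 1:] = tracks[:, :1] + np.cumsum(steps, axis=1)
    else:
        pos = tracks[:, 0].copy()
        for t in range(1, n_frames):
            pos = pos + steps[:, t - 1] - kappa * (pos - anchor_arr)
            tracks[:, t] = pos
    return tracks


def simulate_tip_motion(scene: Scene, n_frames: int, seed: int) -> np.ndarray:
    """Simulate every planned tip of a scene; returns (n_tips, n_frames, 2)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((len(scene.tip_plan), n_frames, 2), dtype=float)
    for i, plan in enumerate(scene.tip_plan):
        if n_frames == 1:
            out[i, 0] = plan.start
            continue
        kappa = plan.kappa if plan.regime == "confined" else 0.0
        out[i] = simulate_random_walks(
            1,
            n_frames,
            plan.sigma,
            kappa=kappa,
            seed=int(rng.integers(2**31)),
            start=plan.start,
            anchor=plan.anchor,
        )[0]
    return out


# ---------------------------------------------------------------------------
# contact-series simulation (analysis-free oracle for run statistics)


def simulate_contact_series(
    n_series: int,
    n_frames: int,
    attach: float,
    detach: float,
    seed: int = 0,
    initial: bool | float = None,
) -> np.ndarray:
    """Simulate two-state Markov contact series, shape (n_series, n_frames).

    ``initial`` may be a bool (all series start there) or a probability of
    starting in contact; by default the stationary probability
    a / (a + q) is used (1.0 if both are 0).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0 <= attach <= 1 and 0 <= detach <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if initial is None:
        p0 = attach / (attach + detach) if (attach + detach) > 0 else 1.0
    elif isinstance(initial, (bool, np.bool_)):
        p0 = 1.0 if initial else 0.0
    else:
        p0 = float(initial)
    state = np.zeros((n_series, n_frames), dtype=bool)
    state[:, 0] = rng.random(n_series) < p0
    for t in range(1, n_frames):
        u = rng.random(n_series)
        prev = state[:, t - 1]
        state[:, t] = np.where(prev, u >= detach, u < attach)
    return state


# ---------------------------------------------------------------------------
# rendering


def render(
    scene: Scene,
    ground_truth: GroundTruth,
    params: ImagingParams | None = None,
    seed: int = 0,
    amplitude: float = 1.0,
    channels: tuple[str, ...] = (CHANNEL_MICROGLIA, CHANNEL_NODES),
) -> dict[str, ChannelStack]:
    """Render clean rasters into noisy intensity stacks, one per channel.

    Pipeline per frame: binary raster x ``amplitude`` -> Gaussian PSF of
    sd ``psf_sigma`` px -> Poisson photon noise at ``photon_gain``
    expected photons per unit intensity -> additive Gaussian read noise.
    With ``photon_gain=None`` and ``read_noise_sd=0`` the blurred clean
    signal is returned (noise-free mode); with ``psf_sigma=0`` as well,
    the output equals the clean raster scaled by ``amplitude``.
    """
    params = params or scene.params
    rng = np.random.default_rng(seed)
    out: dict[str, ChannelStack] = {}
    for ch in channels:
        clean = ground_truth.masks_clean[ch]
        frames = []
        for t in range(clean.shape[0]):
            img = clean[t].astype(float) * amplitude
            if params.psf_sigma > 0:
                img = gaussian_filter(img, params.psf_sigma)
            if params.photon_gain is not None:
                img = rng.poisson(img * params.photon_gain).astype(float) / params.photon_gain
            if params.read_noise_sd > 0:
                img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
            frames.append(np.clip(img, 0.0, None))
        data = np.stack(frames)
        n_frames = data.shape[0]
        if n_frames == 1:
            out[ch] = ChannelStack(
                data=data[0],
                axes="YX",
                voxel_size_xy=params.voxel_size_xy,
                channel=ch,
            )
        else:
            out[ch] = ChannelStack(
                data=data,
                axes="TYX",
                voxel_size_xy=params.voxel_size_xy,
                frame_interval=params.frame_interval,
                channel=ch,
            )
    return out


# ---------------------------------------------------------------------------
# serialization of scene parameters (JSON sidecar)


def scene_to_json(scene: Scene) -> str:
    """JSON description of scene geometry and plans (arrays as lists)."""
    doc = {
        "shape": list(scene.shape),
        "soma_center": list(scene.soma_center),
        "soma_radius": scene.soma_radius,
        "nodes": [
            {"id": nd.id, "axon_id": nd.axon_id, "center": list(nd.center), "radius": nd.radius}
            for nd in scene.nodes
        ],
        "contact_plan": [asdict(cp) for cp in scene.contact_plan],
        "tip_plan": [asdict(tp) for tp in scene.tip_plan],
        "params": asdict(scene.params),
    }
    return json.dumps(doc, indent=2)
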