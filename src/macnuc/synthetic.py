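"""Synthetic beads-on-a-string macronuclei with analytically known volume.

The *Stentor* macronucleus is modelled as a chain of spheres ("nodes",
~30 μm diameter in vivo) joined by thin coaxial cylinders ("connectors",
~1–2 μm wide) along a straight horizontal axis; whole chains reach
~400 μm. Connectors attach at the sphere surfaces, so the ground-truth
volume is an exact disjoint sum of sphere and cylinder volumes — a
closed-form oracle for the silhouette volume estimator. The module also
simulates full coalescence-cycle time courses (node count collapsing to
one while total volume rises ~35%) and two-channel puncta images with
per-spot ground truth, so every downstream stage is testable without any
raw microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .volume import SilhouetteMask

__all__ = [
    "NucleusSpec",
    "TimecourseGroundTruth",
    "SimulatedCell",
    "SimulatedCohort",
    "PunctaImageParams",
    "PunctaGroundTruth",
    "analytic_volume",
    "render_silhouette",
    "simulate_timecourse",
    "render_puncta_image",
]


@dataclass(frozen=True)
class NucleusSpec:
    """Parametric beads-on-string nucleus with closed-form volume.

    Parameters
    ----------
    node_radii
        Sphere radii in μm, ordered along the axis; all > 0.
    gap_lengths
        Axial gap between consecutive sphere *surfaces* in μm; length must
        be ``len(node_radii) - 1``; all >= 0. A zero gap means touching
        spheres with no connector segment.
    connector_radius_um
        Radius of the connecting cylinders in μm; must be smaller than
        every node radius.
    """

    node_radii: tuple[float, ...]
    gap_lengths: tuple[float, ...] = ()
    connector_radius_um: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_radii", tuple(float(r) for r in self.node_radii))
        object.__setattr__(self, "gap_lengths", tuple(float(g) for g in self.gap_lengths))
        if len(self.node_radii) < 1:
            raise ValueError("need at least one node")
        if any(r <= 0 for r in self.node_radii):
            raise ValueError("all node radii must be > 0")
        if len(self.gap_lengths) != len(self.node_radii) - 1:
            raise ValueError(
                f"need {len(self.node_radii) - 1} gaps for "
                f"{len(self.node_radii)} nodes, got {len(self.gap_lengths)}"
            )
        if any(g < 0 for g in self.gap_lengths):
            raise ValueError("gaps must be >= 0")
        if self.connector_radius_um <= 0:
            raise ValueError("connector radius must be > 0")
        if self.connector_radius_um >= min(self.node_radii):
            raise ValueError("connector radius must be < min node radius")

    @property
    def n_nodes(self) -> int:
        return len(self.node_radii)

    @property
    def node_centers(self) -> np.ndarray:
        """Axial sphere-centre positions (μm), chain starting at x=0."""
        centers = [self.node_radii[0]]
        for i, g in enumerate(self.gap_lengths):
            centers.append(
                centers[-1] + self.node_radii[i] + g + self.node_radii[i + 1]
            )
        return np.asarray(centers)

    @property
    def chain_length_um(self) -> float:
        return float(self.node_centers[-1] + self.node_radii[-1])

    @property
    def max_radius_um(self) -> float:
        return max(self.node_radii)


def analytic_volume(spec: NucleusSpec) -> float:
    """Exact volume (μm³) of a beads-on-string spec.

    Σ (4/3)π rᵢ³ over nodes plus Σ π r_c² gⱼ over connectors; the terms
    are disjoint because connectors span only the axial gap between
    sphere surfaces.
    """
    nodes = sum(4.0 / 3.0 * np.pi * r**3 for r in spec.node_radii)
    connectors = sum(
        np.pi * spec.connector_radius_um**2 * g for g in spec.gap_lengths
    )
    return float(nodes + connectors)


def _half_profile(spec: NucleusSpec, x: np.ndarray) -> np.ndarray:
    """Silhouette half-height r(x) in μm of the rotationally symmetric solid."""
    r = np.zeros_like(x, dtype=float)
    centers = spec.node_centers
    for c, R in zip(centers, spec.node_radii):
        inside = np.abs(x - c) < R
        np.maximum(
            r,
            np.where(inside, np.sqrt(np.maximum(R**2 - (x - c) ** 2, 0.0)), 0.0),
            out=r,
        )
    for i, g in enumerate(spec.gap_lengths):
        if g <= 0:
            continue
        x0 = centers[i] + spec.node_radii[i]
        seg = (x >= x0) & (x <= x0 + g)
        np.maximum(r, np.where(seg, spec.connector_radius_um, 0.0), out=r)
    return r


def render_silhouette(
    spec: NucleusSpec,
    pixel_size_um: float,
    margin_px: int = 2,
    shape: Optional[tuple[int, int]] = None,
    cell_id: Optional[str] = None,
    frame: Optional[int] = None,
) -> SilhouetteMask:
    """Rasterize the axial cross-section of a spec into a binary mask.

    A pixel is foreground iff its centre lies within the 2D cross-section
    ``{(x, y): |y| <= r(x)}`` of the solid of revolution (pixel-centre
    rule: unambiguous and resolution-convergent). The raster's horizontal
    axis coincides with the model axis, which passes exactly through the
    centre row.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    s = pixel_size_um
    need_nx = int(np.ceil(spec.chain_length_um / s)) + 2 * margin_px
    half_ny = int(np.ceil(spec.max_radius_um / s)) + margin_px
    need_ny = 2 * half_ny + 1  # odd: axis on a pixel-centre row
    if shape is None:
        ny, nx = need_ny, need_nx
    else:
        ny, nx = shape
        if ny < need_ny or nx < need_nx:
            raise ValueError(
                f"raster {shape} too small; need at least ({need_ny}, {need_nx}) "
                f"for a {spec.chain_length_um:.1f} x "
                f"{2 * spec.max_radius_um:.1f} um chain at {s} um/px"
            )
    cy = ny // 2
    # pixel-centre world coordinates; chain starts margin_px columns in
    x = (np.arange(nx) - margin_px + 0.5) * s
    y = (np.arange(ny) - cy) * s
    r = _half_profile(spec, x)
    raster = np.abs(y)[:, None] <= r[None, :]
    raster &= r[None, :] > 0
    return SilhouetteMask(raster=raster, pixel_size_um=s, cell_id=cell_id, frame=frame)


# ---------------------------------------------------------------------------
# coalescence-cycle time courses
# ---------------------------------------------------------------------------

@dataclass
class TimecourseGroundTruth:
    """Noise-free trajectory shared by all simulated cells of a cohort."""

    frames: pd.DataFrame  # time_min, true_volume_um3, true_node_count
    peak_fold_change: float
    coalescence_time_min: float
    frame_interval_min: float
    baseline_volume_um3: float


@dataclass
class SimulatedCell:
    cell_id: str
    times_min: np.ndarray
    specs: list  # per-frame NucleusSpec


@dataclass
class SimulatedCohort:
    cells: list
    ground_truth: TimecourseGroundTruth


def _node_count_schedule(
    times: np.ndarray,
    max_nodes: int,
    min_nodes: int,
    t_coalesce: float,
    descent_min: float,
    coalesced_min: float,
    renodulation_min: float,
) -> np.ndarray:
    counts = np.full(times.shape, max_nodes, dtype=int)
    t_end = t_coalesce + coalesced_min
    for i, t in enumerate(times):
        if t < t_coalesce - descent_min:
            c = max_nodes
        elif t < t_coalesce:
            frac = (t_coalesce - t) / descent_min
            c = int(np.ceil(min_nodes + frac * (max_nodes - min_nodes)))
            c = min(max_nodes, max(min_nodes + 1, c))
        elif t <= t_end:
            c = min_nodes
        elif t < t_end + renodulation_min:
            frac = (t - t_end) / renodulation_min
            c = int(np.ceil(min_nodes + frac * (max_nodes - min_nodes)))
            c = min(max_nodes, max(min_nodes + 1, c))
        else:
            c = max_nodes
        counts[i] = c
    return counts


def _volume_schedule(
    times: np.ndarray,
    baseline: float,
    fold: float,
    t_coalesce: float,
    descent_min: float,
    coalesced_min: float,
    renodulation_min: float,
) -> np.ndarray:
    """Symmetric piecewise-linear trapezoid.

    Volume rises during node-count descent, holds at ``fold * baseline``
    for the whole minimum-count plateau, and relaxes during renodulation.
    The plateau reproduces the observed ~1.35x ratio of mean volumes
    between minimum- and maximum-node-count frames.
    """
    t_end = t_coalesce + coalesced_min
    v = np.full(times.shape, baseline, dtype=float)
    for i, t in enumerate(times):
        if t_coalesce - descent_min <= t < t_coalesce:
            frac = 1.0 - (t_coalesce - t) / descent_min
            v[i] = baseline * (1.0 + frac * (fold - 1.0))
        elif t_coalesce <= t <= t_end:
            v[i] = baseline * fold
        elif t_end < t < t_end + renodulation_min:
            frac = 1.0 - (t - t_end) / renodulation_min
            v[i] = baseline * (1.0 + frac * (fold - 1.0))
    return v


def _spec_for(
    n_nodes: int,
    target_volume: float,
    gap_um: float,
    connector_radius_um: float,
    radius_noise: np.ndarray,
) -> NucleusSpec:
    """Spec with ``n_nodes`` equal nodes whose noiseless volume is exact."""
    if n_nodes > 1:
        v_conn = (n_nodes - 1) * np.pi * connector_radius_um**2 * gap_um
        gaps = (gap_um,) * (n_nodes - 1)
    else:
        v_conn, gaps = 0.0, ()
    v_node = (target_volume - v_conn) / n_nodes
    if v_node <= 0:
        raise ValueError("target volume too small for connector geometry")
    r = (3.0 * v_node / (4.0 * np.pi)) ** (1.0 / 3.0)
    radii = tuple(r * f for f in radius_noise)
    return NucleusSpec(node_radii=radii, gap_lengths=gaps,
                       connector_radius_um=connector_radius_um)


def simulate_timecourse(
    n_cells: int = 11,
    baseline_spec: NucleusSpec | None = None,
    peak_fold_change: float = 1.35,
    coalescence_time_min: float = 335.0,
    n_frames: int = 40,
    noise_sd: float = 0.05,
    seed: int = 0,
    frame_interval_min: float = 5.0,
    start_time_min: float = 240.0,
    min_nodes: int = 1,
    descent_min: float = 30.0,
    coalesced_min: float = 50.0,
    renodulation_min: float = 30.0,
) -> SimulatedCohort:
    """Simulate a cohort of cells through one coalescence cycle.

    Defaults emulate typical live-imaging conditions: 11 cells imaged every 5 min
    through the latter half of regeneration (240–435 min post sucrose
    shock), node count stepping from 8 down to 1 at ``coalescence_time``
    (the first minimum-count frame), a ~50 min coalesced/elongated phase
    at minimum count, and a 1.35-fold total-volume peak spanning it.

    ``noise_sd`` is the relative standard deviation of the per-frame
    volume measurement: tracing error is strongly correlated across one
    frame (the whole outline is over- or under-traced together), so each
    frame's node radii share one multiplicative lognormal perturbation
    whose cube is the frame's volume factor. Ground truth stays
    noise-free; ``peak_fold_change`` is exact there.

    Deterministic given ``seed``.
    """
    if peak_fold_change < 1.0:
        raise ValueError("peak_fold_change must be >= 1")
    if n_cells < 1 or n_frames < 1:
        raise ValueError("need at least one cell and one frame")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if baseline_spec is None:
        # 8 nodes of 15 um radius, 20 um gaps, 1 um connectors (~420 um chain)
        baseline_spec = NucleusSpec(
            node_radii=(15.0,) * 8, gap_lengths=(20.0,) * 7, connector_radius_um=1.0
        )
    rng = np.random.default_rng(seed)
    max_nodes = baseline_spec.n_nodes
    gap_um = float(np.mean(baseline_spec.gap_lengths)) if baseline_spec.gap_lengths else 20.0
    r_c = baseline_spec.connector_radius_um
    baseline_v = analytic_volume(baseline_spec)
    times = start_time_min + frame_interval_min * np.arange(n_frames)

    counts = _node_count_schedule(
        times, max_nodes, min_nodes, coalescence_time_min,
        descent_min, coalesced_min, renodulation_min,
    )
    volumes = _volume_schedule(
        times, baseline_v, peak_fold_change, coalescence_time_min,
        descent_min, coalesced_min, renodulation_min,
    )
    gt = TimecourseGroundTruth(
        frames=pd.DataFrame(
            {"time_min": times, "true_volume_um3": volumes, "true_node_count": counts}
        ),
        peak_fold_change=peak_fold_change,
        coalescence_time_min=coalescence_time_min,
        frame_interval_min=frame_interval_min,
        baseline_volume_um3=baseline_v,
    )
    sigma_ln = np.sqrt(np.log1p(noise_sd**2))  # lognormal with relative sd noise_sd
    cells = []
    for c in range(n_cells):
        specs = []
        for n, v in zip(counts, volumes):
            factor = float(np.exp(rng.normal(0.0, sigma_ln))) if noise_sd > 0 else 1.0
            scale = factor ** (1.0 / 3.0)
            if int(n) == max_nodes and np.isclose(v, baseline_v):
                # baseline frames keep the baseline geometry (node radii may
                # be heterogeneous), only perturbed by the tracing factor
                specs.append(
                    NucleusSpec(
                        node_radii=tuple(scale * r for r in baseline_spec.node_radii),
                        gap_lengths=baseline_spec.gap_lengths,
                        connector_radius_um=r_c,
                    )
                )
            else:
                specs.append(_spec_for(int(n), float(v), gap_um, r_c,
                                       np.full(int(n), scale)))
        cells.append(SimulatedCell(cell_id=f"cell{c:02d}", times_min=times.copy(),
                                   specs=specs))
    return SimulatedCohort(cells=cells, ground_truth=gt)


# ---------------------------------------------------------------------------
# puncta fixtures
# ---------------------------------------------------------------------------

@dataclass
class PunctaImageParams:
    """Geometry and photometry of a synthetic two-channel puncta image.

    Channel 1 carries Gaussian-profile spots over a smooth background with
    additive Gaussian noise; channel 2 is a filled elliptical cell body
    (pigment-autofluorescence surrogate) used to delineate the cell.
    Intensities are arbitrary units; spot ``amplitude`` is the peak height
    above background.
    """

    shape: tuple[int, int] = (256, 384)
    pixel_size_um: float = 0.25
    exposure_s: float = 1.0
    n_spots: int = 12
    spot_diameter_um: tuple[float, float] = (1.0, 4.0)  # FWHM range
    spot_amplitude: tuple[float, float] = (4000.0, 9000.0)
    min_separation_um: float = 6.0
    background_level: float = 300.0
    background_gradient: float = 200.0  # peak-to-peak of smooth ramp
    noise_sd: float = 30.0
    cell_level: float = 3000.0
    cell_axes_frac: tuple[float, float] = (0.40, 0.42)


@dataclass
class PunctaGroundTruth:
    spots: pd.DataFrame  # y_px, x_px, fwhm_um, amplitude, integrated_intensity
    cell_mask: np.ndarray
    params: PunctaImageParams


def render_puncta_image(
    params: PunctaImageParams | None = None,
    seed: int = 0,
    spot_table: Optional[pd.DataFrame] = None,
) -> tuple[np.ndarray, PunctaGroundTruth]:
    """Render a (2, ny, nx) float image plus per-spot ground truth.

    Spots are placed by rejection sampling inside the eroded cell mask
    with pairwise separation >= ``min_separation_um``. Pass ``spot_table``
    (columns y_px, x_px, fwhm_um, amplitude) to place spots explicitly.
    Deterministic given ``seed``.
    """
    if params is None:
        params = PunctaImageParams()
    rng = np.random.default_rng(seed)
    ny, nx = params.shape
    s = params.pixel_size_um
    yy, xx = np.mgrid[0:ny, 0:nx]

    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ay, ax = params.cell_axes_frac[0] * ny, params.cell_axes_frac[1] * nx
    cell_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    if spot_table is None:
        placed: list[tuple[float, float]] = []
        rows = []
        min_sep_px = params.min_separation_um / s
        attempts = 0
        while len(rows) < params.n_spots and attempts < 20000:
            attempts += 1
            y = rng.uniform(0, ny)
            x = rng.uniform(0, nx)
            iy, ix = int(y), int(x)
            if not (0 <= iy < ny and 0 <= ix < nx and cell_mask[iy, ix]):
                continue
            # keep whole spot inside the cell
            fwhm = rng.uniform(*params.spot_diameter_um)
            r_px = 1.5 * fwhm / s
            if (
                ((iy - cy) / (ay - r_px)) ** 2 + ((ix - cx) / (ax - r_px)) ** 2
                > 1.0
            ):
                continue
            if any((y - py) ** 2 + (x - px) ** 2 < min_sep_px**2 for py, px in placed):
                continue
            placed.append((y, x))
            rows.append(
                {"y_px": y, "x_px": x, "fwhm_um": fwhm,
                 "amplitude": rng.uniform(*params.spot_amplitude)}
            )
        if len(rows) < params.n_spots:
            raise RuntimeError("could not place all spots; relax separation")
        spot_table = pd.DataFrame(rows)
    else:
        spot_table = spot_table.copy()

    # smooth diagonal ramp background
    ramp = (xx / max(nx - 1, 1) + yy / max(ny - 1, 1)) / 2.0
    signal = params.background_level + params.background_gradient * ramp
    integrated = []
    for _, sp in spot_table.iterrows():
        sigma_px = sp.fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s
        g = np.exp(-(((yy - sp.y_px) ** 2 + (xx - sp.x_px) ** 2) / (2 * sigma_px**2)))
        signal = signal + sp.amplitude * g
        integrated.append(float(sp.amplitude * 2 * np.pi * sigma_px**2))
    spot_table["integrated_intensity"] = integrated
    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    autofl = np.where(cell_mask, params.cell_level, params.background_level / 3.0)
    if params.noise_sd > 0:
        autofl = autofl + rng.normal(0.0, params.noise_sd, size=autofl.shape)
    autofl = np.clip(autofl, 0.0, None)

    image = np.stack([signal, autofl]).astype(np.float64)
    gt = PunctaGroundTruth(spots=spot_table, cell_mask=cell_mask, params=params)
    return image, gt
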