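"""Seeded synthetic data: two-channel Ca2+ movies and labeled voxel phantoms.

Every downstream stage of the package is exercised against data produced
here, with construction-time ground truth.  The movie generator emulates a
confocal recording of a retinal capillary: a static vessel channel (SR101)
showing one straight or curved capillary, and a glial channel (Fluo-4) in
which a puff-triggered Ca2+ wave expands radially from its origin and
activates, in turn, the perivascular sheath annulus, bright Mueller-stalk
hotspots, and a dim responsive background.  A "dispersed" mode redistributes
the sheath annulus away from the vessel while conserving total signal,
mimicking the diffuse, vessel-dissociated sheath fluorescence seen in
photoreceptor-degeneration (rd10-like) retinas.

The volume generator builds a capillary phantom: a cylindrical lumen walled
by endothelium, optional pericyte patches on the wall, a glial sheath shell
with programmable gaps, and neuron processes that reach the vessel surface
only through gaps.  Coverage fraction, gap count and the contact table are
known exactly by construction.

Determinism contract: identical spec (including seed) => bit-identical
arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import polyline_distance_map, resample_polyline

NEURON_CLASSES = ("bipolar", "amacrine", "ganglion", "unassigned")

#: fixed label map used for all generated volumes; neuron processes get
#: labels FIRST_NEURON_LABEL + i
LABELS = {
    "background": 0,
    "lumen": 1,
    "endothelium": 2,
    "pericyte": 3,
    "glia": 4,
}
FIRST_NEURON_LABEL = 10


class SpecError(ValueError):
    """An inconsistent generator specification."""


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


@dataclass
class MovieSpec:
    """Parameters of one synthetic two-channel recording.

    Defaults describe the nominal acquisition emulated throughout the
    package: a 256 x 256 px field at 0.4 um/px and 0.5 s/frame, a straight
    4-um-diameter capillary crossing the field center, a 1.5-um sheath
    annulus, ~20 Mueller stalk hotspots, and an ATP puff delivered at the
    field edge whose activation wave travels at 15 um/s.  Amplitudes are in
    arbitrary fluorescence units on a baseline of 100; noise_sd is the
    per-pixel, per-frame additive Gaussian noise scale.
    """

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_size_um: float = 0.4
    n_frames: int = 45
    frame_interval_s: float = 0.5
    vessel_centerline: np.ndarray | None = None  # (N,2) (row,col) px; None = straight
    vessel_radius_um: float = 2.0
    sheath_thickness_um: float = 1.5
    baseline_f0: float = 100.0
    sheath_amplitude: float = 5.0
    stalk_amplitude: float = 25.0
    background_amplitude: float = 0.5
    n_stalks: int = 40
    stalk_radius_um: float = 2.0
    puff_onset_frame: int = 12
    puff_origin: tuple[float, float] | None = None  # (row, col) px; None = left edge
    wave_speed_um_per_s: float = 15.0
    noise_sd: float = 1.0
    dispersion_sd_um: float = 0.0  # 0 = tight sheath; >0 = rd10-like diffuse
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise SpecError("image dimensions must be positive")
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "vessel_radius_um",
            "sheath_thickness_um",
            "baseline_f0",
            "wave_speed_um_per_s",
        ):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        for name in (
            "sheath_amplitude",
            "stalk_amplitude",
            "background_amplitude",
            "noise_sd",
            "dispersion_sd_um",
        ):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be nonnegative")
        if not (0 <= self.puff_onset_frame < self.n_frames):
            raise SpecError("puff_onset_frame must lie within [0, n_frames)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise SpecError("noise_model must be 'gaussian' or 'poisson'")
        if self.vessel_centerline is not None:
            cl = np.asarray(self.vessel_centerline, dtype=float)
            if (
                cl[:, 0].min() < 0
                or cl[:, 1].min() < 0
                or cl[:, 0].max() > self.image_height_px - 1
                or cl[:, 1].max() > self.image_width_px - 1
            ):
                raise SpecError("centerline must lie strictly inside image bounds")
            self.vessel_centerline = cl

    def resolved_centerline(self) -> np.ndarray:
        if self.vessel_centerline is not None:
            return np.asarray(self.vessel_centerline, dtype=float)
        r = self.image_height_px // 2
        return np.array(
            [[r, 1.0], [r, self.image_width_px - 2.0]], dtype=float
        )

    def resolved_origin(self) -> tuple[float, float]:
        if self.puff_origin is not None:
            return tuple(self.puff_origin)
        return (self.image_height_px / 2.0, 2.0)


@dataclass
class TwoChannelMovie:
    """Glial-indicator time series plus the static vessel-label image."""

    glial: np.ndarray  # (T, H, W)
    vessel: np.ndarray  # (H, W)
    pixel_size_um: float
    frame_interval_s: float
    puff_onset_frame: int

    @property
    def n_frames(self) -> int:
        return self.glial.shape[0]


@dataclass
class GroundTruthMovie:
    spec: MovieSpec
    true_peak_z: float | None  # sheath_amplitude / noise_sd (None if noise-free)
    stalk_positions_px: np.ndarray  # (n, 2) (row, col)
    activation_first_frame: float  # earliest activation frame in the field
    activation_last_frame: float  # latest activation frame in the field


def _splat_bilinear(
    weights: np.ndarray, rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Deposit point masses onto the pixel grid bilinearly (mass conserving
    for points inside the grid)."""
    out = np.zeros(shape)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.add.at(out, (rr[ok], cc[ok]), weights[ok] * w[ok])
    return out


def _reflect(x: np.ndarray, upper: float) -> np.ndarray:
    """Fold coordinates into [0, upper] by mirror reflection."""
    period = 2.0 * upper
    xm = np.mod(np.abs(x), period)
    return np.where(xm > upper, period - xm, xm)


def generate_movie(spec: MovieSpec) -> tuple[TwoChannelMovie, GroundTruthMovie]:
    """Render a two-channel movie from a :class:`MovieSpec`.

    The vessel channel is a static tube (hard disk profile convolved with a
    1-px Gaussian, approximating optical blur).  Glial-channel frame t is
    ``baseline_f0 + step(t >= activation_time) * amplitude_map + noise``
    where the activation time of each pixel is set by the radial wavefront
    expanding from the puff origin at ``wave_speed_um_per_s``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height_px, spec.image_width_px
    px = spec.pixel_size_um
    cl = spec.resolved_centerline()

    dist_um = polyline_distance_map((h, w), cl) * px

    # --- vessel channel (static, noise free) ---
    # antialiased disk: pixel value ~ area coverage, so the blurred tube's
    # half-maximum sits at the nominal radius
    tube = np.clip(spec.vessel_radius_um / px + 0.5 - dist_um / px, 0.0, 1.0)
    vessel = ndimage.gaussian_filter(tube, 1.0) * 100.0

    # --- sheath annulus, optionally dispersed away from the vessel ---
    annulus = (dist_um > spec.vessel_radius_um) & (
        dist_um <= spec.vessel_radius_um + spec.sheath_thickness_um
    )
    if spec.dispersion_sd_um > 0:
        ys, xs = np.nonzero(annulus)
        n = len(ys)
        disp = rng.normal(0.0, spec.dispersion_sd_um / px, size=(n, 2))
        # reflect at the field boundary: signal is displaced, never removed
        ny = _reflect(ys + disp[:, 0], h - 1)
        nx = _reflect(xs + disp[:, 1], w - 1)
        sheath_map = _splat_bilinear(np.ones(n), ny, nx, (h, w))
    else:
        sheath_map = annulus.astype(float)

    # --- stalk hotspots: uniform placement, rejected near the vessel ---
    stalk_positions = []
    stalk_map = np.zeros((h, w))
    clearance = (
        spec.vessel_radius_um + 2.0 + spec.stalk_radius_um
    )  # stalk disk stays >= 2 um from the vessel surface
    tries = 0
    while len(stalk_positions) < spec.n_stalks and tries < 1000 * max(
        spec.n_stalks, 1
    ):
        tries += 1
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        ri, ci = int(round(r)), int(round(c))
        if dist_um[ri, ci] <= clearance:
            continue
        stalk_positions.append((r, c))
    stalk_positions = np.array(stalk_positions).reshape(-1, 2)
    if len(stalk_positions):
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for r, c in stalk_positions:
            d2 = (rr - r) ** 2 + (cc - c) ** 2
            stalk_map[d2 <= (spec.stalk_radius_um / px) ** 2] = 1.0

    # background responds only outside the structured components, so the
    # annulus dF is sheath_amplitude exactly (true_peak_z bookkeeping)
    amp_map = (
        spec.sheath_amplitude * sheath_map
        + spec.stalk_amplitude * stalk_map
        + spec.background_amplitude * (1.0 - stalk_map) * (~annulus)
    )

    # --- activation wave ---
    oy, ox = spec.resolved_origin()
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dist_origin_um = np.hypot(rr - oy, cc - ox) * px
    act_frame = spec.puff_onset_frame + dist_origin_um / (
        spec.wave_speed_um_per_s * spec.frame_interval_s
    )

    t = np.arange(spec.n_frames)
    active = t[:, None, None] >= act_frame[None, :, :]
    glial = spec.baseline_f0 + active * amp_map[None, :, :]
    if spec.noise_model == "poisson":
        glial = rng.poisson(np.maximum(glial, 0.0)).astype(float)
    elif spec.noise_sd > 0:
        glial = glial + rng.normal(0.0, spec.noise_sd, size=glial.shape)

    movie = TwoChannelMovie(
        glial=glial,
        vessel=vessel,
        pixel_size_um=px,
        frame_interval_s=spec.frame_interval_s,
        puff_onset_frame=spec.puff_onset_frame,
    )
    truth = GroundTruthMovie(
        spec=spec,
        true_peak_z=(
            spec.sheath_amplitude / spec.noise_sd if spec.noise_sd > 0 else None
        ),
        stalk_positions_px=stalk_positions,
        activation_first_frame=float(act_frame.min()),
        activation_last_frame=float(act_frame.max()),
    )
    return movie, truth


@dataclass
class CohortEntry:
    condition: str
    index: int
    movie: TwoChannelMovie
    truth: GroundTruthMovie


def generate_cohort(
    base_spec: MovieSpec,
    n_per_group: int,
    condition_deltas: dict[str, dict],
    seed: int,
) -> list[CohortEntry]:
    """Generate a multi-condition cohort of movies.

    ``condition_deltas`` maps condition label -> parameter overrides applied
    to ``base_spec``.  Per-movie seeds are derived deterministically from
    (seed, condition index, movie index), so the same call always produces
    the same cohort.
    """
    if n_per_group < 2:
        raise SpecError("n_per_group must be >= 2")
    valid = {f.name for f in dataclasses.fields(MovieSpec)}
    entries = []
    for ci, (label, deltas) in enumerate(condition_deltas.items()):
        bad = set(deltas) - valid
        if bad:
            raise SpecError(f"unknown MovieSpec override key(s): {sorted(bad)}")
        for i in range(n_per_group):
            child = int(
                np.random.SeedSequence((seed, ci, i)).generate_state(1)[0]
                % (2**31)
            )
            spec = replace(base_spec, seed=child, **deltas)
            movie, truth = generate_movie(spec)
            entries.append(CohortEntry(label, i, movie, truth))
    return entries


# ---------------------------------------------------------------------------
# labeled volumes
# ---------------------------------------------------------------------------


@dataclass
class VolumeSpec:
    """Parameters of a capillary-wrapped-by-glia voxel phantom.

    The vessel runs along ``vessel_axis`` through the center of the
    cross-section plane.  ``gap_definitions`` and ``pericyte_patches`` are
    lists of ``((z0, z1), (theta0, theta1))`` regions on the vessel surface:
    an axial span in voxel indices (half-open) and an angular span in
    radians ([0, 2*pi), use (0, 2*pi) for a full ring).  Neuron processes
    are radial spokes that reach the vessel surface through gaps; the i-th
    process takes its class from ``neuron_class_assignment[i]`` and touches
    the structure named by ``contact_targets[i]`` (the generator labels the
    wall beneath a pericyte-targeted process as pericyte).
    """

    shape_voxels: tuple[int, int, int] = (60, 48, 48)
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 0.5)
    vessel_axis: int = 0
    vessel_radius_um: float = 2.5
    wall_thickness_voxels: int = 2
    glia_thickness_voxels: int = 2
    pericyte_patches: tuple = ()
    gap_definitions: tuple = ()
    n_neuron_processes: int = 0
    neuron_class_assignment: tuple = ()
    contact_targets: tuple = ()
    depth_axis: int = 1
    depth_of_vessel_um: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.vessel_axis == self.depth_axis:
            raise SpecError("depth_axis must differ from vessel_axis")
        if self.wall_thickness_voxels < 1:
            raise SpecError("wall_thickness_voxels must be >= 1")
        if any(s <= 0 for s in self.shape_voxels) or any(
            v <= 0 for v in self.voxel_size_um
        ):
            raise SpecError("volume dimensions must be positive")
        if self.n_neuron_processes:
            if len(self.neuron_class_assignment) != self.n_neuron_processes:
                raise SpecError("one class per neuron process required")
            if len(self.contact_targets) != self.n_neuron_processes:
                raise SpecError("one contact target per neuron process required")
            if not self.gap_definitions:
                raise SpecError("contacting processes require at least one gap")
            for c in self.neuron_class_assignment:
                if c not in NEURON_CLASSES:
                    raise SpecError(f"unknown neuron class {c!r}")
            for t in self.contact_targets:
                if t not in ("pericyte", "endothelium"):
                    raise SpecError(f"unknown contact target {t!r}")


@dataclass
class LabeledVolume:
    """3-D integer label volume with physical voxel size and depth context.

    ``depth_offset_um`` is the depth (below the retinal surface) of the
    voxel plane at index 0 along ``depth_axis``; increasing index = deeper.
    """

    labels: np.ndarray
    label_map: dict[int, str]
    voxel_size_um: tuple[float, float, float]
    vessel_axis: int = 0
    depth_axis: int = 1
    depth_offset_um: float = 0.0

    def validate(self) -> None:
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from label_map")


@dataclass
class GroundTruthVolume:
    spec: VolumeSpec
    true_coverage_fraction: float
    true_gap_count: int
    true_gap_faces: list[int]  # faces per constructed gap region
    true_contacts: list[dict]  # {process_id, cls, target}


def _in_angular_span(theta: np.ndarray, span: tuple[float, float]) -> np.ndarray:
    t0, t1 = span
    two_pi = 2 * np.pi
    if t1 - t0 >= two_pi - 1e-12:
        return np.ones_like(theta, dtype=bool)
    t0m = t0 % two_pi
    t1m = t1 % two_pi
    if t0m <= t1m:
        return (theta >= t0m) & (theta < t1m)
    return (theta >= t0m) | (theta < t1m)


def _count_surface_faces(labels: np.ndarray) -> tuple[int, int, np.ndarray]:
    """(total surface faces, glia-covered faces, per-voxel-pair gap-face
    marker array) by direct 6-neighbour counting."""
    vessel = (labels == LABELS["endothelium"]) | (labels == LABELS["pericyte"])
    lumen = labels == LABELS["lumen"]
    exterior = ~vessel & ~lumen
    glia = labels == LABELS["glia"]
    total = 0
    covered = 0
    gap_outside = np.zeros(labels.shape + (6,), dtype=bool)
    d = 0
    for axis in range(3):
        for sign in (1, -1):
            sl_in = [slice(None)] * 3
            sl_out = [slice(None)] * 3
            if sign == 1:
                sl_in[axis] = slice(None, -1)
                sl_out[axis] = slice(1, None)
            else:
                sl_in[axis] = slice(1, None)
                sl_out[axis] = slice(None, -1)
            face = vessel[tuple(sl_in)] & exterior[tuple(sl_out)]
            total += int(face.sum())
            covered += int((face & glia[tuple(sl_out)]).sum())
            mark = face & ~glia[tuple(sl_out)]
            pad = np.zeros(labels.shape, dtype=bool)
            pad[tuple(sl_in)] = mark
            gap_outside[..., d] = pad
            d += 1
    return total, covered, gap_outside


def generate_volume(spec: VolumeSpec) -> tuple[LabeledVolume, GroundTruthVolume]:
    """Build a labeled capillary phantom and its construction ground truth.

    Coverage fraction and per-gap face counts are obtained by direct face
    counting on the constructed label array (6-connectivity), so they hold
    exactly whatever the discretisation.  Gap regions must be pairwise
    non-adjacent for the recorded gap count to equal the component count.
    """
    labels = np.zeros(spec.shape_voxels, dtype=np.uint16)
    axes = [0, 1, 2]
    axes.remove(spec.vessel_axis)
    a1, a2 = axes  # cross-section axes
    shape = spec.shape_voxels
    vs = spec.voxel_size_um

    idx = np.indices(shape).astype(float)
    c1 = shape[a1] // 2
    c2 = shape[a2] // 2
    y = (idx[a1] - c1) * vs[a1]
    x = (idx[a2] - c2) * vs[a2]
    r = np.hypot(y, x)
    theta = np.mod(np.arctan2(x, -y), 2 * np.pi)
    z = idx[spec.vessel_axis]

    wall_um = spec.wall_thickness_voxels * min(vs[a1], vs[a2])
    glia_um = spec.glia_thickness_voxels * min(vs[a1], vs[a2])
    r_out = spec.vessel_radius_um
    r_lumen = r_out - wall_um
    if r_lumen <= 0:
        raise SpecError("wall thicker than vessel radius")

    labels[r <= r_lumen] = LABELS["lumen"]
    wall = (r > r_lumen) & (r <= r_out)
    labels[wall] = LABELS["endothelium"]
    for (z0, z1), tspan in spec.pericyte_patches:
        sel = wall & (z >= z0) & (z < z1) & _in_angular_span(theta, tspan)
        labels[sel] = LABELS["pericyte"]

    shell = (r > r_out) & (r <= r_out + glia_um)
    gap_region = np.zeros(shape, dtype=bool)
    per_gap_regions = []
    for (z0, z1), tspan in spec.gap_definitions:
        g = (z >= z0) & (z < z1) & _in_angular_span(theta, tspan)
        per_gap_regions.append(g)
        gap_region |= g
    labels[shell & ~gap_region] = LABELS["glia"]

    # --- neuron processes: radial spokes through gaps ---
    contacts = []
    if spec.n_neuron_processes:
        n_gaps = len(spec.gap_definitions)
        per_gap_count = [0] * n_gaps
        assignments = [i % n_gaps for i in range(spec.n_neuron_processes)]
        for i, gi in enumerate(assignments):
            (z0, z1), (t0, t1) = spec.gap_definitions[gi]
            # subdivide the gap axially among its processes
            k = per_gap_count[gi]
            per_gap_count[gi] += 1
            zc = z0 + k * 2
            if zc + 1 > z1:
                raise SpecError(
                    f"gap {gi} too short axially for its assigned processes"
                )
            tc = (t0 + t1) / 2 if t1 > t0 else t0
            dtheta = min((t1 - t0) / 2 if t1 > t0 else np.pi, np.pi / 6)
            sel = (
                (z >= zc)
                & (z < zc + 1)
                & (r > r_out)
                & (r <= r_out + glia_um + 2.0)
                & _in_angular_span(theta, (tc - dtheta / 2, tc + dtheta / 2))
                & gap_region
                | (
                    (z >= zc)
                    & (z < zc + 1)
                    & (r > r_out + glia_um)
                    & (r <= r_out + glia_um + 2.0)
                    & _in_angular_span(theta, (tc - dtheta / 2, tc + dtheta / 2))
                )
            )
            if not sel.any():
                raise SpecError(f"process {i} footprint is empty")
            labels[sel & (labels == LABELS["background"])] = FIRST_NEURON_LABEL + i
            if spec.contact_targets[i] == "pericyte":
                psel = (
                    wall
                    & (z >= zc)
                    & (z < zc + 1)
                    & _in_angular_span(theta, (tc - dtheta / 2, tc + dtheta / 2))
                )
                labels[psel] = LABELS["pericyte"]
            contacts.append(
                {
                    "process_id": FIRST_NEURON_LABEL + i,
                    "cls": spec.neuron_class_assignment[i],
                    "target": spec.contact_targets[i],
                }
            )

    label_map = {v: k for k, v in LABELS.items()}
    for i in range(spec.n_neuron_processes):
        label_map[FIRST_NEURON_LABEL + i] = (
            "neuron_" + spec.neuron_class_assignment[i]
        )

    total, covered, gap_marks = _count_surface_faces(labels)
    coverage = covered / total if total else float("nan")

    # per-gap face counts: attribute each uncovered face to the gap region
    # containing its outside voxel
    gap_faces = []
    for g in per_gap_regions:
        cnt = 0
        d = 0
        for axis in range(3):
            for sign in (1, -1):
                sl_out = [slice(None)] * 3
                sl_in = [slice(None)] * 3
                if sign == 1:
                    sl_in[axis] = slice(None, -1)
                    sl_out[axis] = slice(1, None)
                else:
                    sl_in[axis] = slice(1, None)
                    sl_out[axis] = slice(None, -1)
                marks = gap_marks[..., d][tuple(sl_in)]
                cnt += int((marks & g[tuple(sl_out)]).sum())
                d += 1
        gap_faces.append(cnt)

    depth_offset = spec.depth_of_vessel_um - (
        (shape[spec.depth_axis] // 2) * vs[spec.depth_axis]
    )
    volume = LabeledVolume(
        labels=labels,
        label_map=label_map,
        voxel_size_um=tuple(vs),
        vessel_axis=spec.vessel_axis,
        depth_axis=spec.depth_axis,
        depth_offset_um=depth_offset,
    )
    truth = GroundTruthVolume(
        spec=spec,
        true_coverage_fraction=coverage,
        true_gap_count=sum(1 for c in gap_faces if c > 0),
        true_gap_faces=gap_faces,
        true_contacts=contacts,
    )
    return volume, truth
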