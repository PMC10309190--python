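"""Synthetic-data generators with known ground truth.

Every input the analysis modules consume can be generated here with the
true parameters recorded alongside, so the whole pipeline can be tested
by parameter recovery:

* time-lapse phagocytosis movies (engulfed ~3 um yeast disks on a
  cytosolic background, reporter enrichment in a membrane shell
  following a :class:`~phagoflux.profiles.KineticProfile`),
* dextran pulse-chase fields (snapshots of macropinosomes of known age),
* equatorial sections of membrane-coated beads with one-site
  saturation binding of a fluorescent probe,
* mass-photometry event lists drawn from Gaussian mixtures,
* lipid-array intensity panels with a known fold-preference.

All generators are deterministic given (parameters, seed): the same
seed yields bit-identical output.

Geometry conventions: pixel (0, 0) has its center at (x, y) = (0, 0) um
with x along columns and y along rows; a pixel belongs to a disk when
its center lies within the disk radius.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .profiles import KineticProfile

__all__ = [
    "ParticleSpec",
    "SceneConfig",
    "GroundTruth",
    "MassMixtureSpec",
    "MASS_PRESETS",
    "generate_timelapse",
    "generate_pulse_chase_fields",
    "generate_bead_field",
    "generate_mass_events",
    "generate_lipid_panel",
    "grid_centers",
]

LIPID_NAMES = (
    "PI3P",
    "PI4P",
    "PI5P",
    "PI(3,4)P2",
    "PI(3,5)P2",
    "PI(4,5)P2",
    "PI(3,4,5)P3",
)


# --------------------------------------------------------------------------
# ground truth container
# --------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """True parameters of every object rendered by a generator.

    ``kind`` names the generator ("timelapse", "pulse_chase", "beads",
    "mass", "panel"); ``objects`` holds one plain dict per rendered
    object; ``meta`` holds scene-level metadata (pixel size, frame
    interval, channel names, noise settings, seed).  Round-trips
    losslessly through JSON.
    """

    kind: str
    objects: list[dict]
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), default=_jsonable, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(kind=d["kind"], objects=d["objects"], meta=d.get("meta", {}))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _profile_dict(p: KineticProfile) -> dict:
    return {
        "t_on": p.t_on,
        "t_peak": p.t_peak,
        "t_plateau_end": p.t_plateau_end,
        "t_off": p.t_off,
        "e_max": p.e_max,
    }


# --------------------------------------------------------------------------
# scene configuration
# --------------------------------------------------------------------------


@dataclass
class ParticleSpec:
    """One engulfed particle in a time-lapse scene.

    ``center_um`` is (x, y) in um; particles are stationary by default
    but a per-frame trajectory of shape (n_frames, 2) may be given.
    ``profiles`` maps reporter channel name -> KineticProfile.
    """

    center_um: tuple[float, float]
    radius_um: float
    engulfment_frame: int
    profiles: dict[str, KineticProfile]
    trajectory_um: np.ndarray | None = None


@dataclass
class SceneConfig:
    """Rendering parameters for a synthetic time-lapse.

    Intensities are detector counts.  The reporter channels render the
    cytosol at ``cytosol_mean`` everywhere (the whole frame is treated
    as one cell unless ``cell_mask`` is given), the vesicle lumen dimmed
    by ``lumen_factor`` (cytosolic reporter is excluded from the lumen),
    and a membrane shell of ``shell_thickness_um`` just outside the
    particle at ``cytosol_mean * profile(t - t_engulfment)``.  The
    particle channel renders the yeast disk, optionally brightening
    after engulfment to emulate a pH-sensitive (pHrodo) label.
    """

    particles: list[ParticleSpec]
    n_frames: int
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # um / px
    frame_interval: float = 10.0  # s
    channels: tuple[str, ...] = ("particle", "reporter")
    cytosol_mean: float = 1000.0
    particle_intensity: float = 3000.0
    particle_background: float = 100.0
    lumen_factor: float = 0.4
    shell_thickness_um: float = 0.7
    noise_sd_frac: float = 0.05  # gaussian sd as a fraction of cytosol_mean
    shot_noise: bool = False
    phrodo_ramp: bool = True  # particle brightens from 60 s post-engulfment
    phrodo_gain: float = 0.5
    phrodo_rise_s: float = 300.0
    cell_mask: np.ndarray | None = None

    def validate(self) -> None:
        h, w = self.image_shape
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        margin = self.shell_thickness_um
        for k, p in enumerate(self.particles):
            if not (0 <= p.engulfment_frame < self.n_frames):
                raise ValueError(
                    f"particle {k}: engulfment_frame {p.engulfment_frame} outside "
                    f"[0, {self.n_frames})"
                )
            if p.radius_um < 2 * self.pixel_size:
                raise ValueError(f"particle {k}: radius below 2 pixels")
            for ch in p.profiles:
                if ch not in self.channels:
                    raise ValueError(f"particle {k}: unknown channel {ch!r}")
            for cx, cy in _centers_iter(p, self.n_frames):
                ext = p.radius_um + margin
                if not (
                    ext <= cx <= (w - 1) * self.pixel_size - ext
                    and ext <= cy <= (h - 1) * self.pixel_size - ext
                ):
                    raise ValueError(f"particle {k} leaves the usable frame area")
        # reject overlapping particles (shells included): scenes stay unambiguous
        for a in range(len(self.particles)):
            for b in range(a + 1, len(self.particles)):
                pa, pb = self.particles[a], self.particles[b]
                for (ax, ay), (bx, by) in zip(
                    _centers_iter(pa, self.n_frames), _centers_iter(pb, self.n_frames)
                ):
                    lim = pa.radius_um + pb.radius_um + 2 * margin
                    if np.hypot(ax - bx, ay - by) < lim:
                        raise ValueError(f"particles {a} and {b} overlap")


def _centers_iter(p: ParticleSpec, n_frames: int):
    if p.trajectory_um is not None:
        traj = np.asarray(p.trajectory_um, float)
        if traj.shape != (n_frames, 2):
            raise ValueError("trajectory must have shape (n_frames, 2)")
        yield from ((float(x), float(y)) for x, y in traj)
    else:
        yield from ((float(p.center_um[0]), float(p.center_um[1])),) * n_frames


def grid_centers(
    n: int,
    image_shape: tuple[int, int],
    pixel_size: float,
    spacing_um: float,
    margin_um: float,
    rng: np.random.Generator | None = None,
    jitter_um: float = 0.0,
) -> list[tuple[float, float]]:
    """Non-overlapping object centers on a jittered grid (x, y in um).

    Raises ValueError if ``n`` objects do not fit.
    """
    h, w = image_shape
    width_um = (w - 1) * pixel_size
    height_um = (h - 1) * pixel_size
    xs = np.arange(margin_um, width_um - margin_um + 1e-9, spacing_um)
    ys = np.arange(margin_um, height_um - margin_um + 1e-9, spacing_um)
    cells = [(float(x), float(y)) for y in ys for x in xs]
    if len(cells) < n:
        raise ValueError(f"cannot place {n} objects (only {len(cells)} grid cells)")
    if rng is not None:
        order = rng.permutation(len(cells))
        cells = [cells[i] for i in order]
        if jitter_um > 0:
            cells = [
                (x + float(rng.uniform(-jitter_um, jitter_um)),
                 y + float(rng.uniform(-jitter_um, jitter_um)))
                for x, y in cells
            ]
    return cells[:n]


# --------------------------------------------------------------------------
# time-lapse rendering
# --------------------------------------------------------------------------


def _local_distance_map(center_um, extent_um, shape, pixel_size):
    """(row slice, col slice, distance-from-center map in um)."""
    cx, cy = center_um
    h, w = shape
    i0 = max(0, int(np.floor((cy - extent_um) / pixel_size)))
    i1 = min(h, int(np.ceil((cy + extent_um) / pixel_size)) + 1)
    j0 = max(0, int(np.floor((cx - extent_um) / pixel_size)))
    j1 = min(w, int(np.ceil((cx + extent_um) / pixel_size)) + 1)
    yy = np.arange(i0, i1)[:, None] * pixel_size - cy
    xx = np.arange(j0, j1)[None, :] * pixel_size - cx
    return slice(i0, i1), slice(j0, j1), np.hypot(yy, xx)


def _finalize_stack(stack, rng, config) -> np.ndarray:
    if config.shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if config.noise_sd_frac > 0:
        stack = stack + rng.normal(
            0.0, config.noise_sd_frac * config.cytosol_mean, size=stack.shape
        )
    return np.clip(np.round(stack), 0, 65535).astype(np.uint16)


def generate_timelapse(
    config: SceneConfig, seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render a multi-channel time-lapse stack plus its ground truth.

    Returns
    -------
    stack : uint16 array, shape (n_frames, n_channels, H, W)
    truth : GroundTruth with one object per particle (per-frame centers,
        area, engulfment frame, profile parameters per channel).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    h, w = config.image_shape
    nch = len(config.channels)
    reporter_chs = [c for c in config.channels if c != "particle"]
    stack = np.empty((config.n_frames, nch, h, w), dtype=float)

    cell = config.cell_mask
    for ci, ch in enumerate(config.channels):
        if ch == "particle":
            stack[:, ci] = config.particle_background
        else:
            base = np.full((h, w), config.cytosol_mean)
            if cell is not None:
                base = np.where(cell, config.cytosol_mean, config.particle_background)
            stack[:, ci] = base

    objects = []
    for pid, p in enumerate(config.particles):
        centers = list(_centers_iter(p, config.n_frames))
        ext = p.radius_um + config.shell_thickness_um + 2 * config.pixel_size
        t_eng = p.engulfment_frame * config.frame_interval
        for f in range(config.n_frames):
            rows, cols, d = _local_distance_map(
                centers[f], ext, (h, w), config.pixel_size
            )
            disk = d <= p.radius_um
            shell = (d > p.radius_um) & (d <= p.radius_um + config.shell_thickness_um)
            t_rel = f * config.frame_interval - t_eng
            for ci, ch in enumerate(config.channels):
                view = stack[f, ci, rows, cols]
                if ch == "particle":
                    gain = 1.0
                    if config.phrodo_ramp and t_rel > 60.0:
                        gain = 1.0 + config.phrodo_gain * min(
                            1.0, (t_rel - 60.0) / config.phrodo_rise_s
                        )
                    view[disk] = config.particle_intensity * gain
                else:
                    view[disk] = config.lumen_factor * config.cytosol_mean
                    prof = p.profiles.get(ch)
                    enr = prof(t_rel) if prof is not None else 1.0
                    view[shell] = config.cytosol_mean * enr
        px_area = config.pixel_size**2
        n_px = int(
            np.sum(
                _local_distance_map(centers[0], ext, (h, w), config.pixel_size)[2]
                <= p.radius_um
            )
        )
        objects.append(
            {
                "id": pid,
                "radius_um": p.radius_um,
                "area_um2": n_px * px_area,
                "engulfment_frame": p.engulfment_frame,
                "centers_um": [list(c) for c in centers],
                "profiles": {ch: _profile_dict(pr) for ch, pr in p.profiles.items()},
            }
        )

    out = _finalize_stack(stack, rng, config)
    truth = GroundTruth(
        kind="timelapse",
        objects=objects,
        meta={
            "pixel_size": config.pixel_size,
            "frame_interval": config.frame_interval,
            "channels": list(config.channels),
            "cytosol_mean": config.cytosol_mean,
            "noise_sd_frac": config.noise_sd_frac,
            "shell_thickness_um": config.shell_thickness_um,
            "seed": seed,
        },
    )
    return out, truth


# --------------------------------------------------------------------------
# dextran pulse-chase fields
# --------------------------------------------------------------------------


def generate_pulse_chase_fields(
    n_fields: int,
    vesicles_per_field: int,
    profile: KineticProfile,
    timepoints_min: Sequence[float],
    seed: int,
    *,
    pulse_min: float = 2.0,
    vesicle_radius_um: float = 1.5,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1,
    cytosol_mean: float = 1000.0,
    dextran_intensity: float = 3000.0,
    shell_thickness_um: float = 0.7,
    lumen_factor: float = 0.4,
    noise_sd_frac: float = 0.05,
) -> tuple[dict[float, list[np.ndarray]], GroundTruth]:
    """Snapshot fields of dextran-labeled macropinosomes of known age.

    Vesicles are formed at times drawn uniformly over the labeling
    pulse (the first ``pulse_min`` minutes after dextran addition, or
    up to the observation time if earlier), so a field imaged at
    timepoint T contains vesicles aged uniformly over
    [max(0, T - pulse), T].  Channel 0 is dextran (vesicle disk),
    channel 1 the reporter whose membrane-shell enrichment follows
    ``profile`` at the vesicle's age.

    Returns ``{timepoint_min: [field arrays (2, H, W) uint16]}`` and a
    GroundTruth with one entry per vesicle (field, age, true enrichment).
    """
    timepoints = list(timepoints_min)
    if not timepoints:
        raise ValueError("timepoint list is empty")
    if sorted(timepoints) != timepoints:
        raise ValueError("timepoints must be sorted")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    spacing = 2 * (vesicle_radius_um + shell_thickness_um) + 2.2
    # margin leaves room for the measurement outer ring of border vesicles
    margin = vesicle_radius_um + shell_thickness_um + 1.3

    fields: dict[float, list[np.ndarray]] = {}
    objects = []
    for tp in timepoints:
        fields[tp] = []
        t_obs = tp * 60.0
        for fi in range(n_fields):
            centers = grid_centers(
                vesicles_per_field, image_shape, pixel_size, spacing, margin,
                rng=rng, jitter_um=0.3,
            )
            # formed uniformly during the labeling pulse (clipped to the
            # observation time); age = time since formation
            if t_obs > 0:
                formed = rng.uniform(0.0, min(pulse_min * 60.0, t_obs),
                                     size=vesicles_per_field)
                ages = t_obs - formed
            else:
                ages = np.zeros(vesicles_per_field)
            img = np.empty((2, h, w), dtype=float)
            img[0] = 0.1 * cytosol_mean
            img[1] = cytosol_mean
            for vi, ((cx, cy), age) in enumerate(zip(centers, ages)):
                ext = vesicle_radius_um + shell_thickness_um + 2 * pixel_size
                rows, cols, d = _local_distance_map((cx, cy), ext, (h, w), pixel_size)
                disk = d <= vesicle_radius_um
                shell = (d > vesicle_radius_um) & (
                    d <= vesicle_radius_um + shell_thickness_um
                )
                img[0][rows, cols][disk] = dextran_intensity
                rep = img[1][rows, cols]
                rep[disk] = lumen_factor * cytosol_mean
                enr = profile(age)
                rep[shell] = cytosol_mean * enr
                objects.append(
                    {
                        "timepoint_min": tp,
                        "field": fi,
                        "vesicle": vi,
                        "center_um": [cx, cy],
                        "radius_um": vesicle_radius_um,
                        "age_s": float(age),
                        "true_enrichment": float(enr),
                    }
                )
            img = img + rng.normal(0.0, noise_sd_frac * cytosol_mean, size=img.shape)
            fields[tp].append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
    truth = GroundTruth(
        kind="pulse_chase",
        objects=objects,
        meta={
            "pixel_size": pixel_size,
            "channels": ["dextran", "reporter"],
            "profile": _profile_dict(profile),
            "pulse_min": pulse_min,
            "cytosol_mean": cytosol_mean,
            "noise_sd_frac": noise_sd_frac,
            "seed": seed,
        },
    )
    return fields, truth


# --------------------------------------------------------------------------
# membrane-coated beads
# --------------------------------------------------------------------------


def generate_bead_field(
    true_kd: float,
    bmax: float,
    nonspecific: float,
    conc: float,
    n_beads: int,
    seed: int,
    *,
    bead_radius_um: float = 5.0,
    pixel_size: float = 0.2,
    ring_thickness_um: float = 0.6,
    membrane_intensity: float = 1.0,
    solution_background: float = 0.0,
    noise: float = 0.05,
) -> tuple[np.ndarray, GroundTruth]:
    """Equatorial section of membrane-coated beads with bound probe.

    The membrane channel (index 0) renders each bead as a bright
    circle of the stated radius; the probe channel (index 1) carries, on
    the same ring, the one-site saturation signal
    ``nonspecific + bmax * conc / (true_kd + conc)`` before noise.
    Noise is a per-bead multiplicative factor N(1, noise) on the ring
    signal plus per-pixel Gaussian noise of sd ``noise * bmax``.

    Returns a float image of shape (2, H, W) (arbitrary linear units)
    and the ground truth.
    """
    if conc < 0:
        raise ValueError("conc must be >= 0")
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    cell = 2 * (bead_radius_um + ring_thickness_um) + 2.0
    n_cols = int(np.ceil(np.sqrt(n_beads)))
    n_rows = int(np.ceil(n_beads / n_cols))
    w = int(np.ceil((n_cols * cell + 1.0) / pixel_size))
    h = int(np.ceil((n_rows * cell + 1.0) / pixel_size))
    centers = grid_centers(
        n_beads, (h, w), pixel_size, cell, cell / 2, rng=rng, jitter_um=0.3
    )
    specific = bmax * conc / (true_kd + conc) if conc > 0 else 0.0
    img = np.empty((2, h, w), dtype=float)
    img[0] = 0.0
    img[1] = solution_background
    objects = []
    for bi, (cx, cy) in enumerate(centers):
        ext = bead_radius_um + ring_thickness_um + 2 * pixel_size
        rows, cols, d = _local_distance_map((cx, cy), ext, (h, w), pixel_size)
        ring = np.abs(d - bead_radius_um) <= ring_thickness_um / 2
        bead_scale = 1.0 + noise * rng.standard_normal() if noise > 0 else 1.0
        ring_signal = (nonspecific + specific) * bead_scale
        img[0][rows, cols][ring] = membrane_intensity
        img[1][rows, cols][ring] = solution_background + ring_signal
        objects.append(
            {
                "id": bi,
                "center_um": [cx, cy],
                "radius_um": bead_radius_um,
                "true_ring_intensity": ring_signal,
            }
        )
    if noise > 0:
        img[0] += rng.normal(0.0, noise * membrane_intensity, size=img[0].shape)
        img[1] += rng.normal(0.0, noise * max(bmax, 1e-12), size=img[1].shape)
    truth = GroundTruth(
        kind="beads",
        objects=objects,
        meta={
            "pixel_size": pixel_size,
            "channels": ["membrane", "probe"],
            "true_kd": true_kd,
            "bmax": bmax,
            "nonspecific": nonspecific,
            "conc": conc,
            "ring_thickness_um": ring_thickness_um,
            "solution_background": solution_background,
            "noise": noise,
            "seed": seed,
        },
    )
    return img, truth


# --------------------------------------------------------------------------
# mass photometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MassMixtureSpec:
    """Gaussian mixture of event masses: [(mean kD, sd kD, fraction), ...]."""

    components: tuple[tuple[float, float, float], ...]
    n_events: int = 5000

    def __post_init__(self) -> None:
        fr = sum(c[2] for c in self.components)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {fr})")
        if any(c[1] < 0 for c in self.components):
            raise ValueError("component sds must be >= 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


#: Mass-distribution presets for the recombinant reporter constructs.
#: The full-length protein is predominantly (85%) a dimer at 181 kD
#: with a minor monomeric population; the single and tandem PX-domain
#: fusions are single populations at 92 and 104 kD.  Instrument spread
#: (sd) is a generator choice; the source reports apparent masses only.
MASS_PRESETS: dict[str, MassMixtureSpec] = {
    "snxa_full_length": MassMixtureSpec(((92.0, 12.0, 0.15), (181.0, 12.0, 0.85))),
    "px1": MassMixtureSpec(((92.0, 10.0, 1.0),), n_events=2000),
    "px2": MassMixtureSpec(((104.0, 10.0, 1.0),), n_events=2000),
}


def generate_mass_events(spec: MassMixtureSpec, seed: int) -> np.ndarray:
    """Draw event masses (kD) from the mixture; seed-deterministic."""
    rng = np.random.default_rng(seed)
    fractions = np.array([c[2] for c in spec.components])
    which = rng.choice(len(spec.components), size=spec.n_events, p=fractions)
    means = np.array([c[0] for c in spec.components])[which]
    sds = np.array([c[1] for c in spec.components])[which]
    return means + sds * rng.standard_normal(spec.n_events)


# --------------------------------------------------------------------------
# lipid panel
# --------------------------------------------------------------------------


def generate_lipid_panel(
    selective_lipid: str = "PI(3,5)P2",
    fold_preference: float = 20.0,
    lipids: Sequence[str] = LIPID_NAMES,
    noise: float = 0.05,
    n_replicates: int = 8,
    seed: int = 0,
):
    """Per-lipid spot intensities with a known fold-preference.

    Non-selective lipids have mean intensity 1.0; the selective lipid
    ``fold_preference`` times that.  Each replicate spot carries
    Gaussian noise with sd = ``noise`` x its mean.  Returns a tidy
    DataFrame (lipid, replicate, intensity).
    """
    import pandas as pd

    if fold_preference < 1:
        raise ValueError("fold_preference must be >= 1")
    if selective_lipid not in lipids:
        raise ValueError(f"{selective_lipid!r} not in the lipid list")
    rng = np.random.default_rng(seed)
    rows = []
    for lip in lipids:
        mean = fold_preference if lip == selective_lipid else 1.0
        vals = mean * (1.0 + noise * rng.standard_normal(n_replicates))
        for ri, v in enumerate(vals):
            rows.append({"lipid": lip, "replicate": ri, "intensity": float(v)})
    return pd.DataFrame(rows)
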