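"""Synthetic multiplexed-immunofluorescence (MxIF) tissue with known phenotypes.

The generator emulates the structure of a gated MxIF cohort: 17 named gating
channels plus nuisance channels at 0.32 um/px, elliptical nuclei plus larger
pale Muc2-high goblet blobs, a known 14-class phenotype per instance, and a
slide/patient/site provenance hierarchy.  Each class's marker profile turns on
exactly the channels its gating rule requires, so with zero noise the
rule-based gating recovers the true class of every instance.

Morphology carries a *designed* learnability structure for the downstream
pseudo-H&E classifier: a subset of classes has a unique (size, eccentricity,
DAPI brightness) signature (``DESIGNED_SEPARABLE``), while exactly one pair —
helper T and cytotoxic T — is rendered identically and differs only in CD4/CD8,
channels invisible in any H&E-like rendering (``UNLEARNABLE_PAIR``).  That
pair is the suite's negative control: no classifier can beat chance on it from
the rendering alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, MappingError, PackingError
from .image import ChannelError, InstanceMap, MultiplexImage
from .localize import resample_image
from .mapping import ClassMapping
from .rules import CLASS_NAMES, GATING_CHANNELS

#: Classes whose morphology/brightness signature is unique in the default
#: profile, hence learnable from the pseudo-H&E rendering alone.
DESIGNED_SEPARABLE: tuple[str, ...] = (
    "goblet",
    "enteroendocrine",
    "progenitor",
    "enterocyte",
    "macrophage",
    "fibroblast",
)

#: The designed negative control: identical morphology, distinguished only by
#: CD4 vs CD8 — invisible in the rendering.
UNLEARNABLE_PAIR: tuple[str, str] = ("helper T", "cytotoxic T")


@dataclass(frozen=True)
class MarkerLevel:
    """On-intensity mean and pixel-noise standard deviation for one (class, channel)."""

    mean: float
    sd: float = 0.0


@dataclass(frozen=True)
class ClassGeometry:
    """Nucleus/goblet geometry ranges for one class."""

    radius_um: tuple[float, float]
    eccentricity: tuple[float, float]


# positive channels per class (DAPI for every nucleus class; goblets are
# Muc2 regions, not nuclei)
_POSITIVE_CHANNELS: dict[str, tuple[str, ...]] = {
    "goblet": ("Muc2",),
    "enteroendocrine": ("DAPI", "CgA"),
    "progenitor": ("DAPI", "Sox9", "OLFM4"),
    "enterocyte": ("DAPI", "PanCK", "NaKATPase"),
    "helper T": ("DAPI", "CD3d", "CD4"),
    "cytotoxic T": ("DAPI", "CD3d", "CD8"),
    "CD3d+ CD4- CD8- T": ("DAPI", "CD3d"),
    "B": ("DAPI", "CD20"),
    "macrophage": ("DAPI", "CD68"),
    "monocyte": ("DAPI", "CD11b"),
    "myeloid (other)": ("DAPI", "Lysozyme"),
    "leukocyte (other)": ("DAPI", "CD45"),
    "fibroblast": ("DAPI", "SMA"),
    "stromal (undetermined)": ("DAPI", "Vimentin"),
}

# DAPI on-intensity per nucleus class; the brightness axis of the designed
# separability structure.
_DAPI_MEAN: dict[str, float] = {
    "enteroendocrine": 1.0,
    "progenitor": 1.8,
    "enterocyte": 1.0,
    "helper T": 1.35,
    "cytotoxic T": 1.35,
    "CD3d+ CD4- CD8- T": 0.95,
    "B": 1.05,
    "macrophage": 0.65,
    "monocyte": 0.9,
    "myeloid (other)": 1.1,
    "leukocyte (other)": 1.0,
    "fibroblast": 0.85,
    "stromal (undetermined)": 1.0,
}

_DEFAULT_GEOMETRY: dict[str, ClassGeometry] = {
    "goblet": ClassGeometry((4.0, 5.0), (0.0, 0.2)),
    "enteroendocrine": ClassGeometry((1.05, 1.35), (0.0, 0.2)),
    "progenitor": ClassGeometry((2.7, 3.0), (0.0, 0.18)),
    "enterocyte": ClassGeometry((3.3, 3.7), (0.75, 0.85)),
    "helper T": ClassGeometry((1.6, 1.9), (0.0, 0.15)),
    "cytotoxic T": ClassGeometry((1.6, 1.9), (0.0, 0.15)),
    "CD3d+ CD4- CD8- T": ClassGeometry((2.1, 2.5), (0.3, 0.55)),
    "B": ClassGeometry((2.1, 2.6), (0.3, 0.5)),
    "macrophage": ClassGeometry((3.4, 3.8), (0.0, 0.15)),
    "monocyte": ClassGeometry((2.2, 2.7), (0.35, 0.6)),
    "myeloid (other)": ClassGeometry((2.1, 2.6), (0.3, 0.55)),
    "leukocyte (other)": ClassGeometry((2.3, 2.7), (0.4, 0.6)),
    "fibroblast": ClassGeometry((2.4, 2.8), (0.88, 0.94)),
    "stromal (undetermined)": ClassGeometry((2.2, 2.7), (0.45, 0.65)),
}

#: Default positivity threshold applied to every gating channel.
DEFAULT_THRESHOLD = 0.5


@dataclass
class SimulationConfig:
    image_height_px: int = 1024
    image_width_px: int = 1024
    resolution_um_per_px: float = 0.32
    n_cells: int = 600
    class_mixture: dict[str, float] = field(default_factory=dict)
    marker_profile: dict[str, dict[str, MarkerLevel]] = field(default_factory=dict)
    geometry: dict[str, ClassGeometry] = field(default_factory=dict)
    goblet_radius_um: tuple[float, float] = (4.0, 5.0)
    n_nuisance_channels: int = 3
    background_sd: float = 0.08
    seed: int = 0
    slide_id: str = "slide_0"
    patient_id: str = "patient_0"
    site_id: str = "site_0"

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.resolution_um_per_px <= 0:
            raise ConfigurationError("resolution must be positive")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be non-negative")
        if self.n_cells > 0:
            total = sum(self.class_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"class_mixture sums to {total!r}, not 1")
            if any(p < 0 for p in self.class_mixture.values()):
                raise ConfigurationError("class_mixture proportions must be non-negative")
            unknown = set(self.class_mixture) - set(CLASS_NAMES)
            if unknown:
                raise ConfigurationError(f"unknown classes in mixture: {sorted(unknown)}")
            for cls in self.class_mixture:
                if cls not in self.marker_profile:
                    raise ConfigurationError(f"no marker profile for class {cls!r}")
                if cls not in self.geometry:
                    raise ConfigurationError(f"no geometry for class {cls!r}")


def default_marker_profile(noise_sd: float = 0.08) -> dict[str, dict[str, MarkerLevel]]:
    """On/off marker means per class: 1.0 on the gating-required channels
    (class-specific brightness for DAPI), 0 elsewhere."""
    profile: dict[str, dict[str, MarkerLevel]] = {}
    for cls in CLASS_NAMES:
        levels: dict[str, MarkerLevel] = {}
        for ch in _POSITIVE_CHANNELS[cls]:
            mean = _DAPI_MEAN[cls] if ch == "DAPI" else (1.2 if cls == "goblet" else 1.0)
            levels[ch] = MarkerLevel(mean=mean, sd=noise_sd)
        profile[cls] = levels
    return profile


def default_config(
    n_cells: int = 600,
    noise_sd: float = 0.08,
    seed: int = 0,
    image_height_px: int = 1024,
    image_width_px: int = 1024,
    class_mixture: dict[str, float] | None = None,
    slide_id: str = "slide_0",
    patient_id: str = "patient_0",
    site_id: str = "site_0",
) -> SimulationConfig:
    """The default study conditions: uniform 14-class mixture, 0.32 um/px,
    moderate marker noise, three nuisance channels."""
    if class_mixture is None:
        class_mixture = {c: 1.0 / len(CLASS_NAMES) for c in CLASS_NAMES}
    return SimulationConfig(
        image_height_px=image_height_px,
        image_width_px=image_width_px,
        n_cells=n_cells,
        class_mixture=dict(class_mixture),
        marker_profile=default_marker_profile(noise_sd),
        geometry=dict(_DEFAULT_GEOMETRY),
        background_sd=noise_sd,
        seed=seed,
        slide_id=slide_id,
        patient_id=patient_id,
        site_id=site_id,
    )


def default_thresholds() -> dict[str, float]:
    """One positivity threshold per gating channel, matching the default profile."""
    return {ch: DEFAULT_THRESHOLD for ch in GATING_CHANNELS}


@dataclass
class SyntheticTissue:
    """A generated slide: channels, instance map, ground-truth cell table, provenance."""

    image: MultiplexImage
    instances: InstanceMap
    truth: pd.DataFrame
    slide_id: str
    patient_id: str
    site_id: str


def _semi_axes(radius_px: float, ecc: float) -> tuple[float, float]:
    # area-preserving: a*b = r^2, b/a = sqrt(1-e^2)
    ratio = np.sqrt(max(1.0 - ecc**2, 1e-6))
    a = radius_px / ratio**0.5
    return a, a * ratio


def generate_tissue(config: SimulationConfig) -> SyntheticTissue:
    """Generate one synthetic slide.

    Cell classes are drawn multinomially from ``class_mixture``; centres are
    placed by rejection sampling with a minimum centre distance of 95% of the
    sum of the two cells' semi-major axes; nuclei/goblets are painted as
    rotated ellipses; each gating channel gets its class-consistent on/off
    intensity plus Gaussian noise clipped at 0.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height_px, config.image_width_px
    res = config.resolution_um_per_px
    labels = np.zeros((H, W), dtype=np.int32)

    truth_rows: list[dict] = []
    pixel_lists: list[tuple[np.ndarray, np.ndarray]] = []
    classes_drawn: list[str] = []

    if config.n_cells > 0:
        names = sorted(config.class_mixture)
        probs = np.array([config.class_mixture[c] for c in names])
        drawn = rng.choice(len(names), size=config.n_cells, p=probs / probs.sum())
        classes_drawn = [names[i] for i in drawn]

        # geometry per cell
        radii, semis_a, semis_b, thetas = [], [], [], []
        for cls in classes_drawn:
            geo = config.geometry[cls]
            r_um = rng.uniform(*geo.radius_um)
            ecc = rng.uniform(*geo.eccentricity)
            theta = rng.uniform(0, np.pi)
            a, b = _semi_axes(r_um / res, ecc)
            radii.append(r_um / res)
            semis_a.append(a)
            semis_b.append(b)
            thetas.append(theta)

        # centre placement by rejection sampling
        centers = np.empty((config.n_cells, 2))
        placed_a = np.empty(config.n_cells)
        max_attempts = 500 * config.n_cells + 1000
        attempts = 0
        for i in range(config.n_cells):
            margin = semis_a[i] + 1
            ok = False
            while attempts < max_attempts:
                attempts += 1
                cand = rng.uniform([margin, margin], [H - 1 - margin, W - 1 - margin])
                if i == 0:
                    ok = True
                else:
                    d = np.hypot(*(centers[:i] - cand).T)
                    ok = bool(np.all(d > 0.95 * (placed_a[:i] + semis_a[i])))
                if ok:
                    centers[i] = cand
                    placed_a[i] = semis_a[i]
                    break
            if not ok:
                raise PackingError(
                    f"could not place cell {i + 1} of {config.n_cells} "
                    f"in a {H}x{W} image after {max_attempts} attempts"
                )

        for i, cls in enumerate(classes_drawn):
            rr, cc = draw_ellipse(
                centers[i, 0], centers[i, 1], semis_a[i], semis_b[i],
                shape=(H, W), rotation=thetas[i],
            )
            free = labels[rr, cc] == 0
            rr, cc = rr[free], cc[free]
            if rr.size == 0:  # fully occluded (essentially impossible at this spacing)
                raise PackingError(f"cell {i + 1} of {config.n_cells} has no free pixels")
            labels[rr, cc] = i + 1
            pixel_lists.append((rr, cc))
            truth_rows.append(
                {
                    "instance_id": i + 1,
                    "class": cls,
                    "centroid_row": float(rr.mean()),
                    "centroid_col": float(cc.mean()),
                    "slide_id": config.slide_id,
                    "patient_id": config.patient_id,
                    "site_id": config.site_id,
                }
            )

    # channels: gating channels in canonical order, then nuisance channels
    channels: dict[str, np.ndarray] = {}
    for ch in GATING_CHANNELS:
        if config.background_sd > 0:
            arr = rng.normal(0.0, config.background_sd, size=(H, W)).astype(np.float32)
        else:
            arr = np.zeros((H, W), dtype=np.float32)
        for i, cls in enumerate(classes_drawn):
            level = config.marker_profile[cls].get(ch)
            if level is None:
                continue
            rr, cc = pixel_lists[i]
            vals = np.full(rr.size, level.mean, dtype=np.float32)
            if level.sd > 0:
                vals += rng.normal(0.0, level.sd, size=rr.size).astype(np.float32)
            arr[rr, cc] = vals
        channels[ch] = np.clip(arr, 0, None)
    for k in range(config.n_nuisance_channels):
        arr = rng.normal(0.15, max(config.background_sd, 0.02), size=(H, W))
        channels[f"nuisance_{k + 1}"] = np.clip(arr, 0, None).astype(np.float32)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "instance_id", "class", "centroid_row", "centroid_col",
            "slide_id", "patient_id", "site_id",
        ],
    )
    image = MultiplexImage(channels, res)
    return SyntheticTissue(
        image=image,
        instances=InstanceMap(labels, res),
        truth=truth,
        slide_id=config.slide_id,
        patient_id=config.patient_id,
        site_id=config.site_id,
    )


# -- pseudo-H&E rendering ----------------------------------------------------

_BG_COLOR = np.array([0.94, 0.90, 0.92])  # pale pink tissue/background wash
_NUCLEUS_COLOR = np.array([0.32, 0.22, 0.55])  # hematoxylin-like purple-blue
_GOBLET_COLOR = np.array([0.88, 0.90, 0.95])  # pale goblet


def render_pseudo_he(tissue: SyntheticTissue) -> np.ndarray:
    """Deterministic analytic pseudo-H&E rendering, float RGB in [0, 1].

    Nucleus pixels darken toward purple-blue proportionally to their DAPI
    intensity, goblet pixels are pale, everything else a pale pink wash.  The
    rendering preserves instance geometry and DAPI brightness, so classes with
    a unique (size, eccentricity, brightness) signature are learnable from the
    rendering alone; marker-only distinctions (e.g. CD4 vs CD8) are not.
    """
    if "DAPI" not in tissue.image.channels:
        raise ChannelError("pseudo-H&E rendering requires a DAPI channel")
    H, W = tissue.instances.shape
    rgb = np.tile(_BG_COLOR, (H, W, 1)).astype(np.float64)

    labels = tissue.instances.labels
    if tissue.truth.empty:
        return rgb.astype(np.float32)

    is_goblet = np.zeros(int(labels.max()) + 1, dtype=bool)
    gob_ids = tissue.truth.loc[tissue.truth["class"] == "goblet", "instance_id"].to_numpy()
    is_goblet[gob_ids] = True

    inst = labels > 0
    goblet_px = inst & is_goblet[labels]
    nucleus_px = inst & ~goblet_px

    dapi = tissue.image.channel("DAPI")
    # mixing weight: 0.55 at DAPI=0 up to 1 at DAPI>=1.8 (brightest class)
    k = 0.55 + 0.45 * np.clip(dapi / 1.8, 0, 1)
    rgb[nucleus_px] = (1 - k[nucleus_px, None]) * _BG_COLOR + k[nucleus_px, None] * _NUCLEUS_COLOR
    rgb[goblet_px] = _GOBLET_COLOR
    return np.clip(rgb, 0, 1).astype(np.float32)


# -- coarse parent-labeled evaluation sets -----------------------------------


@dataclass
class ParentTile:
    """One color tile with its instance map, parent-labeled cell table and site id."""

    tile: np.ndarray
    instances: InstanceMap
    table: pd.DataFrame
    site_id: str


def _site_color_shift(site_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-site affine RGB shift (scale, offset)."""
    rng = np.random.default_rng(zlib.crc32(site_id.encode("utf-8")))
    scale = rng.uniform(0.9, 1.1, size=3)
    offset = rng.uniform(-0.04, 0.04, size=3)
    return scale, offset


def generate_parent_labeled_set(
    tissues: list[SyntheticTissue],
    mapping: ClassMapping,
    tile_px: int = 256,
    target_res: float = 0.5,
    site_effects: bool = True,
) -> list[ParentTile]:
    """Build a coarse-labeled evaluation set emulating an external H&E cohort.

    Each tissue is rendered to pseudo-H&E, resampled to ``target_res`` (cubic
    for color, nearest-neighbour for labels), given a per-site affine color
    shift, and cut into ``tile_px`` x ``tile_px`` tiles (partial edge tiles are
    dropped).  Fine labels are replaced by parent labels via ``mapping``;
    droppable fine classes (e.g. goblet, which has no nucleus-level coarse
    label) are removed from both the table and the tile's instance map.
    """
    for t in tissues:
        for cls in t.truth["class"].unique():
            if not mapping.covers(cls):
                raise MappingError(f"fine class {cls!r} is neither mapped nor droppable")

    out: list[ParentTile] = []
    for t in tissues:
        rgb = render_pseudo_he(t)
        src_res = t.image.resolution_um_per_px
        rgb_rs = resample_image(rgb, src_res, target_res)
        rgb_rs = np.clip(rgb_rs, 0, 1)
        inst_rs = resample_image(t.instances, src_res, target_res)
        if site_effects:
            scale, offset = _site_color_shift(t.site_id)
            rgb_rs = np.clip(rgb_rs * scale + offset, 0, 1).astype(np.float32)

        drop_ids = t.truth.loc[t.truth["class"].isin(mapping.droppable), "instance_id"].to_numpy()
        fine_class = dict(zip(t.truth["instance_id"], t.truth["class"]))

        H, W = inst_rs.shape
        for r0 in range(0, H - tile_px + 1, tile_px):
            for c0 in range(0, W - tile_px + 1, tile_px):
                tile = rgb_rs[r0 : r0 + tile_px, c0 : c0 + tile_px].copy()
                sub = inst_rs.labels[r0 : r0 + tile_px, c0 : c0 + tile_px].copy()
                if drop_ids.size:
                    sub[np.isin(sub, drop_ids)] = 0
                tile_map = InstanceMap(sub, target_res)
                rows = []
                for uid, (cr, cc) in tile_map.centroids().items():
                    cls = fine_class[uid]
                    rows.append(
                        {
                            "instance_id": uid,
                            "class": mapping.parent(cls),
                            "fine_class": cls,
                            "centroid_row": cr,
                            "centroid_col": cc,
                            "slide_id": t.slide_id,
                            "patient_id": t.patient_id,
                            "site_id": t.site_id,
                        }
                    )
                table = pd.DataFrame(
                    rows,
                    columns=[
                        "instance_id", "class", "fine_class", "centroid_row",
                        "centroid_col", "slide_id", "patient_id", "site_id",
                    ],
                )
                out.append(ParentTile(tile=tile, instances=tile_map, table=table, site_id=t.site_id))
    return out
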