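"""Synthetic voxel phantoms and exposure scenes.

The generator builds a stylized adult body (tapered legs, elliptical trunk,
neck, head) on a regular voxel grid and places the canonical source regions
as ellipsoids at fixed fractional coordinates: bladder low and anterior in
the pelvis, kidneys posterior in the mid trunk, thyroid anterior in the
neck, and so on.  Trunk and leg cross-sections are scaled so the voxelized
mass matches the requested body mass to better than 1%, which is how a
fixed-height family of phantoms spanning a weight range reproduces the
morphology spread of interest (heavier bodies bury deep organs under more
overlying tissue).

These stylized bodies stand in for licensed reference voxel phantoms; the
analyses built on them use ratios, spreads and bounds rather than absolute
organ-dose replication.

Axes: x lateral, y anterior (+) / posterior (-), z vertical (z = 0 at the
feet).  All world coordinates are in cm.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .physics import MATERIALS
from .regions import TABLE1_REGIONS

__all__ = [
    "VoxelPhantom",
    "Scene",
    "GenerationError",
    "generate_phantom",
    "build_scene",
    "make_point_scene",
    "make_vial_phantom",
    "CHEST_FRACTION",
]


class GenerationError(ValueError):
    pass


# --- body proportions (fractions of standing height H) ---------------------
LEG_TOP = 0.50
TRUNK_TOP = 0.85
NECK_TOP = 0.89
CHEST_FRACTION = 0.75  # tally height: "chest height" of the patient
TRUNK_HALF_WIDTH = 0.110  # lateral semi-axis of the trunk ellipse, x H x scale
TRUNK_HALF_DEPTH = 0.062  # antero-posterior semi-axis, x H x scale
HEAD_SEMI_AXES = (0.048, 0.058, 0.055)  # x H, not mass-scaled
NECK_RADIUS = 0.032

LABEL_AIR = 0
LABEL_SOFT = 1
LABEL_BONE = 2
LABEL_LUNG = 3

# organ ellipsoids: (x centre / trunk semi-axis, y centre / trunk semi-axis,
#                    z centre / height, rx cm, ry cm, rz cm, mirrored)
_ORGANS = {
    "Urinary bladder content": (0.00, +0.30, 0.545, 4.5, 4.0, 3.5, False),
    "Kidneys": (0.45, -0.35, 0.630, 3.0, 2.5, 5.5, True),
    "Liver": (0.30, +0.05, 0.700, 7.5, 5.5, 6.5, False),
    "Heart": (-0.15, +0.25, 0.745, 4.5, 4.2, 4.2, False),
    "Stomach wall": (-0.35, +0.30, 0.700, 3.8, 3.2, 4.0, False),
    "Spleen": (-0.60, -0.25, 0.695, 2.8, 2.3, 4.0, False),
    "Pancreas": (-0.05, 0.00, 0.675, 6.0, 1.6, 1.6, False),
    "Small intestine content": (0.00, +0.05, 0.585, 6.5, 4.0, 4.0, False),
    "Right colon content": (+0.55, 0.00, 0.600, 2.4, 2.4, 5.5, False),
    "Left colon content": (-0.55, 0.00, 0.610, 2.4, 2.4, 5.5, False),
    "Recto-sigmoid colon content": (0.00, -0.25, 0.530, 2.8, 2.2, 3.5, False),
}
_ORGAN_LABELS = {name: 10 + i for i, name in enumerate(_ORGANS)}
_ORGAN_LABELS.update({"Thyroid": 30, "Salivary glands": 31, "Brain": 32})


@dataclass
class VoxelPhantom:
    """A labelled voxel grid with per-label region name and material."""

    labels: np.ndarray  # int16 (nx, ny, nz)
    voxel_size_mm: float
    label_map: dict  # label -> (region/organ name, material name)
    origin_cm: tuple  # world coordinates of the grid corner (voxel (0,0,0) corner)
    height_cm: float | None = None
    mass_kg: float | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def voxel_cm(self):
        return self.voxel_size_mm / 10.0

    @property
    def shape(self):
        return self.labels.shape

    def body_mask(self):
        return self.labels != LABEL_AIR

    def region_mask(self, region):
        """Boolean voxel mask for a source region.

        ``Remainder`` is the body minus all named organs; ``Blood`` is
        distributed, sampled uniformly over the whole body.
        """
        if region == "Blood":
            return self.body_mask()
        if region == "Remainder":
            return self.labels == LABEL_SOFT
        matches = [lab for lab, (name, _m) in self.label_map.items() if name == region]
        if not matches:
            raise KeyError(f"region {region!r} not present in phantom")
        return np.isin(self.labels, matches)

    def material_of_label(self):
        out = {LABEL_AIR: "air"}
        for lab, (_name, mat) in self.label_map.items():
            out[lab] = mat
        return out

    def computed_mass_kg(self):
        vol = self.voxel_cm**3
        mass = 0.0
        for lab, mat in self.material_of_label().items():
            if lab == LABEL_AIR:
                continue
            mass += np.count_nonzero(self.labels == lab) * vol * MATERIALS[mat].density
        return mass / 1000.0

    def organ_masses_kg(self):
        vol = self.voxel_cm**3
        out = {}
        for lab, (name, mat) in self.label_map.items():
            n = np.count_nonzero(self.labels == lab)
            out[name] = out.get(name, 0.0) + n * vol * MATERIALS[mat].density / 1000.0
        return out

    def surface_points(self):
        """World coordinates (cm) of body surface voxel centres."""
        body = self.body_mask()
        eroded = np.zeros_like(body)
        eroded[1:-1, 1:-1, 1:-1] = (
            body[1:-1, 1:-1, 1:-1]
            & body[:-2, 1:-1, 1:-1] & body[2:, 1:-1, 1:-1]
            & body[1:-1, :-2, 1:-1] & body[1:-1, 2:, 1:-1]
            & body[1:-1, 1:-1, :-2] & body[1:-1, 1:-1, 2:]
        )
        idx = np.argwhere(body & ~eroded)
        return self.origin_cm + (idx + 0.5) * self.voxel_cm

    def save(self, path):
        header = {
            "voxel_size_mm": self.voxel_size_mm,
            "label_map": {str(k): list(v) for k, v in self.label_map.items()},
            "origin_cm": list(self.origin_cm),
            "height_cm": self.height_cm,
            "mass_kg": self.mass_kg,
            "seed": self.seed,
            "meta": self.meta,
        }
        np.savez_compressed(path, labels=self.labels,
                            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            labels = z["labels"]
            header = json.loads(bytes(z["header"]).decode())
        return cls(
            labels=labels,
            voxel_size_mm=header["voxel_size_mm"],
            label_map={int(k): tuple(v) for k, v in header["label_map"].items()},
            origin_cm=tuple(header["origin_cm"]),
            height_cm=header["height_cm"],
            mass_kg=header["mass_kg"],
            seed=header["seed"],
            meta=header["meta"],
        )


def _ellipsoid(x, y, z, c, r):
    return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0


def _build_labels(height, scale, voxel_cm, jitter):
    """Voxelize the stylized body at a given transverse scale factor."""
    h = height
    ax = TRUNK_HALF_WIDTH * h * scale
    by = TRUNK_HALF_DEPTH * h * scale
    ha, hb, hc = (f * h for f in HEAD_SEMI_AXES)
    half_x = max(ax * 1.9, ha) + 2.0 * voxel_cm
    half_y = max(by, hb) + 2.0 * voxel_cm
    nx = int(np.ceil(2 * half_x / voxel_cm))
    ny = int(np.ceil(2 * half_y / voxel_cm))
    nz = int(np.ceil(h / voxel_cm)) + 2
    origin = (-nx * voxel_cm / 2.0, -ny * voxel_cm / 2.0, 0.0)
    ix = (np.arange(nx) + 0.5) * voxel_cm + origin[0]
    iy = (np.arange(ny) + 0.5) * voxel_cm + origin[1]
    iz = (np.arange(nz) + 0.5) * voxel_cm + origin[2]
    x = ix[:, None, None]
    y = iy[None, :, None]
    z = iz[None, None, :]

    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    # legs: tapered cylinders
    leg_z = (z >= 0) & (z < LEG_TOP * h)
    r_bot, r_top = 0.18 * ax, 0.42 * ax
    r_leg = r_bot + (r_top - r_bot) * np.clip(z / (LEG_TOP * h), 0, 1)
    for sx in (+1, -1):
        cxl = sx * 0.45 * ax
        labels[leg_z & ((x - cxl) ** 2 + y**2 <= r_leg**2)] = LABEL_SOFT
    # trunk
    trunk = (z >= LEG_TOP * h) & (z < TRUNK_TOP * h) & ((x / ax) ** 2 + (y / by) ** 2 <= 1.0)
    labels[trunk] = LABEL_SOFT
    # neck and head
    neck = (z >= TRUNK_TOP * h) & (z < NECK_TOP * h) & (x**2 + y**2 <= (NECK_RADIUS * h) ** 2)
    labels[neck] = LABEL_SOFT
    head_c = (0.0, 0.0, (NECK_TOP + 1.0) / 2.0 * h)
    labels[_ellipsoid(x, y, z, head_c, (ha, hb, hc))] = LABEL_SOFT

    # lungs (before bone/organs; material lung)
    for sx in (+1, -1):
        c = (sx * 0.42 * ax + jitter["Lungs"][0], -0.05 * by + jitter["Lungs"][1],
             0.775 * h + jitter["Lungs"][2])
        r = (0.30 * ax, 0.62 * by, 0.075 * h)
        labels[_ellipsoid(x, y, z, c, r) & (labels == LABEL_SOFT)] = LABEL_LUNG

    # skeleton: spine, pelvic ring, skull shell, leg bones
    spine = (
        (z >= 0.51 * h) & (z < TRUNK_TOP * h)
        & (x**2 + (y + 0.55 * by) ** 2 <= 2.0**2)
    )
    labels[spine & (labels == LABEL_SOFT)] = LABEL_BONE
    rho2 = (x / ax) ** 2 + (y / by) ** 2
    pelvis = (z >= 0.50 * h) & (z < 0.545 * h) & (rho2 >= 0.55) & (rho2 <= 0.85)
    labels[pelvis & (labels == LABEL_SOFT)] = LABEL_BONE
    head_r2 = ((x - head_c[0]) / ha) ** 2 + ((y - head_c[1]) / hb) ** 2 + ((z - head_c[2]) / hc) ** 2
    skull = (head_r2 <= 1.0) & (head_r2 >= 0.82**2)
    labels[skull & (labels == LABEL_SOFT)] = LABEL_BONE
    for sx in (+1, -1):
        legbone = leg_z & ((x - sx * 0.45 * ax) ** 2 + y**2 <= 1.2**2)
        labels[legbone & (labels == LABEL_SOFT)] = LABEL_BONE

    # organs, painted over soft tissue only (guarantees a disjoint partition)
    for name, (fx, fy, fz, rx, ry, rz, mirrored) in _ORGANS.items():
        lab = _ORGAN_LABELS[name]
        jx, jy, jz = jitter[name]
        sides = (+1, -1) if mirrored else (+1,)
        for sx in sides:
            c = (sx * fx * ax + jx, fy * by + jy, fz * h + jz)
            labels[_ellipsoid(x, y, z, c, (rx, ry, rz)) & (labels == LABEL_SOFT)] = lab
    # head/neck organs
    jx, jy, jz = jitter["Thyroid"]
    c = (jx, 0.55 * NECK_RADIUS * h + jy, 0.868 * h + jz)
    labels[_ellipsoid(x, y, z, c, (1.8, 1.2, 1.6)) & (labels == LABEL_SOFT)] = _ORGAN_LABELS["Thyroid"]
    jx, jy, jz = jitter["Salivary glands"]
    c = (jx, 0.25 * hb + jy, 0.905 * h + jz)
    labels[_ellipsoid(x, y, z, c, (2.6, 2.0, 1.3)) & (labels == LABEL_SOFT)] = _ORGAN_LABELS["Salivary glands"]
    jx, jy, jz = jitter["Brain"]
    c = (jx, jy, head_c[2] + 0.1 * hc + jz)
    labels[_ellipsoid(x, y, z, c, (0.78 * ha, 0.78 * hb, 0.72 * hc)) & (labels == LABEL_SOFT)] = _ORGAN_LABELS["Brain"]

    return labels, origin


def generate_phantom(height_cm, mass_kg, region_set=None, seed=0, voxel_mm=5.0):
    """Deterministic stylized adult phantom of given height and mass.

    ``region_set`` restricts which source regions must be present (defaults
    to all); generation fails if a required organ cannot be placed.  The
    seed drives small (<= 3 mm) anatomical jitter of organ centres so
    different seeds give distinct but equivalent anatomies.
    """
    if not (140.0 <= height_cm <= 200.0):
        raise GenerationError(f"height {height_cm} cm outside supported range 140-200")
    if not (40.0 <= mass_kg <= 120.0):
        raise GenerationError(f"mass {mass_kg} kg outside supported range 40-120")
    region_set = set(region_set) if region_set else set(TABLE1_REGIONS)
    unknown = region_set - set(TABLE1_REGIONS)
    if unknown:
        raise GenerationError(f"unknown source regions: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    organ_names = list(_ORGANS) + ["Thyroid", "Salivary glands", "Brain", "Lungs"]
    jitter = {name: rng.uniform(-0.3, 0.3, size=3) for name in organ_names}

    voxel_cm = voxel_mm / 10.0
    scale = 1.0
    labels = origin = None
    mass = np.nan
    for _ in range(12):
        labels, origin = _build_labels(height_cm, scale, voxel_cm, jitter)
        mass = _mass_of(labels, voxel_cm)
        if abs(mass - mass_kg) / mass_kg < 0.005:
            break
        scale *= np.sqrt(mass_kg / mass)
    if abs(mass - mass_kg) / mass_kg > 0.01:
        raise GenerationError(f"mass calibration failed: got {mass:.2f} kg for target {mass_kg}")

    label_map = {
        LABEL_SOFT: ("Remainder", "soft_tissue"),
        LABEL_BONE: ("Bone", "bone"),
        LABEL_LUNG: ("Lungs", "lung"),
    }
    for name, lab in _ORGAN_LABELS.items():
        label_map[lab] = (name, "soft_tissue")

    phantom = VoxelPhantom(
        labels=labels,
        voxel_size_mm=voxel_mm,
        label_map=label_map,
        origin_cm=origin,
        height_cm=height_cm,
        mass_kg=mass_kg,
        seed=seed,
        meta={"generator": "nmdose stylized adult", "scale": scale},
    )
    for region in region_set - {"Remainder", "Blood"}:
        if not phantom.region_mask(region).any():
            raise GenerationError(f"organ {region!r} could not be placed in this body")
    return phantom


def _mass_of(labels, voxel_cm):
    vol = voxel_cm**3 / 1000.0  # kg per voxel per unit density
    return (
        np.count_nonzero(labels == LABEL_SOFT) * MATERIALS["soft_tissue"].density
        + np.count_nonzero(labels == LABEL_BONE) * MATERIALS["bone"].density
        + np.count_nonzero(labels == LABEL_LUNG) * MATERIALS["lung"].density
        + np.count_nonzero(labels >= 10) * MATERIALS["soft_tissue"].density
    ) * vol


def make_vial_phantom(voxel_mm=1.0):
    """Source vial: 50 mm high, 20 mm diameter cylinder with 1 mm borosilicate
    walls, lower half filled with an aqueous solution carrying the activity."""
    voxel_cm = voxel_mm / 10.0
    n_xy = int(np.ceil(2.4 / voxel_cm))
    n_z = int(np.ceil(5.2 / voxel_cm))
    origin = (-n_xy * voxel_cm / 2.0, -n_xy * voxel_cm / 2.0, -n_z * voxel_cm / 2.0)
    ix = (np.arange(n_xy) + 0.5) * voxel_cm + origin[0]
    iz = (np.arange(n_z) + 0.5) * voxel_cm + origin[2]
    x = ix[:, None, None]
    y = ix[None, :, None]
    z = iz[None, None, :]
    r = np.sqrt(x**2 + y**2)
    labels = np.zeros((n_xy, n_xy, n_z), dtype=np.int16)
    inside = (r <= 1.0) & (np.abs(z) <= 2.5)
    wall = inside & ((r > 0.9) | (np.abs(z) > 2.4))
    lumen = inside & ~wall
    labels[wall] = 1
    labels[lumen & (z < 0)] = 2  # lower half: solution
    return VoxelPhantom(
        labels=labels,
        voxel_size_mm=voxel_mm,
        label_map={1: ("Vial wall", "borosilicate_glass"), 2: ("Vial solution", "water")},
        origin_cm=origin,
        meta={"generator": "nmdose vial"},
    )


@dataclass
class Scene:
    """A composed exposure geometry ready for the transport engines."""

    patient: VoxelPhantom
    configuration: str  # point | face_to_face | side_by_side
    gap_cm: float
    counterpart: VoxelPhantom | None
    mat_grid: np.ndarray  # uint8 material indices (world grid)
    materials: tuple  # ordered material names; index 0 is air
    origin_cm: tuple
    voxel_cm: float
    tally_point: np.ndarray | None
    source_labels: np.ndarray  # patient labels placed in the world grid
    organ_grid: np.ndarray | None  # counterpart organ ids, -1 elsewhere
    organ_names: tuple = ()
    measured_gap_cm: float | None = None
    ambient_material: str = "air"  # medium outside the grid bounding box

    def source_voxels(self, region):
        """Flat world-grid indices of the voxels of a patient source region."""
        mask = np.zeros(self.mat_grid.shape, dtype=bool)
        pm = self.patient.region_mask(region)
        mask[self._patient_slices] = pm
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"source region {region!r} is empty")
        return idx

    @property
    def _patient_slices(self):
        return self.__dict__.get("_pslices", tuple(slice(0, s) for s in self.patient.labels.shape))


def _material_grid(phantom):
    mat_names = ["air"] + sorted({m for _n, m in phantom.label_map.values()})
    index = {m: i for i, m in enumerate(mat_names)}
    grid = np.zeros(phantom.labels.shape, dtype=np.uint8)
    for lab, (_name, mat) in phantom.label_map.items():
        grid[phantom.labels == lab] = index[mat]
    return grid, tuple(mat_names)


def make_point_scene(phantom, tally_xyz, gap_cm=None):
    """Scene with a free-space tally point and no exposed individual."""
    grid, mats = _material_grid(phantom)
    return Scene(
        patient=phantom, configuration="point", gap_cm=gap_cm if gap_cm else np.nan,
        counterpart=None, mat_grid=grid, materials=mats,
        origin_cm=phantom.origin_cm, voxel_cm=phantom.voxel_cm,
        tally_point=np.asarray(tally_xyz, dtype=float),
        source_labels=phantom.labels, organ_grid=None,
    )


def build_scene(patient, configuration, gap_cm, counterpart=None):
    """Compose a benchmark geometry.

    ``point``: a tally point at chest height, ``gap_cm`` from the anterior
    skin surface.  ``face_to_face``: the counterpart phantom faces the
    patient, anterior surfaces ``gap_cm`` apart.  ``side_by_side``: the
    counterpart stands beside the patient facing the same direction,
    ``gap_cm`` of air between the nearest lateral surfaces.
    """
    if gap_cm <= 0:
        raise ValueError("phantoms/tally would overlap: gap must be > 0")
    if configuration == "point":
        z_chest = CHEST_FRACTION * patient.height_cm
        grid, mats = _material_grid(patient)
        body = patient.body_mask()
        kz = int((z_chest - patient.origin_cm[2]) / patient.voxel_cm)
        sl = body[:, :, max(kz - 1, 0):kz + 2]
        if not sl.any():
            raise ValueError("no body voxels at chest height")
        jmax = int(np.max(np.argwhere(sl)[:, 1]))
        y_skin = patient.origin_cm[1] + (jmax + 1) * patient.voxel_cm
        tally = np.array([0.0, y_skin + gap_cm, z_chest])
        scene = make_point_scene(patient, tally, gap_cm=gap_cm)
        scene.measured_gap_cm = gap_cm
        return scene

    if counterpart is None:
        raise ValueError(f"configuration {configuration!r} needs a counterpart phantom")
    if configuration not in ("face_to_face", "side_by_side"):
        raise ValueError(f"unknown configuration {configuration!r}")

    axis = 1 if configuration == "face_to_face" else 0
    c_labels = np.flip(counterpart.labels, axis=1) if configuration == "face_to_face" else counterpart.labels
    p_labels = patient.labels
    vox = patient.voxel_cm
    if abs(vox - counterpart.voxel_cm) > 1e-9:
        raise ValueError("patient and counterpart must share the voxel size")

    gap_vox = int(round(gap_cm / vox))
    if gap_vox < 1:
        raise ValueError("phantoms would overlap: gap below one voxel")

    p_body = np.argwhere(p_labels != LABEL_AIR)
    c_body = np.argwhere(c_labels != LABEL_AIR)
    p_hi = int(p_body[:, axis].max())  # nearest-face voxel index of the patient
    c_lo = int(c_body[:, axis].min())
    # counterpart grid start so that surface-to-surface distance = gap_vox voxels
    c_start = p_hi + 1 + gap_vox - c_lo

    shape = [0, 0, 0]
    for a in range(3):
        if a == axis:
            shape[a] = max(p_labels.shape[a], c_start + c_labels.shape[a])
        else:
            shape[a] = max(p_labels.shape[a], c_labels.shape[a])
    world_p = np.zeros(shape, dtype=np.int16)
    world_c = np.zeros(shape, dtype=np.int16)

    def _centered(src_shape, a):
        if a == axis:
            return None
        off = (shape[a] - src_shape[a]) // 2
        return slice(off, off + src_shape[a])

    p_sl = tuple(slice(0, p_labels.shape[a]) if a == axis else _centered(p_labels.shape, a) for a in range(3))
    c_sl = tuple(slice(c_start, c_start + c_labels.shape[a]) if a == axis else _centered(c_labels.shape, a) for a in range(3))
    world_p[p_sl] = p_labels
    world_c[c_sl] = c_labels

    mats = ["air"] + sorted(
        {m for _n, m in patient.label_map.values()} | {m for _n, m in counterpart.label_map.values()}
    )
    index = {m: i for i, m in enumerate(mats)}
    mat_grid = np.zeros(shape, dtype=np.uint8)
    for lab, (_n, m) in patient.label_map.items():
        mat_grid[world_p == lab] = index[m]
    for lab, (_n, m) in counterpart.label_map.items():
        mat_grid[world_c == lab] = index[m]

    organ_names = tuple(dict.fromkeys(name for name, _m in counterpart.label_map.values()))
    organ_id = {name: i for i, name in enumerate(organ_names)}
    organ_grid = np.full(shape, -1, dtype=np.int16)
    for lab, (name, _m) in counterpart.label_map.items():
        organ_grid[world_c == lab] = organ_id[name]

    origin = tuple(patient.origin_cm[a] - p_sl[a].start * vox for a in range(3))
    # measured skin-to-skin distance between surface voxel faces
    tree = cKDTree((np.argwhere(world_c != LABEL_AIR) + 0.5) * vox)
    d_min, _ = tree.query((np.argwhere(world_p != LABEL_AIR) + 0.5) * vox, k=1)
    measured = float(d_min.min()) - vox  # centre-to-centre minus two half-voxels

    scene = Scene(
        patient=patient, configuration=configuration, gap_cm=gap_cm,
        counterpart=counterpart, mat_grid=mat_grid, materials=tuple(mats),
        origin_cm=origin, voxel_cm=vox, tally_point=None,
        source_labels=world_p, organ_grid=organ_grid, organ_names=organ_names,
        measured_gap_cm=measured,
    )
    scene.__dict__["_pslices"] = p_sl
    return scene
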