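"""Dose quantities: fluence-to-H*(10) conversion, per-region dose-rate
factors from the Monte Carlo and point-kernel backends, effective dose, and
the vial reference geometry.

All factors are expressed in uSv/h per MBq of activity in the source
region; raw engine output is per emitted particle (MC) or per decay (point
kernel) and is converted with the total photon yield and the fixed
Sv/s/Bq -> uSv/h/MBq factor of 3.6e15.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from . import physics
from .nuclides import Radionuclide, load_nuclide, total_yield
from .phantoms import make_point_scene, make_vial_phantom
from .transport import TallyResult, _point_kernel_sum, mc_transport

__all__ = [
    "ConversionTable",
    "DoseRateFactor",
    "load_h10_table",
    "h10_per_fluence",
    "load_tissue_weights",
    "effective_dose",
    "convert_units",
    "unconvert_units",
    "h10_factor",
    "point_kernel",
    "vial_reference",
    "organ_dose_factors",
    "effective_dose_factor",
]

UNIT_FACTOR = 3.6e15  # (Sv/s)/Bq -> (uSv/h)/MBq: 3600 * 1e6 * 1e6
PSV_PER_DECAY_TO_USV_H_MBQ = UNIT_FACTOR * 1e-12


@dataclass(frozen=True)
class ConversionTable:
    """Ambient dose equivalent per unit fluence vs photon energy."""

    energies: np.ndarray  # keV
    h10: np.ndarray  # pSv cm^2


@lru_cache(maxsize=1)
def load_h10_table() -> ConversionTable:
    text = resources.files("nmdose.data").joinpath("h10_per_fluence_icrp74.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#") and not r.startswith("energy")]
    data = np.array([[float(v) for v in r.split(",")] for r in rows])
    return ConversionTable(data[:, 0], data[:, 1])


def h10_per_fluence(energy_kev):
    """H*(10) per unit fluence (pSv cm^2), log-log interpolated.

    Exact at table nodes; raises for energies outside the tabulated range
    (no extrapolation).
    """
    tab = load_h10_table()
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < tab.energies[0]) or np.any(e > tab.energies[-1]):
        raise ValueError(
            f"energy outside conversion-table range "
            f"[{tab.energies[0]}, {tab.energies[-1]}] keV"
        )
    out = np.exp(np.interp(np.log(e), np.log(tab.energies), np.log(tab.h10)))
    return float(out) if np.ndim(energy_kev) == 0 else out


@lru_cache(maxsize=1)
def h10_on_grid():
    """H*(10)/fluence evaluated on the internal transport energy grid."""
    return np.ascontiguousarray(h10_per_fluence(physics.E_GRID))


@lru_cache(maxsize=1)
def load_tissue_weights() -> dict:
    text = resources.files("nmdose.data").joinpath("tissue_weights_icrp103.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#") and not r.startswith("tissue")]
    weights = {r.split(",")[0]: float(r.split(",")[1]) for r in rows}
    if abs(sum(weights.values()) - 1.0) > 1e-12:
        raise ValueError("tissue weighting factors must sum to 1")
    return weights


def effective_dose(organ_doses_female, organ_doses_male, weights=None):
    """Sex-averaged effective dose E = sum_T w_T * (D_T,male + D_T,female)/2.

    A tissue absent from a dose map falls back to that map's ``Remainder``
    entry (the remainder rule); if neither is present this raises.
    Units follow the inputs.
    """
    weights = weights or load_tissue_weights()

    def _dose(doses, tissue):
        if tissue in doses:
            return doses[tissue]
        if "Remainder" in doses:
            return doses["Remainder"]
        raise KeyError(f"tissue {tissue!r} missing and no Remainder entry to fall back on")

    return sum(
        w * 0.5 * (_dose(organ_doses_female, t) + _dose(organ_doses_male, t))
        for t, w in weights.items()
    )


def convert_units(x):
    """Sv/s per Bq -> uSv/h per MBq."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("dose rates must be non-negative")
    return x * UNIT_FACTOR


def unconvert_units(x):
    return x / UNIT_FACTOR


@dataclass(frozen=True)
class DoseRateFactor:
    """Per-region dose rate per unit activity in the region (uSv/h/MBq)."""

    source_region: str
    quantity: str  # "H*(10)" or "E"
    geometry: str
    value: float
    rel_se: float = 0.0
    n_histories: int = 0
    seed: int | None = None


def h10_factor(scene, nuclide, source_region, n_histories, seed, **kw) -> DoseRateFactor:
    """Monte Carlo H*(10) dose-rate factor at the scene's tally point."""
    if scene.tally_point is None:
        raise ValueError("scene has no tally point")
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    tally = mc_transport(scene, nuclide, source_region, n_histories, seed, **kw)
    scale = total_yield(nuclide) * PSV_PER_DECAY_TO_USV_H_MBQ
    return DoseRateFactor(
        source_region=source_region,
        quantity="H*(10)",
        geometry=f"{scene.configuration}",
        value=tally.h10_per_particle * scale,
        rel_se=tally.rel_se,
        n_histories=tally.n_histories,
        seed=seed,
    )


@lru_cache(maxsize=1)
def _buildup_tables():
    text = resources.files("nmdose.data").joinpath("buildup_water_berger.csv").read_text()
    rows = [r for r in text.splitlines() if r and not r.startswith("#") and not r.startswith("energy")]
    data = np.array([[float(v) for v in r.split(",")] for r in rows])
    loge = np.log(data[:, 0])
    a = np.interp(np.log(physics.E_GRID), loge, data[:, 1])
    b = np.interp(np.log(physics.E_GRID), loge, data[:, 2])
    return np.ascontiguousarray(a), np.ascontiguousarray(b)


def point_kernel(scene, nuclide, source_region, max_source_voxels=150_000,
                 buildup=True) -> DoseRateFactor:
    """Deterministic point-kernel H*(10) factor at the scene's tally point.

    Attenuated primary fluence per source voxel with a Berger-form buildup
    factor evaluated at the ray's total optical depth; ``buildup=False``
    degenerates to the uncollided line-of-sight estimate.  Large source
    regions are deterministically strided down to ``max_source_voxels``.
    """
    if scene.tally_point is None:
        raise ValueError("scene has no tally point")
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    src = scene.source_voxels(source_region)
    if len(src) > max_source_voxels:
        stride = int(np.ceil(len(src) / max_source_voxels))
        src = src[::stride]
    mu_tot, _ = physics.material_index(scene.materials)
    ambient = getattr(scene, "ambient_material", "air")
    mu_air = np.ascontiguousarray(physics.MATERIALS[ambient].mu_table)
    bu_a, bu_b = _buildup_tables()
    if not buildup:
        bu_a = np.zeros_like(bu_a)
    nx, ny, nz = scene.mat_grid.shape
    psv_per_decay = _point_kernel_sum(
        src, np.ascontiguousarray(scene.mat_grid.reshape(-1)),
        nx, ny, nz,
        float(scene.origin_cm[0]), float(scene.origin_cm[1]), float(scene.origin_cm[2]),
        float(scene.voxel_cm),
        mu_tot, mu_air,
        nuclide.energies(), nuclide.intensities(),
        np.asarray(scene.tally_point, dtype=float),
        h10_on_grid(),
        bu_a, bu_b,
    )
    return DoseRateFactor(
        source_region=source_region,
        quantity="H*(10)",
        geometry=f"{scene.configuration}(point-kernel)",
        value=psv_per_decay * PSV_PER_DECAY_TO_USV_H_MBQ,
        rel_se=0.0,
    )


def vial_reference(nuclide="Tc99m", distance_m=1.0, n_histories=400_000, seed=1,
                   voxel_mm=1.0) -> DoseRateFactor:
    """H*(10) rate per unit activity at ``distance_m`` from the source vial.

    The reference geometry of the measurement-device intercomparison: the
    half-filled vial with the activity in aqueous solution, fluence scored
    at a free-in-air point level with the vial centre and converted with
    the bundled coefficients.
    """
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    vial = make_vial_phantom(voxel_mm=voxel_mm)
    scene = make_point_scene(vial, (0.0, 100.0 * distance_m, 0.0))
    factor = h10_factor(scene, nuclide, "Vial solution", n_histories, seed)
    return DoseRateFactor(
        source_region="Vial solution",
        quantity="H*(10)",
        geometry=f"vial@{distance_m:g}m",
        value=factor.value,
        rel_se=factor.rel_se,
        n_histories=factor.n_histories,
        seed=seed,
    )


# exposed-individual organ -> ICRP-103 weighted tissue, for effective dose.
# Tissues without an explicitly segmented organ fall back to "Remainder".
_TISSUE_SOURCES = {
    "Red bone marrow": ["Bone"],
    "Bone surface": ["Bone"],
    "Colon": ["Right colon content", "Left colon content", "Recto-sigmoid colon content"],
    "Lungs": ["Lungs"],
    "Stomach": ["Stomach wall"],
    "Urinary bladder": ["Urinary bladder content"],
    "Liver": ["Liver"],
    "Thyroid": ["Thyroid"],
    "Brain": ["Brain"],
    "Salivary glands": ["Salivary glands"],
}


def organ_dose_factors(scene, nuclide, tally: TallyResult) -> dict:
    """Organ equivalent-dose rate factors (uSv/h/MBq) for the counterpart."""
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    if not tally.organ_edep:
        raise ValueError("tally carries no organ scores")
    masses = scene.counterpart.organ_masses_kg()
    kev_to_j = 1.602176634e-16
    out = {}
    for organ, edep in tally.organ_edep.items():
        m = masses.get(organ, 0.0)
        if m <= 0:
            continue
        gy_per_decay = edep * kev_to_j / m * total_yield(nuclide)
        out[organ] = gy_per_decay * UNIT_FACTOR  # photons: w_R = 1
    return out


def effective_dose_factor(scene, nuclide, source_region, n_histories, seed) -> DoseRateFactor:
    """Effective dose-rate factor for the exposed phantom of a paired scene.

    The counterpart stands in for both sexes (one synthetic anatomy), so
    the sex average is degenerate; weighting and the remainder rule follow
    :func:`effective_dose`.
    """
    if isinstance(nuclide, str):
        nuclide = load_nuclide(nuclide)
    tally = mc_transport(scene, nuclide, source_region, n_histories, seed)
    organ = organ_dose_factors(scene, nuclide, tally)
    doses = {}
    for tissue, sources in _TISSUE_SOURCES.items():
        vals = [organ[s] for s in sources if s in organ]
        if vals:
            doses[tissue] = float(np.mean(vals))
    doses["Remainder"] = organ.get("Remainder", 0.0)
    e = effective_dose(doses, doses)
    return DoseRateFactor(
        source_region=source_region,
        quantity="E",
        geometry=scene.configuration,
        value=float(e),
        rel_se=max([tally.organ_edep_se.get(o, 0.0) / max(tally.organ_edep.get(o, 1e-300), 1e-300)
                    for o in tally.organ_edep] or [0.0]),
        n_histories=n_histories,
        seed=seed,
    )
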