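"""Photon Monte Carlo transport on voxel scenes.

Analog transport with Woodcock (delta) tracking across the voxel grid and a
next-event (point-detector) estimator for free-space tallies: at the
emission point and at every Compton vertex the expected fluence
contribution at the tally point is scored as

    isotropic emission:  exp(-tau) / (4 pi d^2)
    Compton vertex:      w * (dsigma/dOmega / sigma_KN) * exp(-tau') / d^2

with tau the optical depth along the ray to the detector (fixed-step ray
marching through the grid, plus air attenuation beyond the grid bounding
box).  Interactions are photoelectric absorption (local deposition) and
incoherent scattering with free-electron Klein-Nishina angular sampling by
inverse-CDF table lookup.  Photons below the 15 keV cutoff are absorbed on
the spot.  Energy deposited in labelled organs of an exposed counterpart
phantom is scored analogously per collision.

The random stream is a single seeded generator; identical inputs and seed
reproduce tallies bit for bit (the kernels are single-threaded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import physics
from .physics import E_GRID, ELECTRON_REST_KEV, N_E, R_E_CM

FLU_NBINS = 32
_FLU_LO = np.log(physics.E_MIN_KEV)
_FLU_DLOG = (np.log(physics.E_MAX_KEV) - _FLU_LO) / FLU_NBINS
FLU_EDGES = np.exp(_FLU_LO + _FLU_DLOG * np.arange(FLU_NBINS + 1))

_LOGE0 = np.log(E_GRID[0])
_DLOGE = np.log(E_GRID[1] / E_GRID[0])

_CINV = None  # lazily built Compton inverse-CDF table


def _compton_table():
    global _CINV
    if _CINV is None:
        _CINV = physics.build_compton_inverse_cdf()
    return _CINV


@njit(cache=True, inline="always")
def _row_interp(row, e):
    f = (np.log(e) - _LOGE0) / _DLOGE
    if f <= 0.0:
        return row[0]
    if f >= N_E - 1:
        return row[N_E - 1]
    i = int(f)
    w = f - i
    return row[i] * (1.0 - w) + row[i + 1] * w


@njit(cache=True, inline="always")
def _kn_total(e):
    a = e / ELECTRON_REST_KEV
    t1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log(1.0 + 2.0 * a) / a)
    t2 = np.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / ((1.0 + 2.0 * a) * (1.0 + 2.0 * a))
    return 2.0 * np.pi * R_E_CM * R_E_CM * (t1 + t2 - t3)


@njit(cache=True, inline="always")
def _kn_diff(e, c):
    a = e / ELECTRON_REST_KEV
    x = 1.0 / (1.0 + a * (1.0 - c))
    return 0.5 * R_E_CM * R_E_CM * x * x * (x + 1.0 / x - (1.0 - c * c))


@njit(cache=True)
def _tau_to_point(px, py, pz, dx, dy, dz,
                  mat, nx, ny, nz, ox, oy, oz, vox,
                  mu_tot, mu_air, e):
    """Optical depth from p to the detector d, and their distance."""
    wx = dx - px
    wy = dy - py
    wz = dz - pz
    dist = np.sqrt(wx * wx + wy * wy + wz * wz)
    if dist <= 0.0:
        return 0.0, 0.0
    ux = wx / dist
    uy = wy / dist
    uz = wz / dist
    # exit parameter of the grid bounding box along +u from p
    t_exit = dist
    hx = ox + nx * vox
    hy = oy + ny * vox
    hz = oz + nz * vox
    if ux > 0.0:
        t = (hx - px) / ux
        if t < t_exit:
            t_exit = t
    elif ux < 0.0:
        t = (ox - px) / ux
        if t < t_exit:
            t_exit = t
    if uy > 0.0:
        t = (hy - py) / uy
        if t < t_exit:
            t_exit = t
    elif uy < 0.0:
        t = (oy - py) / uy
        if t < t_exit:
            t_exit = t
    if uz > 0.0:
        t = (hz - pz) / uz
        if t < t_exit:
            t_exit = t
    elif uz < 0.0:
        t = (oz - pz) / uz
        if t < t_exit:
            t_exit = t
    if t_exit < 0.0:
        t_exit = 0.0

    step = 0.5 * vox
    tau = 0.0
    t = 0.5 * step
    while t < t_exit:
        cx = px + t * ux
        cy = py + t * uy
        cz = pz + t * uz
        ix = int((cx - ox) / vox)
        iy = int((cy - oy) / vox)
        iz = int((cz - oz) / vox)
        if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
            m = mat[(ix * ny + iy) * nz + iz]
            tau += _row_interp(mu_tot[m], e) * step
        else:
            tau += _row_interp(mu_air, e) * step
        t += step
    if dist > t_exit:
        tau += _row_interp(mu_air, e) * (dist - t_exit)
    return tau, dist


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0.0 else -1.0
        return sint * cp, sign * sint * sp, sign * cost
    s = np.sqrt(1.0 - uz * uz)
    nxx = cost * ux + sint * (ux * uz * cp - uy * sp) / s
    nyy = cost * uy + sint * (uy * uz * cp + ux * sp) / s
    nzz = cost * uz - sint * s * cp
    return nxx, nyy, nzz


@njit(cache=True)
def _run_histories(seed, n_hist, n_batches,
                   mat, nx, ny, nz, ox, oy, oz, vox,
                   mu_tot, mu_pe, mu_max, mu_air,
                   cinv,
                   line_e, line_cdf,
                   det, has_det,
                   h10,
                   organ, has_organ, n_organs,
                   src,
                   beam, has_beam,
                   e_cut):
    np.random.seed(seed)
    nq = cinv.shape[1]
    batch_h10 = np.zeros(n_batches)
    batch_flu = np.zeros((n_batches, FLU_NBINS))
    batch_org = np.zeros((n_batches, n_organs))
    e_emitted = 0.0
    e_deposited = 0.0
    e_escaped = 0.0
    n_uncollided = 0

    for h in range(n_hist):
        b = h * n_batches // n_hist
        # emission energy
        r = np.random.random()
        k = 0
        while line_cdf[k] < r:
            k += 1
        e = line_e[k]
        # emission position: uniform in a uniformly chosen source voxel
        j = src[int(np.random.random() * len(src))]
        iz0 = j % nz
        iy0 = (j // nz) % ny
        ix0 = j // (ny * nz)
        px = ox + (ix0 + np.random.random()) * vox
        py = oy + (iy0 + np.random.random()) * vox
        pz = oz + (iz0 + np.random.random()) * vox
        # direction
        if has_beam:
            ux, uy, uz = beam[0], beam[1], beam[2]
        else:
            uz = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            s = np.sqrt(max(0.0, 1.0 - uz * uz))
            ux = s * np.cos(phi)
            uy = s * np.sin(phi)
        e_emitted += e

        if has_det and not has_beam:
            tau, dist = _tau_to_point(px, py, pz, det[0], det[1], det[2],
                                      mat, nx, ny, nz, ox, oy, oz, vox,
                                      mu_tot, mu_air, e)
            contrib = np.exp(-tau) / (4.0 * np.pi * dist * dist)
            batch_h10[b] += contrib * _row_interp(h10, e)
            fb = int((np.log(e) - _FLU_LO) / _FLU_DLOG)
            if fb >= FLU_NBINS:
                fb = FLU_NBINS - 1
            batch_flu[b, fb] += contrib

        ncoll = 0
        alive = True
        while alive:
            mumax = _row_interp(mu_max, e)
            if mumax <= 0.0:
                # void medium: photon flies out
                e_escaped += e
                if ncoll == 0:
                    n_uncollided += 1
                break
            # Woodcock flight
            collided = False
            for _ in range(100000):
                s = -np.log(1.0 - np.random.random()) / mumax
                px += s * ux
                py += s * uy
                pz += s * uz
                ix = int((px - ox) / vox)
                iy = int((py - oy) / vox)
                iz = int((pz - oz) / vox)
                if px < ox or py < oy or pz < oz or ix >= nx or iy >= ny or iz >= nz:
                    break
                m = mat[(ix * ny + iy) * nz + iz]
                mu = _row_interp(mu_tot[m], e)
                if np.random.random() * mumax < mu:
                    collided = True
                    break
            if not collided:
                e_escaped += e
                if ncoll == 0:
                    n_uncollided += 1
                break
            ncoll += 1
            flat = (ix * ny + iy) * nz + iz
            mu = _row_interp(mu_tot[m], e)
            mpe = _row_interp(mu_pe[m], e)
            if np.random.random() * mu < mpe:
                # photoelectric absorption
                e_deposited += e
                if has_organ and organ[flat] >= 0:
                    batch_org[b, organ[flat]] += e
                break
            # Compton scattering: next-event contribution first
            if has_det:
                wx = det[0] - px
                wy = det[1] - py
                wz = det[2] - pz
                dd = np.sqrt(wx * wx + wy * wy + wz * wz)
                if dd > 0.0:
                    cosd = (ux * wx + uy * wy + uz * wz) / dd
                    a = e / ELECTRON_REST_KEV
                    e_sc = e / (1.0 + a * (1.0 - cosd))
                    tau, dist = _tau_to_point(px, py, pz, det[0], det[1], det[2],
                                              mat, nx, ny, nz, ox, oy, oz, vox,
                                              mu_tot, mu_air, e_sc)
                    pdf_sr = _kn_diff(e, cosd) / _kn_total(e)
                    contrib = pdf_sr * np.exp(-tau) / (dist * dist)
                    batch_h10[b] += contrib * _row_interp(h10, e_sc)
                    fb = int((np.log(e_sc) - _FLU_LO) / _FLU_DLOG)
                    if fb < 0:
                        fb = 0
                    elif fb >= FLU_NBINS:
                        fb = FLU_NBINS - 1
                    batch_flu[b, fb] += contrib
            # sample the analog scattering angle from the inverse-CDF table
            f = (np.log(e) - _LOGE0) / _DLOGE
            if f < 0.0:
                f = 0.0
            elif f > N_E - 1:
                f = float(N_E - 1)
            i0 = int(f)
            wfe = f - i0
            i1 = i0 + 1 if i0 < N_E - 1 else i0
            q = np.random.random() * (nq - 1)
            qi = int(q)
            qw = q - qi
            q1 = qi + 1 if qi < nq - 1 else qi
            c0 = cinv[i0, qi] * (1.0 - qw) + cinv[i0, q1] * qw
            c1 = cinv[i1, qi] * (1.0 - qw) + cinv[i1, q1] * qw
            cost = c0 * (1.0 - wfe) + c1 * wfe
            a = e / ELECTRON_REST_KEV
            e_new = e / (1.0 + a * (1.0 - cost))
            edep = e - e_new
            e_deposited += edep
            if has_organ and organ[flat] >= 0:
                batch_org[b, organ[flat]] += edep
            if e_new < e_cut:
                e_deposited += e_new
                if has_organ and organ[flat] >= 0:
                    batch_org[b, organ[flat]] += e_new
                break
            phi = 2.0 * np.pi * np.random.random()
            ux, uy, uz = _rotate(ux, uy, uz, cost, phi)
            e = e_new

    return (batch_h10, batch_flu, batch_org,
            e_emitted, e_deposited, e_escaped, n_uncollided)


@njit(cache=True)
def _point_kernel_sum(src, mat, nx, ny, nz, ox, oy, oz, vox,
                      mu_tot, mu_air,
                      line_e, line_i,
                      det, h10,
                      bu_a, bu_b):
    """Deterministic attenuated-primary + buildup sum over source voxels.

    Returns pSv per decay at the detector (fluence-to-H*(10) converted),
    with the Berger buildup evaluated per line at the ray's optical depth.
    """
    total = 0.0
    for n in range(len(src)):
        j = src[n]
        iz0 = j % nz
        iy0 = (j // nz) % ny
        ix0 = j // (ny * nz)
        px = ox + (ix0 + 0.5) * vox
        py = oy + (iy0 + 0.5) * vox
        pz = oz + (iz0 + 0.5) * vox
        for k in range(len(line_e)):
            e = line_e[k]
            tau, dist = _tau_to_point(px, py, pz, det[0], det[1], det[2],
                                      mat, nx, ny, nz, ox, oy, oz, vox,
                                      mu_tot, mu_air, e)
            a = _row_interp(bu_a, e)
            bb = _row_interp(bu_b, e)
            arg = bb * tau
            if arg > 30.0:
                arg = 30.0
            buildup = 1.0 + a * tau * np.exp(arg)
            flu = line_i[k] * np.exp(-tau) * buildup / (4.0 * np.pi * dist * dist)
            total += flu * _row_interp(h10, e)
    return total / len(src)


@dataclass
class TallyResult:
    """Monte Carlo tally: per-energy-bin fluence at the point detector and/or
    per-organ energy deposition in the exposed phantom, per source particle."""

    n_histories: int
    seed: int
    h10_per_particle: float  # pSv per emitted particle
    h10_se: float
    fluence: np.ndarray  # 1/cm^2 per particle, FLU_NBINS log bins
    fluence_se: np.ndarray
    fluence_edges: np.ndarray
    organ_edep: dict  # organ -> keV per particle
    organ_edep_se: dict
    energy_emitted: float  # keV, analog ledger
    energy_deposited: float
    energy_escaped: float
    uncollided_fraction: float

    @property
    def rel_se(self):
        return self.h10_se / self.h10_per_particle if self.h10_per_particle else 0.0


def mc_transport(scene, nuclide, source_region, n_histories, seed,
                 e_cut=15.0, n_batches=25, beam_direction=None):
    """Run the analog MC engine on a scene; see the module docstring.

    ``source_region`` names a patient region; emission positions are
    sampled uniformly over its voxels and energies from the nuclide's line
    spectrum.  Returns a :class:`TallyResult` normalised per emitted
    particle.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    src = scene.source_voxels(source_region)
    mu_tot, mu_pe = physics.material_index(scene.materials)
    mu_max = np.ascontiguousarray(mu_tot.max(axis=0))
    ambient = getattr(scene, "ambient_material", "air")
    mu_air = np.ascontiguousarray(physics.MATERIALS[ambient].mu_table)

    from .dose import h10_on_grid

    h10 = h10_on_grid()
    nx, ny, nz = scene.mat_grid.shape
    mat = np.ascontiguousarray(scene.mat_grid.reshape(-1))
    has_det = scene.tally_point is not None
    det = scene.tally_point if has_det else np.zeros(3)
    has_organ = scene.organ_grid is not None
    organ = (np.ascontiguousarray(scene.organ_grid.reshape(-1))
             if has_organ else np.full(1, -1, dtype=np.int16))
    n_organs = max(len(scene.organ_names), 1)
    e = nuclide.energies()
    i = nuclide.intensities()
    cdf = np.cumsum(i) / i.sum()
    has_beam = beam_direction is not None
    beam = (np.asarray(beam_direction, dtype=float) / np.linalg.norm(beam_direction)
            if has_beam else np.zeros(3))

    (bh, bf, bo, e_em, e_dep, e_esc, n_unc) = _run_histories(
        seed, int(n_histories), int(n_batches),
        mat, nx, ny, nz,
        float(scene.origin_cm[0]), float(scene.origin_cm[1]), float(scene.origin_cm[2]),
        float(scene.voxel_cm),
        mu_tot, mu_pe, mu_max, mu_air,
        _compton_table(),
        e, cdf,
        np.asarray(det, dtype=float), has_det,
        h10,
        organ, has_organ, n_organs,
        src,
        beam, has_beam,
        float(e_cut),
    )

    per_batch = n_histories / n_batches
    bh_m = bh / per_batch
    bf_m = bf / per_batch
    bo_m = bo / per_batch

    def _se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    organ_edep = {}
    organ_se = {}
    if has_organ:
        for oi, name in enumerate(scene.organ_names):
            organ_edep[name] = float(bo_m[:, oi].mean())
            organ_se[name] = _se(bo_m[:, oi])

    return TallyResult(
        n_histories=int(n_histories),
        seed=int(seed),
        h10_per_particle=float(bh_m.mean()),
        h10_se=_se(bh_m),
        fluence=bf_m.mean(axis=0),
        fluence_se=np.array([_se(bf_m[:, k]) for k in range(FLU_NBINS)]),
        fluence_edges=FLU_EDGES.copy(),
        organ_edep=organ_edep,
        organ_edep_se=organ_se,
        energy_emitted=float(e_em),
        energy_deposited=float(e_dep),
        energy_escaped=float(e_esc),
        uncollided_fraction=float(n_unc) / n_histories,
    )
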