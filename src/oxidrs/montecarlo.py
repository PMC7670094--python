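"""White Monte Carlo photon transport in the three-layer probe geometry.

Photons are launched from the source fiber face into a three-layer slab
(epidermis of variable thickness, 0.2 mm upper dermis, semi-infinite deep
dermis) with a common scattering coefficient and **zero absorption**; the
per-layer path lengths of photons collected by the two detector fibers are
stored.  Absorption for any chromophore composition is applied afterwards by
Beer-Lambert weighting of the stored paths, so one simulation per
(epidermis thickness, reduced scattering) grid node serves every wavelength
and every absorption spectrum.

Scattering uses the Henyey-Greenstein phase function with anisotropy
g = 0.8 and mu_s = mu_s' / (1 - g).  Because the geometry is rotationally
symmetric about the source axis, detection uses an exact variance-reduction:
every photon exiting the surface within a detector's radial band and within
the fiber's acceptance cone is recorded with a weight equal to the fraction
of the azimuthal circle covered by the fiber face.  This has the same
expectation as discrete-fiber detection while collecting far more records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from oxidrs.tissue_optics import CONSTANTS

__all__ = [
    "ProbeGeometry",
    "PhotonPathRecord",
    "PathLengthTable",
    "simulate_node",
    "build_table",
    "ExtrapolationError",
]


class ExtrapolationError(ValueError):
    """A lookup-table query fell outside the simulated grid."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-optic probe geometry (mm).

    One emitting fiber and two detecting fibers at 0.4 and 1.2 mm
    center-center separation; all fibers 200 um core, NA 0.37.  The probe
    face is index-matched glass (n = 1.5) on tissue (n = 1.4).
    """

    source_diameter: float = 0.2
    detector_diameter: float = 0.2
    numerical_aperture: float = 0.37
    separations: tuple[float, ...] = (0.4, 1.2)
    n_tissue: float = 1.4
    n_ambient: float = 1.5

    def __post_init__(self):
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValueError("numerical aperture must be in (0,1)")
        for s in self.separations:
            if s <= self.detector_diameter:
                raise ValueError("separation must exceed fiber diameter")


@dataclass
class PhotonPathRecord:
    """Per-layer path lengths (mm) of one detected photon."""

    path_lengths: np.ndarray  # (3,)
    channel: int
    weight: float = 1.0


# ---------------------------------------------------------------------------
# numba transport kernel

@njit(cache=True)
def _transport_kernel(t_epi, mu_s, src_radius, det_radius, sep0, sep1,
                      cos_launch_min, sin2_accept_max, n_tissue, n_ambient,
                      g, path_cap, n_photons, seed, buf_size):
    """Trace photons; return detected-path buffers and bookkeeping counts."""
    np.random.seed(seed)
    L_out = np.zeros((buf_size, 3))
    w_out = np.zeros(buf_size)
    ch_out = np.zeros(buf_size, np.int64)
    n_rec = 0
    n_escaped = 0
    n_capped = 0
    overflow = 0
    t1b = t_epi + 0.2  # upper-dermis lower boundary
    n_rel = n_tissue / n_ambient

    for _ in range(n_photons):
        # launch: uniform over source face, uniform in the acceptance cone
        r = src_radius * math.sqrt(np.random.random())
        phi = 2.0 * math.pi * np.random.random()
        x = r * math.cos(phi)
        y = r * math.sin(phi)
        z = 0.0
        uz = cos_launch_min + (1.0 - cos_launch_min) * np.random.random()
        st = math.sqrt(max(0.0, 1.0 - uz * uz))
        psi = 2.0 * math.pi * np.random.random()
        ux = st * math.cos(psi)
        uy = st * math.sin(psi)

        l1 = 0.0
        l2 = 0.0
        l3 = 0.0
        total = 0.0
        alive = True
        while alive:
            s = -math.log(np.random.random() + 1e-300) / mu_s
            remaining = s
            while remaining > 0.0:
                hit_surface = False
                seg = remaining
                if uz < 0.0:
                    d_surf = -z / uz
                    if d_surf <= remaining:
                        seg = d_surf
                        hit_surface = True
                z_new = z + uz * seg
                # split segment length over the three layers
                zlo = z if z < z_new else z_new
                zhi = z_new if z_new > z else z
                dz = zhi - zlo
                if dz < 1e-14:
                    if z < t_epi:
                        l1 += seg
                    elif z < t1b:
                        l2 += seg
                    else:
                        l3 += seg
                else:
                    o1 = min(zhi, t_epi) - max(zlo, 0.0)
                    if o1 > 0.0:
                        l1 += seg * o1 / dz
                    o2 = min(zhi, t1b) - max(zlo, t_epi)
                    if o2 > 0.0:
                        l2 += seg * o2 / dz
                    o3 = zhi - max(zlo, t1b)
                    if o3 > 0.0:
                        l3 += seg * o3 / dz
                x += ux * seg
                y += uy * seg
                z = z_new
                total += seg
                remaining -= seg
                if hit_surface:
                    z = 0.0
                    # Fresnel at tissue->glass interface (n2 > n1: no TIR)
                    ci = -uz
                    si2 = 1.0 - ci * ci
                    st2 = n_rel * n_rel * si2
                    ct = math.sqrt(max(0.0, 1.0 - st2))
                    rs_num = n_tissue * ci - n_ambient * ct
                    rs_den = n_tissue * ci + n_ambient * ct
                    rp_num = n_tissue * ct - n_ambient * ci
                    rp_den = n_tissue * ct + n_ambient * ci
                    R = 0.5 * ((rs_num / rs_den) ** 2 + (rp_num / rp_den) ** 2)
                    if np.random.random() < R:
                        uz = -uz  # internal reflection, continue this step
                    else:
                        # transmitted: escape; test detection
                        n_escaped += 1
                        if si2 <= sin2_accept_max:
                            rho = math.sqrt(x * x + y * y)
                            for c in range(2):
                                sep = sep0 if c == 0 else sep1
                                if abs(rho - sep) < det_radius:
                                    if rho < 1e-9:
                                        w = 1.0 if sep < det_radius else 0.0
                                    else:
                                        carg = ((rho * rho + sep * sep
                                                 - det_radius * det_radius)
                                                / (2.0 * rho * sep))
                                        if carg > 1.0:
                                            carg = 1.0
                                        elif carg < -1.0:
                                            carg = -1.0
                                        w = math.acos(carg) / math.pi
                                    if w > 0.0:
                                        if n_rec < buf_size:
                                            L_out[n_rec, 0] = l1
                                            L_out[n_rec, 1] = l2
                                            L_out[n_rec, 2] = l3
                                            w_out[n_rec] = w
                                            ch_out[n_rec] = c
                                            n_rec += 1
                                        else:
                                            overflow = 1
                        alive = False
                        remaining = 0.0
                if alive and total > path_cap:
                    n_capped += 1
                    alive = False
                    remaining = 0.0
            if not alive:
                break
            # Henyey-Greenstein scatter
            u = np.random.random()
            if g > 1e-6:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * u - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = math.sqrt(1.0 - ct * ct)
            psi = 2.0 * math.pi * np.random.random()
            cp = math.cos(psi)
            sp = math.sin(psi)
            if abs(uz) > 0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                uz_n = -st * cp * den + uz * ct
                norm = math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

    return L_out[:n_rec], w_out[:n_rec], ch_out[:n_rec], n_escaped, n_capped, overflow


def simulate_node(t_epi, mu_s_prime, geometry: ProbeGeometry, n_photons, seed,
                  path_cap: float = 200.0):
    """Run one white-MC node; return per-channel path records.

    Returns
    -------
    records : list over channels of ``(L, w)`` with ``L`` a ``(n, 3)`` array
        of per-layer path lengths (mm) and ``w`` the detection weights.
    counts : dict with ``n_launched``, ``n_escaped``, ``n_capped``.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if mu_s_prime <= 0:
        raise ValueError("mu_s_prime must be > 0")
    g = CONSTANTS.g_aniso
    mu_s = mu_s_prime / (1.0 - g)
    sin_max = geometry.numerical_aperture / geometry.n_tissue
    cos_launch_min = math.sqrt(1.0 - sin_max ** 2)
    buf = max(4096, n_photons // 8)
    while True:
        out = _transport_kernel(
            float(t_epi), float(mu_s),
            geometry.source_diameter / 2.0, geometry.detector_diameter / 2.0,
            geometry.separations[0], geometry.separations[1],
            cos_launch_min, sin_max ** 2,
            geometry.n_tissue, geometry.n_ambient,
            g, float(path_cap), int(n_photons), int(seed), int(buf))
        L, w, ch, n_escaped, n_capped, overflow = out
        if not overflow:
            break
        buf *= 4
    records = []
    for c in range(len(geometry.separations)):
        m = ch == c
        records.append((np.ascontiguousarray(L[m]), np.ascontiguousarray(w[m])))
    counts = {"n_launched": int(n_photons), "n_escaped": int(n_escaped),
              "n_capped": int(n_capped)}
    return records, counts


# ---------------------------------------------------------------------------
# lookup table

def _node_seed(master_seed: int, node_index: int) -> int:
    # documented counter scheme: deterministic, collision-free per node
    return int((int(master_seed) * 100003 + 7919 * node_index + 1) % (2 ** 31 - 1))


class PathLengthTable:
    """Per-layer path-length records on a (t_epi x mu_s') grid.

    Node intensities for arbitrary layer absorption triplets are obtained by
    Beer-Lambert weighting of the stored paths and interpolated bilinearly
    in (t_epi, log mu_s').
    """

    def __init__(self, t_epi_grid, musp_grid, geometry: ProbeGeometry,
                 master_seed: int, path_cap: float = 200.0):
        self.t_epi_grid = np.asarray(t_epi_grid, float)
        self.musp_grid = np.asarray(musp_grid, float)
        for ax in (self.t_epi_grid, self.musp_grid):
            if ax.ndim != 1 or ax.size < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing, length >= 2")
        self.geometry = geometry
        self.master_seed = int(master_seed)
        self.path_cap = float(path_cap)
        self.n_channels = len(geometry.separations)
        # storage: keyed (i, j, channel)
        self._L: dict[tuple[int, int, int], np.ndarray] = {}
        self._w: dict[tuple[int, int, int], np.ndarray] = {}
        self.n_launched = np.zeros(
            (self.t_epi_grid.size, self.musp_grid.size), np.int64)
        self.node_seeds = np.zeros_like(self.n_launched)

    # -- construction -------------------------------------------------------

    def simulate_all(self, n_photons: int, progress: bool = False):
        nodes = [(i, j) for i in range(self.t_epi_grid.size)
                 for j in range(self.musp_grid.size)]
        for k, (i, j) in enumerate(nodes):
            seed = _node_seed(self.master_seed, k)
            recs, counts = simulate_node(
                self.t_epi_grid[i], self.musp_grid[j], self.geometry,
                n_photons, seed, self.path_cap)
            for c, (L, w) in enumerate(recs):
                self._L[(i, j, c)] = L
                self._w[(i, j, c)] = w
            self.n_launched[i, j] = counts["n_launched"]
            self.node_seeds[i, j] = seed
            if progress:
                print(f"node {k + 1}/{len(nodes)}: t_epi={self.t_epi_grid[i]:.3f} "
                      f"musp={self.musp_grid[j]:.3f} "
                      f"records={[len(self._w[(i, j, c)]) for c in range(self.n_channels)]}")
        return self

    def node_records(self, i, j, channel):
        return self._L[(i, j, channel)], self._w[(i, j, channel)]

    def valid_nodes(self) -> np.ndarray:
        """Boolean mask of nodes with >= 1 record in every channel."""
        ok = np.zeros(self.n_launched.shape, bool)
        for i in range(self.t_epi_grid.size):
            for j in range(self.musp_grid.size):
                ok[i, j] = all(
                    (i, j, c) in self._w and self._w[(i, j, c)].size > 0
                    for c in range(self.n_channels))
        return ok

    # -- queries ------------------------------------------------------------

    def _cell(self, t_epi, musp):
        tg, mg = self.t_epi_grid, self.musp_grid
        if not (tg[0] <= t_epi <= tg[-1]):
            raise ExtrapolationError(
                f"t_epi={t_epi} outside grid [{tg[0]}, {tg[-1]}]")
        if not (mg[0] <= musp <= mg[-1]):
            raise ExtrapolationError(
                f"mu_s'={musp} outside grid [{mg[0]}, {mg[-1]}]")
        i = min(int(np.searchsorted(tg, t_epi, side="right") - 1), tg.size - 2)
        j = min(int(np.searchsorted(mg, musp, side="right") - 1), mg.size - 2)
        u = (t_epi - tg[i]) / (tg[i + 1] - tg[i])
        v = ((math.log(musp) - math.log(mg[j]))
             / (math.log(mg[j + 1]) - math.log(mg[j])))
        return i, j, u, v

    def _node_sums(self, i, j, channel, mua, with_paths=False):
        """Beer-Lambert sums at one node.

        ``mua``: (n_lambda, 3).  Returns intensity (n_lambda,) and, when
        ``with_paths``, the absorption-weighted per-layer path sums
        (n_lambda, 3), both normalized by the launched-photon count.
        """
        key = (i, j, channel)
        if key not in self._w or self._w[key].size == 0:
            raise ExtrapolationError(
                f"grid node (i={i}, j={j}, ch={channel}) has no detected photons")
        L, w = self._L[key], self._w[key]
        b = w[:, None] * np.exp(-(L @ mua.T))  # (n_rec, n_lambda)
        n0 = self.n_launched[i, j]
        intensity = b.sum(axis=0) / n0
        if not with_paths:
            return intensity, None
        paths = np.einsum("kl,kn->ln", b, L) / n0  # (n_lambda, 3)
        return intensity, paths

    def reflectance_at(self, t_epi, musp, mua_triplet, channel=None,
                       return_se=False):
        """Interpolated detected intensity for one (t_epi, mu_s', mu_a) query.

        ``mua_triplet``: absorption in (epidermis, upper dermis, deep dermis)
        in 1/mm.  Returns an array over channels (or a float for a single
        ``channel``); with ``return_se`` also the combined Monte-Carlo
        standard error of the interpolated value.
        """
        mua = np.asarray(mua_triplet, float).reshape(1, 3)
        if np.any(mua < 0):
            raise ValueError("absorption must be nonnegative")
        i, j, u, v = self._cell(t_epi, musp)
        wts = {(i, j): (1 - u) * (1 - v), (i + 1, j): u * (1 - v),
               (i, j + 1): (1 - u) * v, (i + 1, j + 1): u * v}
        channels = range(self.n_channels) if channel is None else [channel]
        vals, ses = [], []
        for c in channels:
            acc = 0.0
            var = 0.0
            for (ii, jj), wt in wts.items():
                if wt == 0.0:
                    continue
                L, w = self._L[(ii, jj, c)], self._w[(ii, jj, c)]
                if w.size == 0:
                    raise ExtrapolationError(
                        f"invalid grid node (i={ii}, j={jj}, ch={c})")
                b = w * np.exp(-(L @ mua[0]))
                n0 = self.n_launched[ii, jj]
                m = b.sum() / n0
                acc += wt * m
                if return_se:
                    var += wt ** 2 * max(0.0, (b ** 2).sum() / n0 - m ** 2) / n0
            vals.append(acc)
            ses.append(math.sqrt(var))
        vals = np.array(vals)
        ses = np.array(ses)
        if channel is not None:
            return (float(vals[0]), float(ses[0])) if return_se else float(vals[0])
        return (vals, ses) if return_se else vals

    def spectrum_sums(self, t_epi, musp_per_lambda, mua_per_lambda,
                      with_paths=False):
        """Vectorized Beer-Lambert interpolation over a wavelength grid.

        Parameters
        ----------
        musp_per_lambda : (n_lambda,) reduced scattering at each wavelength.
        mua_per_lambda : (n_lambda, 3) layer absorption at each wavelength.

        Returns
        -------
        intensity : (n_channels, n_lambda)
        paths : (n_channels, n_lambda, 3) absorption-weighted per-layer path
            sums normalized by launched count, or None.
        """
        musp = np.asarray(musp_per_lambda, float)
        mua = np.asarray(mua_per_lambda, float)
        if mua.shape != (musp.size, 3):
            raise ValueError("mua_per_lambda must have shape (n_lambda, 3)")
        if np.any(mua < 0):
            raise ValueError("absorption must be nonnegative")
        bad = (musp < self.musp_grid[0]) | (musp > self.musp_grid[-1])
        if np.any(bad):
            raise ExtrapolationError(
                "mu_s' outside grid at wavelength indices "
                f"{np.nonzero(bad)[0].tolist()}")
        cells = [self._cell(t_epi, m) for m in musp]
        intensity = np.zeros((self.n_channels, musp.size))
        paths = np.zeros((self.n_channels, musp.size, 3)) if with_paths else None
        # group wavelengths sharing a cell so each node is visited once
        groups: dict[tuple[int, int], list[int]] = {}
        for k, (i, j, _, _) in enumerate(cells):
            groups.setdefault((i, j), []).append(k)
        for (i, j), idx in groups.items():
            idx = np.asarray(idx)
            u = np.array([cells[k][2] for k in idx])
            v = np.array([cells[k][3] for k in idx])
            wts = [((i, j), (1 - u) * (1 - v)), ((i + 1, j), u * (1 - v)),
                   ((i, j + 1), (1 - u) * v), ((i + 1, j + 1), u * v)]
            for c in range(self.n_channels):
                for (ii, jj), wt in wts:
                    ints, pth = self._node_sums(ii, jj, c, mua[idx],
                                                with_paths=with_paths)
                    intensity[c, idx] += wt * ints
                    if with_paths:
                        paths[c, idx, :] += wt[:, None] * pth
        return intensity, paths

    # -- persistence --------------------------------------------------------

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.attrs["t_epi_grid"] = self.t_epi_grid
            f.attrs["musp_grid"] = self.musp_grid
            f.attrs["master_seed"] = self.master_seed
            f.attrs["path_cap"] = self.path_cap
            g = self.geometry
            f.attrs["geometry"] = [g.source_diameter, g.detector_diameter,
                                   g.numerical_aperture, g.n_tissue, g.n_ambient]
            f.attrs["separations"] = list(g.separations)
            f.create_dataset("n_launched", data=self.n_launched)
            f.create_dataset("node_seeds", data=self.node_seeds)
            for (i, j, c), L in self._L.items():
                grp = f.create_group(f"nodes/{i}_{j}/ch{c}")
                grp.create_dataset("L", data=L)
                grp.create_dataset("w", data=self._w[(i, j, c)])
        self._write_manifest(str(path) + ".manifest.txt")

    def _write_manifest(self, path):
        ok = self.valid_nodes()
        with open(path, "w") as fh:
            fh.write("# white-MC path-length table manifest\n")
            fh.write(f"master_seed\t{self.master_seed}\n")
            fh.write(f"t_epi_grid\t{' '.join(f'{t:g}' for t in self.t_epi_grid)}\n")
            fh.write(f"musp_grid\t{' '.join(f'{m:g}' for m in self.musp_grid)}\n")
            fh.write("i\tj\tseed\tn_launched\tn_records_per_channel\tvalid\n")
            for i in range(self.t_epi_grid.size):
                for j in range(self.musp_grid.size):
                    nrec = [self._w.get((i, j, c), np.empty(0)).size
                            for c in range(self.n_channels)]
                    fh.write(f"{i}\t{j}\t{self.node_seeds[i, j]}\t"
                             f"{self.n_launched[i, j]}\t{nrec}\t{bool(ok[i, j])}\n")

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            geom = ProbeGeometry(
                source_diameter=float(f.attrs["geometry"][0]),
                detector_diameter=float(f.attrs["geometry"][1]),
                numerical_aperture=float(f.attrs["geometry"][2]),
                separations=tuple(float(s) for s in f.attrs["separations"]),
                n_tissue=float(f.attrs["geometry"][3]),
                n_ambient=float(f.attrs["geometry"][4]),
            )
            table = cls(f.attrs["t_epi_grid"], f.attrs["musp_grid"], geom,
                        int(f.attrs["master_seed"]), float(f.attrs["path_cap"]))
            table.n_launched = f["n_launched"][()]
            table.node_seeds = f["node_seeds"][()]
            for node_name, node in f["nodes"].items():
                i, j = (int(s) for s in node_name.split("_"))
                for ch_name, grp in node.items():
                    c = int(ch_name[2:])
                    table._L[(i, j, c)] = grp["L"][()]
                    table._w[(i, j, c)] = grp["w"][()]
        return table


def build_table(t_epi_grid, musp_grid, geometry: ProbeGeometry,
                n_photons: int, seed: int, path_cap: float = 200.0,
                progress: bool = False) -> PathLengthTable:
    """Simulate every grid node and return the populated lookup table."""
    table = PathLengthTable(t_epi_grid, musp_grid, geometry, seed, path_cap)
    return table.simulate_all(n_photons, progress=progress)
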