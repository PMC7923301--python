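"""Finite-difference linearized Poisson-Boltzmann electrostatics.

Solves the two-dielectric Poisson problem (zero ionic strength by default)
on a regular grid: solute cavity at dielectric 1 bounded by the
solvent-excluded surface (1.4 A probe), solvent at dielectric 80, Dirichlet
boundary from the Coulomb far field, 7-point stencil with harmonic-mean
link dielectrics, conjugate-gradient solution. Potentials are reported in
kT/e at 298 K, the unit used for molecular-surface maps (+-0.3 kT/e scale)
and isopotential renderings (+-10 kT/e levels).

The solvent-excluded surface is evaluated as a signed field combining the
exact distance to the van der Waals union with a probe-erosion of the
solvent-accessible exterior (Euclidean distance transform), which is exact
for convex regions and approximates reentrant patches to grid resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from skimage import measure

from .forcefield import COULOMB_CONSTANT, KT_298_KCAL, VDW_RADII, parameterize
from .structure import Assembly

__all__ = [
    "GridPotential",
    "SurfaceMap",
    "GridError",
    "solve_potential",
    "solvation_energy",
    "map_to_surface",
    "isopotential_surfaces",
    "ses_field",
    "potential_at",
    "write_dx",
    "write_ply",
    "write_pqr",
    "read_pqr",
]


class GridError(ValueError):
    """Grid cannot contain the solute plus the requested extension."""


@dataclass
class GridPotential:
    origin: np.ndarray                 # A
    spacing: float                     # A
    dims: tuple[int, int, int]
    values: np.ndarray                 # kT/e, shape dims
    solute_dielectric: float = 1.0
    solvent_dielectric: float = 80.0
    probe_radius: float = 1.4
    temperature: float = 298.0
    grid_extension: float = 5.0
    residual: float = 0.0
    charges: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        if min(self.dims) < 2:
            raise GridError("grid needs at least 2 nodes per axis")
        if self.spacing <= 0:
            raise GridError("grid spacing must be positive")

    def axes(self):
        return tuple(self.origin[i] + self.spacing * np.arange(self.dims[i])
                     for i in range(3))


@dataclass
class SurfaceMap:
    vertices: np.ndarray               # (nv, 3) A
    faces: np.ndarray                  # (nf, 3) int
    vertex_potential: np.ndarray       # (nv,) kT/e (raw, unclamped)
    scale_bounds: tuple[float, float] = (-0.3, 0.3)
    view_label: str = ""

    def clamped(self) -> np.ndarray:
        lo, hi = self.scale_bounds
        return np.clip(self.vertex_potential, lo, hi)

    def area(self) -> float:
        return float(measure.mesh_surface_area(self.vertices, self.faces))


def _charges_radii(assembly: Assembly, charges, radii):
    atoms = list(assembly.atoms())
    if charges is None:
        if all(a.charge is not None for a in atoms):
            charges = np.array([a.charge for a in atoms], float)
        else:
            charges = parameterize(assembly).charges
    else:
        charges = np.asarray(charges, float)
    if radii is None:
        radii = np.array([VDW_RADII.get(a.element.upper(), VDW_RADII["C"]) or 1.5
                          for a in atoms], float)
        radii[radii <= 0] = 1.5
    else:
        radii = np.asarray(radii, float)
    xyz = np.array([a.coordinates for a in atoms], float)
    return xyz, charges, radii


def _make_grid(xyz, radii, spacing, extension, probe):
    margin = extension + probe + float(np.max(radii))
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    center = 0.5 * (lo + hi)
    half = np.ceil((hi - lo) / (2 * spacing)).astype(int)
    dims = tuple(int(2 * h + 1) for h in half)  # odd: center lands on a node
    origin = center - spacing * np.array([(d - 1) / 2 for d in dims])
    if min(dims) < 8:
        raise GridError("grid too small to contain solute plus extension")
    return origin, dims


def ses_field(xyz, radii, origin, spacing, dims, probe=1.4):
    """Signed solvent-excluded-surface field on the grid (negative inside).

    min(distance to vdW union, probe - distance to solvent-accessible
    exterior); the first term is exact, the second closes reentrant regions.
    """
    ax = [origin[i] + spacing * np.arange(dims[i]) for i in range(3)]
    f_vdw = np.full(dims, np.inf)
    inside_sas = np.zeros(dims, bool)
    for c, r in zip(xyz, radii):
        reach = r + probe + 2 * spacing
        sl = []
        ok = True
        for i in range(3):
            i0 = int(np.searchsorted(ax[i], c[i] - reach))
            i1 = int(np.searchsorted(ax[i], c[i] + reach)) + 1
            if i0 >= dims[i] or i1 <= 0:
                ok = False
                break
            sl.append(slice(max(i0, 0), min(i1, dims[i])))
        if not ok:
            continue
        X, Y, Z = np.meshgrid(ax[0][sl[0]], ax[1][sl[1]], ax[2][sl[2]], indexing="ij")
        d = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
        reg = tuple(sl)
        f_vdw[reg] = np.minimum(f_vdw[reg], d - r)
        inside_sas[reg] |= d <= (r + probe)
    # distance from each node to the SAS exterior, in A
    d_ext = ndimage.distance_transform_edt(inside_sas, sampling=spacing)
    g = np.minimum(f_vdw, probe - d_ext)
    return g


def _boundary_potential(phi, origin, spacing, dims, xyz, q, eps):
    ax = [origin[i] + spacing * np.arange(dims[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    for face in range(6):
        axis, side = divmod(face, 2)
        idx = [slice(None)] * 3
        idx[axis] = 0 if side == 0 else dims[axis] - 1
        idx = tuple(idx)
        pts = np.stack([X[idx], Y[idx], Z[idx]], axis=-1)
        val = np.zeros(pts.shape[:-1])
        for c, qq in zip(xyz, q):
            r = np.linalg.norm(pts - c, axis=-1)
            r = np.maximum(r, 1e-6)
            val += COULOMB_CONSTANT * qq / (eps * r)
        phi[idx] = val


def solve_potential(
    assembly: Assembly,
    spacing: float = 0.8,
    extension: float = 5.0,
    probe_radius: float = 1.4,
    solute_dielectric: float = 1.0,
    solvent_dielectric: float = 80.0,
    charges=None,
    radii=None,
    uniform_dielectric: float | None = None,
    tol: float = 1e-10,
    maxiter: int = 5000,
) -> GridPotential:
    """Solve the linearized PB equation (zero salt) for the assembly.

    ``uniform_dielectric`` replaces the two-dielectric map with a constant
    (used for reaction-field references and analytic checks). Returns the
    potential in kT/e with the CG residual recorded.
    """
    xyz, q, rad = _charges_radii(assembly, charges, radii)
    origin, dims = _make_grid(xyz, rad, spacing, extension, probe_radius)
    nx, ny, nz = dims
    if uniform_dielectric is not None:
        eps_node = np.full(dims, float(uniform_dielectric))
        eps_far = float(uniform_dielectric)
    else:
        g = ses_field(xyz, rad, origin, spacing, dims, probe=probe_radius)
        eps_node = np.where(g < 0, solute_dielectric, solvent_dielectric)
        eps_far = solvent_dielectric

    # trilinear charge spreading
    rho = np.zeros(dims)
    frac = (xyz - origin) / spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    if np.any(base < 0) or np.any(base + 1 >= np.array(dims)):
        raise GridError("charge outside grid")
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                np.add.at(rho, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), w * q)

    phi = np.zeros(dims)
    if np.any(q):
        _boundary_potential(phi, origin, spacing, dims, xyz, q, eps_far)

        # link dielectrics (harmonic mean) along each axis
        def link(axis):
            sl1 = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl1[axis] = slice(0, -1)
            sl2[axis] = slice(1, None)
            e1 = eps_node[tuple(sl1)]
            e2 = eps_node[tuple(sl2)]
            return 2.0 * e1 * e2 / (e1 + e2)

        ex, ey, ez = link(0), link(1), link(2)

        interior = np.zeros(dims, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        idx3 = np.full(dims, -1, dtype=np.int64)
        ii = np.nonzero(interior)
        n_int = len(ii[0])
        idx3[ii] = np.arange(n_int)

        rows, cols, vals = [], [], []
        rhs = 4.0 * np.pi * COULOMB_CONSTANT * rho[ii] / spacing

        I, J, K = ii
        diag = np.zeros(n_int)
        for axis, e in ((0, ex), (1, ey), (2, ez)):
            for sgn in (-1, 1):
                nb = [I.copy(), J.copy(), K.copy()]
                nb[axis] = nb[axis] + sgn
                # link array e has size dims-1 along `axis`: the link toward
                # the -1 neighbor has index (node-1), toward +1 index (node)
                if sgn == -1:
                    le = [I.copy(), J.copy(), K.copy()]
                    le[axis] = le[axis] - 1
                    w = e[tuple(le)]
                else:
                    w = e[I, J, K]
                diag += w
                nb_interior = idx3[tuple(nb)]
                mask = nb_interior >= 0
                rows.append(np.arange(n_int)[mask])
                cols.append(nb_interior[mask])
                vals.append(-w[mask])
                # Dirichlet neighbors contribute to the RHS
                bmask = ~mask
                rhs[bmask] += w[bmask] * phi[tuple(n[bmask] for n in nb)]
        rows.append(np.arange(n_int))
        cols.append(np.arange(n_int))
        vals.append(diag)
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_int, n_int))
        M = sparse.diags(1.0 / diag)
        x0 = phi[ii]
        x, info = cg(A, rhs, x0=x0, rtol=tol, maxiter=maxiter, M=M)
        if info > 0:
            warnings.warn(f"PB solver did not fully converge (CG info={info})",
                          stacklevel=2)
        phi[ii] = x
        residual = float(np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-30))
    else:
        residual = 0.0

    return GridPotential(
        origin=np.asarray(origin, float), spacing=float(spacing), dims=dims,
        values=phi / KT_298_KCAL,
        solute_dielectric=solute_dielectric, solvent_dielectric=solvent_dielectric,
        probe_radius=probe_radius, grid_extension=extension, residual=residual,
        charges=q, positions=xyz)


def potential_at(grid: GridPotential, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the potential (kT/e) at Cartesian points."""
    pts = np.atleast_2d(np.asarray(points, float))
    frac = (pts - grid.origin) / grid.spacing
    base = np.floor(frac).astype(int)
    if np.any(base < 0) or np.any(base + 1 >= np.array(grid.dims)):
        raise GridError("point outside grid extent")
    t = frac - base
    out = np.zeros(len(pts))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                out += w * grid.values[base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz]
    return out


def solvation_energy(assembly: Assembly, spacing: float = 0.3, **kw) -> float:
    """Reaction-field (polar solvation) energy in kcal/mol.

    Two finite-difference solves on the identical grid - two-dielectric and
    uniform solute dielectric - so the grid self-energy cancels exactly:
    dG = 0.5 * sum q_i * (phi_solvated - phi_reference) at the charge sites.
    """
    solv = solve_potential(assembly, spacing=spacing, **kw)
    kw.pop("uniform_dielectric", None)
    vac = solve_potential(assembly, spacing=spacing,
                          uniform_dielectric=solv.solute_dielectric, **kw)
    phi_r = potential_at(solv, solv.positions) - potential_at(vac, vac.positions)
    return float(0.5 * np.sum(solv.charges * phi_r) * KT_298_KCAL)


def map_to_surface(
    grid: GridPotential,
    assembly: Assembly,
    radii=None,
    scale_bounds: tuple[float, float] = (-0.3, 0.3),
    mesh_spacing: float | None = None,
    view_label: str = "",
) -> SurfaceMap:
    """Triangulate the solvent-excluded surface and color it by potential.

    Raw per-vertex potentials are retained; clamping to the scale bounds
    happens only at render time (``SurfaceMap.clamped``).
    """
    xyz, _q, rad = _charges_radii(assembly, None, radii)
    h = mesh_spacing or min(grid.spacing, 0.5)
    origin, dims = _make_grid(xyz, rad, h, 2.0, grid.probe_radius)
    g = ses_field(xyz, rad, origin, h, dims, probe=grid.probe_radius)
    verts, faces, _n, _v = measure.marching_cubes(g, level=0.0, spacing=(h, h, h))
    verts = verts + origin
    pot = potential_at(grid, verts)
    return SurfaceMap(vertices=verts, faces=faces, vertex_potential=pot,
                      scale_bounds=scale_bounds, view_label=view_label)


def isopotential_surfaces(grid: GridPotential, levels=(-10.0, 10.0)) -> dict[float, SurfaceMap]:
    """Marching-cubes isopotential surface per level (kT/e).

    Levels outside the grid's value range yield an empty mesh with a warning.
    """
    out = {}
    vmin, vmax = float(grid.values.min()), float(grid.values.max())
    for level in levels:
        if not (vmin < level < vmax):
            warnings.warn(f"isopotential level {level} kT/e outside grid range "
                          f"[{vmin:.2f}, {vmax:.2f}]; empty mesh", stacklevel=2)
            out[level] = SurfaceMap(np.zeros((0, 3)), np.zeros((0, 3), int),
                                    np.zeros(0), view_label=f"{level} kT/e")
            continue
        verts, faces, _n, _v = measure.marching_cubes(
            grid.values, level=level,
            spacing=(grid.spacing, grid.spacing, grid.spacing))
        verts = verts + grid.origin
        out[level] = SurfaceMap(vertices=verts, faces=faces,
                                vertex_potential=np.full(len(verts), level),
                                view_label=f"{level} kT/e")
    return out


# ---- exchange formats -----------------------------------------------------

def write_dx(grid: GridPotential, path) -> None:
    """Export the potential grid in OpenDX scalar format (kT/e)."""
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin %.6f %.6f %.6f\n" % tuple(grid.origin))
        fh.write("delta %.6f 0.0 0.0\n" % grid.spacing)
        fh.write("delta 0.0 %.6f 0.0\n" % grid.spacing)
        fh.write("delta 0.0 0.0 %.6f\n" % grid.spacing)
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {nx*ny*nz} data follows\n")
        flat = grid.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join("%.6e" % v for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "potential (kT/e)" class field\n')


def write_ply(mesh: SurfaceMap, path) -> None:
    """Export a mesh with per-vertex potential as ASCII PLY."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float potential\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, p in zip(mesh.vertices, mesh.vertex_potential):
            fh.write("%.4f %.4f %.4f %.4f\n" % (v[0], v[1], v[2], p))
        for f in mesh.faces:
            fh.write("3 %d %d %d\n" % tuple(f))


def write_pqr(assembly: Assembly, path, charges=None, radii=None) -> None:
    """PQR export (charge + radius columns instead of occupancy/B)."""
    xyz, q, rad = _charges_radii(assembly, charges, radii)
    atoms = list(assembly.atoms())
    with open(path, "w") as fh:
        for i, (a, qq, rr) in enumerate(zip(atoms, q, rad), start=1):
            fh.write("ATOM  %5d %4s %-3s %1s%4d    %8.3f%8.3f%8.3f %7.4f %6.3f\n" % (
                i % 100000, a.name if len(a.name) == 4 else f" {a.name:<3s}",
                a.residue_name[:3], a.chain_id[:1] or "A", a.residue_number,
                a.coordinates[0], a.coordinates[1], a.coordinates[2], qq, rr))
        fh.write("END\n")


def read_pqr(path) -> Assembly:
    """Read a PQR file into an Assembly with explicit atom charges."""
    from .structure import AtomRecord, Protomer

    chains: dict[str, list[AtomRecord]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            tok = line.split()
            # whitespace-separated PQR (APBS convention)
            name, res, chain = tok[2], tok[3], tok[4]
            try:
                resnum = int(tok[5])
                x, y, z, q, r = (float(v) for v in tok[6:11])
            except (ValueError, IndexError):
                raise ValueError(f"malformed PQR line {ln}") from None
            chains.setdefault(chain, []).append(AtomRecord(
                serial=len(chains.get(chain, [])) + 1, name=name,
                element=name[0], residue_name=res, chain_id=chain,
                residue_number=resnum, insertion_code="",
                coordinates=np.array([x, y, z]), charge=q))
    protomers = [Protomer(cid, atoms) for cid, atoms in chains.items()]
    return Assembly(protomers, kind="protomer")
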