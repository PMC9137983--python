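"""Grid-based pocket detection, descriptors and druggability scores.

A fine rectangular grid is laid over the structure; a grid point is a *site
point* when it is sterically accessible (outside every van der Waals sphere
plus a 0.5 A probe offset), lies within 4 A of the protein, and is buried:
at least half of 110 quasi-uniform rays from the point must hit a protein
atom within 8 A.  Site points are grouped into sites by 26-neighbour grid
connectivity, small groups (< 15 points) are dropped, and each site gets a
descriptor block (volume, exposure, enclosure, contact, hydrophobic and
hydrophilic character, balance, donor/acceptor character, charged lining
fraction) plus the two druggability scores:

    SiteScore = 0.0733 * sqrt(min(n, 100)) + 0.6688 * e - 0.20  * min(p, 1)
    DScore    = 0.094  * sqrt(min(n, 100)) + 0.60   * e - 0.324 * p

where n is the site-point count, e the enclosure and p the hydrophilic score
(capped at 1 only inside SiteScore).  The square-root form of the site-point
term reproduces the published score scale (reference profile ~ 1.05 / 1.08,
ligandable/druggable threshold 0.8); the literal linear form is available via
``n_transform="linear"``.

The underlying per-point energetics of the original tool are proprietary;
this module uses a documented geometric surrogate (vdW exclusion, proximity,
ray-cast burial, Gaussian-kernel polarity counts) that preserves the ordering
properties the analysis relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from . import config
from .config import (CHARGED_RESIDUES, KERNEL_CUTOFF, KERNEL_SIGMA, N_RAYS,
                     PROBE_OFFSET, RAY_LENGTH)
from .structio import Structure
from .synthdata import SyntheticStructureSpec, _fibonacci_sphere


class SiteFindError(ValueError):
    pass


@dataclass(frozen=True)
class Grid:
    origin: np.ndarray          # (3,)
    spacing: float
    shape: tuple[int, int, int]

    def point(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.spacing


def build_grid(s: Structure, spacing: float = 0.35, margin: float = 6.0) -> Grid:
    """Axis-aligned grid enclosing all protein atoms plus a margin."""
    if spacing <= 0:
        raise SiteFindError("grid spacing must be positive")
    coords = s.coords
    if len(coords) == 0:
        raise SiteFindError("structure has no atoms")
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.floor((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return Grid(origin=lo, spacing=spacing, shape=shape)


_RAY_DIRS = _fibonacci_sphere(N_RAYS)


def burial_fraction(points: np.ndarray, coords: np.ndarray, radii: np.ndarray,
                    tree: cKDTree | None = None,
                    ray_length: float = RAY_LENGTH) -> np.ndarray:
    """Fraction of 110 quasi-uniform rays hitting an atom within ray_length.

    A ray from p along unit vector u hits an atom at c (radius r) when the
    segment of length ray_length passes within r of c at positive projection.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if tree is None:
        tree = cKDTree(coords)
    rmax = float(radii.max()) if len(radii) else 0.0
    out = np.zeros(len(points))
    neighbor_lists = tree.query_ball_point(points, ray_length + rmax)
    for k, (p, nb) in enumerate(zip(points, neighbor_lists)):
        if not nb:
            continue
        d = coords[nb] - p                      # (m, 3)
        r2 = radii[nb] ** 2                     # (m,)
        t = d @ _RAY_DIRS.T                     # (m, n_rays) projections
        perp2 = (d * d).sum(axis=1)[:, None] - t * t
        hit = (t > 0) & (t <= ray_length + radii[nb][:, None]) & (perp2 <= r2[:, None])
        out[k] = hit.any(axis=0).mean()
    return out


@dataclass
class SitePoints:
    """Accepted site points with their grid indices and burial values."""

    grid: Grid
    ijk: np.ndarray       # (m, 3) int
    coords: np.ndarray    # (m, 3)
    burial: np.ndarray    # (m,)


def find_site_points(s: Structure, g: Grid,
                     burial_min: float = 0.5) -> SitePoints:
    """Detect buried, accessible grid points adjacent to the surface."""
    coords = s.coords
    radii = s.vdw_radii
    nx, ny, nz = g.shape
    excluded = np.zeros(g.shape, bool)
    near = np.zeros(g.shape, bool)

    inv = 1.0 / g.spacing
    for c, r in zip(coords, radii):
        _mark_ball(excluded, g, c, r + PROBE_OFFSET, inv)
        _mark_ball(near, g, c, 4.0, inv)

    cand = near & ~excluded
    ijk = np.argwhere(cand)
    if len(ijk) == 0:
        return SitePoints(g, ijk, np.zeros((0, 3)), np.zeros(0))
    pts = g.origin + ijk * g.spacing
    tree = cKDTree(coords)
    burial = burial_fraction(pts, coords, radii, tree=tree)
    keep = burial >= burial_min
    return SitePoints(g, ijk[keep], pts[keep], burial[keep])


def _mark_ball(mask: np.ndarray, g: Grid, center: np.ndarray, radius: float,
               inv: float) -> None:
    lo = np.maximum(np.ceil((center - radius - g.origin) * inv).astype(int), 0)
    hi = np.minimum(np.floor((center + radius - g.origin) * inv).astype(int),
                    np.array(mask.shape) - 1)
    if np.any(lo > hi):
        return
    ax = [np.arange(lo[d], hi[d] + 1) * g.spacing + g.origin[d] - center[d]
          for d in range(3)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= d2 <= radius ** 2


# ---------------------------------------------------------------------------
# descriptors and scores


@dataclass
class SiteDescriptors:
    n: int
    volume: float
    exposure: float
    enclosure: float
    contact: float
    phobic: float
    philic: float
    balance: float
    donacc: float
    charged_fraction: float
    degenerate_exposure: bool = False

    @property
    def n_capped(self) -> int:
        return min(self.n, 100)

    @property
    def p_capped(self) -> float:
        return min(self.philic, 1.0)


@dataclass
class Site:
    points: np.ndarray                 # (n, 3) site-point coordinates
    descriptors: SiteDescriptors
    lining_residues: list[int]         # author residue numbers within 4 A
    sitescore: float
    dscore: float
    rank: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


#: Reference profile of the average submicromolar site (printed constants).
REFERENCE_PROFILE = {
    "n": 132,
    "sitescore": 1.0,   # threshold 0.8
    "dscore": 1.0,      # threshold 0.8
    "exposure": 0.49,
    "enclosure": 0.78,
    "contact": 1.0,
    "phobic": 1.0,
    "philic": 1.0,
    "balance": 1.6,
    "donacc": 0.76,
}


def site_score(d: SiteDescriptors, n_transform: str = "sqrt") -> float:
    """Ligandability: 0.0733*f(n) + 0.6688*e - 0.20*min(p, 1)."""
    n_term = _n_term(d.n, n_transform)
    return 0.0733 * n_term + 0.6688 * d.enclosure - 0.20 * d.p_capped


def d_score(d: SiteDescriptors, n_transform: str = "sqrt") -> float:
    """Druggability: 0.094*f(n) + 0.60*e - 0.324*p (p uncapped)."""
    n_term = _n_term(d.n, n_transform)
    return 0.094 * n_term + 0.60 * d.enclosure - 0.324 * d.philic


def _n_term(n: int, n_transform: str) -> float:
    capped = min(n, 100)
    if n_transform == "sqrt":
        return float(np.sqrt(capped))
    if n_transform == "linear":
        return float(capped)
    raise ValueError(f"unknown n_transform {n_transform!r}")


_APOLAR_ELEMENTS = {"C", "S"}
_POLAR_ELEMENTS = {"N", "O"}


def _atom_polarity(s: Structure) -> np.ndarray:
    """+1 polar, -1 apolar per protein atom; C/S bonded to N/O count polar.

    Without connectivity records, "bonded" is approximated as an N/O atom of
    the same residue within 1.8 A.
    """
    flags = []
    for ri, res_atoms in _atoms_by_residue(s):
        polar_coords = np.array([a.coord for a in res_atoms
                                 if a.element.upper() in _POLAR_ELEMENTS]).reshape(-1, 3)
        for a in res_atoms:
            el = a.element.upper()
            if el in _POLAR_ELEMENTS:
                flags.append(1)
            elif el in _APOLAR_ELEMENTS:
                close = (len(polar_coords) and
                         np.min(np.linalg.norm(polar_coords - a.coord, axis=1)) < 1.8)
                flags.append(1 if close else -1)
            else:
                flags.append(-1)
    return np.array(flags)


def _atoms_by_residue(s: Structure):
    for ri, res in enumerate(s.residues):
        yield ri, res.atoms
    if s.cofactor_atoms:
        yield -1, s.cofactor_atoms


def compute_descriptors(points: np.ndarray, burial: np.ndarray, s: Structure,
                        spacing: float,
                        lining_cutoff: float = 4.0) -> tuple[SiteDescriptors, list[int]]:
    """Descriptor block for one site; returns (descriptors, lining residues)."""
    n = len(points)
    coords = s.coords
    radii = s.vdw_radii
    res_index = s.atom_residue_index
    elements = np.array(s.elements)
    tree = cKDTree(coords)

    volume = n * spacing ** 3
    enclosure = float(burial.mean())

    # exposure: open-ray fraction in the hemisphere of the principal opening
    exposure, degenerate = _exposure(points, coords, radii, tree)

    # proximity-weighted descriptor sums with a Gaussian kernel
    polarity = _atom_polarity(s)
    contact_raw = phobic_raw = philic_raw = don_raw = acc_raw = 0.0
    neighbor_lists = tree.query_ball_point(points, KERNEL_CUTOFF)
    for p, nb in zip(points, neighbor_lists):
        if not nb:
            continue
        nb = np.asarray(nb)
        dist = np.linalg.norm(coords[nb] - p, axis=1)
        w = np.exp(-(dist ** 2) / (2.0 * KERNEL_SIGMA ** 2))
        contact_raw += w.sum()
        phobic_raw += w[polarity[nb] < 0].sum()
        philic_raw += w[polarity[nb] > 0].sum()
        don_raw += w[elements[nb] == "N"].sum()   # protein N: donor-like
        acc_raw += w[elements[nb] == "O"].sum()   # protein O: acceptor-like
    contact = contact_raw / n / config.CONTACT_CAL
    phobic = phobic_raw / n / config.PHOBIC_CAL
    philic = philic_raw / n / config.PHILIC_CAL
    balance = config.BALANCE_CAL * (philic / phobic) if phobic > 1e-9 else float("inf")
    donacc = acc_raw / don_raw if don_raw > 1e-9 else float("inf")

    lining = sorted({int(res_index[i]) for nb in tree.query_ball_point(points, lining_cutoff)
                     for i in nb if res_index[i] >= 0})
    lining_numbers = [s.residues[i].number for i in lining]
    charged = [i for i in lining if s.residues[i].name in CHARGED_RESIDUES]
    charged_fraction = len(charged) / len(lining) if lining else 0.0

    desc = SiteDescriptors(
        n=n, volume=volume, exposure=exposure, enclosure=enclosure,
        contact=contact, phobic=phobic, philic=philic, balance=balance,
        donacc=donacc, charged_fraction=charged_fraction,
        degenerate_exposure=degenerate)
    return desc, lining_numbers


def _exposure(points: np.ndarray, coords: np.ndarray, radii: np.ndarray,
              tree: cKDTree) -> tuple[float, bool]:
    """Mean open-ray fraction restricted to the hemisphere of the opening."""
    # per-point open-ray mask
    rmax = float(radii.max()) if len(radii) else 0.0
    open_dirs = np.zeros(3)
    open_masks = []
    neighbor_lists = tree.query_ball_point(points, RAY_LENGTH + rmax)
    for p, nb in zip(points, neighbor_lists):
        if not nb:
            open_masks.append(np.ones(N_RAYS, bool))
            open_dirs += _RAY_DIRS.sum(axis=0)
            continue
        d = coords[nb] - p
        r2 = radii[nb] ** 2
        t = d @ _RAY_DIRS.T
        perp2 = (d * d).sum(axis=1)[:, None] - t * t
        hit = (t > 0) & (t <= RAY_LENGTH + radii[nb][:, None]) & (perp2 <= r2[:, None])
        mask = ~hit.any(axis=0)
        open_masks.append(mask)
        open_dirs += _RAY_DIRS[mask].sum(axis=0)
    norm = np.linalg.norm(open_dirs)
    degenerate = bool(norm < 1e-9)
    if degenerate:
        # fully enclosed or symmetric: no principal opening
        frac = float(np.mean([m.mean() for m in open_masks]))
        return frac, True
    axis = open_dirs / norm
    upper = _RAY_DIRS @ axis > 0
    vals = [m[upper].mean() for m in open_masks]
    return float(np.mean(vals)), False


# ---------------------------------------------------------------------------
# site clustering


def cluster_site_points(sp: SitePoints, s: Structure, min_points: int = 15,
                        max_sites: int = 10, lining_cutoff: float = 4.0,
                        n_transform: str = "sqrt") -> list[Site]:
    """Group site points into ranked sites.

    Connected components under 26-neighbour grid adjacency; components below
    ``min_points`` are dropped; points 4 A or farther from every other point
    of their site are truncated (isolated satellites); the survivors are
    scored and ranked by SiteScore (ties: larger n, then lexicographic
    centroid), and at most ``max_sites`` are returned.
    """
    if len(sp.ijk) == 0:
        warnings.warn("no site points survive; returning no sites")
        return []
    occ = np.zeros(sp.grid.shape, np.int32)
    occ[sp.ijk[:, 0], sp.ijk[:, 1], sp.ijk[:, 2]] = 1
    labeled, n_comp = ndimage.label(occ, structure=np.ones((3, 3, 3), int))
    comp_of_point = labeled[sp.ijk[:, 0], sp.ijk[:, 1], sp.ijk[:, 2]]

    sites: list[Site] = []
    for comp in range(1, n_comp + 1):
        idx = np.nonzero(comp_of_point == comp)[0]
        pts, burial = sp.coords[idx], sp.burial[idx]
        # truncate satellites >= 4 A from every other point of the site
        if len(pts) > 1:
            ptree = cKDTree(pts)
            dd, _ = ptree.query(pts, k=2)
            keep = dd[:, 1] < 4.0
            pts, burial = pts[keep], burial[keep]
        if len(pts) < min_points:
            continue
        desc, lining = compute_descriptors(pts, burial, s, sp.grid.spacing,
                                           lining_cutoff)
        ss = site_score(desc, n_transform)
        ds = d_score(desc, n_transform)
        sites.append(Site(pts, desc, lining, ss, ds))

    if not sites:
        warnings.warn("no site with enough site points; returning no sites")
        return []
    sites.sort(key=lambda st: (-st.sitescore, -st.descriptors.n,
                               tuple(np.round(st.centroid, 6))))
    sites = sites[:max_sites]
    for r, st in enumerate(sites, start=1):
        st.rank = r
    return sites


def find_sites(s: Structure, spacing: float = 0.35, margin: float = 6.0,
               burial_min: float = 0.5, min_points: int = 15,
               max_sites: int = 10, lining_cutoff: float = 4.0,
               n_transform: str = "sqrt") -> list[Site]:
    """Full detection pipeline: grid, site points, clustering, scoring."""
    g = build_grid(s, spacing, margin)
    sp = find_site_points(s, g, burial_min)
    return cluster_site_points(sp, s, min_points, max_sites, lining_cutoff,
                               n_transform)


def reference_pocket_spec(seed: int = 20) -> SyntheticStructureSpec:
    """The packaged reference pocket used to freeze calibration constants.

    An enclosed, mixed-lining cavity emulating an average submicromolar site:
    mostly hydrophobic lining with a polar component, a modest mouth opening
    and no formal charge concentration.
    """
    return SyntheticStructureSpec(
        shell_radius=13.0, cavity_radius=4.5, mouth_fraction=0.15,
        lining_composition={"hydrophobic": 0.55, "polar": 0.30, "charged": 0.15},
        residue_count=110, plant_ligand=False, seed=seed)


def sites_to_frame(sites: list[Site]):
    """Per-site descriptor table (one row per reported site)."""
    import pandas as pd

    rows = []
    for st in sites:
        d = st.descriptors
        rows.append({
            "rank": st.rank, "n_points": d.n, "volume": d.volume,
            "exposure": d.exposure, "enclosure": d.enclosure,
            "contact": d.contact, "phobic": d.phobic, "philic": d.philic,
            "balance": d.balance, "donacc": d.donacc,
            "charged_fraction": d.charged_fraction,
            "sitescore": st.sitescore, "dscore": st.dscore,
            "lining_residues": ";".join(str(n) for n in st.lining_residues),
        })
    return pd.DataFrame(rows)
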