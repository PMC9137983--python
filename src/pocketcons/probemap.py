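"""Fragment-probe hotspot mapping and consensus-cluster ranking.

A deliberately simplified stand-in for FFT-docking probe mapping: each of the
16 classic organic probes is a single sphere with a typed polar/apolar
character, placed on a 2 A surface lattice and scored by a geometric
interaction surrogate (lower = better): a contact reward, a hydrogen-bond
complementarity reward between probe donors/acceptors and nearby protein
acceptors/donors, a desolvation penalty for apolar probes in polar
surroundings, and an infinite clash penalty inside the van der Waals volume.
Favourable poses are clustered greedily and the clusters ranked by the total
number of nonbonded protein contacts of their member poses — the consensus
ranking convention — from which the top three predicted binding sites with
4 A lining residues are derived.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .config import PROBE_OFFSET
from .structio import Structure

CONTACT_CUTOFF = 4.5   # A, "nonbonded contact" heavy-atom distance
CLUSTER_RADIUS = 3.0   # A, greedy pose clustering
MERGE_RADIUS = 5.0     # A, merging clusters into predicted sites


@dataclass(frozen=True)
class ProbeType:
    name: str
    radius: float       # effective single-sphere radius, A
    donors: int
    acceptors: int
    apolar: bool


#: The 16 probe molecules used by the classic mapping servers.
PROBES: tuple[ProbeType, ...] = (
    ProbeType("acetamide", 2.3, 2, 1, False),
    ProbeType("acetonitrile", 2.1, 0, 1, False),
    ProbeType("acetone", 2.3, 0, 1, False),
    ProbeType("acetaldehyde", 2.1, 0, 1, False),
    ProbeType("methylamine", 2.0, 2, 1, False),
    ProbeType("benzaldehyde", 2.9, 0, 1, False),
    ProbeType("benzene", 2.7, 0, 0, True),
    ProbeType("isobutanol", 2.6, 1, 1, False),
    ProbeType("cyclohexane", 2.9, 0, 0, True),
    ProbeType("N,N-dimethylformamide", 2.5, 0, 1, False),
    ProbeType("dimethyl ether", 2.2, 0, 1, False),
    ProbeType("ethanol", 2.2, 1, 1, False),
    ProbeType("ethane", 2.2, 0, 0, True),
    ProbeType("phenol", 2.8, 1, 1, False),
    ProbeType("isopropanol", 2.4, 1, 1, False),
    ProbeType("urea", 2.3, 4, 1, False),
)


def probe_library() -> list[ProbeType]:
    """The 16-probe library (distinct names, fixed parameters)."""
    return list(PROBES)


@dataclass
class ProbePose:
    probe: str
    center: np.ndarray
    score: float          # lower = better
    contacts: int         # protein heavy atoms within 4.5 A


class ProbeMapError(ValueError):
    pass


def _surface_lattice(s: Structure, spacing: float = 2.0) -> np.ndarray:
    """Grid points outside the vdW volume but within 4 A of some atom."""
    coords = s.coords
    radii = s.vdw_radii
    lo = coords.min(axis=0) - 4.0
    hi = coords.max(axis=0) + 4.0
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(coords)
    dist, idx = tree.query(pts)
    outside = dist > radii[idx]            # outside every vdW sphere (nearest test)
    near = dist <= 4.0 + radii[idx]
    cand = pts[outside & near]
    # exact clash re-check against all neighbours, not just the nearest atom
    keep = []
    for p, nb in zip(cand, tree.query_ball_point(cand, radii.max() + 0.01)):
        if all(np.linalg.norm(coords[i] - p) > radii[i] for i in nb):
            keep.append(p)
    return np.array(keep).reshape(-1, 3)


def map_probes(s: Structure, probes: list[ProbeType] | None = None,
               keep_per_probe: int = 50, seed: int = 0) -> list[ProbePose]:
    """Score each probe over the surface lattice; keep the best poses.

    Deterministic for a fixed structure (the seed is accepted for interface
    symmetry with the stochastic stages; scoring itself is exact).
    """
    probes = probes if probes is not None else probe_library()
    coords = s.coords
    if len(coords) == 0:
        raise ProbeMapError("structure has no atoms")
    radii = s.vdw_radii
    elements = np.array(s.elements)
    pts = _surface_lattice(s)
    if len(pts) == 0:
        raise ProbeMapError("no surface lattice points found")
    tree = cKDTree(coords)

    is_n = elements == "N"
    is_o = elements == "O"
    is_apolar = ~(is_n | is_o)

    poses: list[ProbePose] = []
    neighbor_lists = tree.query_ball_point(pts, 6.0)
    contact_counts = np.array(
        [sum(1 for i in nb if np.linalg.norm(coords[i] - pts[k]) <= CONTACT_CUTOFF)
         for k, nb in enumerate(neighbor_lists)])
    for probe in probes:
        scores = np.full(len(pts), np.inf)
        for k, nb in enumerate(neighbor_lists):
            if not nb:
                continue
            nb = np.asarray(nb)
            dist = np.linalg.norm(coords[nb] - pts[k], axis=1)
            if np.any(dist < radii[nb] + 0.5 * probe.radius):
                continue  # clash: probe sphere overlaps vdW volume
            w = np.exp(-(dist ** 2) / (2.0 * 2.5 ** 2))
            apolar_env = w[is_apolar[nb]].sum()
            don_env = w[is_n[nb]].sum()
            acc_env = w[is_o[nb]].sum()
            polar_env = don_env + acc_env
            e = -1.0 * apolar_env
            e -= 0.8 * (probe.donors * acc_env + probe.acceptors * don_env)
            if probe.apolar:
                e += 0.5 * polar_env   # desolvation penalty in polar patches
            scores[k] = e
        order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], scores))
        for k in order[:keep_per_probe]:
            if not np.isfinite(scores[k]):
                break
            poses.append(ProbePose(probe.name, pts[k].copy(),
                                   float(scores[k]), int(contact_counts[k])))
    return poses


@dataclass
class ConsensusCluster:
    poses: list[ProbePose]
    rank: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([p.center for p in self.poses], axis=0)

    @property
    def total_contacts(self) -> int:
        return sum(p.contacts for p in self.poses)

    @property
    def probe_types(self) -> set[str]:
        return {p.probe for p in self.poses}


def cluster_poses(poses: list[ProbePose],
                  radius: float = CLUSTER_RADIUS) -> list[ConsensusCluster]:
    """Greedy centroid clustering, ranked by total nonbonded contacts.

    The best-scoring unassigned pose seeds each cluster and captures every
    pose within ``radius`` of it.  Clusters are ranked by total contacts
    (descending), ties broken by the number of distinct probe types then the
    lexicographically smallest centroid — a total order.
    """
    if not poses:
        raise ProbeMapError("no poses to cluster")
    order = sorted(range(len(poses)),
                   key=lambda i: (poses[i].score, tuple(np.round(poses[i].center, 6))))
    unassigned = set(order)
    clusters: list[ConsensusCluster] = []
    for i in order:
        if i not in unassigned:
            continue
        seed_pose = poses[i]
        members = [j for j in order
                   if j in unassigned
                   and np.linalg.norm(poses[j].center - seed_pose.center) <= radius]
        unassigned -= set(members)
        clusters.append(ConsensusCluster([poses[j] for j in members]))
    clusters.sort(key=lambda c: (-c.total_contacts, -len(c.probe_types),
                                 tuple(np.round(c.centroid, 6))))
    for r, c in enumerate(clusters, start=1):
        c.rank = r
    return clusters


@dataclass
class PredictedSite:
    clusters: list[ConsensusCluster]
    lining_residues: list[int]
    rank: int = 0

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([p.center for c in self.clusters for p in c.poses], axis=0)

    @property
    def total_contacts(self) -> int:
        return sum(c.total_contacts for c in self.clusters)


def predict_binding_sites(clusters: list[ConsensusCluster], s: Structure,
                          n_sites: int = 3,
                          lining_cutoff: float = 4.0) -> list[PredictedSite]:
    """Top-ranked consensus clusters as predicted binding sites.

    Clusters whose centroids lie within 5 A are merged first; the top
    ``n_sites`` merged groups (by total contacts) are returned, each with the
    residues within ``lining_cutoff`` of any member pose.
    """
    if not clusters:
        raise ProbeMapError("no clusters supplied")
    # union-find merge on centroid proximity
    parents = list(range(len(clusters)))

    def find(i):
        while parents[i] != i:
            parents[i] = parents[parents[i]]
            i = parents[i]
        return i

    cents = [c.centroid for c in clusters]
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if np.linalg.norm(cents[i] - cents[j]) <= MERGE_RADIUS:
                parents[find(j)] = find(i)
    groups: dict[int, list[ConsensusCluster]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(find(i), []).append(c)

    merged = [PredictedSite(g, []) for g in groups.values()]
    merged.sort(key=lambda m: (-m.total_contacts,
                               tuple(np.round(m.centroid, 6))))
    if len(merged) < n_sites:
        warnings.warn(f"only {len(merged)} candidate sites available "
                      f"(requested {n_sites})")
    merged = merged[:n_sites]

    coords = s.coords
    res_index = s.atom_residue_index
    tree = cKDTree(coords)
    for r, m in enumerate(merged, start=1):
        m.rank = r
        pose_centers = np.array([p.center for c in m.clusters for p in c.poses])
        hit = sorted({int(res_index[i])
                      for nb in tree.query_ball_point(pose_centers, lining_cutoff)
                      for i in nb if res_index[i] >= 0})
        m.lining_residues = [s.residues[i].number for i in hit]
    return merged


def clusters_to_frame(clusters: list[ConsensusCluster]):
    import pandas as pd

    rows = []
    for c in clusters:
        cx, cy, cz = c.centroid
        rows.append({"rank": c.rank, "total_contacts": c.total_contacts,
                     "n_poses": len(c.poses),
                     "n_probe_types": len(c.probe_types),
                     "centroid_x": cx, "centroid_y": cy, "centroid_z": cz,
                     "probes": ";".join(sorted(c.probe_types))})
    return pd.DataFrame(rows)
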