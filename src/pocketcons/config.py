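"""Default parameters and physical constants for the pocket analysis pipeline.

All thresholds used by the combined conservation x druggability filter live
here so that a run manifest can record them and a YAML config can override
them. The druggability-score defaults mirror the published SiteMap-style
protocol: 0.35 A grid, at least 15 site points per reported site, at most 10
sites, 4 A lining cutoff, 0.8 score thresholds, 50% conserved-residue
threshold and the 26.3% charged-residue flag (Perola).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Bondi van der Waals radii (A) by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "MG": 1.73,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
VDW_DEFAULT = 1.70

#: Probe offset added to vdW radii when deciding whether a grid point is
#: sterically accessible (A).
PROBE_OFFSET = 0.5

#: Ray casting: number of quasi-uniform directions and maximum ray length (A)
#: used for the burial (enclosure) estimate.
N_RAYS = 110
RAY_LENGTH = 8.0

#: Charged residues at pH 7 (histidine excluded).
CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG"})

#: Calibration constants for the dimensionless descriptor scales.  Frozen once
#: from the packaged reference-pocket fixture (see sitefind.reference_pocket_spec)
#: so that a typical enclosed, mixed-lining submicromolar-like cavity lands near
#: the reference profile (contact 1.0, phobic 1.0, philic 1.0, balance 1.6).
CONTACT_CAL = 11.36
PHOBIC_CAL = 5.77
PHILIC_CAL = 5.60
BALANCE_CAL = 1.6

#: Gaussian proximity kernel width (A) for contact/polarity descriptors.
KERNEL_SIGMA = 2.5
KERNEL_CUTOFF = 8.0


@dataclass
class Thresholds:
    """Decision thresholds of the combined filter and detection stage."""

    sitescore: float = 0.8      # ligandability threshold
    dscore: float = 0.8         # druggability threshold
    conserved: float = 0.5      # fraction of lining residues at grade >= 8
    charged: float = 0.263      # Perola charged-residue flag (strictly greater)
    conserved_grade: int = 8    # "conserved" means grade in {8, 9}
    min_points: int = 15        # minimum site points per reported site
    max_sites: int = 10         # report at most this many sites
    lining_cutoff: float = 4.0  # A, residue-to-site-point lining distance
    burial_min: float = 0.5     # minimum ray-cast burial for a site point
    spacing: float = 0.35       # A, production grid spacing
    margin: float = 6.0         # A, grid margin around the structure
    kmeans_k: int = 6           # representative conformational clusters
    n_transform: str = "sqrt"   # site-point term in Eq scores: "sqrt" | "linear"

    def as_dict(self) -> dict:
        return asdict(self)


#: Grid spacing used by the test suite and synthetic end-to-end runs (A).
#: Coarser than the production 0.35 A default purely for desk-scale runtime.
TEST_SPACING = 0.7

DEFAULT_THRESHOLDS = Thresholds()
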