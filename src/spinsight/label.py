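"""Accessible-volume modeling of the MTSL (R1) nitroxide side chain.

A labeled site is modeled by attaching an idealized MTSL-cysteine adduct at
the residue's CB, sampling the five linker dihedrals uniformly and rejecting
conformers whose heavy atoms clash with the protein.  The paramagnetic
center of each conformer is the midpoint of the nitroxide N–O bond; distance
predictions to nuclei use the ensemble-average center position, and
inter-label distance distributions are smoothed histograms over all pairs of
center positions of two ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .distributions import DistanceDistribution, default_r_grid
from .errors import BuriedSiteError, EmptySelectionError, GridRangeError
from .structure import Structure, substitute_to_cys

# ---------------------------------------------------------------------------
# Idealized R1 side-chain template.
#
# Linker atoms are placed by internal coordinates (bond Å, angle deg) from
# the residue backbone; the five dihedrals chi1..chi5 are the sampled degrees
# of freedom.  The pyrroline-N-oxyl ring (with its four methyl carbons) is a
# rigid body attached at the sp2 ring carbon C3, stored in a local frame with
# C3 at the origin, C4 along +x and the ring in the xy plane.
# ---------------------------------------------------------------------------

#: (name, element, bond length to previous atom Å, bond angle deg)
_CHAIN_GEOMETRY = [
    ("SG", "S", 1.81, 114.0),  # chi1 = N-CA-CB-SG
    ("SD", "S", 2.03, 104.0),  # chi2 = CA-CB-SG-SD
    ("CE", "C", 1.81, 104.0),  # chi3 = CB-SG-SD-CE
    ("C3", "C", 1.50, 114.0),  # chi4 = SG-SD-CE-C3
    ("C4", "C", 1.34, 126.0),  # chi5 = SD-CE-C3-C4
]

#: Ring-body atoms in the C3 local frame (name, element, x, y, z), Å.
_RING_TEMPLATE = [
    ("C5", "C", 1.9057, 1.4000, 0.0000),
    ("N1", "N", 0.6869, 2.2397, 0.0000),
    ("O1", "O", 0.6966, 3.5197, 0.0000),
    ("C2", "C", -0.5447, 1.4190, 0.0000),
    ("C6", "C", -1.3186, 1.6655, 1.2848),
    ("C7", "C", -1.3186, 1.6655, -1.2848),
    ("C8", "C", 2.6826, 1.6334, 1.2854),
    ("C9", "C", 2.6826, 1.6334, -1.2854),
]

LABEL_ATOM_NAMES = [name for name, *_ in _CHAIN_GEOMETRY] + [name for name, *_ in _RING_TEMPLATE]

#: Default clash criterion: label heavy atom within this distance (Å) of any
#: protein heavy atom (outside the labeled residue) rejects the conformer.
DEFAULT_CLASH_TOLERANCE = 2.5

#: Attempt budget multiplier: up to this many times n dihedral draws.
ATTEMPT_FACTOR = 50


@dataclass(frozen=True)
class LabelSite:
    chain: str
    residue_number: int

    def __str__(self) -> str:
        return f"{self.chain}:{self.residue_number}"


@dataclass(frozen=True)
class LabelConformer:
    """One clash-free placement of the R1 side chain."""

    atom_names: tuple[str, ...]
    atom_positions: np.ndarray  # (n_atoms, 3), Å
    no_midpoint: np.ndarray  # midpoint of the nitroxide N-O bond, Å

    def position_of(self, name: str) -> np.ndarray:
        return self.atom_positions[self.atom_names.index(name)]


@dataclass
class RotamerEnsemble:
    site: LabelSite
    conformers: list[LabelConformer]
    n_requested: int
    seed: int
    n_attempted: int

    def __len__(self) -> int:
        return len(self.conformers)

    def midpoints(self) -> np.ndarray:
        return np.array([c.no_midpoint for c in self.conformers])


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d), dihedral(a,b,c,d)."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [-bond * np.cos(ang), bond * np.sin(ang) * np.cos(dih), bond * np.sin(ang) * np.sin(dih)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_conformer(
    n_pos: np.ndarray, ca_pos: np.ndarray, cb_pos: np.ndarray, dihedrals: np.ndarray
) -> LabelConformer:
    """Construct the R1 side chain at a residue for given chi1..chi5 (degrees)."""
    dihedrals = np.asarray(dihedrals, dtype=float)
    if dihedrals.shape != (5,):
        raise ValueError("exactly five dihedrals chi1..chi5 are required")
    frame = [n_pos, ca_pos, cb_pos]
    names: list[str] = []
    positions: list[np.ndarray] = []
    for (name, _elem, bond, angle), chi in zip(_CHAIN_GEOMETRY, dihedrals):
        pos = _place_atom(frame[-3], frame[-2], frame[-1], bond, angle, chi)
        names.append(name)
        positions.append(pos)
        frame.append(pos)
    ce, c3, c4 = positions[2], positions[3], positions[4]
    # ring frame: x along C3->C4, ring plane through CE,C3,C4, +y opposite CE
    x_hat = (c4 - c3) / np.linalg.norm(c4 - c3)
    v = (ce - c3) / np.linalg.norm(ce - c3)
    y0 = v - np.dot(v, x_hat) * x_hat
    y_hat = -y0 / np.linalg.norm(y0)
    z_hat = np.cross(x_hat, y_hat)
    for name, _elem, tx, ty, tz in _RING_TEMPLATE:
        names.append(name)
        positions.append(c3 + tx * x_hat + ty * y_hat + tz * z_hat)
    pos_arr = np.array(positions)
    n1 = pos_arr[names.index("N1")]
    o1 = pos_arr[names.index("O1")]
    return LabelConformer(
        atom_names=tuple(names), atom_positions=pos_arr, no_midpoint=0.5 * (n1 + o1)
    )


def generate_ensemble(
    structure: Structure,
    site: LabelSite | tuple[str, int],
    n: int = 200,
    seed: int = 0,
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE,
) -> RotamerEnsemble:
    """Sample up to ``n`` clash-free R1 conformers at a site.

    The site residue is substituted to Cys first (a no-op when it already
    is one).  chi1..chi5 are drawn uniformly on [0, 360); a conformer is
    rejected when any of its heavy atoms lies within ``clash_tolerance`` Å of
    a protein heavy atom outside the labeled residue.  Sampling is a single
    seeded stream, so rerunning with a larger ``n`` extends the ensemble
    without changing the conformers already accepted (prefix property).
    """
    if not isinstance(site, LabelSite):
        site = LabelSite(*site)
    if n < 1:
        raise ValueError("n must be >= 1")
    structure = substitute_to_cys(structure, site.chain, site.residue_number)
    res_key = (site.chain, site.residue_number)
    n_pos = structure.atom(site.chain, site.residue_number, "N").position
    ca_pos = structure.atom(site.chain, site.residue_number, "CA").position
    cb_pos = structure.atom(site.chain, site.residue_number, "CB").position
    env = structure.heavy_positions(exclude_residue=res_key)
    tree = cKDTree(env) if len(env) else None

    rng = np.random.default_rng(seed)
    conformers: list[LabelConformer] = []
    attempts = 0
    budget = ATTEMPT_FACTOR * n
    while attempts < budget and len(conformers) < n:
        chi = rng.uniform(0.0, 360.0, size=5)
        attempts += 1
        conf = build_conformer(n_pos, ca_pos, cb_pos, chi)
        if tree is not None:
            dmin, _ = tree.query(conf.atom_positions, k=1)
            if np.min(dmin) < clash_tolerance:
                continue
        conformers.append(conf)
    if not conformers:
        raise BuriedSiteError(
            f"site {site}: no clash-free conformer in {attempts} attempts "
            f"(clash tolerance {clash_tolerance} Å); site appears buried"
        )
    return RotamerEnsemble(
        site=site, conformers=conformers, n_requested=n, seed=seed, n_attempted=attempts
    )


def mean_label_position(ensemble: RotamerEnsemble) -> np.ndarray:
    """Unweighted mean of the conformer N–O midpoints (Å)."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    return ensemble.midpoints().mean(axis=0)


def label_to_atom_distances(
    ensemble: RotamerEnsemble,
    structure: Structure,
    residue_name: str | None = "ILE",
    atom_name: str = "CD1",
) -> pd.DataFrame:
    """Distances (Å) from the mean paramagnetic-center position to selected atoms.

    One row per matched atom, sorted by residue number.  The default selector
    targets isoleucine delta-1 carbons, the reporter nuclei of methyl-labeled
    samples.
    """
    center = mean_label_position(ensemble)
    rows = []
    for a in structure.atoms:
        if residue_name is not None and a.residue_name != residue_name.upper():
            continue
        if a.name != atom_name.upper():
            continue
        rows.append(
            {
                "chain": a.chain,
                "residue_number": a.residue_number,
                "residue_name": a.residue_name,
                "distance_A": float(np.linalg.norm(a.position - center)),
            }
        )
    if not rows:
        raise EmptySelectionError(
            f"selector {residue_name}:{atom_name} matched no atom in "
            f"{structure.identifier or 'structure'}"
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["chain", "residue_number"])
        .reset_index(drop=True)
    )


def interlabel_distribution(
    ens_a: RotamerEnsemble,
    ens_b: RotamerEnsemble,
    r_grid: np.ndarray | None = None,
    smoothing_nm: float = 0.05,
) -> DistanceDistribution:
    """Normalized, Gaussian-smoothed histogram of all pairwise center distances.

    Distances are midpoint-to-midpoint over the Cartesian product of the two
    ensembles, in nm; the histogram on ``r_grid`` (default 1–10 nm, 0.02 nm
    step) is smoothed with a Gaussian kernel of ``smoothing_nm``.
    """
    if len(ens_a) == 0 or len(ens_b) == 0:
        raise ValueError("both ensembles must be non-empty")
    if r_grid is None:
        r_grid = default_r_grid()
    r_grid = np.asarray(r_grid, dtype=float)
    d_nm = cdist(ens_a.midpoints(), ens_b.midpoints()).ravel() / 10.0
    step = float(np.mean(np.diff(r_grid)))
    if d_nm.min() < r_grid[0] - step / 2 or d_nm.max() > r_grid[-1] + step / 2:
        raise GridRangeError(
            f"pairwise distances span {d_nm.min():.2f}–{d_nm.max():.2f} nm, "
            f"outside the grid {r_grid[0]:.2f}–{r_grid[-1]:.2f} nm"
        )
    edges = np.concatenate(([r_grid[0] - step / 2], r_grid + step / 2))
    counts, _ = np.histogram(d_nm, bins=edges)
    p = gaussian_filter1d(counts.astype(float), sigma=smoothing_nm / step)
    return DistanceDistribution(
        r=r_grid,
        p=p,
        metadata={
            "site_a": str(ens_a.site),
            "site_b": str(ens_b.site),
            "n_pairs": int(d_nm.size),
            "mean_pairwise_nm": float(d_nm.mean()),
        },
    )
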