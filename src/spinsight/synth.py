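"""Seeded synthetic-data generators for every analysis stage.

These generators produce inputs with the statistical structure the analysis
stages assume — toy structures with known geometry, dipolar traces from a
known P(r), paired para/diamagnetic intensity tables from an r^-6
attenuation model, and spin-lock decay series with or without fast two-site
exchange — so the full pipeline is testable without any external data.
Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from . import deer
from .distributions import DistanceDistribution, default_r_grid
from .label import LabelSite, _place_atom
from .pre import IntensityTable
from .dispersion import SpinLockSeries, _exchange_model
from .structure import Atom, Structure

# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

_HELIX_PHI = -57.0
_HELIX_PSI = -47.0
_BB = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.0,
    "ang_ca_c_n": 116.6,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
    "ca_cb": 1.53,
    "ang_n_ca_cb": 110.5,
}


@dataclass
class ToyStructure:
    """A generated structure plus its designated label sites."""

    structure: Structure
    sites: list[LabelSite]
    meta: dict = field(default_factory=dict)


def _build_helix(
    n_res: int,
    chain: str = "A",
    first_residue: int = 1,
    resname: str = "ALA",
) -> list[Atom]:
    """Ideal poly-Ala alpha helix (phi -57, psi -47) with N, CA, C, O, CB."""
    atoms: list[Atom] = []
    serial = 0

    def add(name, elem, pos, resnum):
        nonlocal serial
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                residue_name=resname,
                chain=chain,
                residue_number=resnum,
                position=np.asarray(pos, float),
                element=elem,
            )
        )

    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(_BB["ang_n_ca_c"])
    c = ca + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = []
    for i in range(n_res):
        if i > 0:
            n = _place_atom(*backbone[-1], _BB["c_n"], _BB["ang_ca_c_n"], _HELIX_PSI)
            ca = _place_atom(backbone[-1][1], backbone[-1][2], n, _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
            c = _place_atom(backbone[-1][2], n, ca, _BB["ca_c"], _BB["ang_n_ca_c"], _HELIX_PHI)
        backbone.append((n, ca, c))
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        resnum = first_residue + i
        add("N", "N", n_i, resnum)
        add("CA", "C", ca_i, resnum)
        add("C", "C", c_i, resnum)
        o = _place_atom(n_i, ca_i, c_i, _BB["c_o"], _BB["ang_ca_c_o"], _HELIX_PSI + 180.0)
        add("O", "O", o, resnum)
        cb = _place_atom(c_i, n_i, ca_i, _BB["ca_cb"], _BB["ang_n_ca_cb"], -120.0)
        add("CB", "C", cb, resnum)
    return atoms


def _renumber(atoms: list[Atom]) -> list[Atom]:
    from dataclasses import replace

    return [replace(a, serial=i + 1) for i, a in enumerate(atoms)]


def _fibonacci_sphere(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(1.0 - z**2)
    theta = golden * i
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return center + radius * pts


def make_toy_structure(kind: str, seed: int = 0, **params) -> ToyStructure:
    """Generate an idealized test structure with known geometry.

    Kinds:

    ``exposed-helix``
        One isolated helix (default 18 residues); the label site is the
        middle residue.  Optional ``reporter_distance_A`` adds a lone Ile
        CD1 reporter atom at that distance from the site CB.
    ``two-site-scaffold``
        Two parallel helices with the two site CB atoms placed exactly
        ``separation_nm`` (default 4.5) apart.
    ``buried-cage``
        The exposed helix surrounded, at the site only, by a dense spherical
        cage of atoms ``cage_radius_A`` (default 3.0) from the site CB, so
        no label conformer can be placed.
    """
    n_res = int(params.get("n_res", 18))
    if kind == "exposed-helix":
        atoms = _build_helix(n_res)
        site = LabelSite("A", n_res // 2 + 1)
        reporter = params.get("reporter_distance_A")
        if reporter is not None:
            cb = next(
                a.position
                for a in atoms
                if a.residue_number == site.residue_number and a.name == "CB"
            )
            ca = next(
                a.position
                for a in atoms
                if a.residue_number == site.residue_number and a.name == "CA"
            )
            direction = cb - ca
            direction /= np.linalg.norm(direction)
            atoms.append(
                Atom(
                    serial=0,
                    name="CD1",
                    residue_name="ILE",
                    chain="R",
                    residue_number=1,
                    position=cb + reporter * direction,
                    element="C",
                )
            )
        return ToyStructure(
            structure=Structure(_renumber(atoms), identifier=f"toy-exposed-helix-{seed}"),
            sites=[site],
            meta={"kind": kind, "seed": seed},
        )
    if kind == "two-site-scaffold":
        separation = float(params.get("separation_nm", 4.5)) * 10.0  # A
        helix_a = _build_helix(n_res, chain="A")
        helix_b = _build_helix(n_res, chain="B")
        site_a = LabelSite("A", n_res // 2 + 1)
        site_b = LabelSite("B", n_res // 2 + 1)
        cb_a = next(
            a.position for a in helix_a if a.residue_number == site_a.residue_number and a.name == "CB"
        )
        cb_b = next(
            a.position for a in helix_b if a.residue_number == site_b.residue_number and a.name == "CB"
        )
        shift = cb_a + np.array([separation, 0.0, 0.0]) - cb_b
        from dataclasses import replace

        helix_b = [replace(a, position=a.position + shift) for a in helix_b]
        return ToyStructure(
            structure=Structure(
                _renumber(helix_a + helix_b), identifier=f"toy-two-site-{seed}"
            ),
            sites=[site_a, site_b],
            meta={"kind": kind, "seed": seed, "separation_nm": separation / 10.0},
        )
    if kind == "buried-cage":
        radius = float(params.get("cage_radius_A", 3.0))
        n_cage = int(params.get("n_cage", 250))
        atoms = _build_helix(n_res)
        site = LabelSite("A", n_res // 2 + 1)
        cb = next(
            a.position
            for a in atoms
            if a.residue_number == site.residue_number and a.name == "CB"
        )
        for i, pos in enumerate(_fibonacci_sphere(n_cage, radius, cb)):
            atoms.append(
                Atom(
                    serial=0,
                    name="C",
                    residue_name="CAG",
                    chain="X",
                    residue_number=i + 1,
                    position=pos,
                    element="C",
                )
            )
        return ToyStructure(
            structure=Structure(_renumber(atoms), identifier=f"toy-buried-cage-{seed}"),
            sites=[site],
            meta={"kind": kind, "seed": seed, "cage_radius_A": radius},
        )
    raise ValueError(f"unknown toy-structure kind: {kind!r}")


# ---------------------------------------------------------------------------
# DEER datasets
# ---------------------------------------------------------------------------


@dataclass
class DeerDataset:
    trace: deer.DipolarTrace
    truth: DistanceDistribution
    spec: dict


#: Default multi-Gaussian scenario: a dominant long distance with two
#: shorter minor-conformer contributions (the bimodal-short + long regime
#: seen for doubly labeled membrane transporters).
DEFAULT_DEER_COMPONENTS = [(2.5, 0.15, 0.2), (3.5, 0.15, 0.2), (5.5, 0.30, 0.6)]


def make_deer_dataset(
    components: list[tuple[float, float, float]] | None = None,
    k: float = 0.2,
    modulation_depth: float = 0.3,
    d: float = 3.0,
    t_max: float = 4.0,
    n_points: int = 500,
    noise_sd: float = 0.01,
    seed: int = 0,
    r_grid: np.ndarray | None = None,
) -> DeerDataset:
    """Simulate a dipolar trace from a known multi-Gaussian P(r)."""
    if components is None:
        components = DEFAULT_DEER_COMPONENTS
    if r_grid is None:
        r_grid = default_r_grid()
    truth = DistanceDistribution.from_gaussians(components, r_grid=r_grid)
    bg = deer.BackgroundModel(k=k, modulation_depth=modulation_depth, dimensionality=d)
    t = np.linspace(0.0, t_max, n_points)
    trace = deer.simulate_trace(truth, bg, t, noise_sd=noise_sd, seed=seed)
    return DeerDataset(
        trace=trace,
        truth=truth,
        spec={
            "components": list(components),
            "k": k,
            "modulation_depth": modulation_depth,
            "d": d,
            "t_max": t_max,
            "n_points": n_points,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# PRE datasets
# ---------------------------------------------------------------------------


@dataclass
class PreDataset:
    para: IntensityTable
    dia: IntensityTable
    truth: pd.DataFrame
    spec: dict


#: Default true label-to-methyl distances (Å): spans fully bleached, partly
#: attenuated and unaffected residues while avoiding the narrow band where
#: the distance radius and the ratio threshold disagree by construction.
DEFAULT_PRE_DISTANCES = {
    "I1": 12.0,
    "I2": 16.0,
    "I3": 20.0,
    "I4": 24.0,
    "I5": 32.0,
    "I6": 38.0,
    "I7": 45.0,
}

#: Gamma2 * t_eff = TAU_FACTOR / r^6 calibrated so r = 25 Å gives ratio 0.5.
DEFAULT_TAU_FACTOR = float(np.log(2.0) * 25.0**6)


def pre_true_ratio(r_angstrom, tau_factor: float = DEFAULT_TAU_FACTOR):
    """Forward attenuation model: I_para/I_dia = exp(-tau_factor * r^-6)."""
    r = np.asarray(r_angstrom, dtype=float)
    return np.exp(-tau_factor / r**6)


def make_pre_dataset(
    true_distances: dict | None = None,
    tau_factor: float = DEFAULT_TAU_FACTOR,
    scale_para: float = 1.0,
    scale_dia: float = 1.0,
    noise_rms: float = 0.0,
    seed: int = 0,
    detection_radius: float = 25.0,
    base_intensity: float = 100.0,
) -> PreDataset:
    """Paired para/dia intensity tables from known label–nucleus distances.

    Diamagnetic intensities are a common base level times ``scale_dia``;
    paramagnetic intensities are additionally attenuated by the r^-6
    exponential model and scaled by ``scale_para`` (distinct global scales
    emulate unequal sample amounts, so raw ratios do not normalize to one).
    Additive Gaussian noise of ``noise_rms`` (per unit scale) perturbs both
    tables; the truth table records true ratios and the expected
    classification at ``detection_radius``.
    """
    if true_distances is None:
        true_distances = dict(DEFAULT_PRE_DISTANCES)
    if any(d <= 0 for d in true_distances.values()):
        raise ValueError("distances must be positive")
    rng = np.random.default_rng(seed)
    ids = list(true_distances)
    r = np.array([true_distances[i] for i in ids], dtype=float)
    ratio = pre_true_ratio(r, tau_factor)
    noise_floor = max(noise_rms, 1e-9)
    dia_i = scale_dia * base_intensity + rng.normal(0, noise_rms * scale_dia, len(ids)) * (
        noise_rms > 0
    )
    para_i = scale_para * base_intensity * ratio + rng.normal(
        0, noise_rms * scale_para, len(ids)
    ) * (noise_rms > 0)
    para_i = np.clip(para_i, 1e-6, None)
    dia_i = np.clip(dia_i, 1e-6, None)
    para = IntensityTable(
        data=pd.DataFrame(
            {
                "residue_id": ids,
                "intensity": para_i,
                "noise_rms": noise_floor * scale_para,
            }
        ),
        condition="para",
        sample=f"synthetic-seed{seed}",
    )
    dia = IntensityTable(
        data=pd.DataFrame(
            {
                "residue_id": ids,
                "intensity": dia_i,
                "noise_rms": noise_floor * scale_dia,
            }
        ),
        condition="dia",
        sample=f"synthetic-seed{seed}",
    )
    truth = pd.DataFrame(
        {
            "residue_id": ids,
            "distance_A": r,
            "true_ratio": ratio,
            "expected": np.where(r <= detection_radius, "attenuated", "unaffected"),
        }
    )
    return PreDataset(
        para=para,
        dia=dia,
        truth=truth,
        spec={
            "tau_factor": tau_factor,
            "scale_para": scale_para,
            "scale_dia": scale_dia,
            "noise_rms": noise_rms,
            "seed": seed,
            "detection_radius": detection_radius,
        },
    )


# ---------------------------------------------------------------------------
# Relaxation-dispersion datasets
# ---------------------------------------------------------------------------

#: Spin-lock fields (kHz) and durations (ms) matching the probed regime.
DEFAULT_NU1_LADDER_KHZ = (1.2, 2.0, 3.0, 4.5, 6.0, 8.0, 10.0)
DEFAULT_DURATIONS_MS = (2.5, 10.0, 25.0, 50.0, 80.0)


def make_dispersion_dataset(
    r20: float = 20.0,
    phi: float = 5e5,
    kex: float = 1e4,
    nu1_ladder_khz: tuple = DEFAULT_NU1_LADDER_KHZ,
    durations_ms: tuple = DEFAULT_DURATIONS_MS,
    noise: float = 0.02,
    seed: int = 0,
    exchange: bool = True,
    r1: float = 1.5,
    residue_id: str = "I1",
    i0: float = 100.0,
) -> SpinLockSeries:
    """Spin-lock decay series with or without fast two-site exchange.

    With ``exchange`` set, R2eff follows the on-resonance fast-exchange
    Lorentzian with parameters (r20, phi, kex); otherwise R2eff = r20 at
    every field.  Decays carry multiplicative Gaussian noise of fractional
    amplitude ``noise``.
    """
    nu1 = np.asarray(nu1_ladder_khz, dtype=float)
    if np.any(nu1 <= 0):
        raise ValueError("spin-lock fields must be positive")
    if nu1.min() < 0.1 or nu1.max() > 100.0:
        warnings.warn("spin-lock ladder outside the typical 0.1-100 kHz range")
    rng = np.random.default_rng(seed)
    points = []
    for f_khz in nu1:
        r2eff = _exchange_model(f_khz, r20, phi, kex) if exchange else r20
        r1rho = float(r2eff)  # on resonance theta = 90 deg
        T = np.asarray(durations_ms, dtype=float)
        decay = i0 * np.exp(-r1rho * T * 1e-3)
        if noise > 0:
            decay = decay * (1.0 + rng.normal(0.0, noise, size=T.shape))
        decay = np.clip(decay, 1e-6, None)
        points.append(
            {
                "nu1_khz": float(f_khz),
                "durations_ms": list(T),
                "intensities": list(decay),
                "offset_khz": 0.0,
            }
        )
    return SpinLockSeries(residue_id=residue_id, points=points, r1=r1, r1_sigma=0.05 * r1)
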