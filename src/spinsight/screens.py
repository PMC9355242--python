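"""Structure-based screening utilities.

Two small tools used to interpret conformational-change experiments:
disulfide-pair feasibility in a resting (crystal) conformation, and
peptide-bound-fraction arithmetic from native-MS peak intensities with decoy
subtraction.  A Cys pair that crosslinks in vivo although its CB atoms are
far apart in the resting structure reports on an alternative conformer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnsupportedResidueError
from .structure import Structure, atom_distance

#: CB-CB distance (Å) below which spontaneous disulfide formation is
#: geometrically plausible without a conformational change (a standard
#: engineering criterion; SG rotamers can bridge roughly this far).
DEFAULT_SS_THRESHOLD = 5.5

#: Observed in-vivo crosslinking outcomes for engineered Cys pairs
#: (experimental input for interpretation reports, not computed output).
#: Keys are (periplasmic site, surface site) residue numbers; values are
#: three-level outcomes.
IN_VIVO_CROSSLINK_OUTCOMES = {
    (195, 224): "yes",
    (176, 224): "yes",
    (48, 224): "yes",
    (48, 545): "yes",
    (167, 224): "weak",
    (167, 290): "no",
    (167, 342): "no",
    (167, 391): "no",
    (176, 290): "no",
    (176, 342): "no",
    (176, 391): "no",
    (176, 503): "no",
    (176, 545): "no",
    (187, 224): "no",
    (187, 503): "no",
    (195, 290): "no",
    (195, 342): "no",
    (195, 391): "no",
    (195, 503): "no",
    (195, 545): "no",
    (48, 290): "no",
    (48, 342): "no",
    (48, 391): "no",
    (48, 503): "no",
    (86, 224): "no",
    (86, 545): "no",
}


@dataclass
class CysPairAssessment:
    pair: tuple[tuple[str, int], tuple[str, int]]
    cb_distance: float
    feasible_resting: bool
    interpretation: str
    threshold: float


@dataclass
class BindingSpectrumSummary:
    intensities: dict  # k-bound -> intensity
    bound_fraction: float
    decoy_corrected_fraction: float  # clipped at 0
    decoy_corrected_raw: float  # may be negative


def assess_cys_pair(
    structure: Structure,
    a: tuple[str, int],
    b: tuple[str, int],
    threshold: float = DEFAULT_SS_THRESHOLD,
) -> CysPairAssessment:
    """Assess whether a Cys pair could form a disulfide in the resting state.

    Uses the CB–CB distance as the feasibility proxy; a pair observed to
    crosslink in vivo while infeasible here requires a conformational
    change to come into contact.
    """
    for addr in (a, b):
        res = structure.residue(*addr)
        if res[0].residue_name == "GLY" or all(at.name != "CB" for at in res):
            raise UnsupportedResidueError(
                f"residue {addr[0]}:{addr[1]} has no CB; cannot assess a Cys pair"
            )
    d = atom_distance(structure, (*a, "CB"), (*b, "CB"))
    feasible = d <= threshold
    return CysPairAssessment(
        pair=(tuple(a), tuple(b)),
        cb_distance=d,
        feasible_resting=feasible,
        interpretation="feasible" if feasible else "requires-conformational-change",
        threshold=threshold,
    )


def bound_fraction(intensities: dict, decoy_fraction: float = 0.0) -> BindingSpectrumSummary:
    """Fraction of peptide-bound protein from per-species peak intensities.

    bound = sum of intensities with >= 1 peptide bound over the total;
    the decoy-protein bound fraction is subtracted to correct for
    non-specific binding (reported raw and clipped at zero).
    """
    if not intensities or all(v == 0 for v in intensities.values()):
        raise ValueError("at least one species must have positive intensity")
    if any(v < 0 for v in intensities.values()):
        raise ValueError("intensities must be non-negative")
    total = float(sum(intensities.values()))
    bound = float(sum(v for k, v in intensities.items() if int(k) >= 1))
    frac = bound / total
    raw = frac - decoy_fraction
    return BindingSpectrumSummary(
        intensities=dict(intensities),
        bound_fraction=frac,
        decoy_corrected_fraction=max(raw, 0.0),
        decoy_corrected_raw=raw,
    )
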