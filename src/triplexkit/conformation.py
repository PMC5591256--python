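"""Glycosidic-torsion and sugar-pucker analysis.

The glycosidic torsion χ is the dihedral O4'-C1'-N1-C2 for pyrimidines and
O4'-C1'-N9-C4 for purines, reported in [0°, 360°) so that the conventional
bins read literally: *anti* 170° < χ < 320° (low anti below 220°, high anti
above 270°, the unnamed middle labelled ``mid_anti``) and *syn*
30° < χ < 90°.

The furanose pucker is summarised by the Altona–Sundaralingam
pseudorotation phase P and amplitude τm, from the five endocyclic torsions
ν0..ν4 (ν2 = C1'-C2'-C3'-C4' = τm·cos P):

    tan P = ((ν4 + ν1) − (ν3 + ν0)) / (2 ν2 (sin 36° + sin 72°))

with P reported in (−90°, 270°] so the *north* (−90° < P ≤ 90°) / *south*
(90° < P ≤ 270°) bins form a partition.  ``conformation_profile`` applies
these per residue per frame and, by default, excludes the last two
nucleotides of each strand end, where fraying dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure import Structure, Trajectory

__all__ = [
    "AnalysisError",
    "GeometryError",
    "CHI_LABELS",
    "PUCKER_LABELS",
    "dihedral",
    "wrap_angle",
    "glycosidic_chi",
    "ring_torsions",
    "phase_amplitude",
    "torsions_from_phase",
    "pseudorotation",
    "classify_chi",
    "classify_pucker",
    "conformation_profile",
]


class AnalysisError(ValueError):
    """Raised for unanalysable selections or degenerate inputs."""


class GeometryError(AnalysisError):
    """Raised for degenerate geometry (coincident/collinear points)."""


CHI_LABELS = ("syn", "low_anti", "mid_anti", "high_anti", "other")
PUCKER_LABELS = ("north", "south")

CHI_QUAD_PURINE = ("O4'", "C1'", "N9", "C4")
CHI_QUAD_PYRIMIDINE = ("O4'", "C1'", "N1", "C2")

RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
# nu_j torsion quadruples, j = 0..4; nu2 = C1'-C2'-C3'-C4'
NU_QUADS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

_S36_72 = math.sin(math.radians(36.0)) + math.sin(math.radians(72.0))


def wrap_angle(angle: float, low: float = -180.0) -> float:
    """Map an angle in degrees into [low, low + 360)."""
    return (angle - low) % 360.0 + low


def dihedral(p1, p2, p3, p4, low: float = -180.0) -> float:
    """Signed torsion angle (degrees, IUPAC sign convention) of four points,
    mapped into [low, low + 360)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-9:
            raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("collinear consecutive points in dihedral")
    b2u = b2 / np.linalg.norm(b2)
    angle = math.degrees(math.atan2(np.dot(np.cross(n1, n2), b2u), np.dot(n1, n2)))
    return wrap_angle(angle, low)


def _residue_xyz(structure: Structure, chain: str, index: int, names) -> list:
    res = structure.residue(chain, index)
    pts = []
    for name in names:
        if name not in res.atom_rows:
            raise AnalysisError(
                f"residue {chain}{index} ({res.base}) is missing atom {name!r}"
            )
        pts.append(structure.coords[res.atom_rows[name]])
    return pts


def glycosidic_chi(structure: Structure, chain: str, index: int) -> float:
    """Glycosidic torsion χ in [0°, 360°); atom quadruple chosen by base
    type (purine N9-C4, pyrimidine N1-C2)."""
    res = structure.residue(chain, index)
    quad = CHI_QUAD_PURINE if res.is_purine else CHI_QUAD_PYRIMIDINE
    return dihedral(*_residue_xyz(structure, chain, index, quad), low=0.0)


def ring_torsions(structure: Structure, chain: str, index: int) -> np.ndarray:
    """The five endocyclic torsions ν0..ν4 in degrees, in (−180, 180]."""
    return np.array(
        [
            dihedral(*_residue_xyz(structure, chain, index, quad), low=-180.0)
            for quad in NU_QUADS
        ]
    )


def phase_amplitude(nu: Sequence[float]) -> tuple[float, float]:
    """Pseudorotation phase P (degrees, in (−90, 270]) and amplitude τm from
    the five torsions ν0..ν4.  Errors on a planar ring."""
    nu = np.asarray(nu, float)
    if nu.shape != (5,):
        raise ValueError("expected five ring torsions")
    if np.abs(nu).max() < 1e-6:
        raise AnalysisError("undefined pucker: planar ring")
    y = (nu[4] + nu[1]) - (nu[3] + nu[0])
    x = 2.0 * nu[2] * _S36_72
    P = math.degrees(math.atan2(y, x))
    tau_m = math.hypot(x, y) / (2.0 * _S36_72)
    if P <= -90.0:
        P += 360.0
    return P, tau_m


def torsions_from_phase(P: float, tau_m: float) -> np.ndarray:
    """Ideal cosine-law torsions νj = τm·cos(P + (j−2)·144°), degrees."""
    j = np.arange(5)
    return tau_m * np.cos(np.radians(P + (j - 2) * 144.0))


def pseudorotation(structure: Structure, chain: str, index: int) -> tuple[float, float]:
    """(P, τm) of a residue's furanose ring, P in (−90°, 270°]."""
    return phase_amplitude(ring_torsions(structure, chain, index))


def classify_chi(chi: float) -> str:
    """Bin χ (degrees in [0, 360)) as syn / low_anti / mid_anti / high_anti
    / other."""
    if not 0.0 <= chi < 360.0:
        raise ValueError("chi must be in [0, 360)")
    if 30.0 < chi < 90.0:
        return "syn"
    if 170.0 < chi < 320.0:
        if chi < 220.0:
            return "low_anti"
        if chi > 270.0:
            return "high_anti"
        return "mid_anti"
    return "other"


def classify_pucker(P: float) -> str:
    """Bin pseudorotation phase as north (−90 < P ≤ 90) or south
    (90 < P ≤ 270)."""
    if not -90.0 < P <= 270.0:
        raise ValueError("P must be in (-90, 270]")
    return "north" if P <= 90.0 else "south"


@dataclass
class ConformationProfile:
    """Per-residue class fractions and histograms over a trajectory."""

    fractions: pd.DataFrame  # one row per (chain, residue)
    histograms: pd.DataFrame  # long format: chain, residue, quantity, bin_left, count
    bin_width: float
    exclude_ends: int


def _included_indices(structure: Structure, chain: str, exclude_ends: int) -> list[int]:
    idx = [r.index for r in structure.residues_of(chain)]
    if exclude_ends <= 0:
        return idx
    if len(idx) <= 2 * exclude_ends:
        return []
    return idx[exclude_ends:-exclude_ends]


def conformation_profile(
    trajectory: Trajectory,
    chains: Optional[Sequence[str]] = None,
    exclude_ends: int = 2,
    bin_width: float = 5.0,
) -> ConformationProfile:
    """χ and pucker class fractions plus binned histograms per residue.

    The ``exclude_ends`` terminal residues of each strand are omitted
    (default two per end, the usual guard against end fraying).
    """
    if trajectory.n_frames < 1:
        raise AnalysisError("empty trajectory")
    topo = trajectory.topology
    chains = list(chains) if chains is not None else topo.chains
    selection = [
        (chain, idx)
        for chain in chains
        for idx in _included_indices(topo, chain, exclude_ends)
    ]
    if not selection:
        raise AnalysisError("empty residue selection")

    frac_rows = []
    hist_rows = []
    chi_edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    p_edges = np.arange(-90.0, 270.0 + bin_width, bin_width)
    for chain, idx in selection:
        chis = np.empty(trajectory.n_frames)
        ps = np.empty(trajectory.n_frames)
        for f in range(trajectory.n_frames):
            frame = trajectory.frame(f)
            chis[f] = glycosidic_chi(frame, chain, idx)
            ps[f], _ = pseudorotation(frame, chain, idx)
        chi_labels = [classify_chi(c) for c in chis]
        p_labels = [classify_pucker(p) for p in ps]
        n = float(trajectory.n_frames)
        row = {"chain": chain, "residue": idx, "n_frames": trajectory.n_frames}
        res = topo.residue(chain, idx)
        row["base"] = res.base
        row["chemistry"] = res.chemistry
        for lab in CHI_LABELS:
            row[lab] = chi_labels.count(lab) / n
        for lab in PUCKER_LABELS:
            row[lab] = p_labels.count(lab) / n
        frac_rows.append(row)

        for quantity, values, edges in (("chi", chis, chi_edges), ("P", ps, p_edges)):
            counts, _ = np.histogram(values, bins=edges)
            for left, cnt in zip(edges[:-1], counts):
                if cnt:
                    hist_rows.append(
                        {
                            "chain": chain,
                            "residue": idx,
                            "quantity": quantity,
                            "bin_left": float(left),
                            "count": int(cnt),
                        }
                    )

    return ConformationProfile(
        fractions=pd.DataFrame(frac_rows),
        histograms=pd.DataFrame(hist_rows),
        bin_width=bin_width,
        exclude_ends=exclude_ends,
    )
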