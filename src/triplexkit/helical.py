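"""Base-pair-step helical parameters, groove widths and duplex-form calls.

Base reference frames come from a least-squares fit of each base's ring
atoms to its idealized planar template; the strand-II frame of a
Watson-Crick pair is flipped 180° about x before averaging into the pair
frame.  Step parameters (twist, roll, tilt, shift, slide, rise) use the
symmetric mid-frame (CEHS-style, 3DNA-compatible) convention; the helical
decomposition of each step (x-displacement, inclination) uses the local
helical axis of the step rotation, expressed in the 5'-pair frame, which
makes the fiber-builder round trip exact.  Note that Curves+-style
curvilinear-axis parameters can differ from these by a few tenths of an
Å/degree.

Groove widths are shortest cross-strand P-P distances per base-pair level
minus 5.8 Å for the two phosphate-group radii; the minor groove is the
closest-approach family, the major groove the closest approach on the
opposite side of the pairing register.

``classify_helix`` labels the mean interior-step geometry as B, A,
intermediate, or LirA ("Low Inclination & Roll A-DNA"): A-like
x-displacement, slide and twist without the inclination/roll of a true
A-form helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .builder import BASE_TEMPLATES
from .conformation import AnalysisError
from .structure import Structure

__all__ = [
    "BaseFrame",
    "HelixCall",
    "ClassifierThresholds",
    "base_reference_frame",
    "pair_frames",
    "step_parameters",
    "mean_step_parameters",
    "groove_widths",
    "classify_helix",
]

_FLIP = np.diag([1.0, -1.0, -1.0])
_FRAME_RMSD_MAX = 0.5
PHOSPHATE_CORRECTION = 5.8  # Å, El Hassan-Calladine style P-P correction


@dataclass(frozen=True)
class BaseFrame:
    """Origin plus right-handed orthonormal triad (columns x, y, z)."""

    origin: np.ndarray
    rotation: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]


def base_reference_frame(structure: Structure, chain: str, index: int) -> BaseFrame:
    """Fit the residue's base atoms to the standard template geometry."""
    res = structure.residue(chain, index)
    template = BASE_TEMPLATES[res.base]
    names = [n for n in template if n in res.atom_rows]
    if len(names) < 3:
        raise AnalysisError(
            f"residue {chain}{index} has too few base atoms for a frame fit"
        )
    obs = np.array([structure.coords[res.atom_rows[n]] for n in names])
    ref = np.array([template[n] for n in names])
    obs_c = obs.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, rssd = Rotation.align_vectors(obs - obs_c, ref - ref_c)
    rmsd = rssd / math.sqrt(len(names))
    if rmsd > _FRAME_RMSD_MAX:
        raise AnalysisError(
            f"base of residue {chain}{index} deviates from the ideal "
            f"template (fit RMSD {rmsd:.2f} Å > {_FRAME_RMSD_MAX} Å); "
            "deformed or misnamed base"
        )
    R = rot.as_matrix()
    origin = obs_c - R @ ref_c
    return BaseFrame(origin=origin, rotation=R)


def _mean_rotation(Ra: np.ndarray, Rb: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix([Ra, Rb]).mean().as_matrix()


def pair_frames(structure: Structure) -> list[BaseFrame]:
    """Watson-Crick pair frames, 5'→3' along chain W.  W residue i pairs
    C residue n+1−i; the C-frame is flipped about x before averaging."""
    w_res = structure.residues_of("W")
    c_res = structure.residues_of("C")
    if not w_res or not c_res:
        raise AnalysisError("duplex chains W and C are required")
    n = len(w_res)
    if len(c_res) != n:
        raise AnalysisError("chains W and C differ in length")
    frames = []
    for i in range(1, n + 1):
        fw = base_reference_frame(structure, "W", i)
        fc = base_reference_frame(structure, "C", n + 1 - i)
        Rc = fc.rotation @ _FLIP
        R = _mean_rotation(fw.rotation, Rc)
        origin = 0.5 * (fw.origin + fc.origin)
        frames.append(BaseFrame(origin=origin, rotation=R))
    return frames


def _signed_angle(u: np.ndarray, v: np.ndarray, axis: np.ndarray) -> float:
    return math.degrees(
        math.atan2(float(np.dot(np.cross(u, v), axis)), float(np.dot(u, v)))
    )


def _step_from_frames(f1: BaseFrame, f2: BaseFrame) -> dict:
    z1, z2 = f1.z, f2.z
    gamma = math.degrees(
        math.acos(float(np.clip(np.dot(z1, z2), -1.0, 1.0)))
    )
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) > 1e-12:
        hinge = hinge / np.linalg.norm(hinge)
        rot_half = Rotation.from_rotvec(hinge * math.radians(gamma / 2.0))
        R1p = rot_half.as_matrix() @ f1.rotation
        R2p = rot_half.inv().as_matrix() @ f2.rotation
    else:
        hinge = None
        R1p, R2p = f1.rotation, f2.rotation

    zm = R1p[:, 2]
    twist = _signed_angle(R1p[:, 1], R2p[:, 1], zm)

    # Mid frame: average of the two hinge-corrected frames.
    Rm = _mean_rotation(R1p, R2p)
    disp = f2.origin - f1.origin
    shift, slide, rise = Rm.T @ disp

    if hinge is None or gamma < 1e-10:
        roll = tilt = 0.0
    else:
        phi = _signed_angle(hinge, Rm[:, 1], zm)
        roll = gamma * math.cos(math.radians(phi))
        tilt = -gamma * math.sin(math.radians(phi))

    # Local helical decomposition.
    Rg = f2.rotation @ f1.rotation.T
    rotvec = Rotation.from_matrix(Rg).as_rotvec()
    theta = float(np.linalg.norm(rotvec))
    if theta < 1e-10:
        x_disp = float(np.dot(f1.x, disp))
        inclination = 0.0
        twist_h = 0.0
        rise_h = float(np.dot(zm, disp))
    else:
        h = rotvec / theta
        if np.dot(h, zm) < 0:
            h, theta = -h, -theta
        twist_h = math.degrees(theta)
        rise_h = float(np.dot(disp, h))
        # Axis anchor: o2 = Rg (o1 - A) + A + rise_h h  =>
        # (I - Rg)(o1 - A) = -(disp - rise_h h); solve in the plane ⊥ h.
        rhs = disp - rise_h * h
        M = np.eye(3) - Rg
        x_vec, *_ = np.linalg.lstsq(M, rhs, rcond=None)
        x_perp = x_vec - np.dot(x_vec, h) * h  # = A - o1 (⊥ component)
        # Tip frame 1 so its z coincides with the helical axis.
        f1h = _align_z(f1.rotation, h)
        x_disp = float(np.dot(f1h[:, 0], -x_perp))
        # Inclination: component about x of the rotation aligning z_mid to h.
        rv = _rotvec_between(zm, h)
        inclination = -math.degrees(float(np.dot(rv, Rm[:, 0])))

    return {
        "twist": twist,
        "roll": roll,
        "tilt": tilt,
        "shift": float(shift),
        "slide": float(slide),
        "rise": float(rise),
        "x_displacement": x_disp,
        "inclination": inclination,
        "helical_twist": twist_h,
        "helical_rise": rise_h,
    }


def _align_z(R: np.ndarray, h: np.ndarray) -> np.ndarray:
    rv = _rotvec_between(R[:, 2], h)
    return Rotation.from_rotvec(rv).as_matrix() @ R


def _rotvec_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.clip(np.dot(a, b), -1.0, 1.0))
    if s < 1e-12:
        return np.zeros(3)
    return v / s * math.atan2(s, c)


def step_parameters(structure: Structure) -> pd.DataFrame:
    """Per-step helical parameters of the duplex part of a structure.

    Rows are indexed by the 5' base-pair number of each step; terminal
    steps carry ``terminal=True`` and are excluded from summary means by
    default (the exclude-ends convention).
    """
    frames = pair_frames(structure)
    if len(frames) < 2:
        raise AnalysisError("at least two base pairs are required for steps")
    rows = []
    n_steps = len(frames) - 1
    for i in range(n_steps):
        rec = _step_from_frames(frames[i], frames[i + 1])
        rec["step"] = i + 1
        rec["terminal"] = i == 0 or i == n_steps - 1
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("step")
    cols = [
        "twist", "roll", "tilt", "shift", "slide", "rise",
        "x_displacement", "inclination", "helical_twist", "helical_rise",
        "terminal",
    ]
    return df[cols]


def mean_step_parameters(
    steps: pd.DataFrame, include_terminal: bool = False
) -> pd.Series:
    sel = steps if include_terminal else steps[~steps["terminal"]]
    if sel.empty:
        raise AnalysisError("no interior steps to average")
    return sel.drop(columns="terminal").mean()


# ---------------------------------------------------------------------------
# Groove widths
# ---------------------------------------------------------------------------


def groove_widths(structure: Structure) -> pd.DataFrame:
    """Minor/major groove widths per base-pair level, from cross-strand
    P-P closest approaches minus the 5.8 Å phosphate correction."""
    w_res = structure.residues_of("W")
    c_res = structure.residues_of("C")
    n = len(w_res)
    pw = {r.index: structure.coords[r.atom_rows["P"]] for r in w_res if "P" in r.atom_rows}
    pc = {r.index: structure.coords[r.atom_rows["P"]] for r in c_res if "P" in r.atom_rows}
    if not pw or not pc:
        raise AnalysisError("phosphate atoms are required for groove widths")
    rows = []
    c_keys = sorted(pc)
    for level in sorted(pw):
        partner = n + 1 - level
        dists = {j: float(np.linalg.norm(pw[level] - pc[j])) for j in c_keys}
        jmin = min(dists, key=dists.get)
        side = np.sign(jmin - partner)
        opposite = [j for j in c_keys if np.sign(j - partner) == -side and j != jmin]
        if side == 0 or not opposite:
            continue
        major = min(dists[j] for j in opposite)
        rows.append(
            {
                "level": level,
                "minor": dists[jmin] - PHOSPHATE_CORRECTION,
                "major": major - PHOSPHATE_CORRECTION,
            }
        )
    return pd.DataFrame(rows, columns=["level", "minor", "major"]).set_index("level")


# ---------------------------------------------------------------------------
# Duplex-form classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierThresholds:
    """Decision thresholds for the B / A / LirA / intermediate call.

    Defaults bracket the canonical mean tuples: B-form means
    (x ≈ −0.8 Å, slide ≈ 0 Å, twist ≈ 36°) and the LirA hetero-duplex
    means (−4.3 Å, −1.6 Å, 30°).
    """

    b_x_min: float = -1.5
    b_twist_min: float = 34.0
    a_x_max: float = -3.0
    a_slide_max: float = -1.0
    a_twist_max: float = 32.0
    a_inclination_min: float = 12.0
    a_roll_min: float = 8.0
    lira_inclination_max: float = 8.0
    lira_roll_max: float = 8.0


@dataclass(frozen=True)
class HelixCall:
    label: str  # B, A, LirA, intermediate
    evidence: dict = field(default_factory=dict)


def classify_helix(
    means,
    thresholds: Optional[ClassifierThresholds] = None,
    min_steps: int = 4,
    n_steps: Optional[int] = None,
) -> HelixCall:
    """Classify mean interior-step geometry as B, A, LirA or intermediate.

    ``means`` maps x_displacement, slide, twist, inclination, roll to mean
    values (a pandas Series from :func:`mean_step_parameters` works).
    """
    th = thresholds or ClassifierThresholds()
    if n_steps is not None and n_steps < min_steps:
        raise AnalysisError(
            f"need at least {min_steps} interior steps, got {n_steps}"
        )
    x = float(means["x_displacement"])
    slide = float(means["slide"])
    twist = float(means["twist"])
    incl = float(means["inclination"])
    roll = float(means["roll"])
    evidence = {
        "x_displacement": x,
        "slide": slide,
        "twist": twist,
        "inclination": incl,
        "roll": roll,
    }
    if x >= th.b_x_min and twist >= th.b_twist_min:
        label = "B"
    elif x <= th.a_x_max and slide <= th.a_slide_max and twist <= th.a_twist_max:
        if incl >= th.a_inclination_min or roll >= th.a_roll_min:
            label = "A"
        elif incl < th.lira_inclination_max and roll < th.lira_roll_max:
            label = "LirA"
        else:
            label = "intermediate"
    else:
        label = "intermediate"
    return HelixCall(label=label, evidence=evidence)
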