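"""Idealized fiber-model builder for B/A-form duplexes and parallel
pyrimidine-motif triplexes.

Base pairs are placed on a straight helix axis: pair *i* sits at rotation
``i·twist`` about and translation ``i·rise`` along the global z axis, with
an optional lateral x-displacement and inclination of each pair frame.
Bases use planar templates in the standard nucleic-acid reference frame
(origin at the pairing pseudo-dyad, x toward the major groove, z along the
strand-I base normal); the strand-II base of a Watson-Crick pair is the
strand-I template of the complement rotated 180° about x.

Sugars are built from an exact pseudorotation solver: for a requested
(P, τm) the five-membered ring is closed numerically so that the measured
Altona–Sundaralingam phase/amplitude reproduces the request to better than
1e-6°, then attached to the base at the requested glycosidic torsion χ.
LNA riboses are modelled as rings locked at north (P = 17°, τm = 48°); the
2'-O,4'-C methylene bridge atoms are not placed explicitly because no
analysis in this package consumes them.  The third (TFO) strand is placed
in the major groove parallel to the purine strand, with Hoogsteen
N7(purine)-N3(pyrimidine) distances built at 2.9 Å; TFO cytosines are
protonated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .conformation import (
    AnalysisError,
    dihedral,
    phase_amplitude,
    torsions_from_phase,
    wrap_angle,
)
from .oligo import (
    TINA,
    DuplexTarget,
    NotationError,
    Oligo,
    find_tfo_binding_site,
    wc_complement,
)
from .structure import (
    Structure,
    StructureAssembler,
    read_pdb,
    write_pdb,
)

__all__ = [
    "BuildError",
    "HelixParamsSpec",
    "BASE_TEMPLATES",
    "build_duplex",
    "build_triplex",
    "set_sugar_pucker",
    "sugar_ring_coords",
    "write_pdb",
    "read_pdb",
]


class BuildError(ValueError):
    """Raised when a model cannot be built from the given inputs."""


# ---------------------------------------------------------------------------
# Base templates: standard reference frame, coordinates in Å, base in z = 0
# plane, x toward the major groove.  C1' included for sugar attachment and
# frame fitting.
# ---------------------------------------------------------------------------

BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    },
}
BASE_TEMPLATES = {
    base: {name: np.array(xyz, float) for name, xyz in atoms.items()}
    for base, atoms in BASE_TEMPLATES.items()
}

GLYCO_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}
CHI_REF = {"A": "C4", "G": "C4", "C": "C2", "T": "C2"}

# Flip of the strand-II base into the shared pair frame (180° about x).
_FLIP = np.diag([1.0, -1.0, -1.0])


# ---------------------------------------------------------------------------
# Helix specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HelixParamsSpec:
    """Per-step fiber parameters of an idealized straight helix.

    ``x_displacement`` shifts every pair frame laterally from the axis
    (strongly negative in A-form), ``inclination`` tilts the pair frames
    about their long axis.  ``dna_pucker``/``chi_dna`` set the deoxyribose
    geometry of DNA residues; LNA residues always use the locked north
    ring (``LNA_PUCKER``) and a low-anti χ.
    """

    form: str = "B"
    twist_per_step: float = 36.0
    rise_per_step: float = 3.38
    x_displacement: float = 0.0
    inclination: float = 0.0
    dna_pucker: tuple[float, float] = (162.0, 38.0)
    chi_dna: float = 262.0
    chi_north: float = 203.0

    def __post_init__(self) -> None:
        if not 0.0 < self.twist_per_step < 60.0:
            raise BuildError("twist_per_step must be in (0, 60) degrees")
        if self.rise_per_step <= 0:
            raise BuildError("rise_per_step must be positive")

    @classmethod
    def b_form(cls, **overrides) -> "HelixParamsSpec":
        """Canonical B-DNA fiber values: 36.0°, 3.38 Å, C2'-endo sugars."""
        return cls(**{**dict(form="B"), **overrides})

    @classmethod
    def a_form(cls, **overrides) -> "HelixParamsSpec":
        """Canonical A-DNA fiber values: 32.7°, 2.81 Å, C3'-endo sugars,
        x-displacement −4.1 Å."""
        defaults = dict(
            form="A",
            twist_per_step=32.7,
            rise_per_step=2.81,
            x_displacement=-4.1,
            dna_pucker=(18.0, 40.0),
            chi_dna=203.0,
        )
        return cls(**{**defaults, **overrides})


LNA_PUCKER = (17.0, 48.0)
NORTH_PUCKER = (18.0, 40.0)

# ---------------------------------------------------------------------------
# Sugar ring construction (exact pseudorotation closure)
# ---------------------------------------------------------------------------

# Ring bond lengths, Å, around O4'-C1'-C2'-C3'-C4'.
_D_O4_C1 = 1.42
_D_C1_C2 = 1.528
_D_C2_C3 = 1.525
_D_C3_C4 = 1.528
_D_C4_O4 = 1.446

_GLYCO_BOND = 1.475
_ANG_O4_C1_N = 108.2  # degrees
_ANG_C2_C1_N = 114.0


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # manual cross product: much cheaper than np.cross for single vectors
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _fast_dihedral(p1, p2, p3, p4) -> float:
    """Unchecked signed torsion in degrees, (−180, 180]; hot-path variant."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    m = _cross(n1, n2)
    b2u = b2 / math.sqrt(b2 @ b2)
    return math.degrees(math.atan2(m @ b2u, n1 @ n2))


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: new atom at given internal coordinates w.r.t. a-b-c."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= math.sqrt(bc @ bc)
    n = _cross(b - a, bc)
    n /= math.sqrt(n @ n)
    m = _cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return c + basis @ d


def _ring_from_internal(theta: np.ndarray, nu1: float, nu2: float) -> np.ndarray:
    """Chain-build O4', C1', C2', C3', C4' from three bond angles (degrees)
    and the torsions ν1 (O4'-C1'-C2'-C3') and ν2 (C1'-C2'-C3'-C4')."""
    o4 = np.zeros(3)
    c1 = np.array([_D_O4_C1, 0.0, 0.0])
    ang1 = math.radians(theta[0])
    c2 = c1 + np.array(
        [-_D_C1_C2 * math.cos(ang1), _D_C1_C2 * math.sin(ang1), 0.0]
    )
    c3 = _place_atom(o4, c1, c2, _D_C2_C3, theta[1], nu1)
    c4 = _place_atom(c1, c2, c3, _D_C3_C4, theta[2], nu2)
    return np.array([o4, c1, c2, c3, c4])


def _angle(a, b, c) -> float:
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _measure_ring(ring: np.ndarray) -> np.ndarray:
    """The five ν torsions of a ring given as (O4', C1', C2', C3', C4')."""
    o4, c1, c2, c3, c4 = ring
    return np.array(
        [
            _fast_dihedral(c4, o4, c1, c2),
            _fast_dihedral(o4, c1, c2, c3),
            _fast_dihedral(c1, c2, c3, c4),
            _fast_dihedral(c2, c3, c4, o4),
            _fast_dihedral(c3, c4, o4, c1),
        ]
    )


def _solve_ring(nus: np.ndarray, theta0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Close the ring for target torsions ν0..ν4: ν1, ν2 are imposed by
    construction, the three free bond angles are solved so that the closure
    bond length and the remaining torsions ν3, ν4 are met (square Newton
    system with finite-difference Jacobian)."""

    def residuals(theta):
        ring = _ring_from_internal(theta, nus[1], nus[2])
        o4, c1, c2, c3, c4 = ring
        d = c4 - o4
        return np.array(
            [
                math.sqrt(d @ d) - _D_C4_O4,
                wrap_angle(_fast_dihedral(c2, c3, c4, o4) - nus[3]),
                wrap_angle(_fast_dihedral(c3, c4, o4, c1) - nus[4]),
            ]
        )

    theta = np.asarray(theta0, float).copy()
    r = residuals(theta)
    for _ in range(40):
        if float(np.abs(r).max()) < 1e-11:
            break
        J = np.empty((3, 3))
        eps = 1e-6
        for j in range(3):
            tp = theta.copy()
            tp[j] += eps
            J[:, j] = (residuals(tp) - r) / eps
        try:
            step = np.linalg.solve(J, r)
        except np.linalg.LinAlgError:  # pragma: no cover
            step, *_ = np.linalg.lstsq(J, r, rcond=None)
        theta = theta - step
        r = residuals(theta)
    return _ring_from_internal(theta, nus[1], nus[2]), theta


@lru_cache(maxsize=8192)
def sugar_ring_coords(P: float, tau_m: float) -> np.ndarray:
    """Coordinates (5×3: O4', C1', C2', C3', C4') of a furanose ring whose
    measured pseudorotation equals (P, τm) to < 1e-6°.

    An outer fixed-point iteration corrects the cosine-law target torsions
    for the small closure-induced deviations.
    """
    if tau_m <= 0.0:
        raise BuildError("pucker amplitude must be positive")
    P = wrap_angle(P, -90.0 + 1e-12) if not (-90.0 < P <= 270.0) else P
    target = np.array([P, tau_m])
    guess = target.copy()
    theta0 = np.array([106.0, 102.0, 102.0])
    ring = None
    for _ in range(60):
        nus = torsions_from_phase(guess[0], guess[1])
        ring, theta0 = _solve_ring(nus, theta0)
        Pm, tm = phase_amplitude(_measure_ring(ring))
        err = np.array([wrap_angle(Pm - target[0]), tm - target[1]])
        if max(abs(err)) < 1e-8:
            break
        guess = guess - 0.9 * err
        guess[0] = wrap_angle(guess[0], guess[0] - 180.0)
    ring = ring - ring.mean(axis=0)
    ring.setflags(write=False)
    return ring


def _exocyclic_direction(
    apex: np.ndarray, n1: np.ndarray, n2: np.ndarray,
    ang1: float, ang2: float, sign: float,
) -> np.ndarray:
    """Unit vector from ``apex`` making angles ang1/ang2 (degrees) with the
    bonds apex→n1 and apex→n2; ``sign`` picks the out-of-plane solution
    (ring-face chirality)."""
    u1 = n1 - apex
    u1 = u1 / math.sqrt(u1 @ u1)
    u2 = n2 - apex
    u2 = u2 / math.sqrt(u2 @ u2)
    w = _cross(u1, u2)
    wn = math.sqrt(w @ w)
    if wn < 1e-9:
        raise BuildError("degenerate exocyclic geometry")
    w /= wn
    c1 = math.cos(math.radians(ang1))
    c2 = math.cos(math.radians(ang2))
    # d = a*u1 + b*u2 + c*w with d.u1 = c1, d.u2 = c2
    g = np.dot(u1, u2)
    det = 1.0 - g * g
    a = (c1 - g * c2) / det
    b = (c2 - g * c1) / det
    rem = 1.0 - (a * a + b * b + 2 * a * b * g)
    c = sign * math.sqrt(max(rem, 0.0))
    d = a * u1 + b * u2 + c * w
    return d / np.linalg.norm(d)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    # Rodrigues formula (cheaper than scipy Rotation for the hot path)
    x, y, z = axis / math.sqrt(axis @ axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


# Out-of-plane sign at C1' giving the natural D-nucleoside face; fixed by
# the chirality convention of _measure_ring / sugar_ring_coords.
_C1_FACE_SIGN = 1.0
_C4_FACE_SIGN = 1.0

_ANG_C3_C4_C5 = 115.7
_ANG_O4_C4_C5 = 109.4
_D_C4_C5 = 1.51
_D_C5_O5 = 1.44
_ANG_C4_C5_O5 = 110.2
_TOR_GAMMA = 38.0  # O5'-C5'-C4'-C3'
_D_O5_P = 1.595
_ANG_C5_O5_P = 120.9
_TOR_BETA = 205.0  # P-O5'-C5'-C4'


def _sugar_for_base(
    n_pos: np.ndarray,
    c1_dir: np.ndarray,
    base_atoms: dict[str, np.ndarray],
    base: str,
    P: float,
    tau_m: float,
    chi: float,
) -> dict[str, np.ndarray]:
    """Build ring + C5'/O5'/P attached to a placed base.

    ``n_pos`` is the glycosidic nitrogen position, ``c1_dir`` the unit
    direction N→C1' (from the base template), ``chi`` the target
    glycosidic torsion.
    """
    ring0 = np.array(sugar_ring_coords(round(P, 6), round(tau_m, 6)))
    o4, c1, c2, c3, c4 = ring0
    d = _exocyclic_direction(c1, o4, c2, _ANG_O4_C1_N, _ANG_C2_C1_N, _C1_FACE_SIGN)

    c1_target = n_pos + _GLYCO_BOND * c1_dir
    # Rotate the ring so its exocyclic direction at C1' points back at N.
    want = (n_pos - c1_target) / np.linalg.norm(n_pos - c1_target)
    v = _cross(d, want)
    s = math.sqrt(v @ v)
    cth = float(np.dot(d, want))
    if s < 1e-12:
        R0 = np.eye(3) if cth > 0 else _rotation_about_axis(
            _orthogonal(d), 180.0
        )
    else:
        R0 = _rotation_about_axis(v / s, math.degrees(math.atan2(s, cth)))
    ring = (ring0 - c1) @ R0.T + c1_target

    # Spin about the glycosidic bond to the requested chi (the rotation
    # sense depends on the axis orientation, so try both).
    cref = base_atoms[CHI_REF[base]]
    cur = _fast_dihedral(ring[0], ring[1], n_pos, cref) % 360.0
    axis = n_pos - c1_target
    delta = wrap_angle(chi - cur)
    for sign in (1.0, -1.0):
        R1 = _rotation_about_axis(axis, sign * delta)
        trial = (ring - c1_target) @ R1.T + c1_target
        got = _fast_dihedral(trial[0], trial[1], n_pos, cref) % 360.0
        if abs(wrap_angle(got - chi)) < 1e-6:
            ring = trial
            break
    else:  # pragma: no cover
        raise BuildError("failed to set glycosidic torsion")

    o4, c1, c2, c3, c4 = ring
    c5_dir = _exocyclic_direction(c4, c3, o4, _ANG_C3_C4_C5, _ANG_O4_C4_C5, _C4_FACE_SIGN)
    c5 = c4 + _D_C4_C5 * c5_dir
    o5 = _place_atom(c3, c4, c5, _D_C5_O5, _ANG_C4_C5_O5, _TOR_GAMMA)
    p = _place_atom(c4, c5, o5, _D_O5_P, _ANG_C5_O5_P, _TOR_BETA)
    return {
        "P": p,
        "O5'": o5,
        "C5'": c5,
        "C4'": c4,
        "O4'": o4,
        "C3'": c3,
        "C2'": c2,
        "C1'": c1,
    }


def _orthogonal(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    out = np.cross(v, w)
    return out / np.linalg.norm(out)


# ---------------------------------------------------------------------------
# Pair-frame placement
# ---------------------------------------------------------------------------


def _rz(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _pair_frame(step: int, spec: HelixParamsSpec) -> tuple[np.ndarray, np.ndarray]:
    R = _rz(step * spec.twist_per_step) @ _rx(spec.inclination)
    origin = _rz(step * spec.twist_per_step) @ np.array(
        [spec.x_displacement, 0.0, 0.0]
    ) + np.array([0.0, 0.0, step * spec.rise_per_step])
    return R, origin


def _placed_base(
    base: str, R: np.ndarray, origin: np.ndarray, flip: bool
) -> dict[str, np.ndarray]:
    M = R @ _FLIP if flip else R
    return {name: M @ xyz + origin for name, xyz in BASE_TEMPLATES[base].items()}


def _residue_atoms(
    base: str,
    placed_base: dict[str, np.ndarray],
    P: float,
    tau_m: float,
    chi: float,
) -> dict[str, np.ndarray]:
    n_name = GLYCO_N[base]
    n_pos = placed_base[n_name]
    c1_dir = placed_base["C1'"] - n_pos
    c1_dir /= np.linalg.norm(c1_dir)
    sugar = _sugar_for_base(n_pos, c1_dir, placed_base, base, P, tau_m, chi)
    atoms = dict(sugar)
    for name, xyz in placed_base.items():
        if name != "C1'":  # sugar provides the real C1'
            atoms[name] = xyz
    return atoms


def _pucker_and_chi(chemistry: str, spec: HelixParamsSpec) -> tuple[tuple[float, float], float]:
    if chemistry == "LNA":
        return LNA_PUCKER, spec.chi_north
    if spec.dna_pucker[0] <= 90.0:
        return spec.dna_pucker, spec.chi_north
    return spec.dna_pucker, spec.chi_dna


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def build_duplex(duplex: DuplexTarget, spec: Optional[HelixParamsSpec] = None) -> Structure:
    """Build an idealized straight-axis duplex fiber model.

    Chain W holds the purine strand 5'→3' (residues 1..n), chain C the
    pyrimidine strand 5'→3'; W residue i pairs C residue n+1−i.  LNA
    residues get locked north sugars, DNA residues the form's canonical
    pucker.
    """
    spec = spec or HelixParamsSpec.b_form()
    pur = duplex.purine_strand.nucleotides
    pyr = duplex.pyrimidine_strand.nucleotides
    if any(m.chemistry == TINA for m in duplex.purine_strand.monomers) or any(
        m.chemistry == TINA for m in duplex.pyrimidine_strand.monomers
    ):
        raise BuildError("TINA monomers have no 3D representation in duplex strands")
    n = len(pur)

    w_atoms: list[dict] = []
    c_atoms: dict[int, dict] = {}
    for i in range(1, n + 1):
        R, origin = _pair_frame(i - 1, spec)
        mono_w = pur[i - 1]
        mono_c = pyr[n - i]  # chain C residue n+1-i, stored 5'->3'
        if wc_complement(mono_w.base) != mono_c.base:
            raise BuildError(
                f"strands not complementary at purine-strand position {i}"
            )
        base_w = _placed_base(mono_w.base, R, origin, flip=False)
        base_c = _placed_base(mono_c.base, R, origin, flip=True)
        (pk_w, chi_w) = _pucker_and_chi(mono_w.chemistry, spec)
        (pk_c, chi_c) = _pucker_and_chi(mono_c.chemistry, spec)
        w_atoms.append(_residue_atoms(mono_w.base, base_w, *pk_w, chi_w))
        c_atoms[n + 1 - i] = _residue_atoms(mono_c.base, base_c, *pk_c, chi_c)

    asm = StructureAssembler()
    for i in range(1, n + 1):
        m = pur[i - 1]
        asm.add_residue("W", i, m.base, m.chemistry, m.protonated, w_atoms[i - 1])
    for j in range(1, n + 1):
        m = pyr[j - 1]
        asm.add_residue("C", j, m.base, m.chemistry, m.protonated, c_atoms[j])
    return asm.build(
        meta={
            "form": spec.form,
            "twist_per_step": spec.twist_per_step,
            "rise_per_step": spec.rise_per_step,
            "name": duplex.name,
        }
    )


# Hoogsteen third-strand placement: map the TFO pyrimidine template into
# the purine's frame so that N3(pyrimidine) sits 2.9 Å from N7(purine)
# along the major-groove direction, with the second contact (O4->N6 for
# T*A, N4->O6 for C+*G) aligned.  Computed once per triad type.
_HG_DISTANCE = 2.9


@lru_cache(maxsize=4)
def _hg_transform(purine: str) -> tuple[np.ndarray, np.ndarray]:
    pyrimidine = "T" if purine == "A" else "C"
    pu = BASE_TEMPLATES[purine]
    py = BASE_TEMPLATES[pyrimidine]
    second_pu = "N6" if purine == "A" else "O6"
    second_py = "O4" if purine == "A" else "N4"
    u = pu["N7"] - pu["C5"]
    u = u / np.linalg.norm(u)
    v = pu[second_pu] - pu["C6"]
    v = v / np.linalg.norm(v)
    t1 = pu["N7"] + _HG_DISTANCE * u
    t2 = pu[second_pu] + _HG_DISTANCE * v
    s1 = py["N3"]
    s2 = py[second_py]
    # In-plane rotation aligning s1->s2 with t1->t2, exact on the N3 contact.
    ang_t = math.atan2((t2 - t1)[1], (t2 - t1)[0])
    ang_s = math.atan2((s2 - s1)[1], (s2 - s1)[0])
    R = _rz(math.degrees(ang_t - ang_s))
    t = t1 - R @ s1
    return R, t


def build_triplex(
    duplex: DuplexTarget, tfo: Oligo, spec: Optional[HelixParamsSpec] = None
) -> Structure:
    """Build a parallel pyrimidine-motif triplex fiber model.

    The TFO is placed in the major groove with its 5' end at the 5' purine
    end of the binding site; every Hoogsteen N7-N3 distance is built below
    the pairing cutoff and TFO cytosines are protonated.
    """
    spec = spec or HelixParamsSpec.b_form()
    m = len(tfo)
    if duplex.binding_site is not None and m > duplex.binding_site[1] - duplex.binding_site[0] + 1:
        raise BuildError(
            f"TFO ({m} nt) is longer than the binding site {duplex.binding_site}"
        )
    try:
        site = find_tfo_binding_site(duplex, tfo)
    except NotationError as exc:
        raise BuildError(str(exc)) from None
    if site is None:
        raise BuildError(
            "TFO has no parallel Hoogsteen binding site on this duplex"
        )

    structure = build_duplex(duplex, spec)
    asm = StructureAssembler()
    for res in structure.residues:
        atoms = {
            name: structure.coords[row] for name, row in res.atom_rows.items()
        }
        asm.add_residue(res.chain, res.index, res.base, res.chemistry, res.protonated, atoms)

    for k, mono in enumerate(tfo.nucleotides, start=1):
        pos = site[0] + k - 1  # purine-strand partner
        R, origin = _pair_frame(pos - 1, spec)
        purine_base = duplex.purine_strand.sequence[pos - 1]
        Rh, th = _hg_transform(purine_base)
        placed = {
            name: R @ (Rh @ xyz + th) + origin
            for name, xyz in BASE_TEMPLATES[mono.base].items()
        }
        if mono.chemistry == "LNA":
            pucker, chi = LNA_PUCKER, spec.chi_north
        else:
            pucker, chi = NORTH_PUCKER, spec.chi_north
        atoms = _residue_atoms(mono.base, placed, *pucker, chi)
        protonated = mono.base == "C"
        asm.add_residue("T", k, mono.base, mono.chemistry, protonated, atoms)

    out = asm.build(meta={**structure.meta, "tfo_site_start": site[0]})
    return out


# ---------------------------------------------------------------------------
# Re-puckering an existing residue
# ---------------------------------------------------------------------------

_RING_NAMES = ("O4'", "C1'", "C2'", "C3'", "C4'")
_C4_ATTACHED = ("C5'", "O5'", "P")


def set_sugar_pucker(
    structure: Structure,
    chain: str,
    index: int,
    P: float,
    tau_m: float,
    inplace: bool = False,
) -> Structure:
    """Rebuild a residue's sugar ring at pseudorotation (P, τm).

    The base stays fixed; the ring is re-attached at the current glycosidic
    torsion and the C5'/O5'/P group rides rigidly on the C4' local frame.
    LNA residues reject south targets (the ring is conformationally
    locked).
    """
    res = structure.residue(chain, index)
    P_wrapped = wrap_angle(P, -90.0 + 1e-9)
    if res.chemistry == "LNA" and P_wrapped > 90.0:
        raise BuildError(
            f"locked nucleotide: LNA residue {chain}{index} cannot take a "
            f"south pucker (P={P:g})"
        )
    out = structure if inplace else structure.copy()
    coords = out.coords

    rows = res.atom_rows
    for name in _RING_NAMES:
        if name not in rows:
            raise AnalysisError(f"residue {chain}{index} missing ring atom {name!r}")
    n_name = GLYCO_N[res.base]
    cref_name = CHI_REF[res.base]
    n_pos = coords[rows[n_name]]
    cref = coords[rows[cref_name]]
    c1_old = coords[rows["C1'"]]
    o4_old = coords[rows["O4'"]]
    chi_cur = dihedral(o4_old, c1_old, n_pos, cref, low=0.0)
    c1_dir = c1_old - n_pos
    c1_dir /= np.linalg.norm(c1_dir)

    old_c4_frame = _local_frame(
        coords[rows["C4'"]], coords[rows["C3'"]], coords[rows["O4'"]]
    )

    base_atoms = {cref_name: cref}
    sugar = _sugar_for_base(n_pos, c1_dir, base_atoms, res.base, P, tau_m, chi_cur)
    for name in _RING_NAMES:
        coords[rows[name]] = sugar[name]

    new_c4_frame = _local_frame(sugar["C4'"], sugar["C3'"], sugar["O4'"])
    for name in _C4_ATTACHED:
        if name in rows:
            local = old_c4_frame[1].T @ (coords[rows[name]] - old_c4_frame[0])
            coords[rows[name]] = new_c4_frame[0] + new_c4_frame[1] @ local
    return out


def _local_frame(origin: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    e1 = p1 - origin
    e1 /= np.linalg.norm(e1)
    e2 = p2 - origin
    e2 = e2 - np.dot(e2, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return origin, np.column_stack([e1, e2, e3])
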