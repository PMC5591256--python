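"""Seeded synthetic trajectories with MD-snapshot-like statistics.

The generator does not integrate any dynamics; it emulates the statistical
structure that the analysis stages consume, on top of a built fiber model:

* per-residue two-state sugar repuckering — a stationary Markov chain over
  {north, south} with a per-chemistry north fraction (DNA prefers south,
  default f_N = 0.30; LNA is locked north, f_N = 1), realized each frame by
  rebuilding the ring at P drawn from N(17°, 5°) (north) or N(162°, 8°)
  (south), truncated to the respective bin;
* per-HG-pair two-state opening — a stationary Markov chain over
  {closed, open} with per-pair open probability; an open pair's TFO
  nucleotide is displaced rigidly by ``opening_displacement`` (default
  3 Å) along the groove-exit (radial) direction, carrying its N3 past the
  3.5 Å criterion;
* isotropic Gaussian positional noise (default σ = 0.15 Å) on every atom.

Frames are spaced 40 ps apart by convention.  The realized state series
are returned as :class:`GroundTruth`, and the emitted coordinates are kept
consistent with it: after noise is added, any monitored distance that
crossed the cutoff against its state is redrawn, so a persistence analysis
at the default cutoff recovers the ground truth exactly.  All randomness
flows from one seed; equal seeds give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np

from .builder import (
    BuildError,
    HelixParamsSpec,
    build_duplex,
    build_triplex,
    set_sugar_pucker,
)
from .oligo import DuplexTarget, Oligo, get_duplex, get_oligo
from .pairing import DEFAULT_CUTOFF, BasePair, pair_registry
from .structure import Structure, Trajectory

__all__ = [
    "TrajSpec",
    "GroundTruth",
    "Scenario",
    "generate",
    "preset_scenarios",
    "PRESETS",
]

NORTH_DRAW = (17.0, 5.0)  # mean, sd of P in the north state (degrees)
SOUTH_DRAW = (162.0, 8.0)
NORTH_TAU = {"DNA": 40.0, "LNA": 48.0}
SOUTH_TAU = 38.0
_P_QUANTUM = 0.25  # degrees; P draws snap to this grid (sugar-cache grid)


@dataclass(frozen=True)
class TrajSpec:
    """Statistical specification of a synthetic trajectory."""

    n_frames: int
    seed: int
    frame_interval: float = 40.0  # ps between snapshots
    noise_sigma: float = 0.15  # Å, isotropic positional noise
    f_north_dna: float = 0.30  # stationary north fraction of DNA sugars
    f_north_lna: float = 1.0  # LNA is conformationally locked
    flip_rate: float = 0.05  # pucker-chain switching scale per frame
    p_open: float = 0.02  # baseline stationary HG open probability
    open_rate: float = 0.05  # opening-chain switching scale per frame
    p_open_by_pair: Optional[dict[int, float]] = None  # TFO position -> p
    opening_displacement: float = 3.0  # Å, rigid TFO-nucleotide shift
    f_north_by_chain: Optional[dict[str, float]] = None  # chain overrides
    cutoff: float = DEFAULT_CUTOFF

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.f_north_dna <= 1.0:
            raise ValueError("f_north_dna must be in [0, 1]")
        if self.f_north_lna != 1.0:
            raise ValueError("LNA north fraction is locked at 1")
        probs = [self.flip_rate, self.open_rate, self.p_open]
        if self.p_open_by_pair:
            probs += list(self.p_open_by_pair.values())
        if self.f_north_by_chain:
            probs += list(self.f_north_by_chain.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if self.noise_sigma < 0 or self.opening_displacement <= 0:
            raise ValueError("invalid noise/displacement")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")


@dataclass
class GroundTruth:
    """Realized latent states: per-residue pucker and per-HG-pair opening."""

    residues: list[tuple[str, int]]  # (chain, index)
    north_states: np.ndarray  # (n_residues, n_frames) bool, True = north
    hg_pairs: list[BasePair]
    open_states: np.ndarray  # (n_hg_pairs, n_frames) bool, True = open

    def north_fraction(self) -> np.ndarray:
        return self.north_states.mean(axis=1)

    def open_fraction(self) -> np.ndarray:
        if self.open_states.size == 0:
            return np.zeros(0)
        return self.open_states.mean(axis=1)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"kind": "pucker", "key": f"{c}{i}", "fraction_north_or_open": f}
            for (c, i), f in zip(self.residues, self.north_fraction())
        ] + [
            {"kind": "opening", "key": p.label, "fraction_north_or_open": f}
            for p, f in zip(self.hg_pairs, self.open_fraction())
        ]
        return pd.DataFrame(rows)


def _markov_series(
    rng: np.random.Generator, n: int, p_state1: float, rate: float
) -> np.ndarray:
    """Two-state stationary Markov chain (True = state 1) with stationary
    probability ``p_state1`` and switching scale ``rate`` per frame."""
    if p_state1 >= 1.0:
        return np.ones(n, dtype=bool)
    if p_state1 <= 0.0:
        return np.zeros(n, dtype=bool)
    p01 = rate * p_state1  # 0 -> 1
    p10 = rate * (1.0 - p_state1)  # 1 -> 0
    out = np.empty(n, dtype=bool)
    u = rng.random(n)
    out[0] = u[0] < p_state1
    for t in range(1, n):
        out[t] = (u[t] < p01) if not out[t - 1] else (u[t] >= p10)
    return out


def _ring_is_north(coords: np.ndarray, rows: np.ndarray) -> bool:
    """Measured pucker class of a ring given atom rows (O4',C1',C2',C3',C4')."""
    from .builder import _measure_ring
    from .conformation import phase_amplitude

    P, _ = phase_amplitude(_measure_ring(coords[rows]))
    return P <= 90.0


def _draw_p(rng: np.random.Generator, north: bool) -> float:
    mean, sd = NORTH_DRAW if north else SOUTH_DRAW
    lo, hi = (-90.0, 90.0) if north else (90.0, 270.0)
    for _ in range(100):
        p = rng.normal(mean, sd)
        if lo < p <= hi:
            break
    else:  # pragma: no cover
        p = mean
    return round(p / _P_QUANTUM) * _P_QUANTUM


def generate(base: Structure, spec: TrajSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic trajectory on top of a built structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    residues = [(r.chain, r.index) for r in base.residues]
    n_res = len(residues)
    pairs = pair_registry(base)
    hg_pairs = [p for p in pairs if p.kind == "HG"]
    wc_pairs = [p for p in pairs if p.kind == "WC"]

    # Latent state series.
    north = np.empty((n_res, spec.n_frames), dtype=bool)
    for ri, r in enumerate(base.residues):
        if r.chemistry == "LNA":
            fN = 1.0
        else:
            fN = spec.f_north_dna
            if spec.f_north_by_chain and r.chain in spec.f_north_by_chain:
                fN = spec.f_north_by_chain[r.chain]
        north[ri] = _markov_series(rng, spec.n_frames, fN, spec.flip_rate)

    open_states = np.empty((len(hg_pairs), spec.n_frames), dtype=bool)
    for pi, p in enumerate(hg_pairs):
        p_open = spec.p_open
        if spec.p_open_by_pair and p.acceptor[1] in spec.p_open_by_pair:
            p_open = spec.p_open_by_pair[p.acceptor[1]]
        open_states[pi] = _markov_series(rng, spec.n_frames, p_open, spec.open_rate)

    # Monitored atom rows for the consistency redraw.
    def rows_of(plist):
        r1 = np.array(
            [base.atom_row(p.donor[0], p.donor[1], p.atoms[0]) for p in plist],
            dtype=int,
        )
        r2 = np.array(
            [base.atom_row(p.acceptor[0], p.acceptor[1], p.atoms[1]) for p in plist],
            dtype=int,
        )
        return r1, r2

    hg_r1, hg_r2 = rows_of(hg_pairs) if hg_pairs else (np.zeros(0, int), np.zeros(0, int))
    wc_r1, wc_r2 = rows_of(wc_pairs) if wc_pairs else (np.zeros(0, int), np.zeros(0, int))

    tfo_rows = {
        p.acceptor[1]: np.arange(
            base.residue("T", p.acceptor[1]).start,
            base.residue("T", p.acceptor[1]).stop,
        )
        for p in hg_pairs
    }

    coords_out = np.empty((spec.n_frames, base.n_atoms, 3))
    work = base.copy()
    # The base geometry of each residue is static across frames, so the
    # rebuilt sugar is a pure function of (residue, P, tau): memoize it.
    _movable = ("O4'", "C1'", "C2'", "C3'", "C4'", "C5'", "O5'", "P")
    movable_rows = [
        np.array([r.atom_rows[n] for n in _movable if n in r.atom_rows])
        for r in base.residues
    ]
    _ring = ("O4'", "C1'", "C2'", "C3'", "C4'")
    ring_rows = [
        np.array([r.atom_rows[n] for n in _ring]) for r in base.residues
    ]
    sugar_cache: dict[tuple[int, float, float], np.ndarray] = {}
    for f in range(spec.n_frames):
        work.coords[:] = base.coords

        for ri, r in enumerate(base.residues):
            is_north = bool(north[ri, f])
            P = _draw_p(rng, is_north)
            tau = NORTH_TAU[r.chemistry] if is_north else SOUTH_TAU
            key = (ri, P, tau)
            cached = sugar_cache.get(key)
            if cached is None:
                set_sugar_pucker(work, r.chain, r.index, P, tau, inplace=True)
                sugar_cache[key] = work.coords[movable_rows[ri]].copy()
            else:
                work.coords[movable_rows[ri]] = cached

        clean = work.coords.copy()
        for pi, p in enumerate(hg_pairs):
            if open_states[pi, f]:
                rows = tfo_rows[p.acceptor[1]]
                centroid = clean[rows].mean(axis=0)
                radial = np.array([centroid[0], centroid[1], 0.0])
                nrm = np.linalg.norm(radial)
                if nrm < 1e-9:
                    radial = np.array([1.0, 0.0, 0.0])
                    nrm = 1.0
                clean[rows] += spec.opening_displacement * radial / nrm

        noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)

        # Consistency redraw (1): measured pucker class must match the
        # latent state (ground truth is authoritative).
        if spec.noise_sigma > 0:
            for ri in range(n_res):
                rows = ring_rows[ri]
                want_north = bool(north[ri, f])
                for _ in range(200):
                    if _ring_is_north(noisy, rows) == want_north:
                        break
                    noisy[rows] = clean[rows] + rng.normal(
                        0.0, spec.noise_sigma, size=(5, 3)
                    )
                else:  # pragma: no cover
                    noisy[rows] = clean[rows]

        # Consistency redraw (2): monitored distances must agree with the
        # latent state at the analysis cutoff.
        for _ in range(200):
            bad_atoms: list[int] = []
            if len(hg_pairs):
                d = np.linalg.norm(noisy[hg_r1] - noisy[hg_r2], axis=1)
                should_open = open_states[:, f]
                viol = np.nonzero(should_open != (d >= spec.cutoff))[0]
                for v in viol:
                    bad_atoms += [hg_r1[v], hg_r2[v]]
            if len(wc_pairs):
                d = np.linalg.norm(noisy[wc_r1] - noisy[wc_r2], axis=1)
                viol = np.nonzero(d >= spec.cutoff)[0]
                for v in viol:
                    bad_atoms += [wc_r1[v], wc_r2[v]]
            if not bad_atoms:
                break
            bad = np.unique(bad_atoms)
            noisy[bad] = clean[bad] + rng.normal(
                0.0, spec.noise_sigma, size=(len(bad), 3)
            )
        else:  # pragma: no cover
            raise BuildError("could not reconcile noise with latent states")

        coords_out[f] = noisy

    traj = Trajectory(base, coords_out, frame_interval=spec.frame_interval)
    truth = GroundTruth(
        residues=residues,
        north_states=north,
        hg_pairs=hg_pairs,
        open_states=open_states,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Presets: desk-scale stand-ins for the simulated systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    name: str
    description: str
    duplex: DuplexTarget
    tfo: Optional[Oligo]
    helix_spec: HelixParamsSpec
    traj_spec: TrajSpec

    def build(self) -> Structure:
        if self.tfo is None:
            return build_duplex(self.duplex, self.helix_spec)
        return build_triplex(self.duplex, self.tfo, self.helix_spec)


def _dna_run_positions(tfo: Oligo, end: str) -> list[int]:
    """Nucleotide positions of the terminal all-DNA run at the 5' or 3'
    end of a mixmer TFO."""
    chems = tfo.chemistries
    n = len(chems)
    positions = []
    order = range(n - 1, -1, -1) if end == "3" else range(n)
    for i in order:
        if chems[i] == "DNA":
            positions.append(i + 1)
        else:
            break
    return sorted(positions)


PRESETS = {
    "3prime-reduced": "LNA-reduced 3' end: HG opening concentrated on the "
    "3' DNA-only TFO segment",
    "5prime-reduced": "LNA-reduced 5' end: mildly elevated HG opening at "
    "the 5' DNA-only TFO segment, no lasting loss",
    "lna-tfo": "alternating LNA/DNA TFO bound in the groove; TFO sugars "
    "all north, duplex DNA mixed",
    "triplex-stable": "fully stable triplex, near-zero opening",
    "hetero-duplex": "LNA/DNA hetero-duplex alone, built from an A-like "
    "low-inclination/low-roll (LirA) helix spec",
    "duplex-only": "unmodified homo-duplex alone, canonical B form",
}


def preset_scenarios(
    name: str, n_frames: int = 500, seed: int = 0
) -> Scenario:
    """Ready-to-run scenarios reproducing the qualitative signatures of
    the simulated systems at desk scale."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    b = HelixParamsSpec.b_form()
    base_spec = TrajSpec(n_frames=n_frames, seed=seed)

    if name == "3prime-reduced":
        duplex = get_duplex("c-MYC_DS19")
        tfo = get_oligo("ON3-3′LNA⦁reduced")
        overrides = {p: 0.85 for p in _dna_run_positions(tfo, "3")}
        spec = dc_replace(base_spec, p_open_by_pair=overrides)
    elif name == "5prime-reduced":
        duplex = get_duplex("c-MYC_DS19")
        tfo = get_oligo("ON3-5′LNA⦁reduced")
        overrides = {p: 0.30 for p in _dna_run_positions(tfo, "5")}
        spec = dc_replace(base_spec, p_open_by_pair=overrides)
    elif name == "lna-tfo":
        duplex = get_duplex("c-MYC_DS19")
        tfo = get_oligo("ON2")
        spec = dc_replace(base_spec, f_north_by_chain={"T": 1.0})
    elif name == "triplex-stable":
        duplex = get_duplex("c-MYC_DS19")
        tfo = get_oligo("ON2-5′DNA")
        spec = dc_replace(base_spec, p_open=0.01)
    elif name == "hetero-duplex":
        duplex = get_duplex("c-MYC_DS19Hetero")
        tfo = None
        b = HelixParamsSpec(
            form="LirA",
            twist_per_step=30.0,
            rise_per_step=3.2,
            x_displacement=-4.3,
        )
        spec = base_spec
    else:  # duplex-only
        duplex = get_duplex("c-MYC_DS19")
        tfo = None
        spec = base_spec

    return Scenario(
        name=name,
        description=PRESETS[name],
        duplex=duplex,
        tfo=tfo,
        helix_spec=b,
        traj_spec=spec,
    )
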