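"""Watson-Crick / Hoogsteen base-pair enumeration and persistence.

Pair maintenance is monitored through one heavy-atom distance per pair:
N1(purine)-N3(pyrimidine) for WC pairs and N7(purine)-N3(TFO pyrimidine)
for HG pairs.  A distance below the cutoff (default 3.5 Å) counts the pair
as hydrogen bonded in that frame.  ``lost_pairs`` applies a final-window
criterion: a pair is lost when its unpaired fraction over the last third
of the trajectory exceeds one half (both knobs configurable) — a stated,
reproducible version of reading persistence plots whose traces go blank.
No smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conformation import AnalysisError
from .oligo import hoogsteen_parallel_complement, wc_complement
from .structure import Structure, Trajectory

__all__ = [
    "BasePair",
    "PairPersistence",
    "LostPair",
    "pair_registry",
    "pair_distance",
    "persistence_matrix",
    "lost_pairs",
    "render_mosaic",
    "persistence_long_table",
    "occupancy_summary",
]

DEFAULT_CUTOFF = 3.5  # Å, heavy-atom hydrogen-bond criterion


@dataclass(frozen=True)
class BasePair:
    """One monitored base pair (WC or HG) and its distance atoms."""

    kind: str  # "WC" or "HG"
    donor: tuple[str, int]  # (chain, residue) purine side
    acceptor: tuple[str, int]  # (chain, residue) pyrimidine side
    atoms: tuple[str, str]  # atom on donor, atom on acceptor
    triad: Optional[str] = None  # "T*A" or "C+*G" for HG pairs

    @property
    def label(self) -> str:
        d, a = self.donor, self.acceptor
        base = f"{self.kind} {d[0]}{d[1]}-{a[0]}{a[1]}"
        return f"{base} ({self.triad})" if self.triad else base


def pair_registry(structure: Structure) -> list[BasePair]:
    """Enumerate the WC pairs of the duplex and, when a TFO chain is
    present, the HG pairs aligned to the binding site."""
    w_res = structure.residues_of("W")
    c_res = structure.residues_of("C")
    if not w_res or not c_res:
        raise AnalysisError("duplex chains W and C are required")
    n = len(w_res)
    if len(c_res) != n:
        raise AnalysisError("chains W and C differ in length")
    pairs: list[BasePair] = []
    for i in range(1, n + 1):
        rw = structure.residue("W", i)
        rc = structure.residue("C", n + 1 - i)
        if wc_complement(rw.base) != rc.base:
            raise AnalysisError(
                f"unpairable duplex position {i}: {rw.base} vs {rc.base}"
            )
        if rw.is_purine:
            pairs.append(
                BasePair("WC", ("W", i), ("C", n + 1 - i), ("N1", "N3"))
            )
        else:
            pairs.append(
                BasePair("WC", ("C", n + 1 - i), ("W", i), ("N1", "N3"))
            )

    t_res = structure.residues_of("T")
    if t_res:
        site_start = structure.meta.get("tfo_site_start")
        if site_start is None:
            site_start = _infer_site_start(structure, len(t_res))
        for k, rt in enumerate(t_res, start=1):
            pos = site_start + k - 1
            rw = structure.residue("W", pos)
            if not rw.is_purine:
                raise AnalysisError(
                    f"TFO residue {k} faces non-purine duplex position {pos}"
                )
            if rt.base == "T" and rw.base == "A":
                triad = "T*A"
            elif rt.base == "C" and rw.base == "G":
                if not rt.protonated:
                    raise AnalysisError(
                        f"HG cytosine T{k} must be protonated (C+*G triad)"
                    )
                triad = "C+*G"
            else:
                raise AnalysisError(
                    f"unpairable HG position {k}: {rt.base} over {rw.base}"
                )
            pairs.append(BasePair("HG", ("W", pos), ("T", k), ("N7", "N3"), triad))
    return pairs


def _infer_site_start(structure: Structure, m: int) -> int:
    purine_seq = "".join(r.base for r in structure.residues_of("W"))
    tfo_seq = "".join(r.base for r in structure.residues_of("T")).lower()
    hits = []
    for i in range(len(purine_seq) - m + 1):
        window = purine_seq[i : i + m]
        if all(b in "AG" for b in window):
            if hoogsteen_parallel_complement(window).sequence == tfo_seq:
                hits.append(i + 1)
    if len(hits) != 1:
        raise AnalysisError(
            "cannot infer a unique TFO binding site from the structure"
        )
    return hits[0]


def pair_distance(frame: Structure, pair: BasePair) -> float:
    """Euclidean distance (Å) between the pair's two ring nitrogens."""
    d_chain, d_idx = pair.donor
    a_chain, a_idx = pair.acceptor
    try:
        p1 = frame.xyz(d_chain, d_idx, pair.atoms[0])
        p2 = frame.xyz(a_chain, a_idx, pair.atoms[1])
    except KeyError as exc:
        raise AnalysisError(str(exc)) from None
    return float(np.linalg.norm(p1 - p2))


@dataclass
class PairPersistence:
    """Boolean pair×frame hydrogen-bond matrix plus the raw distances."""

    pairs: list[BasePair]
    matrix: np.ndarray  # (n_pairs, n_frames) bool
    distances: np.ndarray  # (n_pairs, n_frames) float
    cutoff: float
    frame_interval: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.matrix.shape != self.distances.shape or self.matrix.shape[0] != len(
            self.pairs
        ):
            raise ValueError("inconsistent persistence dimensions")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def fraction_paired(self) -> np.ndarray:
        """Per-pair fraction of frames with the hydrogen bond formed."""
        return self.matrix.mean(axis=1)

    def fraction_paired_per_frame(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def persistence_matrix(
    trajectory: Trajectory,
    pairs: Optional[Sequence[BasePair]] = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> PairPersistence:
    """Monitor every pair's distance over the trajectory; an entry is True
    iff the distance is below ``cutoff`` in that frame."""
    if trajectory.n_frames < 1:
        raise AnalysisError("empty trajectory")
    topo = trajectory.topology
    pairs = list(pairs) if pairs is not None else pair_registry(topo)
    rows1 = np.array(
        [topo.atom_row(p.donor[0], p.donor[1], p.atoms[0]) for p in pairs]
    )
    rows2 = np.array(
        [topo.atom_row(p.acceptor[0], p.acceptor[1], p.atoms[1]) for p in pairs]
    )
    diff = trajectory.coords[:, rows1, :] - trajectory.coords[:, rows2, :]
    dist = np.linalg.norm(diff, axis=2).T  # (n_pairs, n_frames)
    return PairPersistence(
        pairs=pairs,
        matrix=dist < cutoff,
        distances=dist,
        cutoff=cutoff,
        frame_interval=trajectory.frame_interval,
    )


@dataclass(frozen=True)
class LostPair:
    pair: BasePair
    unpaired_fraction: float
    end: str  # "5prime", "3prime" or "mid"


def lost_pairs(
    persistence: PairPersistence,
    window_fraction: float = 1.0 / 3.0,
    open_threshold: float = 0.5,
    kinds: Sequence[str] = ("HG",),
) -> list[LostPair]:
    """Pairs whose unpaired fraction over the final window exceeds the
    threshold, annotated with 5'/3'-end proximity along their strand."""
    F = persistence.n_frames
    if F < 3:
        raise AnalysisError("need at least 3 frames to assess pair loss")
    w = int(F * window_fraction)
    if w < 1:
        raise AnalysisError("final window is shorter than one frame")
    window = persistence.matrix[:, F - w :]
    unpaired = 1.0 - window.mean(axis=1)

    def strand_position(p: BasePair) -> tuple[str, int]:
        # HG pairs are located along the TFO strand; WC pairs along W.
        if p.kind == "HG":
            return p.acceptor
        return p.donor if p.donor[0] == "W" else p.acceptor

    by_strand: dict[str, list[int]] = {}
    for p in persistence.pairs:
        strand_chain, strand_idx = strand_position(p)
        by_strand.setdefault(strand_chain, []).append(strand_idx)

    lost: list[LostPair] = []
    for p, frac in zip(persistence.pairs, unpaired):
        if p.kind not in kinds or frac <= open_threshold:
            continue
        chain, idx = strand_position(p)
        indices = by_strand.get(chain, [idx])
        lo, hi = min(indices), max(indices)
        d5 = idx - lo
        d3 = hi - idx
        end = "5prime" if d5 < d3 else "3prime" if d3 < d5 else "mid"
        lost.append(LostPair(pair=p, unpaired_fraction=float(frac), end=end))
    return lost


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def persistence_long_table(persistence: PairPersistence) -> pd.DataFrame:
    """Long-format table: pair, frame, time_ps, distance, paired."""
    rows = []
    times = np.arange(persistence.n_frames) * persistence.frame_interval
    for i, p in enumerate(persistence.pairs):
        for f in range(persistence.n_frames):
            rows.append(
                {
                    "pair": p.label,
                    "kind": p.kind,
                    "frame": f,
                    "time_ps": times[f],
                    "distance": persistence.distances[i, f],
                    "paired": bool(persistence.matrix[i, f]),
                }
            )
    return pd.DataFrame(rows)


def occupancy_summary(persistence: PairPersistence) -> pd.DataFrame:
    """Per-pair hydrogen-bond occupancy and mean distance."""
    return pd.DataFrame(
        {
            "pair": [p.label for p in persistence.pairs],
            "kind": [p.kind for p in persistence.pairs],
            "occupancy": persistence.fraction_paired(),
            "mean_distance": persistence.distances.mean(axis=1),
        }
    )


def render_mosaic(persistence: PairPersistence, width: int = 100) -> str:
    """Text mosaic of the pair×time matrix: '#' hydrogen bonded, ' ' open
    (one row per pair, time left to right)."""
    F = persistence.n_frames
    cols = min(width, F)
    edges = np.linspace(0, F, cols + 1).astype(int)
    lines = []
    for i, p in enumerate(persistence.pairs):
        cells = []
        for c in range(cols):
            seg = persistence.matrix[i, edges[c] : max(edges[c + 1], edges[c] + 1)]
            cells.append("#" if seg.mean() >= 0.5 else " ")
        lines.append(f"{p.label:<24s}|{''.join(cells)}|")
    return "\n".join(lines)
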