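"""Structure-based alignment quality metrics.

Three indicators summarise how well a superfamily's multiple alignment
holds together:

* initial equivalences — alignment columns with a residue in every member
  (no gaps), the aligned common core;
* secondary-structural (SST) equivalences — gapless columns whose residues
  additionally share one secondary-structure state (H/E/C) in all members;
* RMSD — root-mean-square deviation of corresponding C-alpha atoms after
  optimal rigid-body superposition, reported both as the mean over member
  pairs and as the mean deviation from an iteratively refined consensus
  framework (each member is superposed onto the current mean structure at
  the equivalenced positions, the mean is recomputed, and the loop runs to
  convergence — the classic iterative multiple-superposition scheme).

Superpositions use the Kabsch algorithm: the SVD-based least-squares fit
restricted to proper rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import GAP, Superfamily


@dataclass
class Superposition:
    """Rigid motion mapping a mobile point set onto a reference: y -> R @ y + t."""

    rotation: np.ndarray   # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class QualityMetrics:
    superfamily_code: str
    n_initial_equivalences: int
    n_sst_equivalences: Optional[int]
    mean_pairwise_rmsd: Optional[float]
    consensus_rmsd: Optional[float]
    n_members_with_coords: int

    def to_dict(self) -> dict:
        return {
            "superfamily_code": self.superfamily_code,
            "n_initial_equivalences": self.n_initial_equivalences,
            "n_sst_equivalences": self.n_sst_equivalences,
            "mean_pairwise_rmsd": self.mean_pairwise_rmsd,
            "consensus_rmsd": self.consensus_rmsd,
            "n_members_with_coords": self.n_members_with_coords,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QualityMetrics":
        return cls(**d)


def _check_alignment(alignment: dict[str, str]) -> int:
    if not alignment:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment lengths {lengths}")
    return lengths.pop()


def gapless_columns(alignment: dict[str, str]) -> list[int]:
    """Indices of columns holding a residue in every member."""
    ncol = _check_alignment(alignment)
    rows = list(alignment.values())
    return [j for j in range(ncol) if all(r[j] != GAP for r in rows)]


def initial_equivalences(alignment: dict[str, str]) -> int:
    """Number of fully gapless alignment columns."""
    return len(gapless_columns(alignment))


def sst_equivalences(alignment: dict[str, str],
                     ss_map: dict[str, str]) -> int:
    """Gapless columns whose residues share one H/E/C state in all members."""
    _check_alignment(alignment)
    missing = set(alignment) - set(ss_map)
    if missing:
        raise ValueError(f"missing secondary structure for {sorted(missing)}")
    # per member: residue index at each column (cumulative non-gap count)
    states: dict[str, list[Optional[str]]] = {}
    for mid, row in alignment.items():
        ss = ss_map[mid]
        col_states: list[Optional[str]] = []
        ri = 0
        for ch in row:
            if ch == GAP:
                col_states.append(None)
            else:
                col_states.append(ss[ri])
                ri += 1
        if ri != len(ss):
            raise ValueError(
                f"{mid}: secondary-structure string length {len(ss)} does "
                f"not cover {ri} aligned residues")
        states[mid] = col_states
    count = 0
    for j in gapless_columns(alignment):
        column = {s[j] for s in states.values()}
        if len(column) == 1:
            count += 1
    return count


def kabsch_superpose(points_x: np.ndarray, points_y: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``points_y`` onto ``points_x``.

    Kabsch algorithm: centre both sets, take the SVD of the covariance
    matrix, and correct the sign of the smallest singular direction so the
    rotation is proper (no reflection).  Requires >= 3 points.
    """
    x = np.asarray(points_x, dtype=float)
    y = np.asarray(points_y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); "
                         f"got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise ValueError("superposition needs at least 3 points")
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    xc = x - cx
    yc = y - cy
    cov = yc.T @ xc
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = cx - R @ cy
    moved = y @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - x) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def consensus_superpose(
    members: dict[str, np.ndarray],
    alignment: dict[str, str],
    tol: float = 1e-6,
    max_iter: int = 50,
    return_history: bool = False,
):
    """Iterative superposition of all members onto a consensus framework.

    ``members`` maps member id to its full C-alpha trace; correspondence is
    taken at the columns gapless across all listed members.  The consensus
    is initialised from the lexicographically first member and refined by
    alternating member-onto-mean superposition with mean recomputation until
    the mean moves less than ``tol`` (Angstrom RMS) or ``max_iter`` rounds.

    Returns (per-member RMSD to the consensus, their average); with
    ``return_history`` also the per-iteration objective (total squared
    deviation to the mean), which is non-increasing.
    """
    if len(members) < 2:
        raise ValueError("consensus superposition needs >= 2 members")
    sub_alignment = {mid: alignment[mid] for mid in members}
    cols = gapless_columns(sub_alignment)
    if len(cols) < 3:
        raise ValueError(
            f"only {len(cols)} equivalenced positions; need >= 3")
    # per member: coordinates at the equivalenced columns
    equiv: dict[str, np.ndarray] = {}
    for mid, trace in members.items():
        trace = np.asarray(trace, dtype=float)
        row = sub_alignment[mid]
        residue_of_col = {}
        ri = 0
        for j, ch in enumerate(row):
            if ch != GAP:
                residue_of_col[j] = ri
                ri += 1
        if ri != len(trace):
            raise ValueError(f"{mid}: trace length {len(trace)} does not "
                             f"match {ri} residues in alignment row")
        equiv[mid] = trace[[residue_of_col[j] for j in cols]]

    order = sorted(equiv)
    mean = equiv[order[0]].copy()
    fitted = dict(equiv)
    history: list[float] = []
    for _ in range(max_iter):
        fitted = {mid: kabsch_superpose(mean, equiv[mid]).apply(equiv[mid])
                  for mid in order}
        new_mean = np.mean([fitted[mid] for mid in order], axis=0)
        history.append(consensus_objective(fitted))
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    per_member = {
        mid: float(np.sqrt(np.mean(np.sum((fitted[mid] - mean) ** 2, axis=1))))
        for mid in order
    }
    consensus_rmsd = float(np.mean(list(per_member.values())))
    if return_history:
        return per_member, consensus_rmsd, history
    return per_member, consensus_rmsd


def consensus_objective(fitted: dict[str, np.ndarray]) -> float:
    """Sum of squared deviations of fitted member coordinates to their mean;
    the quantity the consensus iteration drives downhill."""
    arr = np.array(list(fitted.values()))
    mean = arr.mean(axis=0)
    return float(np.sum((arr - mean) ** 2))


def pairwise_rmsds(members: dict[str, np.ndarray],
                   alignment: dict[str, str]) -> dict[tuple[str, str], float]:
    """Kabsch RMSD for every member pair, each at the columns gapless
    across that pair only (pairs see more columns than the full core)."""
    out: dict[tuple[str, str], float] = {}
    order = sorted(members)
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            pair_aln = {a: alignment[a], b: alignment[b]}
            cols = gapless_columns(pair_aln)
            if len(cols) < 3:
                continue
            pa = _coords_at(members[a], alignment[a], cols)
            pb = _coords_at(members[b], alignment[b], cols)
            out[(a, b)] = kabsch_superpose(pa, pb).rmsd
    return out


def _coords_at(trace: np.ndarray, row: str, cols: list[int]) -> np.ndarray:
    trace = np.asarray(trace, dtype=float)
    residue_of_col = {}
    ri = 0
    for j, ch in enumerate(row):
        if ch != GAP:
            residue_of_col[j] = ri
            ri += 1
    return trace[[residue_of_col[j] for j in cols]]


def quality_report(superfamily: Superfamily) -> QualityMetrics:
    """Assemble the quality metrics available for a superfamily.

    Equivalence counts always; SST equivalences only when every aligned
    member carries a secondary-structure string; RMSDs only when at least
    two members carry coordinates.
    """
    n_init = initial_equivalences(superfamily.alignment)
    ss_map = {m.member_id: m.ss_string for m in superfamily.members
              if m.ss_string is not None}
    n_sst = None
    if len(ss_map) == len(superfamily.members):
        n_sst = sst_equivalences(superfamily.alignment, ss_map)
    coords = {m.member_id: m.ca_trace for m in superfamily.members
              if m.ca_trace is not None}
    mean_pairwise = None
    consensus = None
    if len(coords) >= 2:
        prmsds = pairwise_rmsds(coords, superfamily.alignment)
        if prmsds:
            mean_pairwise = float(np.mean(list(prmsds.values())))
        try:
            _, consensus = consensus_superpose(coords, superfamily.alignment)
        except ValueError:
            consensus = None
    return QualityMetrics(
        superfamily_code=superfamily.code,
        n_initial_equivalences=n_init,
        n_sst_equivalences=n_sst,
        mean_pairwise_rmsd=mean_pairwise,
        consensus_rmsd=consensus,
        n_members_with_coords=len(coords),
    )
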