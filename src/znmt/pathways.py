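"""Metal-dissociation pathway analysis from CN matrices.

For every trajectory frame the Zn-S coordination number of each metal site is
computed over the full 20-Cys candidate set, giving a frames x sites CN
matrix.  A metal counts as free once its CN drops below 0.9 and stays below
for a persistence window of frames (the window guards against transient
re-crossings; W=1 reduces to first crossing).  The ordered metal ids of the
per-run events define the pathway; identical orders across runs are pooled
and their empirical probabilities reported — e.g. the first ion leaving from
the beta-domain in 70% of pulling runs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .colvars import SwitchingParams, cn_znS_defaults, switching
from .errors import ValidationError
from .topology import SiteTopology
from .trajio import Trajectory

__all__ = [
    "CNMatrix",
    "DissociationPathway",
    "build_cn_matrix",
    "detect_events",
    "classify_pathways",
    "species_ledger",
]

FREE_THRESHOLD = 0.9
DEFAULT_PERSISTENCE = 10


@dataclass
class CNMatrix:
    """Per-frame, per-metal coordination numbers."""

    values: np.ndarray  # (n_frames, n_metals)
    metal_ids: list[str]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("CN matrix must be 2-D (frames x metals)")
        if self.values.shape[1] != len(self.metal_ids):
            raise ValidationError("metal id count does not match matrix width")
        if np.any(self.values < 0):
            raise ValidationError("CN values must be non-negative")
        if self.times is None:
            self.times = np.arange(self.values.shape[0], dtype=float)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class DissociationPathway:
    """Ordered dissociation events of one run."""

    events: list[tuple[str, int]]  # (metal_id, event_frame)
    run_id: int | str | None = None
    tied_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [f for _, f in self.events]
        if any(b < a for a, b in zip(frames, frames[1:])):
            raise ValidationError("event frames must be non-decreasing")
        metals = [m for m, _ in self.events]
        if len(set(metals)) != len(metals):
            raise ValidationError("a metal may dissociate at most once")

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.events)


def build_cn_matrix(
    traj: Trajectory,
    topo: SiteTopology,
    params: SwitchingParams | None = None,
) -> CNMatrix:
    """CN of every metal over the full candidate ligand set, every frame.

    Candidate ligands are *all* Cys S-gamma atoms in the topology (the matrix
    records every possible Zn-S contact, not just the initially bound set).
    """
    params = params or cn_znS_defaults()
    ligand_ids = topo.ligand_ids
    try:
        metal_idx = [traj.atom_index(m) for m in topo.metal_ids]
        ligand_idx = [traj.atom_index(l) for l in ligand_ids]
    except ValidationError as exc:
        raise ValidationError(f"trajectory does not cover topology atoms: {exc}")
    metals = traj.coords[:, metal_idx, :]      # (F, M, 3)
    ligands = traj.coords[:, ligand_idx, :]    # (F, L, 3)
    d = np.linalg.norm(metals[:, :, None, :] - ligands[:, None, :, :], axis=-1)
    cn = switching(d, params).sum(axis=2)
    return CNMatrix(values=cn, metal_ids=list(topo.metal_ids), times=traj.times)


def detect_events(
    cn: CNMatrix,
    threshold: float = FREE_THRESHOLD,
    window: int = DEFAULT_PERSISTENCE,
    run_id: int | str | None = None,
) -> DissociationPathway:
    """First frame from which each metal's CN stays below ``threshold`` for
    at least ``window`` consecutive frames; metals that never dissociate are
    absent.  Ties (same event frame) are broken by metal id and flagged."""
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    if window < 1:
        raise ValidationError("persistence window must be >= 1")
    if cn.n_frames == 0:
        raise ValidationError("empty CN matrix")
    events: list[tuple[str, int]] = []
    below = cn.values < threshold
    for j, metal in enumerate(cn.metal_ids):
        col = below[:, j]
        if window > cn.n_frames:
            continue
        runlen = np.convolve(col.astype(int), np.ones(window, dtype=int), "valid")
        hits = np.nonzero(runlen == window)[0]
        if hits.size:
            events.append((metal, int(hits[0])))
    events.sort(key=lambda e: (e[1], e[0]))
    frame_counts = Counter(f for _, f in events)
    ties = sorted(f for f, c in frame_counts.items() if c > 1)
    return DissociationPathway(events=events, run_id=run_id, tied_frames=ties)


def classify_pathways(runs: list[DissociationPathway]) -> dict[tuple[str, ...], float]:
    """Empirical probability of each distinct metal-id order.

    Pathway identity is the order alone (kinetics are ignored); probabilities
    are counts over the total and sum to 1.
    """
    if not runs:
        raise ValidationError("at least one run is required")
    counts = Counter(p.order for p in runs)
    total = len(runs)
    return {
        order: counts[order] / total
        for order in sorted(counts, key=lambda o: (-counts[o], o))
    }


def species_ledger(
    path: DissociationPathway, topo: SiteTopology
) -> list[tuple[int, int, int]]:
    """Occupancy ledger along a pathway: (n_bound, alpha_count, beta_count)
    after each event, starting from full occupancy.

    E.g. a Zn7 start whose first event is a beta metal gives a second entry
    (6, 4, 2) — the Zn6 species with 4 alpha + 2 beta ions.
    """
    domains = {m: topo.metal_domain(m) for m in topo.metal_ids}
    bound = set(topo.metal_ids)

    def entry() -> tuple[int, int, int]:
        alpha = sum(1 for m in bound if domains[m] == "alpha")
        beta = sum(1 for m in bound if domains[m] == "beta")
        return (len(bound), alpha, beta)

    ledger = [entry()]
    for metal, _ in path.events:
        if metal not in bound:
            raise ValidationError(f"event metal {metal!r} not in topology or repeated")
        bound.discard(metal)
        ledger.append(entry())
    return ledger


def pathway_table_json(probs: dict[tuple[str, ...], float],
                       path: str | Path) -> None:
    """Persist a classify_pathways result as JSON."""
    payload = [
        {"order": list(order), "probability": p} for order, p in probs.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
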