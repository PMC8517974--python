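"""Synthetic inputs with known ground truth for every pipeline stage.

Everything downstream (pathway detection, rupture-force statistics,
metadynamics free energies, per-Cys label fractions) is exercised on data
generated here: scripted coordination-number decays rendered as coordinates,
sawtooth force-extension curves, Langevin toy trajectories, and peptide
label tables drawn from a known per-Cys occupancy vector.  All generators
are pure functions of (parameters, seed); per-run streams are derived from
``SeedSequence(seed, spawn_key=(run,))`` so each run is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import topology as topo_mod
from .colvars import (SwitchingParams, cn_znS_defaults, inverse_switching,
                      switching)
from .dynamics import ToySystem, langevin_trajectory  # noqa: F401 (re-export)
from .errors import ValidationError
from .trajio import AtomLabel, Trajectory

__all__ = [
    "DissociationScript",
    "LabelTruth",
    "ToySystem",
    "langevin_trajectory",
    "make_star_topology",
    "gen_dissociation_runs",
    "gen_smd_curve",
    "tryptic_peptides",
    "gen_peptide_table",
]

#: tetrahedral unit vectors for placing a metal's four dedicated ligands
_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)

#: metal-site spacing (Å); far enough that cross-site switching
#: contributions are < 1e-11 for the Zn-S defaults
_SITE_SPACING = 200.0


@dataclass
class DissociationScript:
    """Scripted CN decay for one ensemble of runs.

    ``events`` is the ordered list of (metal_id, event_frame); the event
    frame is where the noiseless CN profile first drops below ``threshold``.
    The decay is logistic with half-width ``transition_width`` frames from
    ``cn_bound`` (~4, a full ZnCys4 site) to ``cn_free`` (~0).
    """

    events: list[tuple[str, int]]
    n_frames: int = 500
    cn_bound: float = 4.0
    cn_free: float = 0.0
    transition_width: float = 5.0
    noise_sd: float = 0.0
    threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        frames = [f for _, f in self.events]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError("event frames must be strictly increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if not 0.0 <= self.cn_free < self.threshold < self.cn_bound <= 4.0:
            raise ValidationError(
                "need cn_free < threshold < cn_bound and CN within [0, 4]"
            )
        if any(not 0 <= f < self.n_frames for f in frames):
            raise ValidationError("event frames must lie within the run")

    def cn_profile(self, metal_id: str) -> np.ndarray:
        """Noiseless CN time series for one metal (constant cn_bound if the
        metal never dissociates)."""
        t = np.arange(self.n_frames, dtype=float)
        for mid, frame in self.events:
            if mid == metal_id:
                w = self.transition_width
                amp = self.cn_bound - self.cn_free
                # centre the logistic so the profile crosses `threshold`
                # between frames (frame-1) and frame
                t_mid = (frame - 0.5) - w * math.log(
                    amp / (self.threshold - self.cn_free) - 1.0
                )
                return self.cn_free + amp / (1.0 + np.exp((t - t_mid) / w))
        return np.full(self.n_frames, self.cn_bound)


def make_star_topology(n_metals: int = 5,
                       sequence: str | None = None) -> topo_mod.SiteTopology:
    """Dedicated-ligand topology for scripted trajectories: each metal owns
    four Cys (no bridging), so per-metal CN values can be realised
    geometrically and independently.  At most 5 metals fit the 20 Cys."""
    seq = sequence or topo_mod.default_sequence()
    cys = topo_mod.cys_positions(seq)
    if not 1 <= n_metals <= len(cys) // 4:
        raise ValidationError(
            f"n_metals must be in 1..{len(cys) // 4} for {len(cys)} Cys"
        )
    ligand_map = {
        f"Zn{i + 1}": {f"SG{r}" for r in cys[4 * i: 4 * i + 4]}
        for i in range(n_metals)
    }
    return topo_mod.SiteTopology(
        metal_ids=[f"Zn{i + 1}" for i in range(n_metals)],
        ligand_map=ligand_map,
        residue_index_of={f"SG{r}": r for r in cys},
        sequence_length=len(seq),
    )


def gen_dissociation_runs(
    script: DissociationScript,
    n_runs: int,
    topo: topo_mod.SiteTopology | None = None,
    params: SwitchingParams | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Render scripted CN decays as coordinate trajectories.

    Each metal sits at a fixed site centre with its four dedicated ligands on
    tetrahedral rays at the distance whose switching value realises the
    scripted per-ligand contribution; unassigned Cys are parked far from every
    site.  Returns the trajectories and a truth table with columns
    (run, metal_id, event_frame).
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    topo = topo or make_star_topology()
    params = params or cn_znS_defaults()
    for mid, _ in script.events:
        if mid not in topo.metal_ids:
            raise ValidationError(f"scripted metal {mid!r} not in topology")

    ligand_ids = topo.ligand_ids
    metal_ids = list(topo.metal_ids)
    atoms = [AtomLabel(m, int("".join(ch for ch in m if ch.isdigit()) or i + 1), "Zn")
             for i, m in enumerate(metal_ids)]
    atoms += [AtomLabel(l, topo.residue_index_of[l], "S") for l in ligand_ids]
    site_centre = {m: np.array([_SITE_SPACING * i, 0.0, 0.0])
                   for i, m in enumerate(metal_ids)}
    owned = {m: sorted(topo.ligand_map[m]) for m in metal_ids}
    owner_of = {l: m for m, ligs in owned.items() for l in ligs}
    far = np.array([0.0, 0.0, -10.0 * _SITE_SPACING])

    profiles = {m: script.cn_profile(m) for m in metal_ids}
    # CN -> distance inversion via a table uniform in r (where the switching
    # function is smooth); interpolating the inverse through exact (s, r)
    # nodes keeps the reconstructed CN accurate to ~1e-6 at every contrast
    r_far = inverse_switching(2.5e-7, params)
    r_table = np.linspace(params.d0, r_far, 30001)
    s_table = switching(r_table, params)

    trajectories: list[Trajectory] = []
    rows = []
    for run in range(n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=script.seed, spawn_key=(run,))
        )
        coords = np.empty((script.n_frames, len(atoms), 3))
        for mi, m in enumerate(metal_ids):
            cn = profiles[m].copy()
            if script.noise_sd > 0:
                cn = cn + rng.normal(0.0, script.noise_sd, size=cn.shape)
            cn = np.clip(cn, 1e-6, 4.0)
            r = np.interp(-cn / 4.0, -s_table, r_table)
            centre = site_centre[m]
            coords[:, mi, :] = centre
            for k, lig in enumerate(owned[m]):
                li = len(metal_ids) + ligand_ids.index(lig)
                coords[:, li, :] = centre + r[:, None] * _TETRAHEDRON[k]
        for li, lig in enumerate(ligand_ids):
            if lig not in owner_of:
                coords[:, len(metal_ids) + li, :] = far + [5.0 * li, 0.0, 0.0]
        trajectories.append(Trajectory(atoms=list(atoms), coords=coords))
        for mid, frame in script.events:
            rows.append({"run": run, "metal_id": mid, "event_frame": frame})
    truth = pd.DataFrame(rows, columns=["run", "metal_id", "event_frame"])
    return trajectories, truth


def gen_smd_curve(
    true_ruptures: list[tuple[float, float]],
    k: float = 3.0,
    v: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 2000,
    ext_start: float = 0.0,
    ext_end: float | None = None,
    baseline: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sawtooth force-extension curve with known rupture peaks.

    Force rises linearly from ``baseline`` (pN) to each scripted peak and
    drops sharply after it — the sawtooth pattern of multi-step metal-cluster
    rupture.  ``k`` (kcal/mol/Å², recorded as metadata) and ``v`` (Å/ns) set
    the time axis via t = extension / v.  Returns (force log DataFrame with
    columns time_ns/extension_A/force_pN, truth DataFrame with the on-grid
    peak positions and forces).
    """
    if not true_ruptures:
        raise ValidationError("at least one rupture is required")
    exts = [e for e, _ in true_ruptures]
    if any(b <= a for a, b in zip(exts, exts[1:])) or exts[0] <= ext_start:
        raise ValidationError("rupture extensions must be increasing")
    if any(f <= 0 for _, f in true_ruptures):
        raise ValidationError("rupture forces must be positive")
    if ext_end is None:
        ext_end = exts[-1] * 1.1
    x = np.linspace(ext_start, ext_end, n_points)
    force = np.full_like(x, baseline)
    truth_rows = []
    prev = ext_start
    for e, f_peak in true_ruptures:
        seg = (x > prev) & (x <= e)
        if not np.any(seg):
            raise ValidationError("grid too coarse to resolve a rupture segment")
        x_seg = x[seg]
        x_top = x_seg[-1]
        force[seg] = baseline + (f_peak - baseline) * (x_seg - prev) / (x_top - prev)
        truth_rows.append({"extension_A": x_top, "force_pN": f_peak})
        prev = e
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    df = pd.DataFrame(
        {"time_ns": x / v, "extension_A": x, "force_pN": force}
    )
    df.attrs["k_kcal_mol_A2"] = k
    df.attrs["v_A_ns"] = v
    return df, pd.DataFrame(truth_rows)


def tryptic_peptides(sequence: str) -> list[tuple[int, int]]:
    """1-based inclusive spans of a simple tryptic digest (cut after K/R)."""
    spans = []
    start = 1
    for i, aa in enumerate(sequence, start=1):
        if aa in "KR":
            spans.append((start, i))
            start = i + 1
    if start <= len(sequence):
        spans.append((start, len(sequence)))
    return spans


@dataclass
class LabelTruth:
    """Ground-truth per-Cys Zn-bound fraction, realised as NEM share.

    In the dual-label scheme free thiols carry IAM and Zn-protected thiols
    (labelled after metal removal) carry NEM, so a Cys with bound fraction f
    shows NEM:IAM abundance f : (1-f).  ``noise_sd`` is the sd of the
    multiplicative log-normal intensity noise; ``n_replicates`` emulates
    repeated peptide observations (charge states, injections).
    """

    bound_fraction: dict[int, float]
    sequence: str = field(default_factory=topo_mod.default_sequence)
    abundance_scale: float = 1e6
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        cys = set(topo_mod.cys_positions(self.sequence))
        for pos, f in self.bound_fraction.items():
            if pos not in cys:
                raise ValidationError(f"position {pos} is not a Cys")
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"bound fraction at Cys{pos} outside [0, 1]")
        missing = cys - set(self.bound_fraction)
        if missing:
            raise ValidationError(f"no bound fraction for Cys {sorted(missing)}")
        covered = set()
        for a, b in tryptic_peptides(self.sequence):
            covered |= {p for p in cys if a <= p <= b}
        if covered != cys:
            raise ValidationError("tryptic digest does not cover every Cys")


def gen_peptide_table(truth: LabelTruth) -> pd.DataFrame:
    """Peptide abundance table with columns start, end, cys_position, label,
    abundance.  Expected per-Cys NEM share equals the truth vector."""
    rng = np.random.default_rng(truth.seed)
    rows = []
    spans = tryptic_peptides(truth.sequence)
    cys = topo_mod.cys_positions(truth.sequence)
    for (a, b) in spans:
        for pos in cys:
            if not a <= pos <= b:
                continue
            f = truth.bound_fraction[pos]
            for _ in range(truth.n_replicates):
                for label, share in (("NEM", f), ("IAM", 1.0 - f)):
                    if share <= 0.0:
                        continue
                    noise = (
                        math.exp(rng.normal(0.0, truth.noise_sd))
                        if truth.noise_sd > 0 else 1.0
                    )
                    rows.append(
                        {
                            "start": a,
                            "end": b,
                            "cys_position": pos,
                            "label": label,
                            "abundance": truth.abundance_scale * share * noise,
                        }
                    )
    return pd.DataFrame(rows, columns=["start", "end", "cys_position",
                                       "label", "abundance"])
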