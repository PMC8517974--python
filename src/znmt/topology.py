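"""Metal-binding architecture of metallothionein-2.

MT2 folds into two metal-thiolate cluster domains: the N-terminal beta-domain
(residues 1-30) holds a Zn3Cys9 cluster, the C-terminal alpha-domain
(residues 31-61) a Zn4Cys11 cluster.  Within a cluster a Cys sulfur either
*bridges* two metals (degree 2 in the bipartite metal-ligand graph) or is a
*terminal* donor for one metal (degree 1).  With every metal tetrahedrally
coordinated the bridging/terminal split is fixed by the composition alone:

    2*b + t = coord * n_metals        (edge count)
    b + t   = n_ligands               (ligand count)

so b = coord*n_metals - n_ligands and t = 2*n_ligands - coord*n_metals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    InfeasibleStoichiometryError,
    InvalidClusterError,
    InvalidOccupancyError,
    ValidationError,
)

DEFAULT_DOMAIN_BOUNDS: dict[str, tuple[int, int]] = {
    "beta": (1, 30),
    "alpha": (31, 61),
}


def read_fasta_sequence(path: str | Path) -> str:
    """Return the first sequence in a FASTA file as an upper-case string."""
    seq_lines: list[str] = []
    with open(path) as fh:
        seen_header = False
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if seen_header:
                    break
                seen_header = True
                continue
            seq_lines.append(line)
    if not seq_lines:
        raise ValidationError(f"no sequence found in {path}")
    return "".join(seq_lines).upper()


def default_sequence() -> str:
    """The packaged 61-residue, 20-Cys human MT2 sequence."""
    return read_fasta_sequence(Path(__file__).parent / "data" / "mt2.fasta")


def cys_positions(sequence: str) -> list[int]:
    """1-based positions of Cys residues."""
    return [i + 1 for i, aa in enumerate(sequence) if aa == "C"]


@dataclass
class SiteTopology:
    """Metal sites and their candidate ligand atoms (Cys S-gamma).

    Parameters
    ----------
    metal_ids
        Identifiers of the metal sites, e.g. ``["Zn1", ..., "Zn7"]``.
    ligand_map
        Metal-site id -> set of candidate ligand-atom ids.
    residue_index_of
        Ligand-atom id -> 1-based residue index in the chain.
    domain_bounds
        Domain name -> inclusive ``(start, end)`` residue interval.
    sequence_length
        Declared chain length; the domain intervals must tile ``1..length``.
    """

    metal_ids: list[str]
    ligand_map: dict[str, set[str]]
    residue_index_of: dict[str, int]
    domain_bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_BOUNDS)
    )
    sequence_length: int = 61

    def __post_init__(self) -> None:
        self.domain_bounds = {k: (int(a), int(b)) for k, (a, b) in self.domain_bounds.items()}
        covered: set[int] = set()
        for name, (a, b) in self.domain_bounds.items():
            if a > b:
                raise ValidationError(f"domain {name!r}: empty interval {a}-{b}")
            interval = set(range(a, b + 1))
            if interval & covered:
                raise ValidationError(f"domain {name!r} overlaps another domain")
            covered |= interval
        if covered != set(range(1, self.sequence_length + 1)):
            raise ValidationError(
                "domain intervals must cover residues 1.."
                f"{self.sequence_length} exactly"
            )
        for mid in self.metal_ids:
            if not self.ligand_map.get(mid):
                raise ValidationError(f"metal site {mid!r} lists no candidate ligand")
        for mid, ligs in self.ligand_map.items():
            for lig in ligs:
                if lig not in self.residue_index_of:
                    raise ValidationError(f"ligand {lig!r} has no residue index")

    @property
    def ligand_ids(self) -> list[str]:
        """All ligand-atom ids, sorted by residue index then id."""
        return sorted(self.residue_index_of, key=lambda k: (self.residue_index_of[k], k))

    def domain_of(self, residue_index: int) -> str:
        """Domain name for a 1-based residue index (beta: 1-30, alpha: 31-61)."""
        if not 1 <= residue_index <= self.sequence_length:
            raise ValidationError(
                f"residue index {residue_index} outside 1..{self.sequence_length}"
            )
        for name, (a, b) in self.domain_bounds.items():
            if a <= residue_index <= b:
                return name
        raise ValidationError(f"residue {residue_index} not covered by any domain")

    def metal_domain(self, metal_id: str) -> str:
        """Domain a metal site belongs to: majority domain of its candidate
        ligands (ties broken toward beta, the N-terminal domain)."""
        ligs = self.ligand_map[metal_id]
        tally = Counter(self.domain_of(self.residue_index_of[l]) for l in ligs)
        best = max(tally.values())
        winners = sorted(name for name, n in tally.items() if n == best)
        return "beta" if "beta" in winners else winners[0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteTopology":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            metal_ids=list(raw["metal_ids"]),
            ligand_map={m: set(v) for m, v in raw["ligand_map"].items()},
            residue_index_of={k: int(v) for k, v in raw["residue_index_of"].items()},
            domain_bounds={k: tuple(v) for k, v in raw.get(
                "domain_bounds", DEFAULT_DOMAIN_BOUNDS
            ).items()},
            sequence_length=int(raw.get("sequence_length", 61)),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "metal_ids": list(self.metal_ids),
            "ligand_map": {m: sorted(v) for m, v in self.ligand_map.items()},
            "residue_index_of": dict(self.residue_index_of),
            "domain_bounds": {k: list(v) for k, v in self.domain_bounds.items()},
            "sequence_length": self.sequence_length,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def domain_of(residue_index: int, bounds: Mapping[str, tuple[int, int]] | None = None,
              sequence_length: int = 61) -> str:
    """Module-level convenience: domain of a residue under the MT2 bounds."""
    bounds = dict(bounds or DEFAULT_DOMAIN_BOUNDS)
    if not 1 <= residue_index <= sequence_length:
        raise ValidationError(f"residue index {residue_index} outside 1..{sequence_length}")
    for name, (a, b) in bounds.items():
        if a <= residue_index <= b:
            return name
    raise ValidationError(f"residue {residue_index} not covered by any domain")


@dataclass
class ClusterGraph:
    """Bipartite metal <-> thiolate-ligand graph of one cluster.

    ``edges`` are (metal_id, ligand_id) pairs.  Every metal must reach its
    coordination number (default 4, tetrahedral Zn/Cd); every ligand serves
    one or two metals.
    """

    edges: list[tuple[str, str]]
    coordination_number: int = 4

    def __post_init__(self) -> None:
        self.edges = [(str(m), str(l)) for m, l in self.edges]
        if len(set(self.edges)) != len(self.edges):
            raise InvalidClusterError("duplicate metal-ligand edge")
        metal_deg = Counter(m for m, _ in self.edges)
        ligand_deg = Counter(l for _, l in self.edges)
        for m, d in metal_deg.items():
            if d != self.coordination_number:
                raise InvalidClusterError(
                    f"metal {m!r} has degree {d}, expected {self.coordination_number}"
                )
        for l, d in ligand_deg.items():
            if d > 2:
                raise InvalidClusterError(f"ligand {l!r} bridges {d} metals (max 2)")

    @property
    def metals(self) -> list[str]:
        return sorted({m for m, _ in self.edges})

    @property
    def ligands(self) -> list[str]:
        return sorted({l for _, l in self.edges})

    def ligand_degrees(self) -> Counter:
        return Counter(l for _, l in self.edges)


def classify_ligands(graph: ClusterGraph) -> dict[str, int]:
    """Count bridging (degree-2) and terminal (degree-1) thiolates.

    The alpha Zn4Cys11 cluster has five bridging and six terminal donors;
    the beta Zn3Cys9 cluster has three bridging and six terminal donors.
    """
    degs = graph.ligand_degrees()
    bridging = sum(1 for d in degs.values() if d == 2)
    terminal = sum(1 for d in degs.values() if d == 1)
    return {"bridging": bridging, "terminal": terminal}


def solve_stoichiometry(n_metals: int, n_ligands: int, coord: int = 4) -> dict[str, int]:
    """Closed-form bridging/terminal split for an M_x(Cys)_y cluster.

    Solves ``2b + t = coord*n_metals`` and ``b + t = n_ligands``.
    """
    if n_metals < 0 or n_ligands < 0 or coord <= 0:
        raise ValidationError("counts must be non-negative and coord positive")
    bridging = coord * n_metals - n_ligands
    terminal = 2 * n_ligands - coord * n_metals
    if bridging < 0 or terminal < 0:
        raise InfeasibleStoichiometryError(
            f"no valid cluster with {n_metals} metals, {n_ligands} ligands, "
            f"coordination {coord}"
        )
    return {"bridging": bridging, "terminal": terminal}


def free_cys_count(total_cys: int, occupancy: Iterable[ClusterGraph]) -> int:
    """Number of Cys not engaged in any cluster.

    One ZnCys4 site on the 20-Cys protein leaves 16 Cys free (the species the
    IAM-labelling profile centres on at 1 Zn(II) equivalent).
    """
    occupied: set[str] = set()
    for graph in occupancy:
        ligs = set(graph.ligands)
        clash = occupied & ligs
        if clash:
            raise InvalidOccupancyError(
                f"ligand(s) {sorted(clash)} shared between clusters"
            )
        occupied |= ligs
    if len(occupied) > total_cys:
        raise ValidationError(
            f"{len(occupied)} occupied ligands exceed total_cys={total_cys}"
        )
    return total_cys - len(occupied)


def _ring_cluster(metal_ids: Sequence[str], ligand_ids: Sequence[str],
                  n_bridges: int, coord: int = 4) -> ClusterGraph:
    """Construct one valid cluster graph with the requested composition.

    Bridges are laid along a metal cycle (plus chords when more bridges than
    cycle edges are needed); terminals fill each metal up to ``coord``.
    """
    n_m, n_l = len(metal_ids), len(ligand_ids)
    expect = solve_stoichiometry(n_m, n_l, coord)
    if expect["bridging"] != n_bridges:
        raise InfeasibleStoichiometryError(
            f"{n_m} metals / {n_l} ligands at coordination {coord} force "
            f"{expect['bridging']} bridges, not {n_bridges}"
        )
    pairs: list[tuple[str, str]] = []
    if n_m == 1:
        if n_bridges:
            raise InfeasibleStoichiometryError("single metal cannot bridge")
    else:
        cycle = [(metal_ids[i], metal_ids[(i + 1) % n_m]) for i in range(n_m)]
        chords = [
            (metal_ids[i], metal_ids[j])
            for i in range(n_m) for j in range(i + 2, n_m)
            if not (i == 0 and j == n_m - 1)
        ]
        avail = cycle + chords
        if n_bridges > len(avail):
            raise InfeasibleStoichiometryError("too many bridges requested")
        pairs = avail[:n_bridges]
    edges: list[tuple[str, str]] = []
    lig_iter = iter(ligand_ids)
    for (ma, mb) in pairs:
        lig = next(lig_iter)
        edges.append((ma, lig))
        edges.append((mb, lig))
    deg = Counter(m for m, _ in edges)
    for m in metal_ids:
        for _ in range(coord - deg.get(m, 0)):
            edges.append((m, next(lig_iter)))
    return ClusterGraph(edges=edges, coordination_number=coord)


def mt2_alpha_cluster(ligand_ids: Sequence[str] | None = None) -> ClusterGraph:
    """The alpha-domain Zn4Cys11 cluster (5 bridging + 6 terminal donors)."""
    if ligand_ids is None:
        ligand_ids = [f"SG{r}" for r in (33, 34, 36, 37, 41, 44, 48, 50, 57, 59, 60)]
    metals = ["Zn4", "Zn5", "Zn6", "Zn7"]
    return _ring_cluster(metals, list(ligand_ids), n_bridges=5)


def mt2_beta_cluster(ligand_ids: Sequence[str] | None = None) -> ClusterGraph:
    """The beta-domain Zn3Cys9 cluster (3 bridging + 6 terminal donors)."""
    if ligand_ids is None:
        ligand_ids = [f"SG{r}" for r in (5, 7, 13, 15, 19, 21, 24, 26, 29)]
    metals = ["Zn1", "Zn2", "Zn3"]
    return _ring_cluster(metals, list(ligand_ids), n_bridges=3)


def mt2_default_topology(sequence: str | None = None) -> SiteTopology:
    """Full Zn7MT2 topology: 3 beta metals on the 9 beta Cys, 4 alpha metals
    on the 11 alpha Cys, candidate ligands taken from the cluster graphs."""
    seq = sequence or default_sequence()
    cys = cys_positions(seq)
    residue_index_of = {f"SG{r}": r for r in cys}
    beta = mt2_beta_cluster()
    alpha = mt2_alpha_cluster()
    ligand_map: dict[str, set[str]] = {}
    for graph in (beta, alpha):
        for m, l in graph.edges:
            ligand_map.setdefault(m, set()).add(l)
    return SiteTopology(
        metal_ids=[f"Zn{i}" for i in range(1, 8)],
        ligand_map=ligand_map,
        residue_index_of=residue_index_of,
        sequence_length=len(seq),
    )
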