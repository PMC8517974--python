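"""Dual-label (IAM/NEM) cysteine quantification and proteoform mass ledger.

Free thiols are alkylated with iodoacetamide (IAM, carbamidomethyl, ~+57 Da)
while Zn-protected thiols — labelled after metal removal — carry
N-ethylmaleimide (NEM, ~+125 Da).  Summing peptide abundances per modified
Cys and normalising by the residue's total (NEM + IAM) gives the per-residue
bound fraction; matching intact masses against the
(n_metal, n_IAM, n_NEM) grid assigns species such as Zn_4_IAM_9_MT2.
Successive-difference molar absorption spectra from metal titrations are the
spectrophotometric companion of the same binding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .errors import GridMismatchError, ValidationError

__all__ = [
    "PeptideRecord",
    "Proteoform",
    "per_cys_label_fractions",
    "modification_mass",
    "metal_adduct_mass",
    "proteoform_mass",
    "species_name",
    "assign_species",
    "increment_difference_spectra",
]

LABELS = ("IAM", "NEM")


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide observation: span (1-based inclusive), the modified Cys
    position, its label, and an abundance in arbitrary intensity units."""

    start: int
    end: int
    cys_position: int
    label: str
    abundance: float

    def __post_init__(self) -> None:
        if not self.start <= self.cys_position <= self.end:
            raise ValidationError(
                f"Cys {self.cys_position} outside span {self.start}-{self.end}"
            )
        if self.label not in LABELS + ("none",):
            raise ValidationError(f"unknown label {self.label!r}")
        if self.abundance < 0:
            raise ValidationError("abundance must be non-negative")


@dataclass(frozen=True)
class Proteoform:
    """One labelled/metalated species of the intact protein."""

    n_iam: int
    n_nem: int
    n_metal: int
    metal: str = "Zn"
    mass: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_iam, self.n_nem, self.n_metal) < 0:
            raise ValidationError("proteoform counts must be non-negative")


def per_cys_label_fractions(records, sequence: str) -> pd.DataFrame:
    """Per-Cys NEM/IAM fractions from peptide records.

    For every Cys the label-summed abundance is normalised by the residue's
    total abundance (NEM + IAM), so fraction_NEM + fraction_IAM = 1 wherever
    the residue is covered; uncovered Cys are flagged, never imputed.
    Accepts a DataFrame (columns start, end, cys_position, label, abundance)
    or an iterable of :class:`PeptideRecord`.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        required = {"start", "end", "cys_position", "label", "abundance"}
        if not required <= set(df.columns):
            raise ValidationError(f"peptide table needs columns {sorted(required)}")
    else:
        df = pd.DataFrame([
            {"start": r.start, "end": r.end, "cys_position": r.cys_position,
             "label": r.label, "abundance": r.abundance}
            for r in records
        ], columns=["start", "end", "cys_position", "label", "abundance"])
    n = len(sequence)
    for _, row in df.iterrows():
        if not 1 <= row["start"] <= row["end"] <= n:
            raise ValidationError(
                f"span {row['start']}-{row['end']} outside sequence of length {n}"
            )
        pos = int(row["cys_position"])
        if sequence[pos - 1] != "C":
            raise ValidationError(f"modified position {pos} is not a Cys")
    cys_all = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
    labelled = df[df["label"].isin(LABELS)]
    sums = (labelled.groupby(["cys_position", "label"])["abundance"].sum()
            .unstack(fill_value=0.0))
    for lab in LABELS:
        if lab not in sums.columns:
            sums[lab] = 0.0
    rows = []
    for pos in cys_all:
        iam = float(sums["IAM"].get(pos, 0.0))
        nem = float(sums["NEM"].get(pos, 0.0))
        total = iam + nem
        covered = total > 0
        rows.append({
            "cys_position": pos,
            "fraction_NEM": nem / total if covered else np.nan,
            "fraction_IAM": iam / total if covered else np.nan,
            "total_abundance": total,
            "covered": covered,
        })
    return pd.DataFrame(rows).set_index("cys_position")


def modification_mass(label: str, kind: str = "monoisotopic") -> float:
    """Mass shift of one Cys alkylation: IAM ~57 Da, NEM ~125 Da.

    ``kind`` is 'monoisotopic', 'average', or 'nominal' (rounded integer).
    """
    mono = {"IAM": C.MASS_IAM_MONO, "NEM": C.MASS_NEM_MONO}
    avg = {"IAM": C.MASS_IAM_AVG, "NEM": C.MASS_NEM_AVG}
    if label not in mono:
        raise ValidationError(f"unknown label {label!r}")
    if kind == "monoisotopic":
        return mono[label]
    if kind == "average":
        return avg[label]
    if kind == "nominal":
        return float(round(mono[label]))
    raise ValidationError(f"unknown mass kind {kind!r}")


def metal_adduct_mass(metal: str = "Zn", kind: str = "monoisotopic",
                      charge_neutral: bool = True) -> float:
    """Mass change of the neutral species per bound metal ion.

    Zn(II) on thiolates displaces two protons, so the default is
    M(Zn) - 2 M(H) = 61.913 Da (monoisotopic); ``charge_neutral=False``
    returns the bare-metal mass for comparison with deconvolved spectra that
    report metal addition directly.
    """
    if metal != "Zn":
        raise ValidationError("only Zn adducts are tabulated")
    if kind == "monoisotopic":
        return C.DELTA_ZN_MONO if charge_neutral else C.MASS_ZN_MONO
    if kind == "average":
        return C.DELTA_ZN_AVG if charge_neutral else C.MASS_ZN_AVG
    raise ValidationError(f"unknown mass kind {kind!r}")


def proteoform_mass(
    apo_mass: float,
    n_iam: int,
    n_nem: int,
    n_metal: int,
    metal: str = "Zn",
    kind: str = "monoisotopic",
    charge_neutral: bool = True,
) -> float:
    """Mass of an apo protein carrying the given labels and metals.

    Affine in every count: apo + n_IAM*57.02146 + n_NEM*125.04767
    + n_metal*(M(Zn) - 2 M(H)) for the monoisotopic neutral-species ledger.
    """
    if min(n_iam, n_nem, n_metal) < 0:
        raise ValidationError("counts must be non-negative")
    return (apo_mass
            + n_iam * modification_mass("IAM", kind)
            + n_nem * modification_mass("NEM", kind)
            + n_metal * metal_adduct_mass(metal, kind, charge_neutral))


def species_name(p: Proteoform, protein: str = "MT2") -> str:
    """Ledger naming, e.g. Zn_4_IAM_9_MT2 or IAM_17_NEM_3_MT2."""
    parts = []
    if p.n_metal:
        parts.append(f"{p.metal}_{p.n_metal}")
    if p.n_iam or not (p.n_metal or p.n_nem):
        parts.append(f"IAM_{p.n_iam}")
    if p.n_nem:
        parts.append(f"NEM_{p.n_nem}")
    return "_".join(parts + [protein])


def assign_species(
    observed_masses,
    apo_mass: float,
    tolerance: float,
    total_cys: int = 20,
    max_metal: int = 7,
    metal: str = "Zn",
    kind: str = "monoisotopic",
    charge_neutral: bool = True,
) -> pd.DataFrame:
    """Match observed intact masses onto the (n_metal, n_IAM, n_NEM) grid.

    Each observed mass is assigned to every grid point within ``tolerance``
    Da; masses with no match are reported unassigned, masses with several
    are flagged ambiguous (all candidates listed).  Grid constraint:
    n_IAM + n_NEM <= total_cys.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    grid = []
    for nm in range(max_metal + 1):
        for ni in range(total_cys + 1):
            for nn in range(total_cys + 1 - ni):
                mass = proteoform_mass(apo_mass, ni, nn, nm, metal, kind,
                                       charge_neutral)
                grid.append((mass, nm, ni, nn))
    grid_mass = np.array([g[0] for g in grid])
    rows = []
    for obs in np.atleast_1d(np.asarray(observed_masses, dtype=float)):
        hits = np.nonzero(np.abs(grid_mass - obs) <= tolerance)[0]
        if hits.size == 0:
            rows.append({"observed_mass": obs, "species": None,
                         "n_metal": None, "n_iam": None, "n_nem": None,
                         "mass_error": np.nan, "ambiguous": False,
                         "candidates": []})
            continue
        best = hits[np.argmin(np.abs(grid_mass[hits] - obs))]
        cands = [species_name(
            Proteoform(grid[i][2], grid[i][3], grid[i][1], metal, grid[i][0])
        ) for i in hits]
        _, nm, ni, nn = grid[best]
        rows.append({
            "observed_mass": obs,
            "species": species_name(Proteoform(ni, nn, nm, metal)),
            "n_metal": nm, "n_iam": ni, "n_nem": nn,
            "mass_error": obs - grid[best][0],
            "ambiguous": hits.size > 1,
            "candidates": cands,
        })
    return pd.DataFrame(rows)


def increment_difference_spectra(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    path_length_cm: float,
    concentration_M: float,
) -> pd.DataFrame:
    """Successive-difference molar absorption spectra of a titration.

    ``spectra`` is (n_points, n_wavelengths) absorbance on a common
    wavelength grid, ordered by added metal equivalents; returns
    d(eps)_i(lambda) = (A_i - A_{i-1}) / (c * l) in M^-1 cm^-1, one column
    per titration step.  A shrinking d(eps) step marks cluster formation
    rather than a new independent ZnCys4 site.
    """
    a = np.asarray(spectra, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValidationError("need >= 2 spectra as a 2-D array")
    if a.shape[1] != wl.size:
        raise GridMismatchError("spectra and wavelength grid differ in length")
    if path_length_cm <= 0 or concentration_M <= 0:
        raise ValidationError("path length and concentration must be positive")
    deltas = np.diff(a, axis=0) / (concentration_M * path_length_cm)
    out = pd.DataFrame(deltas.T, index=pd.Index(wl, name="wavelength_nm"),
                       columns=[f"step_{i + 1}" for i in range(deltas.shape[0])])
    return out
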