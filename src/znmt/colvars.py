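"""Collective variables: rational switching function, coordination numbers,
and the distance-RMSD (dRMSD).

The contact number between a metal ion A and a group of donor atoms B is

    CN = sum_{j in B} s(r_j),    s(r) = (1 - x^n) / (1 - x^m),
    x = (r - d0) / r0,

a smooth step that is ~1 inside the contact distance and decays to 0 outside.
For the Zn-S contact the exponents are n=8, m=12 with r0=0.3 Å and d0=2.4 Å
(placed just past the Zn-S bond length, from the Zn radial distribution in
the protein); a tetrahedral ZnCys4 site then reads CN ≈ 4 and a fully
dissociated ion CN ≈ 0.  The Zn-O (water) contact uses n=12, m=24,
r0=2.9 Å with a 5 Å hard cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .errors import UndefinedDrmsdError, ValidationError

__all__ = [
    "SwitchingParams",
    "switching",
    "inverse_switching",
    "contact_number",
    "cn_znS_defaults",
    "cn_znO_defaults",
    "cn_total_zn_mt2",
    "drmsd",
    "drmsd_pair_list",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the rational switching function.

    ``n`` and ``m`` set the steepness (m > n > 0), ``r0`` the switch width,
    ``d0`` the offset, and ``d_max`` an optional hard cutoff beyond which the
    function is exactly zero.  Lengths in Å by default; set ``units='nm'``
    for PLUMED-style nm interoperability (values are used as given — the
    flag only documents the convention carried by the object).
    """

    n: int = 8
    m: int = 12
    r0: float = 0.3
    d0: float = 2.4
    d_max: float | None = None
    units: str = "A"

    def __post_init__(self) -> None:
        if not (self.m > self.n > 0):
            raise ValidationError(f"need m > n > 0, got n={self.n}, m={self.m}")
        if self.r0 <= 0:
            raise ValidationError("r0 must be positive")
        if self.d0 < 0:
            raise ValidationError("d0 must be non-negative")
        if self.d_max is not None and self.d_max <= self.d0:
            raise ValidationError("d_max must exceed d0")
        if self.units not in ("A", "nm"):
            raise ValidationError("units must be 'A' or 'nm'")


def cn_znS_defaults() -> SwitchingParams:
    """Zn-S contact switching: n=8, m=12, r0=0.3 Å, d0=2.4 Å."""
    return SwitchingParams(n=8, m=12, r0=0.3, d0=2.4)


def cn_znO_defaults() -> SwitchingParams:
    """Zn-O(water) contact switching: n=12, m=24, r0=2.9 Å, d_max=5 Å.

    The offset d0 is taken as 0 Å (the switch is centred by r0 alone).
    """
    return SwitchingParams(n=12, m=24, r0=2.9, d0=0.0, d_max=5.0)


def switching(r, p: SwitchingParams):
    """Evaluate the switching function (scalar or array input).

    Clamped to 1 for r <= d0; the removable singularity at x=1 is filled with
    its analytic limit n/m; exactly 0 at and beyond ``d_max`` if set.
    """
    scalar_in = np.isscalar(r) or np.asarray(r).ndim == 0
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if not np.all(np.isfinite(r_arr)):
        raise ValidationError("non-finite distance passed to switching")
    x = (r_arr - p.d0) / p.r0
    out = np.empty_like(x)

    below = x <= 0.0
    near_one = np.abs(x - 1.0) < 1e-9
    regular = ~(below | near_one)

    out[below] = 1.0
    out[near_one] = p.n / p.m
    xr = x[regular]
    out[regular] = (1.0 - xr**p.n) / (1.0 - xr**p.m)

    if p.d_max is not None:
        out[r_arr >= p.d_max] = 0.0
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar_in else out


def inverse_switching(value: float, p: SwitchingParams, r_hi: float = 500.0) -> float:
    """Distance at which the switching function equals ``value`` in (0, 1].

    Used by the synthetic generators to emit coordinates realising a scripted
    contact number.  ``value=1`` maps to d0; values approaching 0 map to large
    distances (capped at ``r_hi``).
    """
    if not 0.0 < value <= 1.0:
        raise ValidationError("switching value must lie in (0, 1]")
    if value >= 1.0:
        return p.d0
    lo = p.d0 + 1e-12
    if switching(r_hi, p) >= value:
        raise ValidationError("r_hi too small to bracket the requested value")
    return float(brentq(lambda r: switching(r, p) - value, lo, r_hi, xtol=1e-12))


def contact_number(metal: Sequence[float], ligands, p: SwitchingParams) -> float:
    """CN of one metal over a set of ligand positions (may be empty)."""
    lig = np.asarray(ligands, dtype=float)
    if lig.size == 0:
        return 0.0
    lig = lig.reshape(-1, 3)
    d = np.linalg.norm(lig - np.asarray(metal, dtype=float), axis=1)
    return float(np.sum(switching(d, p)))


def cn_total_zn_mt2(per_site_cn, n_sites: int = 7, literal_filter: bool = False) -> float:
    """Combine per-site Zn-S coordination numbers into the total number of
    Zn(II) ions bound to the protein.

    Each per-site CN (in [0, 4]) is passed through the switching function with
    r0=2.5 and d0=0.  Applied literally that filter reads ~1 for an *unbound*
    site and small for a bound one, so by default the complement
    ``b(CN) = 1 - s(CN)`` is summed — a bound indicator that rises from 0 to
    ~0.67 as a site fills, making the combined CV increase with the number of
    bound ions (0 when the protein is apo, toward 7 at full loading).
    ``literal_filter=True`` sums s(CN) directly instead.
    """
    cn = np.asarray(per_site_cn, dtype=float)
    if cn.ndim != 1 or cn.size != n_sites:
        raise ValidationError(f"expected {n_sites} per-site CN values, got shape {cn.shape}")
    if np.any(cn < 0):
        raise ValidationError("per-site CN values must be non-negative")
    p = SwitchingParams(n=8, m=12, r0=2.5, d0=0.0)
    s = switching(cn, p)
    return float(np.sum(s) if literal_filter else np.sum(1.0 - s))


def drmsd_pair_list(reference: np.ndarray, window: tuple[float, float] = (0.1, 8.0)):
    """Indices (i, j), i<j, whose reference distance lies inside ``window``."""
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    n = ref.shape[0]
    d = pdist(ref)
    iu = np.triu_indices(n, k=1)
    lo, hi = window
    keep = (d >= lo) & (d <= hi)
    return iu[0][keep], iu[1][keep], d[keep]


def drmsd(frame, reference, window: tuple[float, float] = (0.1, 8.0)) -> float:
    """Distance-RMSD of a frame against a reference structure.

    Root-mean-square of (d_ij - d_ij^ref) over atom pairs whose *reference*
    separation lies within ``window`` (0.1-8 Å by default).  Superposition-free:
    only internal distances enter.
    """
    frm = np.asarray(frame, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if frm.shape != ref.shape:
        raise ValidationError("frame and reference must have identical atom counts")
    ii, jj, d_ref = drmsd_pair_list(ref, window)
    if len(ii) == 0:
        raise UndefinedDrmsdError("no atom pair inside the dRMSD window")
    d_frm = np.linalg.norm(frm[ii] - frm[jj], axis=1)
    return float(np.sqrt(np.mean((d_frm - d_ref) ** 2)))
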