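"""Worm-like-chain geometry of an intrinsically disordered chain and the
sarcomeric lattice-reach construction.

For an ideal chain of contour length ``Lc`` and persistence length ``Lp``
the mean end-to-end distance is ``R = sqrt(Lc * Lp)`` and the radius of
gyration ``RG = R / sqrt(6)``.  The contour length is the residue count
times the 0.38 nm per-residue spacing of a polypeptide.  These apply to a
disordered titin PEVK domain (2174 residues, Lp ≈ 1 nm), whose RG sets
the reach of the domain in the myofilament lattice: in an ideal vertebrate
hexagonal double-lattice the thick–thin filament distance is 2·d10/3,
with d10 the 1,0 lattice-plane spacing (37.4 nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RESIDUE_SPACING_NM",
    "D10_DEFAULT_NM",
    "ChainGeometry",
    "LatticeGeometry",
    "contour_length",
    "end_to_end",
    "radius_of_gyration",
    "chain_geometry",
    "lattice_reach",
    "round_sig",
]

RESIDUE_SPACING_NM = 0.38
D10_DEFAULT_NM = 37.4


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


@dataclass(frozen=True)
class ChainGeometry:
    """Full worm-like-chain summary of one chain (all lengths in nm)."""

    n_residues: int
    residue_spacing: float
    persistence_length: float
    contour_length: float
    end_to_end: float
    radius_of_gyration: float


@dataclass(frozen=True)
class LatticeGeometry:
    """Hexagonal double-lattice distances and the chain's reach margin (nm)."""

    d10: float
    thick_thin_distance: float
    reach_margin: float


def contour_length(n_residues: int, residue_spacing: float = RESIDUE_SPACING_NM) -> float:
    """Contour length Lc = n_residues · residue_spacing, in nm."""
    _check_nonneg(n_residues=n_residues, residue_spacing=residue_spacing)
    return n_residues * residue_spacing


def end_to_end(lc: float, lp: float) -> float:
    """Ideal-chain mean end-to-end distance R = sqrt(Lc · Lp), in nm."""
    _check_nonneg(lc=lc, lp=lp)
    return math.sqrt(lc * lp)


def radius_of_gyration(r: float) -> float:
    """RG = R / sqrt(6): radius of the mass-equivalent sphere, in nm."""
    _check_nonneg(r=r)
    return r / math.sqrt(6.0)


def chain_geometry(n_residues: int, persistence_length: float,
                   residue_spacing: float = RESIDUE_SPACING_NM) -> ChainGeometry:
    """Compose contour length, end-to-end distance, and radius of gyration."""
    lc = contour_length(n_residues, residue_spacing)
    r = end_to_end(lc, persistence_length)
    return ChainGeometry(
        n_residues=n_residues,
        residue_spacing=residue_spacing,
        persistence_length=persistence_length,
        contour_length=lc,
        end_to_end=r,
        radius_of_gyration=radius_of_gyration(r),
    )


def lattice_reach(rg: float, d10: float = D10_DEFAULT_NM) -> LatticeGeometry:
    """Chain reach vs the thick–thin distance of an ideal hexagonal lattice.

    Thin filaments sit at the trigonal positions of the thick-filament
    hexagonal lattice, a thick–thin distance of 2·d10/3.  The margin
    ``rg − 2·d10/3`` is positive when a relaxed chain tethered at a thick
    filament can span to the nearest thin filament.  This construction is
    an idealization of the sarcomeric cross-section, not a measurement.
    """
    _check_nonneg(rg=rg)
    if d10 <= 0:
        raise ValueError(f"d10 must be positive, got {d10}")
    thick_thin = 2.0 * d10 / 3.0
    return LatticeGeometry(d10=d10, thick_thin_distance=thick_thin,
                           reach_margin=rg - thick_thin)
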