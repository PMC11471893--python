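"""Helical-symmetry <-> monomer-spacing conversions.

A microtubule built from ``n_pf`` protofilaments arranged as an ``n_start``
helix has one subunit per helical step: rise ``r`` (Å) along the axis and
twist ``-360/n_pf`` degrees about it.  Walking ``n_pf / n_start`` subunit
steps returns to the same protofilament one monomer up, so the axial repeat
along a protofilament (the monomer spacing ``a``) is

    a = rise * n_pf / n_start

For the canonical 13-protofilament, 3-start lattice a rise of 9.46 Å gives
a ~= 41 Å (compacted); 9.82 Å gives 42.5 Å (expanded).  These conversions
let a lattice spacing from layer-line analysis be cross-checked against the
helical parameters refined in a subtomogram average.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HelicalParams",
    "spacing_from_helix",
    "twist_per_monomer",
    "helix_from_spacing",
]


def _validate_counts(n_pf: int, n_start: int) -> None:
    if int(n_pf) != n_pf or n_pf < 8:
        raise ValueError(f"n_pf: must be an integer >= 8, got {n_pf}")
    if int(n_start) != n_start or not (1 <= n_start <= n_pf):
        raise ValueError(
            f"n_start: must be an integer in [1, n_pf], got {n_start}")


@dataclass(frozen=True)
class HelicalParams:
    """Helical lattice symmetry: subunit rise (Å) and twist (degrees)."""

    n_pf: int
    n_start: int
    rise: float
    twist: float

    def __post_init__(self) -> None:
        _validate_counts(self.n_pf, self.n_start)
        if not self.rise > 0:
            raise ValueError(f"rise: must be > 0, got {self.rise}")

    @property
    def monomer_spacing(self) -> float:
        return spacing_from_helix(self.rise, self.n_pf, self.n_start)


def spacing_from_helix(rise: float, n_pf: int, n_start: int) -> float:
    """Monomer spacing along a protofilament, ``rise * n_pf / n_start`` (Å)."""
    _validate_counts(n_pf, n_start)
    if not rise > 0:
        raise ValueError(f"rise: must be > 0, got {rise}")
    return rise * n_pf / n_start


def twist_per_monomer(n_pf: int) -> float:
    """Azimuthal twist per subunit step, ``-360 / n_pf`` degrees."""
    if int(n_pf) != n_pf or n_pf <= 0:
        raise ValueError(f"n_pf: must be a positive integer, got {n_pf}")
    return -360.0 / n_pf


def helix_from_spacing(spacing: float, n_pf: int, n_start: int) -> HelicalParams:
    """Inverse of :func:`spacing_from_helix` (exact roundtrip)."""
    _validate_counts(n_pf, n_start)
    if not spacing > 0:
        raise ValueError(f"spacing: must be > 0, got {spacing}")
    return HelicalParams(
        n_pf=n_pf,
        n_start=n_start,
        rise=spacing * n_start / n_pf,
        twist=twist_per_monomer(n_pf),
    )
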