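"""Lennard-Jones 6-12 force field: pair parameters, mixing rule, pair potential.

The non-bonded interaction between two atoms a distance ``rho`` apart is

    Phi(rho) = -A/rho^6 + B/rho^12,

with attractive constant ``A = 2*eps*sigma^6`` and repulsive constant
``B = eps*sigma^12``, where ``eps`` is the well depth (eV) and ``sigma`` the
van der Waals diameter (Angstrom).  Phi has its unique minimum ``-eps`` at
``rho = sigma``.  Unlike pairs are built with the Lorentz-Berthelot mixing
rule ``sigma_ij = (sigma_i + sigma_j)/2``, ``eps_ij = sqrt(eps_i*eps_j)``.

Units are fixed package-wide: Angstrom, eV, radians (degrees only at report
boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ELEMENTS",
    "ATOMIC_WEIGHTS",
    "DISTANCE_GUARD",
    "PENALTY_ENERGY",
    "InvalidParameterError",
    "GuardError",
    "PairParams",
    "ForceFieldTable",
    "mix_pair",
    "lj_constants",
    "pair_potential",
    "default_forcefield",
]

#: Elements handled by the model: the drug's C/H/N/O plus graphene carbon.
ELEMENTS = ("C", "H", "N", "O")

#: IUPAC standard atomic weights, used for centers of mass.
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999}

#: Below this separation (Angstrom) the potential is considered singular.
DISTANCE_GUARD = 0.1

#: Finite objective value returned for guard violations in "penalized" mode,
#: keeping the GA objective well-defined without overflow.
PENALTY_ENERGY = 1.0e6


class InvalidParameterError(ValueError):
    """A force-field parameter violated its positivity constraint."""


class GuardError(ValueError):
    """An interatomic distance fell at or below the singularity guard."""


def mix_pair(
    sigma_i: float, sigma_j: float, eps_i: float, eps_j: float
) -> tuple[float, float]:
    """Combine per-element (sigma, eps) into pair values by the mixing rule.

    Returns ``(sigma_ij, eps_ij)`` with the arithmetic mean of the diameters
    and the geometric mean of the well depths.  Symmetric and idempotent.
    """
    for v in (sigma_i, sigma_j, eps_i, eps_j):
        if not v > 0:
            raise InvalidParameterError(
                f"mixing rule requires positive sigma/eps, got {v!r}"
            )
    return 0.5 * (sigma_i + sigma_j), math.sqrt(eps_i * eps_j)


def lj_constants(sigma: float, eps: float) -> tuple[float, float]:
    """Convert (sigma, eps) to the attractive/repulsive constants (A, B).

    ``A = 2*eps*sigma^6`` (eV * Angstrom^6), ``B = eps*sigma^12``
    (eV * Angstrom^12).
    """
    if not (sigma > 0 and eps > 0):
        raise InvalidParameterError(
            f"lj_constants requires sigma > 0 and eps > 0, got ({sigma!r}, {eps!r})"
        )
    s6 = sigma**6
    return 2.0 * eps * s6, eps * s6 * s6


def pair_potential(
    A: float, B: float, rho: float, mode: str = "strict", guard: float = DISTANCE_GUARD
) -> float:
    """Evaluate Phi(rho) = -A/rho^6 + B/rho^12 for one atom pair.

    ``mode="strict"`` raises :class:`GuardError` when ``rho <= guard``;
    ``mode="penalized"`` returns the finite :data:`PENALTY_ENERGY` instead so
    that optimizers see a large but well-defined objective.
    """
    if rho <= guard:
        if mode == "penalized":
            return PENALTY_ENERGY
        raise GuardError(f"pair distance {rho!r} <= guard {guard!r}")
    inv6 = rho**-6
    return (B * inv6 - A) * inv6


@dataclass(frozen=True)
class PairParams:
    """Lennard-Jones parameters for one unordered element pair.

    ``A`` and ``B`` are stored at full floating precision, derived from
    (sigma, eps); tabulated literature values are treated as 4-5
    significant-figure roundings of these.
    """

    sigma: float
    epsilon: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.epsilon > 0):
            raise InvalidParameterError(
                f"PairParams requires positive sigma/epsilon, "
                f"got ({self.sigma!r}, {self.epsilon!r})"
            )

    @property
    def A(self) -> float:
        """Attractive constant 2*eps*sigma^6 (eV * Angstrom^6)."""
        return 2.0 * self.epsilon * self.sigma**6

    @property
    def B(self) -> float:
        """Repulsive constant eps*sigma^12 (eV * Angstrom^12)."""
        return self.epsilon * self.sigma**12

    @property
    def rho_min(self) -> float:
        """Location of the potential minimum, (2B/A)^(1/6) = sigma."""
        return (2.0 * self.B / self.A) ** (1.0 / 6.0)

    def potential(self, rho: float, mode: str = "strict") -> float:
        return pair_potential(self.A, self.B, rho, mode=mode)


class ForceFieldTable:
    """Symmetric lookup of :class:`PairParams` for any element pair.

    Built from per-element (sigma, eps).  The bundled defaults store the
    four drug-element-vs-carbon pair rows; per-element values are recovered
    with carbon as the reference (``sigma_X = 2*sigma_CX - sigma_C``,
    ``eps_X = eps_CX^2 / eps_C``) so that forward mixing reproduces the
    tabulated pairs exactly and also yields every non-carbon pair the
    two-molecule sum needs.
    """

    def __init__(self, element_params: dict[str, tuple[float, float]]):
        for el, (s, e) in element_params.items():
            if el not in ELEMENTS:
                raise InvalidParameterError(f"unknown element {el!r}")
            if not (s > 0 and e > 0):
                raise InvalidParameterError(
                    f"element {el}: sigma/eps must be positive, got ({s!r}, {e!r})"
                )
        self._elements = dict(element_params)
        self._cache: dict[frozenset, PairParams] = {}

    @classmethod
    def from_pair_rows(
        cls, rows: list[tuple[str, str, float, float]], reference: str = "C"
    ) -> "ForceFieldTable":
        """Build from (el_i, el_j, sigma_ij, eps_ij) rows sharing ``reference``.

        The reference element's own row (e.g. C-C) must be present; every
        other row must pair an element with the reference.
        """
        by_pair = {frozenset((a, b)): (s, e) for a, b, s, e in rows}
        ref_key = frozenset((reference,))
        if ref_key not in by_pair:
            raise InvalidParameterError(
                f"pair table must include the {reference}-{reference} row"
            )
        s_ref, e_ref = by_pair.pop(ref_key)
        elements = {reference: (s_ref, e_ref)}
        for key, (s, e) in by_pair.items():
            other = set(key) - {reference}
            if len(other) != 1:
                raise InvalidParameterError(
                    f"row {sorted(key)} does not involve reference {reference!r}"
                )
            # back-solve the mixing rule for the non-reference element
            (el,) = other
            elements[el] = (2.0 * s - s_ref, e * e / e_ref)
        return cls(elements)

    @property
    def elements(self) -> dict[str, tuple[float, float]]:
        return dict(self._elements)

    def pair(self, el_i: str, el_j: str) -> PairParams:
        """Pair parameters for (el_i, el_j); symmetric in its arguments."""
        key = frozenset((el_i, el_j))
        if key not in self._cache:
            try:
                s_i, e_i = self._elements[el_i]
                s_j, e_j = self._elements[el_j]
            except KeyError as err:
                raise InvalidParameterError(
                    f"no parameters for element {err.args[0]!r}"
                ) from None
            self._cache[key] = PairParams(*mix_pair(s_i, s_j, e_i, e_j))
        return self._cache[key]

    def __contains__(self, el: str) -> bool:
        return el in self._elements


def _parse_pair_file(text: str) -> list[tuple[str, str, float, float]]:
    rows = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        a, b, s, e = line.split()
        rows.append((a, b, float(s), float(e)))
    return rows


def load_forcefield(path: str | Path) -> ForceFieldTable:
    """Read a pair-parameter text file (element_i element_j sigma eps)."""
    return ForceFieldTable.from_pair_rows(_parse_pair_file(Path(path).read_text()))


def default_forcefield() -> ForceFieldTable:
    """The bundled UFF-derived drug/graphene table."""
    text = (
        resources.files("nanopose.data").joinpath("forcefield_pairs.txt").read_text()
    )
    return ForceFieldTable.from_pair_rows(_parse_pair_file(text))
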