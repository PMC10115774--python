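"""Exact carbon-isotope arithmetic and two-source mixing.

Everything downstream of this module mixes carbon in *atom-fraction* space,

    F = 13C / (12C + 13C),

which is the linear mixing coordinate at any enrichment.  Delta notation,

    delta13C = (R_sample / R_std - 1) * 1000   with   R = 13C / 12C,

is only a reporting convention here: delta-space mixing is a good
approximation near natural abundance but breaks down badly against a
99 atom% tracer, so no pipeline code path mixes in delta space.  The
:func:`delta_space_fraction` helper exists solely for natural-abundance
cross-checks and refuses highly enriched inputs.

The 13C/12C ratio of the VPDB standard is fixed at 0.011180 by default
(configurable through :class:`IsotopeStandard`); the value in effect is echoed
into every output file's metadata so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EndMemberSeparationError,
    InvalidCompositionError,
    UndefinedMixtureError,
)

#: Default 13C/12C ratio assigned to the VPDB reference.
DEFAULT_R_VPDB = 0.011180

#: Minimum |F_src - F_ref| for a two-source split to be considered
#: identifiable (~1 permil at natural abundance, i.e. instrument-precision
#: scale).
DEFAULT_MIN_SEPARATION = 1e-5

#: Delta bound beyond which the delta-space approximation is refused.
_DELTA_SPACE_LIMIT = 100.0


@dataclass(frozen=True)
class IsotopeStandard:
    """A carbon isotope reference scale, defined by its 13C/12C ratio."""

    r_std: float = DEFAULT_R_VPDB

    def __post_init__(self):
        if not self.r_std > 0:
            raise InvalidCompositionError(f"r_std must be > 0, got {self.r_std}")


#: The module-wide default standard.
VPDB = IsotopeStandard()


def delta_to_atom_fraction(delta, std: IsotopeStandard = VPDB):
    """Convert delta13C (permil) to atom fraction 13C.

    F = R / (1 + R) with R = (delta/1000 + 1) * r_std.  Strictly increasing
    in delta.  Accepts scalars or arrays; NaN propagates.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta[~np.isnan(delta)] <= -1000.0):
        raise InvalidCompositionError(
            "delta13C <= -1000 permil implies a negative 13C amount"
        )
    r = (delta / 1000.0 + 1.0) * std.r_std
    f = r / (1.0 + r)
    return float(f) if f.ndim == 0 else f


def atom_fraction_to_delta(atom_fraction, std: IsotopeStandard = VPDB):
    """Convert atom fraction 13C to delta13C (permil); exact inverse of
    :func:`delta_to_atom_fraction`."""
    f = np.asarray(atom_fraction, dtype=float)
    valid = ~np.isnan(f)
    if np.any((f[valid] < 0.0) | (f[valid] >= 1.0)):
        raise InvalidCompositionError("atom fraction must lie in [0, 1)")
    r = f / (1.0 - f)
    delta = (r / std.r_std - 1.0) * 1000.0
    return float(delta) if delta.ndim == 0 else delta


@dataclass(frozen=True)
class IsotopeValue:
    """A carbon isotope composition, stored canonically as atom fraction.

    ``delta_permil`` is derived on demand against the attached standard, so a
    value can be constructed from either notation without loss:

    >>> IsotopeValue.from_delta(-12.6).atom_fraction   # doctest: +ELLIPSIS
    0.01091859...
    """

    atom_fraction: float
    standard: IsotopeStandard = VPDB

    def __post_init__(self):
        if not (0.0 <= self.atom_fraction < 1.0):
            raise InvalidCompositionError(
                f"atom fraction must lie in [0, 1), got {self.atom_fraction}"
            )

    @classmethod
    def from_delta(cls, delta_permil: float, standard: IsotopeStandard = VPDB):
        return cls(delta_to_atom_fraction(delta_permil, standard), standard)

    @property
    def delta_permil(self) -> float:
        return atom_fraction_to_delta(self.atom_fraction, self.standard)


def mix_atom_fraction(masses, fractions):
    """Atom fraction of a mixture: the C-mass-weighted mean of component
    atom fractions.

    Parameters
    ----------
    masses : array-like of float
        Carbon masses (any single unit, e.g. ug C); all >= 0, total > 0.
    fractions : array-like of float
        Atom fractions of the components, same length.
    """
    m = np.asarray(masses, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if m.shape != f.shape:
        raise UndefinedMixtureError("masses and fractions differ in length")
    if np.any(m < 0):
        raise UndefinedMixtureError("component masses must be >= 0")
    total = m.sum()
    if not total > 0:
        raise UndefinedMixtureError("total mixture mass must be > 0")
    return float(np.dot(m, f) / total)


def two_source_fraction(f_mix, f_ref, f_src, min_separation=DEFAULT_MIN_SEPARATION):
    """Fraction of mixture carbon contributed by the *src* end member.

    f = (F_mix - F_ref) / (F_src - F_ref).  The result is deliberately NOT
    clipped to [0, 1]: values outside that interval signal mass-balance
    violations (noise, priming, bad end members) and are flagged downstream
    rather than hidden here.

    Raises
    ------
    EndMemberSeparationError
        If any |F_src - F_ref| < ``min_separation`` (unidentifiable split).
    """
    f_mix = np.asarray(f_mix, dtype=float)
    f_ref = np.asarray(f_ref, dtype=float)
    f_src = np.asarray(f_src, dtype=float)
    sep = f_src - f_ref
    bad = np.abs(sep) < min_separation
    if np.any(bad & ~np.isnan(sep)):
        raise EndMemberSeparationError(
            f"end members separated by less than {min_separation} in atom "
            "fraction; the source fraction is unidentifiable"
        )
    out = (f_mix - f_ref) / sep
    return float(out) if out.ndim == 0 else out


def delta_space_fraction(delta_mix, delta_ref, delta_src):
    """Two-source fraction computed in delta space — natural abundance ONLY.

    This is the classical approximation f = (d_mix - d_ref)/(d_src - d_ref).
    It is provided for cross-checking against atom-fraction mixing at natural
    abundance and is never used by the pipeline.  Inputs with |delta| >
    100 permil (far outside natural abundance, e.g. a 99 atom% tracer) are
    refused, which makes accidental use against an enriched end member a hard
    error rather than a silent bias.
    """
    deltas = np.asarray([delta_mix, delta_ref, delta_src], dtype=float)
    if np.any(np.abs(deltas) > _DELTA_SPACE_LIMIT):
        raise InvalidCompositionError(
            "delta-space mixing is a natural-abundance approximation; "
            f"|delta| > {_DELTA_SPACE_LIMIT} permil is not allowed"
        )
    sep = deltas[2] - deltas[1]
    if abs(sep) < 1e-12:
        raise EndMemberSeparationError("identical delta end members")
    return float((deltas[0] - deltas[1]) / sep)
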