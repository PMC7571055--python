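"""Scalar mass arithmetic for intact-protein MALDI-TOF work.

Everything in here operates on *average* molecular masses (Da). At 67-101 kDa
the isotopic envelope is unresolved in linear-mode TOF, so average masses are
the only meaningful scale; monoisotopic masses are never used.

The one chemistry-specific piece is the 4-vinylpyridine (4-vp) adduct:
alkylation of cysteine thiols during glutenin extraction adds 105.14 Da per
cysteine residue. Observed masses of alkylated subunits therefore exceed the
bare mature-protein mass by ``105.14 * n_cys``, and comparisons against
gene-predicted masses must first strip that shift.
"""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

from .errors import ValidationError

#: Average mass added per alkylated cysteine residue (4-vinylpyridine), Da.
VP_PER_SITE_MASS = 105.14

#: Average mass of one water molecule, Da (added once per intact chain).
WATER_MASS = 18.0153

# Average (not monoisotopic) residue masses of the 20 standard amino acids,
# Da, as used by the Expasy Compute pI/MW tool.
AVERAGE_RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention of the printed
    comparison tables), avoiding Python's default banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    out = Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP)
    return float(out)


def average_mass(sequence: str) -> float:
    """Average molecular mass of a protein given as one-letter codes.

    Sum of average residue masses plus one water; matches Expasy Compute
    pI/MW. Raises :class:`ValidationError` on an empty sequence or an
    unknown residue code (the error names the offending position).
    """
    if not sequence:
        raise ValidationError("empty sequence")
    total = WATER_MASS
    for pos, code in enumerate(sequence, start=1):
        try:
            total += AVERAGE_RESIDUE_MASSES[code.upper()]
        except KeyError:
            raise ValidationError(
                f"unknown residue code {code!r} at position {pos}"
            ) from None
    return total


def average_masses_from_fasta(path) -> dict[str, float]:
    """Average mass for every record of a FASTA file of mature protein
    sequences, keyed by record id."""
    from Bio import SeqIO

    out: dict[str, float] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = average_mass(str(record.seq))
    return out


def vp_shift(n_cys: int, per_site_mass: float = VP_PER_SITE_MASS) -> float:
    """Total 4-vp adduct mass for ``n_cys`` alkylated cysteines."""
    if n_cys < 0:
        raise ValidationError(f"negative cysteine count: {n_cys}")
    return per_site_mass * n_cys


def strip_vp(measured: float, n_cys: int,
             per_site_mass: float = VP_PER_SITE_MASS) -> int:
    """Remove the 4-vp adduct from a measured mass; report integer Da.

    The corrected value is floored, not rounded: this is the convention that
    reproduces the printed adduct-free masses from the raw measured ones
    (e.g. 84,014 - 2 x 105.14 = 83,803.72 is reported as 83,803).
    """
    shift = vp_shift(n_cys, per_site_mass)
    corrected = measured - shift
    if corrected <= 0:
        raise ValidationError(
            f"corrected mass non-positive ({measured} - {shift:.2f})"
        )
    return math.floor(corrected)


def diff_and_error(measured_corrected: float, predicted: float) -> tuple[int, float]:
    """Signed difference (Da) and relative error (%) of a corrected measured
    mass against a sequence-predicted mass.

    Returns ``(difference, error_pct)`` with the difference as a signed
    integer and the error rounded half-away-from-zero to two decimals.
    """
    if measured_corrected <= 0 or predicted <= 0:
        raise ValidationError("masses must be positive")
    diff = measured_corrected - predicted
    difference = int(round_half_away(diff, 0))
    error_pct = round_half_away(100.0 * diff / predicted, 2)
    return difference, error_pct


def rsd_percent(values: Iterable[float]) -> float:
    """Relative standard deviation (%) of replicate mass measurements.

    Sample standard deviation (n-1 denominator) over the mean, times 100,
    rounded to three decimals.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValidationError("need at least 2 values for an RSD")
    if any(v <= 0 for v in vals):
        raise ValidationError("RSD requires positive values")
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    return round_half_away(100.0 * math.sqrt(var) / mean, 3)
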