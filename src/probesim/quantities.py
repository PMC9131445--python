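"""Units and affinity-scale conversions.

Everything inside the package works in molar (M). Concentrations and
dissociation constants arrive from the CLI or config files as strings with
an optional metric-prefix unit (``"10nM"``, ``"10 uM"``, ``"1e-7 M"``) and
are converted at the boundary. Affinities may equivalently be given on the
pKD scale, pKD = -log10(KD / M), the customary log scale in assay work
(pKD 7 corresponds to 100 nM).
"""

from __future__ import annotations

import math
import re

__all__ = [
    "kd_from_pkd",
    "pkd_from_kd",
    "parse_quantity",
    "check_concentration",
    "check_kd",
]

# Metric-prefix suffixes accepted for molar quantities.
_UNIT_SCALE = {
    "pM": 1e-12,
    "nM": 1e-9,
    "uM": 1e-6,
    "µM": 1e-6,
    "μM": 1e-6,
    "mM": 1e-3,
    "M": 1.0,
}

_QUANTITY_RE = re.compile(
    r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*([pnuµμm]?M)?\s*$"
)


def kd_from_pkd(pkd: float) -> float:
    """Convert a pKD to a dissociation constant in molar, KD = 10**(-pKD).

    Raises
    ------
    ValueError
        If ``pkd`` is not finite.
    """
    if not math.isfinite(pkd):
        raise ValueError(f"pKD must be finite, got {pkd!r}")
    # cast so numpy scalars take the same pow path as Python floats
    return 10.0 ** (-float(pkd))


def pkd_from_kd(kd: float) -> float:
    """Convert a dissociation constant in molar to the pKD scale.

    The round trip ``kd_from_pkd(pkd_from_kd(kd))`` is exact to relative
    1e-12 over the physically meaningful range.
    """
    check_kd(kd)
    return -math.log10(kd)


def parse_quantity(text: str) -> float:
    """Parse a concentration or KD string into molar.

    Accepts a number with an optional unit suffix (pM, nM, uM/µM, mM, M);
    a bare number is taken as already being in molar for concentration/KD
    fields, or dimensionless for pKD fields (the caller decides which field
    it feeds). Negative values are rejected.

    Raises
    ------
    ValueError
        On unparseable text or a negative value, naming the offending token.
    """
    if not isinstance(text, str):
        raise ValueError(f"expected a quantity string, got {text!r}")
    m = _QUANTITY_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse quantity {text!r}")
    value = float(m.group(1))
    unit = m.group(2)
    if value < 0:
        raise ValueError(f"quantity must be non-negative, got {text!r}")
    return value * (_UNIT_SCALE[unit] if unit else 1.0)


def check_concentration(value: float, name: str = "concentration") -> float:
    """Validate a total concentration: finite and >= 0 (molar)."""
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0 M, got {value!r}")
    return float(value)


def check_kd(kd: float, name: str = "KD") -> float:
    """Validate a dissociation constant: finite and strictly positive."""
    if not math.isfinite(kd) or kd <= 0:
        raise ValueError(f"{name} must be finite and > 0 M, got {kd!r}")
    return float(kd)
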