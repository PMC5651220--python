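"""Van der Waals radii: a bundled Bondi-style element table plus user overrides.

The bundled values are the widely used Bondi set (C 1.70, N 1.55, O 1.52,
H 1.20 ...), with transition metals from the later consensus compilations.
A user file of ``ELEMENT RADIUS`` lines ('#' comments allowed) overrides or
extends the table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional, Union

from .errors import ConfigurationError, InputOutputError

__all__ = ["BONDI_RADII", "load_radii_table", "radius_for"]

# Bondi (1964) main-group values; metals from Batsanov-style compilations.
BONDI_RADII: Dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "B": 1.92,
    "SI": 2.10,
    "SE": 1.90,
    "MG": 1.73,
    "ZN": 1.39,
    "MN": 2.05,
    "FE": 2.05,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "CU": 1.40,
    "NI": 1.63,
}


def load_radii_table(path: Union[str, Path]) -> Dict[str, float]:
    """Read a plain-text override table: one ``ELEMENT RADIUS_Å`` pair per line."""
    table = dict(BONDI_RADII)
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputOutputError(f"cannot read radii table {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 'ELEMENT RADIUS', got {raw!r}"
            )
        element, value = parts[0].upper(), parts[1]
        try:
            radius = float(value)
        except ValueError as exc:
            raise ConfigurationError(f"{path}:{lineno}: bad radius {value!r}") from exc
        if radius <= 0:
            raise ConfigurationError(f"{path}:{lineno}: radius must be positive")
        table[element] = radius
    return table


def radius_for(
    element: str,
    table: Optional[Dict[str, float]] = None,
    default_radius: Optional[float] = None,
) -> float:
    """Radius for an element symbol, falling back to ``default_radius`` if given."""
    tab = BONDI_RADII if table is None else table
    value = tab.get(element.upper())
    if value is None:
        if default_radius is not None:
            return default_radius
        raise ConfigurationError(
            f"no van der Waals radius for element {element!r} and no default configured"
        )
    return value
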