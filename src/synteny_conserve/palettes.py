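"""Deterministic colour gradients for conservation and identity scales.

A palette is an ordered list of hex stops placed evenly on [0, 1];
values between stops are linearly interpolated per RGB channel and the
endpoints map exactly to the first and last stop.  The default
conservation palette runs yellow (unique) -> green -> blue -> purple
(strictly conserved); the default cross-link identity gradient runs
light grey (low identity) -> dark red (100%).
"""

from __future__ import annotations

from typing import Sequence

PALETTES: dict[str, list[str]] = {
    # unique .. strictly conserved
    "conservation": ["#F1C40F", "#2ECC71", "#2E86C1", "#6C3483"],
    # viridis-like alternative
    "viridis": ["#FDE725", "#35B779", "#31688E", "#440154"],
    # cross-link identity: low .. 100%
    "identity": ["#D5D8DC", "#8B0000"],
}


def _hex_to_rgb(colour: str) -> tuple[int, int, int]:
    c = colour.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _rgb_to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def colour_for_fraction(fraction: float, stops: Sequence[str]) -> str:
    """Map a value in [0, 1] through evenly spaced hex stops.

    Exact at the endpoints: 0 returns the first stop, 1 the last.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    stops = list(stops)
    if len(stops) < 2:
        raise ValueError("palette needs at least two stops")
    if fraction <= 0.0:
        return stops[0].upper()
    if fraction >= 1.0:
        return stops[-1].upper()
    span = len(stops) - 1
    idx = min(int(fraction * span), span - 1)
    local = fraction * span - idx
    lo = _hex_to_rgb(stops[idx])
    hi = _hex_to_rgb(stops[idx + 1])
    rgb = tuple(round(a + (b - a) * local) for a, b in zip(lo, hi))
    return _rgb_to_hex(rgb)  # type: ignore[arg-type]


def colour_for_identity(identity: float, stops: Sequence[str] | None = None) -> str:
    """Map a percent identity in [0, 100] through the identity gradient."""
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity must be in [0, 100], got {identity}")
    return colour_for_fraction(identity / 100.0, stops or PALETTES["identity"])
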