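"""Small shared helpers: unit conversions and report-precision rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def un_to_mn(force_un: float) -> float:
    """Convert micronewtons to millinewtons."""
    return force_un / 1000.0


def mn_to_un(force_mn: float) -> float:
    """Convert millinewtons to micronewtons."""
    return force_mn * 1000.0


def report_round(value: float, ndigits: int = 0) -> float:
    """Round half-up at report precision.

    Computation keeps full precision everywhere; rounding to the precision used
    in published tables (integer μN, one decimal for mg or ratios) happens only
    when a number is reported.  Half-up on a short decimal rendering avoids
    binary artefacts such as 35.849999999999994 rounding down to 35.8.
    """
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{value:.{ndigits + 4}f}").quantize(quant, rounding=ROUND_HALF_UP))
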