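"""Report rounding conventions: OR to 2 decimals, p to 2 significant figures
(scientific below 0.01), percents to 2 decimals above 0.1% else 2 significant
figures with trailing zeros trimmed."""

from __future__ import annotations

import math


def round_sig(x: float, digits: int = 2) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def format_or(odds_ratio: float) -> str:
    if math.isnan(odds_ratio):
        return "NA"
    if math.isinf(odds_ratio):
        return "inf"
    return f"{odds_ratio:.2f}"


def format_p(p: float) -> str:
    rounded = round_sig(p, 2)
    if rounded >= 0.01:
        # enough decimals to keep 2 significant figures
        decimals = max(2, 1 - int(math.floor(math.log10(rounded))))
        return f"{rounded:.{decimals}f}"
    mantissa, exponent = f"{rounded:.1e}".split("e")
    return f"{mantissa}e{int(exponent)}"


def format_percent(fraction: float) -> str:
    pct = 100.0 * fraction
    if pct == 0:
        return "0%"
    if pct >= 0.1:
        return f"{pct:.2f}%"
    text = f"{round_sig(pct, 2):.10f}".rstrip("0")
    return f"{text}%"
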