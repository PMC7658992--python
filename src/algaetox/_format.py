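"""Display formatting shared by result serializers.

Internal values stay at full precision; rounding to the reporting style
(3 significant figures, censored thresholds as ``"> max"``) happens only
when a result is rendered for display.
"""

from __future__ import annotations

import math


def format_sig(x: float | None, sig: int = 3) -> str:
    """Format ``x`` to ``sig`` significant figures without scientific notation.

    ``format_sig(12.400001) == "12.4"``; ``format_sig(4570.0) == "4570"``.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if x == 0:
        return "0"
    decimals = sig - 1 - math.floor(math.log10(abs(x)))
    rounded = round(x, decimals)
    if decimals <= 0:
        return str(int(rounded))
    return f"{rounded:.{decimals}f}"


def format_censored(max_conc: float, sig: int = 3) -> str:
    """Censored-threshold display convention: ``"> <max tested conc>"``."""
    return f"> {format_sig(max_conc, sig)}"
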