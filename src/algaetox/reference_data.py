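"""Published *Chaetoceros muelleri* toxicity thresholds used as worked-example inputs.

Reported EC50s (ug/L) from a 72-h growth / 24-h quantum-yield bioassay
series on four herbicides, with diuron as the reference toxicant.  Haloxyfop
produced no response up to the highest concentration tested, so its
thresholds are censored and carry no numeric EC50.  These values feed the
potency arithmetic (ReP, SGR:yield EC50 ratios) in examples and in the
reproduction script; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

REFERENCE_HERBICIDE = "diuron"

#: herbicide -> endpoint -> reported EC50 (ug/L); None = censored (no response)
REFERENCE_EC50: dict[str, dict[str, float | None]] = {
    "diuron": {"sgr": 12.4, "yield": 4.25},
    "propazine": {"sgr": 98.2, "yield": 48.6},
    "tebuthiuron": {"sgr": 187.0, "yield": 47.7},
    "haloxyfop": {"sgr": None, "yield": None},
}

#: highest tested concentration (ug/L) for the censored herbicide
MAX_TESTED = {"haloxyfop": 4570.0}
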