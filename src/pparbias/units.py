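"""Concentration unit conversion. Internal computation is always in nM."""

_FACTORS = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


def to_nanomolar(value, unit: str = "nM"):
    """Convert a concentration (scalar or array) in `unit` to nM."""
    try:
        return value * _FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; use one of {sorted(_FACTORS)}")


def from_nanomolar(value, unit: str = "nM"):
    """Convert a concentration in nM to `unit`."""
    try:
        return value / _FACTORS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}; use one of {sorted(_FACTORS)}")
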