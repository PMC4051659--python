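"""Frequency-band definitions shared across the package.

Half-open intervals [low, high) in Hz so that boundary frequencies (8 Hz,
13 Hz) are counted in exactly one band.
"""

BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 25.0),
    "gamma": (25.0, 40.0),
}

BAND_ORDER: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
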