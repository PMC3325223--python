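"""The authoritative vocabulary of the 17 melatonin phase markers.

Every module and every output file uses these spellings.  The markers fall
into six method families: absolute-threshold DLMO, relative-threshold DLMO,
24-h-mean crossings, 2- and 3-harmonic Fourier fits, a skewed bimodal cosine
fit, and the physiological differential-equation model.
"""

MARKERS: tuple[str, ...] = (
    "DLMOpost-threshold",
    "DLMOinterpolated",
    "DLMOn25%",
    "DLMOff25%",
    "24hUpcross",
    "24hMidpoint",
    "24hDowncross",
    "F2Max",
    "F2Upcross",
    "F2Downcross",
    "F3Max",
    "F3Upcross",
    "F3Downcross",
    "SkewedUpcross",
    "SkewedDowncross",
    "Syn-on",
    "Syn-off",
)

#: Markers on the rising portion of the secretion pulse.
ONSET_MARKERS: tuple[str, ...] = (
    "DLMOpost-threshold",
    "DLMOinterpolated",
    "DLMOn25%",
    "24hUpcross",
    "F2Upcross",
    "F3Upcross",
    "SkewedUpcross",
    "Syn-on",
)

#: Markers on the falling portion of the pulse.
OFFSET_MARKERS: tuple[str, ...] = (
    "DLMOff25%",
    "24hDowncross",
    "F2Downcross",
    "F3Downcross",
    "SkewedDowncross",
    "Syn-off",
)
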