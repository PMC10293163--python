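"""The 19-channel International 10-20 montage used throughout the package.

All recordings carry exactly these channels, in exactly this order; feature
names, cross-spectral pair indices and topographic tables all derive from it.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

N_CHANNELS = len(CHANNELS)

#: Frontal / frontotemporal channels carrying the amyloid-related theta increase.
FRONTOTEMPORAL = ("Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8", "T3", "T4")

#: Centroparietal channels carrying the amyloid-related beta2 decrease.
CENTROPARIETAL = ("C3", "Cz", "C4", "P3", "Pz", "P4")

#: Posterior channels where the resting alpha rhythm dominates.
POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

#: Temporal channels prone to myogenic (EMG) contamination.
TEMPORAL = ("F7", "F8", "T3", "T4", "T5", "T6")

_INDEX = {name.upper(): i for i, name in enumerate(CHANNELS)}


def channel_index(name: str) -> int:
    """Index of a channel in montage order (case-insensitive)."""
    try:
        return _INDEX[name.upper()]
    except KeyError:
        raise KeyError(f"unknown 10-20 channel: {name!r}") from None


def normalize_label(label: str) -> str | None:
    """Map a vendor channel label onto the canonical 10-20 name.

    Strips the common ``EEG `` prefix and reference decorations such as
    ``-REF`` / ``-LE`` / ``-AVG``, case-insensitively.  Returns ``None`` if
    the label does not correspond to one of the 19 montage channels.
    """
    s = label.strip()
    if s.upper().startswith("EEG "):
        s = s[4:]
    for suffix in ("-REF", "-LE", "-AVG", "-A1", "-A2"):
        if s.upper().endswith(suffix):
            s = s[: -len(suffix)]
    s = s.strip().upper()
    # T7/T8/P7/P8 are the modern names for T3/T4/T5/T6
    modern = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}
    s = modern.get(s, s)
    if s in _INDEX:
        return CHANNELS[_INDEX[s]]
    return None


def pair_names() -> list[tuple[str, str]]:
    """The 171 unordered channel pairs (i < j in montage order)."""
    return [
        (CHANNELS[i], CHANNELS[j])
        for i in range(N_CHANNELS)
        for j in range(i + 1, N_CHANNELS)
    ]
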