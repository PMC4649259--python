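"""Electrode montage bookkeeping for the 32-channel gel cap.

Channel names follow the extended 10-20 convention: the leading letters name
the scalp row (F frontal, FC fronto-central, C central, CP centro-parietal,
P parietal, O occipital, ...), odd digits are left-hemisphere sites, even
digits right-hemisphere sites, and a trailing ``z`` marks the midline.

The study montage is a 32-channel active gel cap referenced to FCz. Twelve
peripheral channels, the sites most exposed to facial-muscle and motion
artifact, are dropped before any analysis, leaving the 20-channel montage all
feature and connectivity computations run on. PO7/PO8 were repurposed as EOG
electrodes and are treated as auxiliary channels throughout: never part of
the scalp analysis set.
"""

from __future__ import annotations

import re

#: Full 32-channel scalp montage of the gel cap (online reference FCz).
ACTICAP_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

#: Peripheral channels removed before analysis (motion / myoelectric artifact).
PERIPHERAL_DEFAULT: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F8", "T7", "T8",
    "TP9", "TP10", "P7", "P8", "PO9", "PO10",
)

#: Channels repurposed for electrooculography; auxiliary, never analyzed.
EOG_AUX: tuple[str, ...] = ("PO7", "PO8")

#: The 20-channel montage retained after peripheral removal.
RETAINED_20: tuple[str, ...] = tuple(
    ch for ch in ACTICAP_32 if ch not in PERIPHERAL_DEFAULT
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+|z)$")

# Row prefixes counted as anterior / posterior for the directed-pattern
# definitions. The central row (C, T) belongs to neither.
_ANTERIOR_ROWS = {"Fp", "AF", "F", "FC", "FT"}
_POSTERIOR_ROWS = {"CP", "TP", "P", "PO", "O"}


def split_label(label: str) -> tuple[str, str]:
    """Split a 10-20 label into (row prefix, position token).

    >>> split_label("FC5")
    ('FC', '5')
    >>> split_label("Oz")
    ('O', 'z')
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"not an extended 10-20 label: {label!r}")
    return m.group(1), m.group(2)


def is_midline(label: str) -> bool:
    return split_label(label)[1] == "z"


def is_left(label: str) -> bool:
    _, pos = split_label(label)
    return pos != "z" and int(pos) % 2 == 1


def is_right(label: str) -> bool:
    _, pos = split_label(label)
    return pos != "z" and int(pos) % 2 == 0


def is_anterior(label: str) -> bool:
    return split_label(label)[0] in _ANTERIOR_ROWS


def is_posterior(label: str) -> bool:
    return split_label(label)[0] in _POSTERIOR_ROWS


def occipital_channels(labels) -> list[str]:
    """Channels in the O/PO rows (visual cortex coverage)."""
    return [ch for ch in labels if split_label(ch)[0] in {"O", "PO"}]
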