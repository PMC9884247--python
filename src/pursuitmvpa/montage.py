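"""Synthetic 64-channel montage and the channel groups used in the analysis.

The layout follows the common 64-channel active-electrode arrangement of the
10-10 system (a synthetic stand-in: generated epochs borrow these names so
channel-subset rules are exercised on realistic labels). Seventeen channels
prone to muscle activity and noise are excluded to form the default
47-channel analysis set; two regional groups cover frontal-central and
central-parietal cortex.
"""

from __future__ import annotations

# 64 unique 10-10 labels; includes every name in the exclusion list below.
ACTICAP_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "Iz",
]

#: channels excluded from analysis as muscle/noise prone
NOISE_PRONE = [
    "Fp1", "Fp2", "AF7", "AF8", "F7", "F8", "FT7", "FT8", "FT9", "FT10",
    "T7", "T8", "TP7", "TP8", "TP9", "TP10", "Iz",
]

FRONTAL_CENTRAL = ["FC1", "FC2", "FC3", "FC4", "FC5", "FC6",
                   "Cz", "C1", "C2", "C3", "C4", "C5", "C6"]

CENTRAL_PARIETAL = ["Cz", "C1", "C2", "C3", "C4", "C5", "C6",
                    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6"]

DEFAULT_47 = [ch for ch in ACTICAP_64 if ch not in NOISE_PRONE]

CHANNEL_GROUPS: dict[str, list[str]] = {
    "all-64": list(ACTICAP_64),
    "default-47": list(DEFAULT_47),
    "frontal-central": list(FRONTAL_CENTRAL),
    "central-parietal": list(CENTRAL_PARIETAL),
}


def default_channel_names(n_channels: int) -> list[str]:
    """Channel names for synthetic epochs of arbitrary width.

    Uses the 47-channel analysis set (padded from the full montage, then
    generic labels) so subset operations work out of the box.
    """
    pool = DEFAULT_47 + [ch for ch in ACTICAP_64 if ch not in DEFAULT_47]
    if n_channels <= len(pool):
        return pool[:n_channels]
    return pool + [f"ch{i}" for i in range(len(pool), n_channels)]
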