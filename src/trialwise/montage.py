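"""Idealized 10-10 sensor layout (synthetic stand-in positions).

The packaged montage covers the 64 recorded scalp electrodes of a standard
64-channel cap plus the recovered reference A1 and the infraorbital EOG
channel IO1.  Positions are computed, not measured: each electrode is placed
on a unit sphere by an azimuthal-equidistant scheme — an anterior-posterior
angle per electrode row and a lateral angle per electrode number, both in 18
degree (10%) steps from the vertex.  This is adequate for distance-based
channel adjacency and ROI definitions; it is not a digitized head model.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ChannelLayout

__all__ = ["standard_layout", "SCALP_64", "N2_ROI", "P3B_ROI"]

# fronto-central N2 and centro-parietal P3b ROI electrode sets
N2_ROI = ("FC1", "FC2", "C1", "Cz", "C2")
P3B_ROI = ("CP3", "CP1", "CPz", "CP2", "CP4",
           "P3", "Pz", "P4", "PO3", "POz", "PO4")

# anterior(+)/posterior(-) angle from the vertex, degrees, per row prefix;
# FT/TP share the FC/CP rows, T shares the C row
_ROW_ANGLE = {
    "Fp": 72.0, "AF": 54.0, "F": 36.0, "FT": 18.0, "FC": 18.0,
    "C": 0.0, "T": 0.0, "TP": -18.0, "CP": -18.0,
    "P": -36.0, "PO": -54.0, "O": -72.0,
}

# lateral angle per numeric suffix (odd = left, negative)
_LATERAL = {"z": 0.0, "1": -18.0, "2": 18.0, "3": -36.0, "4": 36.0,
            "5": -54.0, "6": 54.0, "7": -72.0, "8": 72.0,
            "9": -90.0, "10": 90.0}

SCALP_64 = (
    "Fp1 Fp2 "
    "AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT9 FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 FT10 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP9 TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 TP10 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 "
    "O1 Oz O2"
).split()


def _split(label: str) -> tuple[str, str]:
    i = len(label)
    while i > 0 and (label[i - 1].isdigit() or label[i - 1] == "z"):
        i -= 1
    return label[:i], label[i:]


def _position(ap_deg: float, lr_deg: float) -> np.ndarray:
    """Unit-sphere point; +x right, +y anterior, +z up."""
    rho = np.hypot(ap_deg, lr_deg)
    alpha = np.arctan2(lr_deg, ap_deg)  # 0 = straight ahead
    rho_r = np.deg2rad(rho)
    return np.array(
        [np.sin(rho_r) * np.sin(alpha), np.sin(rho_r) * np.cos(alpha), np.cos(rho_r)]
    )


def standard_layout(include_eog: bool = True) -> ChannelLayout:
    """The packaged 65-channel layout (64 cap electrodes + A1), plus IO1 EOG.

    A1 is flagged as scalp so that it participates in the average reference
    once recovered; IO1 is non-scalp.
    """
    labels, positions, scalp = [], [], []
    for label in SCALP_64:
        prefix, suffix = _split(label)
        row = "C" if prefix == "T" else prefix
        labels.append(label)
        positions.append(_position(_ROW_ANGLE[row], _LATERAL[suffix]))
        scalp.append(True)
    # left earlobe reference, slightly below the equator
    labels.append("A1")
    positions.append(_position(0.0, -100.0))
    scalp.append(True)
    if include_eog:
        labels.append("IO1")
        positions.append(_position(95.0, -20.0))
        scalp.append(False)
    return ChannelLayout(
        labels=labels, positions=np.asarray(positions), scalp=np.asarray(scalp)
    )
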