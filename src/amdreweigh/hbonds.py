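"""Backbone hydrogen bonds, turn-type classes and end-to-end distances.

A backbone H-bond is counted in a frame when the carbonyl-O (acceptor) to
amide-N (donor) heavy-atom distance is at most the distance cutoff and
the N-H...O angle at the hydrogen is at least the angle cutoff.  The
donor-acceptor residue offset maps to the classic turn types: i+2 -> i is
a gamma turn, i+3 -> i a 3_10-helical turn, i+4 -> i an alpha-helical
turn.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .amd import FrameWeights, PMFGrid, reweight_histogram
from .constants import DEFAULT_TEMPERATURE
from .trajectory import TrajectorySet

#: Heavy-atom O...N distance cutoff (Angstrom) and D-H...A angle cutoff
#: (degrees).  Chosen to sit just above typical helical H-bond geometry
#: (average N...O 2.78-2.91 A, angles 146-163 deg).
DISTANCE_CUTOFF = 3.0
ANGLE_CUTOFF = 135.0

TURN_CLASSES = {2: "i2_gamma", 3: "i3_310", 4: "i4_alpha"}


def turn_class(acceptor: int, donor: int) -> str:
    """Turn type from the donor - acceptor residue offset."""
    return TURN_CLASSES.get(donor - acceptor, "other")


_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")

#: The C-terminal phenylalaninol appears as both 'Pheol' and 'Pol' in
#: peptaibol H-bond tables; both aliases resolve to the same residue name.
_ALIASES = {"pol": "Pheol"}


def parse_residue_label(label: str) -> tuple[str, int]:
    """Split labels like 'Ala3' or 'Pheol18'/'Pol18' into (name, number)."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse residue label {label!r}")
    name, num = m.group(1), int(m.group(2))
    name = _ALIASES.get(name.lower(), name)
    return name, num


def detect_hbonds(
    traj: TrajectorySet,
    distance_cutoff: float = DISTANCE_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
) -> tuple[dict, pd.DataFrame]:
    """Per-frame backbone H-bond presence and an occupancy table.

    Returns ``(presence, table)`` where ``presence[(acceptor, donor)]``
    is a boolean per-frame array and ``table`` aggregates fraction of
    frames, mean O...N distance and mean N-H...O angle per pair (averages
    over present frames only), sorted by acceptor then donor.  Donors
    without an amide hydrogen (e.g. proline, chain start) are skipped.
    """
    res_ids = [int(r) for r in traj.residue_ids]
    acceptors = {}
    donors = {}
    for rid in res_ids:
        o_idx = traj.atom_index(rid, "O")
        if o_idx >= 0:
            acceptors[rid] = o_idx
        n_idx = traj.atom_index(rid, "N")
        h_idx = traj.atom_index(rid, "H")
        if n_idx >= 0 and h_idx >= 0:
            donors[rid] = (n_idx, h_idx)
    presence = {}
    rows = []
    for acc, o_idx in acceptors.items():
        for don, (n_idx, h_idx) in donors.items():
            if don - acc in (0, 1) or don == acc:
                continue  # self / adjacent amide: covalently constrained
            o = traj.coords[:, o_idx, :]
            n = traj.coords[:, n_idx, :]
            h = traj.coords[:, h_idx, :]
            dist = np.linalg.norm(o - n, axis=1)
            v1 = n - h
            v2 = o - h
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            present = (dist <= distance_cutoff) & (angle >= angle_cutoff)
            presence[(acc, don)] = present
            if present.any():
                rows.append(
                    {
                        "acceptor": acc,
                        "donor": don,
                        "acceptor_label": f"{traj.residue_name(acc)}{acc}",
                        "donor_label": f"{traj.residue_name(don)}{don}",
                        "fraction": present.mean(),
                        "avg_distance": dist[present].mean(),
                        "avg_angle": angle[present].mean(),
                        "turn_class": turn_class(acc, don),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "acceptor", "donor", "acceptor_label", "donor_label",
            "fraction", "avg_distance", "avg_angle", "turn_class",
        ],
    )
    if len(table):
        table = table.sort_values(["acceptor", "donor"]).reset_index(drop=True)
    return presence, table


def classify_turns(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """(Re)assign turn classes and summarise occupancy by class.

    The summary sums bond fractions per class — an aggregate propensity,
    not a probability.
    """
    table = table.copy()
    table["turn_class"] = [
        turn_class(int(a), int(d)) for a, d in zip(table["acceptor"], table["donor"])
    ]
    summary = table.groupby("turn_class")["fraction"].sum()
    return table, summary


def end_to_end(
    traj: TrajectorySet,
    weights: Optional[FrameWeights] = None,
    bins: int = 50,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[np.ndarray, PMFGrid]:
    """Per-frame terminal distance and its reweighted 1D PMF.

    Measured from the first residue's N to the last residue's C-terminal
    heavy atom (the carbonyl C here; toy chains carry no terminal extras).
    """
    res_ids = traj.residue_ids
    first_n = traj.atom_coords(int(res_ids[0]), "N")
    last = None
    for name in ("OXT", "C"):
        idx = traj.atom_index(int(res_ids[-1]), name)
        if idx >= 0:
            last = traj.coords[:, idx, :]
            break
    if last is None:
        raise ValueError("cannot resolve a terminal heavy atom on the last residue")
    distances = np.linalg.norm(last - first_n, axis=1)
    if weights is None:
        weights = FrameWeights.uniform(distances.shape[0], temperature=temperature)
    grid = reweight_histogram(
        distances, weights, bins=bins, temperature=temperature,
        axis_names=("end_to_end",),
    )
    return distances, grid
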