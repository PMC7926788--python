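"""Backbone-dihedral secondary-structure assignment (3-state H/E/C).

A deterministic stand-in for hydrogen-bond-based assigners: residues are
labeled by which region of the Ramachandran plane their (φ, ψ) pair falls
in, then short runs are smoothed away (helices shorter than 4, strands
shorter than 3).  Only the coarse per-pocket H/E/C composition is consumed
downstream, so the approximation relative to energy-based assigners is a
documented, acceptable divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import Chain, Residue, Structure

logger = logging.getLogger(__name__)

#: Cα–Cα distance beyond which consecutive residues are treated as a chain break (Å).
CHAIN_BREAK_CA_DIST = 4.5

MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3


@dataclass
class SSLabel:
    residue: Residue
    label: str  # 'H' | 'E' | 'C'


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def _backbone(res: Residue):
    return res.atom("N"), res.atom("CA"), res.atom("C")


def backbone_dihedrals(chain: Chain) -> list[tuple[float | None, float | None]]:
    """Per-residue (φ, ψ) in degrees; None where undefined.

    φ_i needs C(i-1); ψ_i needs N(i+1).  Dihedrals spanning a chain break
    (consecutive Cα more than 4.5 Å apart) or a missing backbone atom are
    None.
    """
    residues = chain.residues
    bb = [_backbone(r) for r in residues]
    connected = []
    for i in range(len(residues) - 1):
        ca1, ca2 = bb[i][1], bb[i + 1][1]
        ok = (
            ca1 is not None and ca2 is not None
            and np.linalg.norm(ca1.coords - ca2.coords) <= CHAIN_BREAK_CA_DIST
        )
        connected.append(ok)

    out: list[tuple[float | None, float | None]] = []
    for i, (n, ca, c) in enumerate(bb):
        phi = psi = None
        if None in (n, ca, c):
            logger.debug("residue %s missing backbone atoms", residues[i].key)
            out.append((None, None))
            continue
        if i > 0 and connected[i - 1]:
            c_prev = bb[i - 1][2]
            if c_prev is not None:
                phi = dihedral(c_prev.coords, n.coords, ca.coords, c.coords)
        if i < len(residues) - 1 and connected[i]:
            n_next = bb[i + 1][0]
            if n_next is not None:
                psi = dihedral(n.coords, ca.coords, c.coords, n_next.coords)
        out.append((phi, psi))
    return out


def _region_label(phi: float | None, psi: float | None) -> str:
    if phi is None or psi is None:
        return "C"
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "H"
    if -180 <= phi <= -80 and (90 <= psi <= 180 or -180 <= psi <= -170):
        return "E"
    return "C"


def _demote_short_runs(labels: list[str]) -> list[str]:
    out = list(labels)
    i = 0
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        run, length = out[i], j - i
        if (run == "H" and length < MIN_HELIX_RUN) or (run == "E" and length < MIN_STRAND_RUN):
            out[i:j] = ["C"] * length
        i = j
    return out


def assign_ss(chain: Chain) -> list[SSLabel]:
    """H/E/C label per residue of the chain."""
    dihedrals = backbone_dihedrals(chain)
    raw = [_region_label(phi, psi) for phi, psi in dihedrals]
    smoothed = _demote_short_runs(raw)
    return [SSLabel(residue=r, label=lab) for r, lab in zip(chain.residues, smoothed)]


def assign_ss_structure(structure: Structure) -> dict[tuple, str]:
    """Labels for every polymer residue, keyed by (chain_id, number, icode)."""
    out: dict[tuple, str] = {}
    for chain in structure.chains:
        for ss in assign_ss(chain):
            out[ss.residue.key] = ss.label
    return out


def ss_to_table(structure: Structure):
    import pandas as pd

    rows = []
    for chain in structure.chains:
        for ss in assign_ss(chain):
            rows.append({
                "chain": ss.residue.chain_id,
                "number": ss.residue.number,
                "icode": ss.residue.icode,
                "label": ss.label,
            })
    return pd.DataFrame(rows, columns=["chain", "number", "icode", "label"])
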