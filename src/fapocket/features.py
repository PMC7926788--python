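"""Pocket descriptor vectors.

The fixed 14-descriptor contract combines alpha-sphere geometry (counts,
radii, Monte-Carlo union volume, compactness), lining-residue
physico-chemistry (Kyte-Doolittle hydrophobicity, polar/charged/aromatic
fractions) and secondary-structure composition of the lining.  The field
order is part of the trained-model contract and is versioned: a model
refuses feature matrices from a different schema.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .constants import (
    AROMATIC_RESIDUES,
    CHARGED_RESIDUES,
    KYTE_DOOLITTLE,
    POLAR_RESIDUES,
)
from .detect import AlphaSphere, Pocket
from .structure import Structure

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "fapocket-features-1"

FEATURE_NAMES = (
    "n_spheres",
    "mean_radius",
    "max_radius",
    "apolar_fraction",
    "volume",
    "compactness",
    "hydrophobicity",
    "polar_residue_fraction",
    "charged_residue_fraction",
    "aromatic_residue_fraction",
    "helix_fraction",
    "strand_fraction",
    "coil_fraction",
    "n_lining_residues",
)


@dataclass
class FeatureVector:
    n_spheres: float
    mean_radius: float
    max_radius: float
    apolar_fraction: float
    volume: float
    compactness: float
    hydrophobicity: float
    polar_residue_fraction: float
    charged_residue_fraction: float
    aromatic_residue_fraction: float
    helix_fraction: float
    strand_fraction: float
    coil_fraction: float
    n_lining_residues: float

    def __post_init__(self) -> None:
        ss_sum = self.helix_fraction + self.strand_fraction + self.coil_fraction
        if abs(ss_sum - 1.0) > 1e-9:
            raise ValueError(f"H/E/C fractions sum to {ss_sum}, not 1")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)


def pocket_volume(
    spheres: list[AlphaSphere], n_samples: int = 20_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo volume of the union of spheres (ų) and its standard error.

    Uniform sampling in the axis-aligned bounding box of the spheres.
    """
    if not spheres:
        raise ValueError("no spheres")
    if n_samples < 10_000:
        raise ValueError("n_samples must be >= 10000")
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    # inside-union test against all spheres (pocket sphere counts are small)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    inside = (d2 <= radii[None, :] ** 2).any(axis=1)
    p = inside.mean()
    volume = box_vol * p
    stderr = box_vol * float(np.sqrt(p * (1 - p) / n_samples))
    return float(volume), stderr


def compute_features(
    pocket: Pocket,
    structure: Structure,
    ss_labels: dict[tuple, str],
    n_volume_samples: int = 20_000,
    seed: int = 0,
) -> FeatureVector:
    """Assemble the fixed-order descriptor vector for a finalized pocket.

    Ligand residues in the lining are excluded from residue-class and SS
    composition.  Residues without a hydropathy entry (non-standard codes)
    contribute zero weight to the hydrophobicity mean; lining residues
    without an SS label count as coil.
    """
    lining = [r for r in pocket.lining_residues if r.kind == "polymer"]
    if not lining:
        raise ValueError(f"pocket {pocket.id}: empty polymer lining (malformed)")

    radii = np.array([s.radius for s in pocket.spheres])
    centers = pocket.centers()
    if len(centers) > 1:
        diff = centers[:, None, :] - centers[None, :, :]
        dists = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(len(centers), k=1)
        compactness = float(dists[iu].mean())
    else:
        compactness = 0.0

    volume, _se = pocket_volume(pocket.spheres, n_volume_samples, seed)

    n = len(lining)
    kd = [KYTE_DOOLITTLE[r.name] for r in lining if r.name in KYTE_DOOLITTLE]
    hydrophobicity = float(np.mean(kd)) if kd else 0.0
    polar = sum(r.name in POLAR_RESIDUES for r in lining) / n
    charged = sum(r.name in CHARGED_RESIDUES for r in lining) / n
    aromatic = sum(r.name in AROMATIC_RESIDUES for r in lining) / n

    labels = [ss_labels.get(r.key, "C") for r in lining]
    helix = labels.count("H") / n
    strand = labels.count("E") / n
    coil = 1.0 - helix - strand

    return FeatureVector(
        n_spheres=float(pocket.n_spheres),
        mean_radius=float(radii.mean()),
        max_radius=float(radii.max()),
        apolar_fraction=float(pocket.apolar_fraction),
        volume=volume,
        compactness=compactness,
        hydrophobicity=hydrophobicity,
        polar_residue_fraction=polar,
        charged_residue_fraction=charged,
        aromatic_residue_fraction=aromatic,
        helix_fraction=helix,
        strand_fraction=strand,
        coil_fraction=coil,
        n_lining_residues=float(n),
    )


def features_to_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    return np.array([v.to_array() for v in vectors], dtype=float)


def matrix_to_frame(X: np.ndarray):
    import pandas as pd

    return pd.DataFrame(X, columns=list(FEATURE_NAMES))


class FeatureNormalizer:
    """Per-column z-scoring with training-fold statistics.

    Zero-variance columns pass through unscaled (logged); statistics are
    stored inside the trained model so prediction uses training-time scaling.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureNormalizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "zero-variance feature columns passed through unscaled: %s",
                [i for i in np.flatnonzero(constant)],
            )
            self.mean_ = np.where(constant, 0.0, self.mean_)
            sd = np.where(constant, 1.0, sd)
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"column count {X.shape[1]} != fitted {self.mean_.shape[0]}"
            )
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
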