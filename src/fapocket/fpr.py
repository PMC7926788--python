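"""False-positive-rate estimation on a negative pool.

The negative pool holds ligand-bound structures whose ligands are *not*
fatty acids (an exclusion list of FA-like chemical-component codes is
applied first).  A random sample of the pool is run through the full
detection → featurization → two-model scoring pipeline; the FPR of a model
is the percentage of detected pockets it calls positive, and the consensus
FPR uses the both-models rule, so it can never exceed the smaller per-model
rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import TrainedModel, consensus, predict
from .curation import DEFAULT_CONTACT_DISTANCE  # noqa: F401  (shared defaults)
from .detect import DetectionParams, detect_pockets
from .features import compute_features, features_to_matrix
from .ss import assign_ss_structure
from .structure import Structure

logger = logging.getLogger(__name__)


@dataclass
class PoolEntry:
    id: str
    structure: Structure
    ligand_codes: tuple[str, ...] = ()


@dataclass
class NegativePool:
    entries: list[PoolEntry] = field(default_factory=list)
    exclusion_applied: bool = False

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FPRReport:
    n_structures_sampled: int
    n_pockets_total: int
    n_positive_all_species: int
    n_positive_human: int
    n_positive_consensus: int
    fpr_all_species: float
    fpr_human: float
    fpr_consensus: float
    sample_seed: int
    manifest: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_structures_sampled": self.n_structures_sampled,
            "n_pockets_total": self.n_pockets_total,
            "n_positive_all_species": self.n_positive_all_species,
            "n_positive_human": self.n_positive_human,
            "n_positive_consensus": self.n_positive_consensus,
            "fpr_all_species": self.fpr_all_species,
            "fpr_human": self.fpr_human,
            "fpr_consensus": self.fpr_consensus,
            "sample_seed": self.sample_seed,
        }])


def apply_exclusion(pool: NegativePool, exclusion: set[str]) -> NegativePool:
    """Strip excluded ligand codes from every entry's structure."""
    codes = {c.upper() for c in exclusion}
    entries = []
    for e in pool.entries:
        st = e.structure.without_ligands(codes=codes)
        kept = tuple(l.name.upper() for l in st.ligands)
        entries.append(PoolEntry(id=e.id, structure=st, ligand_codes=kept))
    return NegativePool(entries=entries, exclusion_applied=True)


def sample_pool(pool: NegativePool, n: int, seed: int) -> NegativePool:
    """Uniform sample of n entries without replacement, seed-reproducible."""
    if n > len(pool):
        raise ValueError(f"sample size {n} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool.entries), size=n, replace=False)
    entries = [pool.entries[i] for i in sorted(idx)]
    return NegativePool(entries=entries, exclusion_applied=pool.exclusion_applied)


def compute_fpr(n_positive: int, n_total: int) -> float:
    """Positive-call percentage, to one decimal."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    return round(100.0 * n_positive / n_total, 1)


def evaluate_fpr(
    pool: NegativePool,
    model_all_species: TrainedModel,
    model_human: TrainedModel,
    detection_params: DetectionParams = DetectionParams(),
    n_sample: int | None = None,
    seed: int = 0,
    volume_seed: int = 0,
) -> FPRReport:
    """Run detection + both models over a pool sample; report per-model and
    consensus positive counts and FPR percentages.

    Ligand atoms are removed before detection, matching the training
    convention.  Detection parameters are the training-time ones.
    """
    sampled = sample_pool(pool, n_sample, seed) if n_sample is not None else pool
    feats = []
    for entry in sampled.entries:
        apo = entry.structure.without_ligands()
        try:
            pockets = detect_pockets(apo, detection_params)
        except ValueError:
            logger.warning("%s: too few atoms, skipped", entry.id)
            continue
        if not pockets:
            continue
        ss = assign_ss_structure(apo)
        for pocket in pockets:
            feats.append(compute_features(pocket, apo, ss, seed=volume_seed))
    if not feats:
        raise RuntimeError(
            "no pockets detected over the sampled pool — detection is likely "
            "misconfigured for these structures"
        )
    X = features_to_matrix(feats)
    scores_a = predict(model_all_species, X)
    scores_h = predict(model_human, X)
    cons = consensus(scores_a, scores_h)
    n_total = len(feats)
    n_a = sum(s.positive for s in scores_a)
    n_h = sum(s.positive for s in scores_h)
    n_c = sum(cons)
    return FPRReport(
        n_structures_sampled=len(sampled.entries),
        n_pockets_total=n_total,
        n_positive_all_species=n_a,
        n_positive_human=n_h,
        n_positive_consensus=n_c,
        fpr_all_species=compute_fpr(n_a, n_total),
        fpr_human=compute_fpr(n_h, n_total),
        fpr_consensus=compute_fpr(n_c, n_total),
        sample_seed=seed,
        manifest=[e.id for e in sampled.entries],
    )
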