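"""Cα model quality metrics against a reference structure.

Five metrics, all computed on Cα coordinates in a shared frame. Two are
sequence-dependent — they pair atoms by residue index and so penalize a
wrong sequence register:

* RMSD over residue-matched pairs (optionally after Kabsch
  superposition; the default is frame-fixed because traced models live
  in the map's own coordinate frame, like the fitted references).
* GDT-TS: the mean over cutoffs {1, 2, 4, 8} Å of the percentage of
  reference residues whose matched model Cα lies within the cutoff.
  Normalizing by the reference length makes unmodeled residues count as
  misses, so a partial model caps its own GDT-TS.

Three are sequence-independent — they see only point clouds and so
reward a geometrically correct trace even when the register is wrong
(reversed-chain models score well here and poorly above, a diagnostic
contrast worth preserving):

* unlabeled RMSD: root-mean-square of each model Cα's distance to its
  nearest reference Cα (model→reference direction by default).
* recall@t: fraction of reference Cα closer than t to any model Cα.
* precision@t: fraction of model Cα closer than t to any reference Cα.
  "Closer than" is strict, and recall(a, b) == precision(b, a) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .map_io import CaStructure
from .seq_threading import CaModel

__all__ = [
    "EvalReport",
    "ca_rmsd",
    "gdt_ts",
    "unlabeled_rmsd",
    "recall_precision",
    "evaluate",
    "kabsch_superpose",
]

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


@dataclass
class EvalReport:
    rmsd: float
    gdt_ts: float
    unlabeled_rmsd: float
    recall_2: float
    recall_3: float
    precision_2: float
    precision_3: float
    n_model: int
    n_reference: int

    def as_dict(self) -> dict[str, float]:
        return {
            "rmsd": self.rmsd,
            "gdt_ts": self.gdt_ts,
            "unlabeled_rmsd": self.unlabeled_rmsd,
            "recall_2": self.recall_2,
            "recall_3": self.recall_3,
            "precision_2": self.precision_2,
            "precision_3": self.precision_3,
            "n_model": self.n_model,
            "n_reference": self.n_reference,
        }


def _structure(obj: CaModel | CaStructure) -> CaStructure:
    return obj.structure if isinstance(obj, CaModel) else obj


def _matched_pairs(
    model: CaStructure, reference: CaStructure
) -> tuple[np.ndarray, np.ndarray]:
    ref_lookup = {i: p for i, _, p in reference.residues}
    pairs = [
        (p, ref_lookup[i]) for i, _, p in model.residues if i in ref_lookup
    ]
    if not pairs:
        raise ValueError("model and reference share no residue indices")
    a = np.stack([p for p, _ in pairs])
    b = np.stack([q for _, q in pairs])
    return a, b


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``mobile`` onto ``target``."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ mc.T).T + target.mean(axis=0)


def ca_rmsd(
    model: CaModel | CaStructure,
    reference: CaStructure,
    superpose: bool = False,
) -> float:
    """RMSD over residue-index-matched Cα pairs.

    Frame-fixed by default; ``superpose`` applies a Kabsch least-squares
    fit of the matched model atoms onto the reference first.
    """
    a, b = _matched_pairs(_structure(model), reference)
    if superpose:
        a = kabsch_superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def gdt_ts(model: CaModel | CaStructure, reference: CaStructure) -> float:
    """Global distance test total score, frame-fixed, 0–100.

    Each cutoff's percentage is normalized by the reference length, so
    residues the model does not cover count as misses at every cutoff.
    """
    m = _structure(model)
    a, b = _matched_pairs(m, reference)
    d = np.linalg.norm(a - b, axis=1)
    n_ref = len(reference)
    percentages = [100.0 * np.sum(d <= c) / n_ref for c in GDT_CUTOFFS]
    return float(np.mean(percentages))


def unlabeled_rmsd(
    model: CaModel | CaStructure,
    reference: CaStructure,
    direction: str = "model_to_reference",
) -> float:
    """RMSD of nearest-Cα distances, ignoring sequence identity."""
    m = _structure(model)
    a = m.coords
    b = reference.coords
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both structures must be non-empty")
    if direction == "reference_to_model":
        a, b = b, a
    elif direction != "model_to_reference":
        raise ValueError(f"unknown direction {direction!r}")
    d, _ = cKDTree(b).query(a)
    return float(np.sqrt(np.mean(d**2)))


def recall_precision(
    model: CaModel | CaStructure,
    reference: CaStructure,
    threshold: float,
) -> tuple[float, float]:
    """(recall, precision) at a strict distance threshold.

    Recall: fraction of reference Cα strictly closer than ``threshold``
    to any model Cα; precision: the same with roles swapped.
    """
    a = _structure(model).coords
    b = reference.coords
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both structures must be non-empty")
    d_ref, _ = cKDTree(a).query(b)  # each reference atom -> nearest model atom
    d_mod, _ = cKDTree(b).query(a)
    recall = float(np.sum(d_ref < threshold) / len(b))
    precision = float(np.sum(d_mod < threshold) / len(a))
    return recall, precision


def evaluate(
    model: CaModel | CaStructure,
    reference: CaStructure,
    superpose: bool = False,
) -> EvalReport:
    """All five metrics at both recall/precision thresholds."""
    m = _structure(model)
    r2, p2 = recall_precision(m, reference, 2.0)
    r3, p3 = recall_precision(m, reference, 3.0)
    return EvalReport(
        rmsd=ca_rmsd(m, reference, superpose=superpose),
        gdt_ts=gdt_ts(m, reference),
        unlabeled_rmsd=unlabeled_rmsd(m, reference),
        recall_2=r2,
        recall_3=r3,
        precision_2=p2,
        precision_3=p3,
        n_model=len(m),
        n_reference=len(reference),
    )
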