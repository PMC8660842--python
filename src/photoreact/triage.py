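"""Outlier triage: explain high-confidence misclassifications.

Misclassified molecules whose vote probability exceeds a threshold (strict
``> 0.8`` by default) are collected as FP/FN entries and explained by (a) the
data-quality flags of their spectrum records — boundary-proximal peaks,
MEC values near the threshold, suspected log-unit MEC transcription — and
(b) a Tanimoto similarity search against the training set: a highly similar
training neighbor whose label matches the (wrong) prediction marks a
training-set conflict, the situation where the model faithfully reproduced a
contradictory or noisy training example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import NEG, POS, LabelConfig, SpectrumRecord, quality_flags
from .models import Prediction

TRIAGE_REASONS = (
    "near_lower_endpoint",
    "near_mec_threshold",
    "suspect_log_mec",
    "training_neighbor_conflict",
    "unexplained",
)


@dataclass
class Neighbor:
    mol_id: str
    tanimoto: float
    label: str


@dataclass
class TriageEntry:
    mol_id: str
    error_type: str  # FP or FN
    probability: float
    predicted: str
    truth: str
    reasons: frozenset[str] = frozenset()
    neighbors: list[Neighbor] = field(default_factory=list)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| between two equal-length binary
    fingerprints; two all-zero fingerprints are 1.0 by convention."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def high_confidence_errors(
    preds: Sequence[Prediction], truth: Mapping[str, str], p_threshold: float = 0.8
) -> list[TriageEntry]:
    """Misclassifications with probability strictly above ``p_threshold``,
    typed FP (predicted POS, truly NEG) or FN (predicted NEG, truly POS)."""
    entries = []
    for p in preds:
        t = truth[p.mol_id]
        if p.predicted == t or p.probability <= p_threshold:
            continue
        error_type = "FP" if p.predicted == POS else "FN"
        entries.append(
            TriageEntry(p.mol_id, error_type, p.probability, p.predicted, t)
        )
    return entries


def explain(
    entry: TriageEntry,
    spectrum: SpectrumRecord | None,
    train_fps: Mapping[str, np.ndarray],
    train_labels: Mapping[str, str],
    query_fp: np.ndarray,
    k_neighbors: int = 3,
    sim_floor: float = 0.7,
    label_cfg: LabelConfig | None = None,
) -> TriageEntry:
    """Populate reasons and nearest training neighbors for one entry.

    Reasons come from the spectrum record's quality flags plus
    ``training_neighbor_conflict`` when a neighbor at Tanimoto >= ``sim_floor``
    carries the label matching the wrong prediction; ``unexplained`` when
    nothing fires. Neighbors are sorted by descending similarity (top-k),
    excluding the query molecule itself.
    """
    reasons: set[str] = set()
    if spectrum is not None:
        qf = quality_flags(spectrum, label_cfg)
        reasons |= qf & {"near_lower_endpoint", "near_mec_threshold", "suspect_log_mec"}
    sims = []
    for tid, fp in train_fps.items():
        if tid == entry.mol_id:
            continue
        sims.append((tanimoto(query_fp, fp), tid))
    sims.sort(key=lambda t: (-t[0], t[1]))
    neighbors = [
        Neighbor(tid, sim, train_labels[tid]) for sim, tid in sims[:k_neighbors]
    ]
    if any(n.tanimoto >= sim_floor and n.label == entry.predicted for n in neighbors):
        reasons.add("training_neighbor_conflict")
    if not reasons:
        reasons.add("unexplained")
    entry.reasons = frozenset(reasons)
    entry.neighbors = neighbors
    return entry


def triage_report(
    preds: Sequence[Prediction],
    truth: Mapping[str, str],
    spectra: Mapping[str, SpectrumRecord],
    fingerprints: Mapping[str, np.ndarray],
    train_ids: Sequence[str],
    train_labels: Mapping[str, str],
    p_threshold: float = 0.8,
    k_neighbors: int = 3,
    sim_floor: float = 0.7,
) -> list[TriageEntry]:
    """End-to-end triage: select high-confidence errors and explain each."""
    train_fps = {tid: fingerprints[tid] for tid in train_ids if tid in fingerprints}
    entries = high_confidence_errors(preds, truth, p_threshold)
    out = []
    for e in entries:
        if e.mol_id not in fingerprints:
            e.reasons = frozenset({"unexplained"})
            out.append(e)
            continue
        out.append(
            explain(
                e,
                spectra.get(e.mol_id),
                train_fps,
                train_labels,
                fingerprints[e.mol_id],
                k_neighbors=k_neighbors,
                sim_floor=sim_floor,
            )
        )
    return out


def triage_to_frame(entries: Sequence[TriageEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "mol_id": e.mol_id,
                "error_type": e.error_type,
                "probability": e.probability,
                "reasons": ";".join(sorted(e.reasons)),
                "neighbors": ";".join(
                    f"{n.mol_id}:{n.tanimoto:.2f}:{n.label}" for n in e.neighbors
                ),
            }
        )
    return pd.DataFrame(rows, columns=["mol_id", "error_type", "probability", "reasons", "neighbors"])
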