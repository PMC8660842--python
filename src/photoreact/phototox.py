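"""Cross-evaluation of the UV-Vis spectrum class against in vitro
phototoxicity outcomes (3T3 NRU assay).

The POS spectrum class is treated as a toxicity alarm: sensitivity is the
fraction of toxic molecules flagged POS, specificity the fraction of
non-toxic molecules labeled NEG. Cross-tabs built from ML-predicted and from
experimental spectrum classes can be compared side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .evaluation import round2
from .labeling import NEG, POS

TOXIC = "toxic"
NON_TOXIC = "non_toxic"


@dataclass(frozen=True)
class PhototoxRecord:
    mol_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in (TOXIC, NON_TOXIC):
            raise ValueError(f"outcome must be '{TOXIC}' or '{NON_TOXIC}'")


@dataclass
class CrossTab:
    """2x2 counts (rows: toxic / non-toxic; columns: POS / NEG) with the
    POS-as-alarm sensitivity and specificity."""

    toxic_pos: int
    toxic_neg: int
    nontoxic_pos: int
    nontoxic_neg: int

    @property
    def n(self) -> int:
        return self.toxic_pos + self.toxic_neg + self.nontoxic_pos + self.nontoxic_neg

    @property
    def se_tox(self) -> float:
        denom = self.toxic_pos + self.toxic_neg
        return self.toxic_pos / denom if denom else math.nan

    @property
    def sp_tox(self) -> float:
        denom = self.nontoxic_pos + self.nontoxic_neg
        return self.nontoxic_neg / denom if denom else math.nan

    @property
    def se_undefined(self) -> bool:
        return self.toxic_pos + self.toxic_neg == 0

    @property
    def sp_undefined(self) -> bool:
        return self.nontoxic_pos + self.nontoxic_neg == 0

    @property
    def concordant(self) -> int:
        """Molecules where the spectrum class agrees with the assay outcome."""
        return self.toxic_pos + self.nontoxic_neg

    def summary(self) -> dict:
        return {
            "counts": [[self.toxic_pos, self.toxic_neg], [self.nontoxic_pos, self.nontoxic_neg]],
            "n": self.n,
            "se_tox": None if self.se_undefined else round2(self.se_tox),
            "sp_tox": None if self.sp_undefined else round2(self.sp_tox),
            "concordant": self.concordant,
        }


def crosstab(classes: Mapping[str, str], outcomes: Sequence[PhototoxRecord]) -> CrossTab:
    """Cross-tabulate spectrum classes (predicted or experimental) against
    assay outcomes; every outcome molecule must have a class."""
    missing = [r.mol_id for r in outcomes if r.mol_id not in classes]
    if missing:
        raise ValueError(f"no spectrum class for outcome molecules: {missing}")
    ct = {"tp": 0, "tn": 0, "np": 0, "nn": 0}
    for r in outcomes:
        pos = classes[r.mol_id] == POS
        if r.outcome == TOXIC:
            ct["tp" if pos else "tn"] += 1
        else:
            ct["np" if pos else "nn"] += 1
    return CrossTab(ct["tp"], ct["tn"], ct["np"], ct["nn"])


def compare_predictors(ct_predicted: CrossTab, ct_experimental: CrossTab) -> dict:
    """Side-by-side comparison of two cross-tabs over the same cohort:
    concordant totals and per-cell deltas (predicted minus experimental)."""
    if ct_predicted.n != ct_experimental.n:
        raise ValueError(
            f"cohort sizes differ: {ct_predicted.n} vs {ct_experimental.n}"
        )
    cells = ("toxic_pos", "toxic_neg", "nontoxic_pos", "nontoxic_neg")
    return {
        "n": ct_predicted.n,
        "predicted": ct_predicted.summary(),
        "experimental": ct_experimental.summary(),
        "concordant": {
            "predicted": ct_predicted.concordant,
            "experimental": ct_experimental.concordant,
            "delta": ct_predicted.concordant - ct_experimental.concordant,
        },
        "cell_deltas": {
            c: getattr(ct_predicted, c) - getattr(ct_experimental, c) for c in cells
        },
    }
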