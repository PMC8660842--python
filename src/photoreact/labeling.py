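"""ICH S10-based POS/NEG spectrum labeling from UV-Vis peak lists.

A molecule is labeled POS (photoreactive potential) when at least one listed
absorption maximum lies in the 290-700 nm window with a molar extinction
coefficient (MEC) of at least 1000 L·mol⁻¹·cm⁻¹; NEG otherwise. POS records
get a sub-category from the strongest in-window peak; NEG records get per-peak
region flags; every record gets advisory data-quality flags modeled on the
failure modes seen in literature peak lists (log-unit MEC transcription,
boundary-proximal peaks, missing MEC values).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

POS = "POS"
NEG = "NEG"

# POS sub-categories: bands of the maximal in-window MEC, half-open at the
# upper edge so every value lands in exactly one band.
POS_BANDS = ("mec_1k_5k", "mec_5k_10k", "mec_ge_10k")

NEG_FLAGS = (
    "below290_lowMEC",
    "below290_highMEC",
    "above700_lowMEC",
    "above700_highMEC",
    "inwindow_le900",
    "inwindow_gt900",
)

QUALITY_FLAGS = (
    "suspect_log_mec",
    "near_lower_endpoint",
    "near_mec_threshold",
    "missing_mec",
    "empty_list",
)


@dataclass(frozen=True)
class Peak:
    """One absorption maximum: wavelength (nm) and MEC (L·mol⁻¹·cm⁻¹, may be
    missing in incomplete literature lists)."""

    wavelength: float
    mec: float | None = None

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.mec is not None and self.mec < 0:
            raise ValueError("MEC must be nonnegative when present")


@dataclass(frozen=True)
class SpectrumRecord:
    mol_id: str
    peaks: tuple[Peak, ...] = ()
    solvent: str = ""
    source_id: str = ""

    def merged_with(self, other: "SpectrumRecord") -> "SpectrumRecord":
        """Union of peak lists (used when duplicate structures are merged)."""
        extra = tuple(p for p in other.peaks if p not in self.peaks)
        return SpectrumRecord(self.mol_id, self.peaks + extra, self.solvent, self.source_id)


@dataclass(frozen=True)
class LabelConfig:
    """Photoreactivity window and MEC threshold (all bounds inclusive)."""

    window_low: float = 290.0
    window_high: float = 700.0
    mec_threshold: float = 1000.0
    # Advisory quality-flag windows (never used for labeling):
    near_endpoint_range: tuple[float, float] = (281.0, 317.0)
    near_threshold_range: tuple[float, float] = (661.0, 1500.0)
    log_mec_range: tuple[float, float] = (3.0, 5.0)

    def __post_init__(self) -> None:
        if not self.window_low < self.window_high:
            raise ValueError("window_low must be < window_high")
        if not self.mec_threshold > 0:
            raise ValueError("mec_threshold must be positive")

    def in_window(self, wavelength: float) -> bool:
        return self.window_low <= wavelength <= self.window_high


@dataclass(frozen=True)
class SpectrumClass:
    label: str
    pos_band: str = "none"
    neg_flags: frozenset[str] = frozenset()
    quality_flags: frozenset[str] = frozenset()


def _qualifies(peak: Peak, cfg: LabelConfig) -> bool:
    return peak.mec is not None and cfg.in_window(peak.wavelength) and peak.mec >= cfg.mec_threshold


def pos_subcategory(rec: SpectrumRecord, cfg: LabelConfig | None = None) -> str:
    """Band of the peak with the highest MEC within the window; POS records only."""
    cfg = cfg or LabelConfig()
    in_window = [p.mec for p in rec.peaks if _qualifies(p, cfg)]
    if not in_window:
        raise ValueError(f"pos_subcategory called on a NEG record ({rec.mol_id})")
    top = max(in_window)
    if top >= 10_000:
        return "mec_ge_10k"
    if top >= 5_000:
        return "mec_5k_10k"
    return "mec_1k_5k"


def neg_peak_flags(rec: SpectrumRecord, cfg: LabelConfig | None = None) -> frozenset[str]:
    """Per-peak (λ, MEC) region flags for a NEG record.

    Peaks exactly at the window edges count as in-window; in-window NEG peaks
    split at MEC 900 (by construction of NEG no in-window peak reaches the
    1000 threshold). Peaks without a MEC fall in the low-MEC rows.
    """
    cfg = cfg or LabelConfig()
    flags: set[str] = set()
    for p in rec.peaks:
        mec = p.mec
        if p.wavelength < cfg.window_low:
            flags.add("below290_highMEC" if (mec is not None and mec >= cfg.mec_threshold) else "below290_lowMEC")
        elif p.wavelength > cfg.window_high:
            flags.add("above700_highMEC" if (mec is not None and mec >= cfg.mec_threshold) else "above700_lowMEC")
        else:
            flags.add("inwindow_gt900" if (mec is not None and mec > 900) else "inwindow_le900")
    return frozenset(flags)


def quality_flags(rec: SpectrumRecord, cfg: LabelConfig | None = None) -> frozenset[str]:
    """Advisory data-quality heuristics derived from known literature-list
    failure modes; never used in labeling itself."""
    cfg = cfg or LabelConfig()
    flags: set[str] = set()
    if not rec.peaks:
        return frozenset({"empty_list"})
    present = [p.mec for p in rec.peaks if p.mec is not None]
    lo, hi = cfg.log_mec_range
    if present and all(lo <= m <= hi for m in present):
        flags.add("suspect_log_mec")
    e_lo, e_hi = cfg.near_endpoint_range
    if any(e_lo <= p.wavelength <= e_hi for p in rec.peaks):
        flags.add("near_lower_endpoint")
    t_lo, t_hi = cfg.near_threshold_range
    if any(
        cfg.in_window(p.wavelength) and p.mec is not None and t_lo <= p.mec <= t_hi
        for p in rec.peaks
    ):
        flags.add("near_mec_threshold")
    if any(p.mec is None for p in rec.peaks):
        flags.add("missing_mec")
    return frozenset(flags)


def label_spectrum(rec: SpectrumRecord, cfg: LabelConfig | None = None) -> SpectrumClass:
    """Assign the POS/NEG class plus sub-category and flags for one record."""
    cfg = cfg or LabelConfig()
    if any(_qualifies(p, cfg) for p in rec.peaks):
        return SpectrumClass(
            label=POS,
            pos_band=pos_subcategory(rec, cfg),
            quality_flags=quality_flags(rec, cfg),
        )
    return SpectrumClass(
        label=NEG,
        pos_band="none",
        neg_flags=neg_peak_flags(rec, cfg) if rec.peaks else frozenset(),
        quality_flags=quality_flags(rec, cfg),
    )


def split_dataset(
    labeled: Sequence, sizes: tuple[int, int, int], seed: int
) -> tuple[list, list, list]:
    """Uniform random partition into (train, test I, test II); reproducible
    under ``seed``; errors if the sizes exceed the population."""
    n_train, n_t1, n_t2 = sizes
    total = n_train + n_t1 + n_t2
    if total > len(labeled):
        raise ValueError(f"requested {total} items from a population of {len(labeled)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled))
    pick = lambda idx: [labeled[i] for i in idx]
    return (
        pick(order[:n_train]),
        pick(order[n_train : n_train + n_t1]),
        pick(order[n_train + n_t1 : total]),
    )


# ---------------------------------------------------------------------------
# CSV interchange


def read_peaks_csv(path: str | Path) -> list[SpectrumRecord]:
    """Read a per-peak CSV (mol_id, wavelength_nm, mec, solvent, source_id;
    mec may be blank) into one SpectrumRecord per molecule."""
    by_id: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            mol_id = row["mol_id"]
            entry = by_id.setdefault(
                mol_id,
                {"peaks": [], "solvent": row.get("solvent", "") or "", "source_id": row.get("source_id", "") or ""},
            )
            wl = row.get("wavelength_nm", "")
            if wl is None or str(wl).strip() == "":
                continue  # row registers the molecule but lists no peak
            mec_raw = row.get("mec", "")
            mec = None if mec_raw is None or str(mec_raw).strip() == "" else float(mec_raw)
            entry["peaks"].append(Peak(float(wl), mec))
    return [
        SpectrumRecord(mol_id, tuple(v["peaks"]), v["solvent"], v["source_id"])
        for mol_id, v in by_id.items()
    ]


def write_labels_csv(
    records: Iterable[SpectrumRecord], path: str | Path, cfg: LabelConfig | None = None
) -> "pd.DataFrame":
    """Label every record and write mol_id/label/pos_band/flags CSV."""
    import pandas as pd

    cfg = cfg or LabelConfig()
    rows = []
    for rec in records:
        sc = label_spectrum(rec, cfg)
        rows.append(
            {
                "mol_id": rec.mol_id,
                "label": sc.label,
                "pos_band": sc.pos_band,
                "neg_flags": ";".join(sorted(sc.neg_flags)),
                "quality_flags": ";".join(sorted(sc.quality_flags)),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def class_distribution(classes: Iterable[SpectrumClass]) -> dict[str, float]:
    """Percentage breakdown of POS bands and NEG flags over a labeled set,
    in the layout of the study's feature-distribution table."""
    classes = list(classes)
    pos = [c for c in classes if c.label == POS]
    neg = [c for c in classes if c.label == NEG]
    out: dict[str, float] = {}
    for band in POS_BANDS:
        out[f"pos_{band}"] = 100.0 * sum(c.pos_band == band for c in pos) / len(pos) if pos else math.nan
    n_neg_flags = sum(len(c.neg_flags) for c in neg)
    for flag in NEG_FLAGS:
        out[f"neg_{flag}"] = (
            100.0 * sum(flag in c.neg_flags for c in neg) / n_neg_flags if n_neg_flags else math.nan
        )
    return out
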