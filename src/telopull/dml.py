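"""Dimethyl-labeling (DML) crossover ratio analysis.

The isotope-labeling arm of the pulldown screen: peptides from bait
and control pulldowns carry light/medium dimethyl labels and are mixed
1:1, so each run yields one normalized bait/control ratio per protein.
A label switch between the two runs ("forward": bait light / control
medium inverted relative to "reverse") controls for labeling bias. A
protein is called a binder only when its forward AND reverse ratios
both exceed the threshold — a concordance requirement that makes
spurious single-set outliers essentially impossible to call.

An incorporation check (labeled-peptide fraction >= 95% per sample)
gates the whole analysis; the fraction itself is an upstream input
from the peptide-level search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ProteinGroupTable

__all__ = [
    "DmlRatioRecord",
    "IncorporationReport",
    "IncorporationError",
    "check_incorporation",
    "orient_ratios",
    "call_concordant",
    "records_to_frame",
]


@dataclass(frozen=True)
class DmlRatioRecord:
    """Oriented forward/reverse log2 bait-over-control ratios for one protein."""

    protein_id: str
    fwd_log2: Optional[float]
    rev_log2: Optional[float]
    call: str = "pending"  # "bait" | "control" | "none" | "pending"

    @property
    def complete(self) -> bool:
        return self.fwd_log2 is not None and self.rev_log2 is not None


@dataclass(frozen=True)
class IncorporationReport:
    sample: str
    labeled_fraction: float
    min_fraction: float
    passed: bool


class IncorporationError(RuntimeError):
    """Raised when a sample fails the label-incorporation gate."""


def check_incorporation(
    labeled_fraction: float, min_frac: float = 0.95, sample: str = ""
) -> IncorporationReport:
    """Pass iff the dimethyl-labeled peptide fraction is at least ``min_frac``."""
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ValueError(f"labeled fraction must be in [0,1], got {labeled_fraction}")
    return IncorporationReport(
        sample=sample,
        labeled_fraction=labeled_fraction,
        min_fraction=min_frac,
        passed=labeled_fraction >= min_frac,
    )


def require_incorporation(
    fractions: dict[str, float], min_frac: float = 0.95, force: bool = False
) -> list[IncorporationReport]:
    """Check every sample; raise IncorporationError on failures unless forced."""
    reports = [check_incorporation(f, min_frac, sample=s) for s, f in fractions.items()]
    failed = [r.sample for r in reports if not r.passed]
    if failed and not force:
        raise IncorporationError(
            f"label incorporation below {min_frac:.0%} in samples: {failed}"
        )
    return reports


def _oriented_log2(ratio: float, bait_channel: str) -> float:
    """Stored ratios are medium/light; invert when bait was light."""
    if bait_channel == "medium":
        return math.log2(ratio)
    return math.log2(1.0 / ratio)


def orient_ratios(
    table: ProteinGroupTable, median_center: bool = False
) -> list[DmlRatioRecord]:
    """Re-express each set's ratio as bait/control and log2-transform.

    The sample sheet must assign every DML column a ``dml_set``
    (forward/reverse) and the channel that carried the bait. When a set
    has several ratio columns (replicate runs), their log2 ratios are
    averaged. A protein missing from a set yields an incomplete record.
    Ratios are assumed normalized upstream; ``median_center``
    additionally subtracts each set's median log2 ratio.
    """
    sets: dict[str, list] = {"forward": [], "reverse": []}
    for s in table.sample_sheet:
        if s.quant_mode != "dml":
            continue
        if s.dml_set is None or s.dml_channel is None:
            raise ValueError(f"DML column {s.name!r} lacks dml_set/dml_channel")
        sets[s.dml_set].append(s)
    if not sets["forward"] or not sets["reverse"]:
        raise ValueError("need at least one forward and one reverse DML ratio column")

    per_set: dict[str, np.ndarray] = {}
    for which, infos in sets.items():
        cols = []
        for s in infos:
            ratios = table.intensities[s.name].to_numpy(dtype=float)
            finite = ratios[~np.isnan(ratios)]
            if finite.size and (finite <= 0).any():
                raise ValueError(f"non-positive ratio in column {s.name!r}")
            with np.errstate(divide="ignore", invalid="ignore"):
                l2 = np.log2(ratios)
            if s.dml_channel == "light":
                l2 = -l2
            cols.append(l2)
        stacked = np.vstack(cols)
        present = (~np.isnan(stacked)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            merged = np.where(present > 0, np.nansum(stacked, axis=0), np.nan)
            merged = merged / np.where(present > 0, present, 1)
        if median_center:
            merged = merged - np.nanmedian(merged)
        per_set[which] = merged

    records = []
    for i, pid in enumerate(table.protein_ids):
        fwd = per_set["forward"][i]
        rev = per_set["reverse"][i]
        records.append(
            DmlRatioRecord(
                protein_id=str(pid),
                fwd_log2=None if np.isnan(fwd) else float(fwd),
                rev_log2=None if np.isnan(rev) else float(rev),
            )
        )
    return records


def call_concordant(
    records: Sequence[DmlRatioRecord], threshold: float = 4.0, strict: bool = True
) -> list[DmlRatioRecord]:
    """Call bait binders as proteins whose forward and reverse ratios
    both exceed ``threshold`` (linear scale; > 4 means log2 ratio > 2),
    controls symmetrically below 1/threshold; anything else, including
    proteins seen in only one set, is "none"."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    cut = math.log2(threshold)
    out = []
    for r in records:
        if not r.complete:
            call = "none"
        else:
            fwd, rev = r.fwd_log2, r.rev_log2
            assert fwd is not None and rev is not None
            if (fwd > cut and rev > cut) if strict else (fwd >= cut and rev >= cut):
                call = "bait"
            elif (fwd < -cut and rev < -cut) if strict else (fwd <= -cut and rev <= -cut):
                call = "control"
            else:
                call = "none"
        out.append(replace(r, call=call))
    return out


def records_to_frame(records: Sequence[DmlRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "fwd_log2": np.nan if r.fwd_log2 is None else r.fwd_log2,
                "rev_log2": np.nan if r.rev_log2 is None else r.rev_log2,
                "complete": r.complete,
                "call": r.call,
            }
            for r in records
        ],
        columns=["protein_id", "fwd_log2", "rev_log2", "complete", "call"],
    )


def write_dml_outputs(
    records: Sequence[DmlRatioRecord], out_dir, plot: bool = True
) -> dict:
    """Write dml_calls.tsv and a forward-vs-reverse scatter."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    tsv = out_dir / "dml_calls.tsv"
    frame.to_csv(tsv, sep="\t", index=False, float_format="%.10g")
    written = {"tsv": tsv}
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        comp = frame[frame["complete"]]
        bg = comp["call"] == "none"
        ax.scatter(comp.loc[bg, "rev_log2"], comp.loc[bg, "fwd_log2"], s=8, c="lightgray")
        ax.scatter(comp.loc[~bg, "rev_log2"], comp.loc[~bg, "fwd_log2"], s=12, c="black")
        ax.set_xlabel("log2 ratio, reverse experiment (bait/control)")
        ax.set_ylabel("log2 ratio, forward experiment (bait/control)")
        png = out_dir / "dml_scatter.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written["plot"] = png
    return written
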