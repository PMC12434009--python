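"""Trophic capabilities of species bins from the variety of their predictions.

A transcriptome reflects expression at the moment of sampling, not the
genomic potential of a species, so capabilities are inferred from how a
bin's per-sample predictions vary across all datasets rather than from a
single prediction. A species bin is labeled *mixotrophic-capable* when at
least 23% of its (non-excluded) predictions differ from its dominant trophic
mode — and that divergence is not just a split between replicates or size
fractions of the same samples — or when more than 77% of its predictions are
mixotrophy outright. Otherwise it is a phototrophic or heterotrophic
specialist named by its dominant mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import DOMINANT_TIE_PRECEDENCE, MODES, Thresholds, canonical_mode

CAPABILITIES = ("mixotrophic_capable", "phototrophic_specialist", "heterotrophic_specialist")

_SPECIALIST = {
    "phototrophy": "phototrophic_specialist",
    "heterotrophy": "heterotrophic_specialist",
    # a mixotrophy-dominant bin failing the >77% override is still best
    # described as mixotrophic-capable; handled in classify_capability
}


@dataclass(frozen=True)
class CapabilityCall:
    species_bin: str
    counts: dict
    dominant_mode: str
    divergence_fraction: float
    replicate_split_only: bool
    capability: str


def dominant_mode(counts: Mapping[str, int]) -> str:
    """The trophic mode with the most predictions for a species bin.

    Ties are broken by fixed precedence heterotrophy > mixotrophy >
    phototrophy so the result is deterministic.
    """
    norm = {canonical_mode(m): int(n) for m, n in counts.items() if n}
    total = sum(norm.values())
    if total <= 0:
        raise ValueError("dominant_mode requires at least one prediction")
    best = max(norm.values())
    for mode in DOMINANT_TIE_PRECEDENCE:
        if norm.get(mode, 0) == best:
            return mode
    raise AssertionError("unreachable")


def divergence_fraction(counts: Mapping[str, int]) -> float:
    """Fraction of predictions differing from the dominant mode."""
    norm = {canonical_mode(m): int(n) for m, n in counts.items() if n}
    total = sum(norm.values())
    return 1.0 - norm.get(dominant_mode(norm), 0) / total


def classify_capability(
    counts: Mapping[str, int],
    replicate_split_only: bool = False,
    thresholds: Thresholds | None = None,
) -> str:
    """Capability class of a species bin from its aggregated prediction counts.

    ``mixotrophic_capable`` iff divergence from the dominant mode is >= 23%
    (inclusive) and the divergence is not purely a replicate/size-fraction
    split, OR the mixotrophy fraction strictly exceeds 77%. Otherwise the bin
    is a specialist named by its dominant mode; a mixotrophy-dominant bin
    that reaches neither branch is still called mixotrophic-capable (there is
    no "mixotrophic specialist" class).
    """
    thr = thresholds or Thresholds()
    norm = {canonical_mode(m): int(n) for m, n in counts.items() if n}
    total = sum(norm.values())
    if total <= 0:
        raise ValueError("classify_capability requires at least one prediction")
    mixo_frac = norm.get("mixotrophy", 0) / total
    if mixo_frac > thr.capability_mixotrophy_frac:
        return "mixotrophic_capable"
    div = divergence_fraction(norm)
    if div >= thr.capability_divergence_frac and not replicate_split_only:
        return "mixotrophic_capable"
    dom = dominant_mode(norm)
    if dom == "mixotrophy":
        return "mixotrophic_capable"
    return _SPECIALIST[dom]


def detect_replicate_split(predictions: pd.DataFrame) -> bool:
    """Whether a bin's divergent predictions are *only* a replicate split.

    ``predictions`` holds one bin's non-excluded predictions with columns
    ``mode`` and ``grouping_unit``. Returns True (split-only) iff no grouping
    unit is unanimous for a single non-dominant mode — i.e. every divergent
    prediction co-occurs in its unit with a dominant-mode prediction from
    another replicate or size fraction. A unit unanimous for a non-dominant
    mode (even a singleton) is evidence of a genuine shift, so the result is
    False.
    """
    if predictions.empty:
        raise ValueError("detect_replicate_split requires predictions")
    counts = predictions["mode"].value_counts().to_dict()
    dom = dominant_mode(counts)
    for _, grp in predictions.groupby("grouping_unit"):
        modes = set(grp["mode"])
        if len(modes) == 1 and modes != {dom}:
            return False
    return True


def call_capabilities(
    predictions: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Aggregate non-excluded predictions per species bin and classify.

    ``predictions`` is the combined prediction table across all datasets
    (surface transects, depth profiles, incubations, diel studies); exclusion
    flags must already be applied. The result is order-invariant and additive:
    merging datasets before calling equals summing their counts.
    """
    usable = predictions[~predictions["excluded"].astype(bool)]
    rows = []
    for species_bin, grp in usable.groupby("species_bin"):
        counts = {m: int((grp["mode"] == m).sum()) for m in MODES}
        split_only = detect_replicate_split(grp)
        dom = dominant_mode(counts)
        rows.append(
            {
                "species_bin": species_bin,
                "n_phototrophy": counts["phototrophy"],
                "n_mixotrophy": counts["mixotrophy"],
                "n_heterotrophy": counts["heterotrophy"],
                "dominant_mode": dom,
                "divergence_fraction": divergence_fraction(counts),
                "replicate_split_only": split_only,
                "capability": classify_capability(counts, split_only, thresholds),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species_bin", "n_phototrophy", "n_mixotrophy", "n_heterotrophy",
            "dominant_mode", "divergence_fraction", "replicate_split_only", "capability",
        ],
    )


def write_capabilities(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_capabilities(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"species_bin": str})
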