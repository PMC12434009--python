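"""Absolute transcript abundance of species bins from spike-in standards.

Synthetic RNA standards of known copy number are added to each sample before
sequencing; the ratio of a bin's mapped reads to standard-mapped reads then
converts read counts into absolute transcript copies, and dividing by the
volume filtered yields transcripts per liter:

    T/L = (bin_reads / standard_reads) * standard_copies_added / volume_L

Transcript concentration tracks carbon biomass across broad taxonomic groups
except dinoflagellates, which carry ~6.4x more transcripts per unit carbon;
their concentrations are scaled down by that factor before groups are
compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Thresholds


@dataclass(frozen=True)
class SpikeInRecord:
    """Per-sample internal-standard accounting."""

    sample_id: str
    standard_copies_added: float
    reads_mapped_to_standards: float
    volume_filtered_L: float

    def __post_init__(self) -> None:
        if self.standard_copies_added <= 0 or self.volume_filtered_L <= 0:
            raise ValueError(f"non-positive spike-in fields for sample {self.sample_id}")
        if self.reads_mapped_to_standards < 0:
            raise ValueError(f"negative standard read count for sample {self.sample_id}")


def transcripts_per_liter(bin_reads: float, spike: SpikeInRecord) -> float:
    """Absolute transcript concentration of one bin in one sample.

    Linear in ``bin_reads``; inversely proportional to standard reads and to
    volume. A sample with zero reads mapped to the standards cannot be
    quantified and raises.
    """
    if bin_reads < 0:
        raise ValueError("negative bin read count")
    if spike.reads_mapped_to_standards == 0:
        raise ValueError(
            f"sample {spike.sample_id}: no reads mapped to spike-in standards; unquantifiable"
        )
    return (
        bin_reads / spike.reads_mapped_to_standards
    ) * spike.standard_copies_added / spike.volume_filtered_L


def quantify(
    bin_reads: pd.DataFrame,
    spikes: pd.DataFrame,
    taxonomy_flags: pd.DataFrame | None = None,
    dino_factor: float = Thresholds.dino_correction_factor,
) -> pd.DataFrame:
    """Transcripts per liter for every (species_bin, sample) pair.

    ``bin_reads`` columns: species_bin, sample_id, reads (plus any metadata
    such as replicate/size_fraction/station, carried through).
    ``spikes`` columns: sample_id, standard_copies_added,
    reads_mapped_to_standards, volume_filtered_L.
    ``taxonomy_flags`` columns: species_bin, is_dinoflagellate; bins absent
    from the table are treated as non-dinoflagellate.
    """
    merged = bin_reads.merge(spikes, on="sample_id", how="left")
    if merged["standard_copies_added"].isna().any():
        missing = merged.loc[merged["standard_copies_added"].isna(), "sample_id"].unique()
        raise ValueError(f"no spike-in record for samples: {sorted(map(str, missing))}")
    if (merged["reads_mapped_to_standards"] == 0).any():
        bad = merged.loc[merged["reads_mapped_to_standards"] == 0, "sample_id"].unique()
        raise ValueError(f"zero standard reads; unquantifiable samples: {sorted(map(str, bad))}")
    out = merged.copy()
    out["raw_transcripts_per_L"] = (
        out["reads"] / out["reads_mapped_to_standards"]
        * out["standard_copies_added"] / out["volume_filtered_L"]
    )
    is_dino = pd.Series(False, index=out.index)
    if taxonomy_flags is not None:
        flags = taxonomy_flags.drop_duplicates("species_bin").set_index("species_bin")[
            "is_dinoflagellate"
        ]
        is_dino = out["species_bin"].map(lambda b: bool(flags.get(b, False)))
    out["is_dinoflagellate"] = is_dino
    out["corrected_transcripts_per_L"] = np.where(
        is_dino, out["raw_transcripts_per_L"] / dino_factor, out["raw_transcripts_per_L"]
    )
    drop = ["standard_copies_added", "reads_mapped_to_standards", "volume_filtered_L"]
    return out.drop(columns=drop)


def dino_correction(
    records: pd.DataFrame,
    dino_factor: float = Thresholds.dino_correction_factor,
) -> pd.DataFrame:
    """Divide dinoflagellate concentrations by the correction factor.

    Expects ``raw_transcripts_per_L`` and ``is_dinoflagellate`` columns;
    writes ``corrected_transcripts_per_L``. Commutes with summation within a
    dinoflagellate-only group (the correction is a scalar multiple).
    """
    out = records.copy()
    out["corrected_transcripts_per_L"] = np.where(
        out["is_dinoflagellate"].astype(bool),
        out["raw_transcripts_per_L"] / dino_factor,
        out["raw_transcripts_per_L"],
    )
    return out


def sum_size_fractions(
    records: pd.DataFrame,
    value_cols: tuple[str, ...] = ("raw_transcripts_per_L", "corrected_transcripts_per_L"),
    keep_cols: tuple[str, ...] = ("station", "replicate"),
) -> pd.DataFrame:
    """Sum transcript concentrations over size fractions of the same sample.

    Grouping is by species_bin plus any of ``keep_cols`` present, preserving
    replicate structure; concentration columns are added, which is
    order-invariant.
    """
    keys = ["species_bin"] + [c for c in keep_cols if c in records.columns]
    agg = {c: "sum" for c in value_cols if c in records.columns}
    carried = [
        c for c in records.columns
        if c not in keys and c not in agg and c not in ("sample_id", "size_fraction", "reads")
    ]
    agg.update({c: "first" for c in carried})
    return records.groupby(keys, as_index=False).agg(agg)


def group_totals(
    records: pd.DataFrame,
    capability_calls: pd.DataFrame,
    location_cols: tuple[str, ...] = ("station",),
) -> pd.DataFrame:
    """Total corrected concentration per trophic group at each location.

    Every species bin in ``records`` must have a capability call. Within each
    replicate at a location, corrected concentrations are summed across the
    bins of each trophic group; the replicate sums are then averaged (mean,
    with standard error). Each group's share of the summed location total is
    reported as ``proportion``; locations whose total is zero get missing
    proportions.
    """
    calls = capability_calls.drop_duplicates("species_bin").set_index("species_bin")["capability"]
    missing = sorted(set(records["species_bin"]) - set(calls.index))
    if missing:
        raise ValueError(f"species bins without capability calls: {missing}")
    df = records.copy()
    df["trophic_group"] = df["species_bin"].map(calls)
    loc = [c for c in location_cols if c in df.columns]
    rep_keys = loc + ["trophic_group", "replicate"] if "replicate" in df.columns else loc + ["trophic_group"]
    per_rep = df.groupby(rep_keys, as_index=False)["corrected_transcripts_per_L"].sum()
    gkeys = loc + ["trophic_group"]
    out = per_rep.groupby(gkeys, as_index=False)["corrected_transcripts_per_L"].agg(
        mean_transcripts_per_L="mean",
        se_transcripts_per_L=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
        n_replicates="size",
    )
    totals = out.groupby(loc)["mean_transcripts_per_L"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["proportion"] = np.where(
            totals > 0, out["mean_transcripts_per_L"] / totals, np.nan
        )
    return out
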