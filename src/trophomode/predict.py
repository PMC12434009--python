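"""Applying the trained classifier to environmental species-bin profiles.

Environmental metatranscriptomes differ from the culture transcriptomes the
model was trained on: a species bin may be sequenced too shallowly for its
expression profile to be trustworthy, and model failure can show up as a bin
being called both phototrophic and heterotrophic under the same conditions.
Three safeguards are applied here:

* a transcriptional-completeness gate — a bin must express at least 70% of
  the eukaryotic Core Transcribed Genes (CTGs) in a sample for a prediction
  to be made;
* a split-prediction exclusion — within a grouping unit (e.g. one latitude
  of one cruise), all predictions for a bin are discarded when phototrophy
  and heterotrophy each exceed 25% of them;
* an agreement summary across replicates and size fractions, quantifying
  prediction uncertainty.

Excluded predictions are kept in the output with flags rather than deleted,
so every decision is auditable downstream.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MODES, Thresholds
from .profiles import profiles_to_matrix
from .train import TrophicModelBundle

PREDICTION_COLUMNS = [
    "species_bin", "sample_id", "replicate", "size_fraction", "grouping_unit",
    "mode", "p_phototrophy", "p_mixotrophy", "p_heterotrophy",
    "ctg_coverage", "excluded", "reason",
]


def read_ctg_list(path: str | Path) -> list[str]:
    """Read a Core Transcribed Gene Pfam list (one accession per line)."""
    accs = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    return _validate_ctg(accs)


def _validate_ctg(ctg_list: Sequence[str]) -> list[str]:
    accs = list(ctg_list)
    if not accs:
        raise ValueError("CTG list is empty")
    if len(set(accs)) != len(accs):
        raise ValueError("CTG list contains duplicate accessions")
    return accs


def ctg_coverage(tpm: Mapping[str, float] | pd.Series, ctg_list: Sequence[str]) -> float:
    """Fraction of CTG Pfams with nonzero TPM in a profile.

    Monotone non-decreasing as Pfams gain nonzero expression. Eligibility for
    prediction uses ``coverage >= 0.70`` (inclusive): with the reference list
    of 605 CTGs, 424 expressed (0.7008) passes and 423 (0.6992) does not.
    """
    accs = _validate_ctg(ctg_list)
    if isinstance(tpm, pd.Series):
        tpm = tpm.to_dict()
    expressed = sum(1 for acc in accs if tpm.get(acc, 0.0) > 0)
    return expressed / len(accs)


def predict_modes(
    profiles: pd.DataFrame,
    bundle: TrophicModelBundle,
    ctg_list: Sequence[str],
    sample_metadata: pd.DataFrame | None = None,
    group_cols: Sequence[str] = (),
    min_coverage: float = Thresholds.ctg_min_coverage,
    scaler_mode: str = "train",
    binarize_input: bool = False,
) -> pd.DataFrame:
    """One trophic prediction per (species bin, sample) passing the CTG gate.

    ``profiles`` is a long table (species_bin, sample_id, pfam_acc, tpm)
    containing *all* Pfams observed for each bin (the CTG gate is computed on
    the full profile, not just model features). Profiles are zero-filled to
    the bundle's feature list and scaled with the bundle's scaler before
    prediction. Bins below the completeness gate are emitted with
    ``excluded=True, reason='low_coverage'`` and no mode.

    ``sample_metadata`` maps sample_id to replicate, size_fraction and the
    metadata columns named in ``group_cols``; the grouping unit used by the
    exclusion rule is their values joined with ``|``.

    ``scaler_mode='train'`` (default) scales with the bundle's
    training-fitted min/max; ``'refit'`` refits the scaler on this dataset's
    feature matrix instead. ``binarize_input`` converts the profiles to
    presence/absence before scaling, for bundles trained on binarized data.
    """
    if scaler_mode not in ("train", "refit"):
        raise ValueError(f"scaler_mode must be 'train' or 'refit', got {scaler_mode!r}")
    full = profiles_to_matrix(profiles)
    coverage = pd.Series(
        {idx: ctg_coverage(row, ctg_list) for idx, row in full.iterrows()}
    )

    feat_matrix = full.reindex(columns=bundle.features, fill_value=0.0)
    if binarize_input:
        from .profiles import binarize

        feat_matrix = binarize(feat_matrix)
    if scaler_mode == "refit" and len(feat_matrix) >= 2:
        from .profiles import fit_scaler

        bundle = replace(bundle, scaler=fit_scaler(feat_matrix))
    proba = bundle.predict_proba(feat_matrix)

    rows = []
    for idx in full.index:
        species_bin, sample_id = idx
        cov = float(coverage.loc[[idx]].iloc[0])
        eligible = cov >= min_coverage
        p = proba.loc[[idx]].iloc[0]
        rec = {
            "species_bin": species_bin,
            "sample_id": sample_id,
            "ctg_coverage": cov,
            "excluded": not eligible,
            "reason": "" if eligible else "low_coverage",
            "mode": MODES[int(np.argmax(p.to_numpy()))] if eligible else "",
        }
        for m in MODES:
            rec[f"p_{m}"] = float(p[m]) if eligible else np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)

    if sample_metadata is not None:
        meta = sample_metadata.drop_duplicates("sample_id")
        out = out.merge(meta, on="sample_id", how="left")
    for col in ("replicate", "size_fraction"):
        if col not in out.columns:
            out[col] = ""
    if group_cols:
        missing = [c for c in group_cols if c not in out.columns]
        if missing:
            raise ValueError(f"grouping columns absent from metadata: {missing}")
        out["grouping_unit"] = out[list(group_cols)].astype(str).agg("|".join, axis=1)
    elif "grouping_unit" not in out.columns:
        out["grouping_unit"] = ""
    return out[PREDICTION_COLUMNS + [c for c in out.columns if c not in PREDICTION_COLUMNS]]


def apply_exclusion(
    predictions: pd.DataFrame,
    split_frac: float = Thresholds.exclusion_split_frac,
) -> pd.DataFrame:
    """Flag split phototrophy/heterotrophy groups as model failure.

    Within each (species_bin, grouping_unit), over predictions that passed
    the CTG gate: if phototrophy and heterotrophy *each* account for strictly
    more than ``split_frac`` (25%) of predictions across replicates and size
    fractions, every prediction in the group is flagged
    ``excluded=True, reason='split_P_H'``. Idempotent and order-invariant.
    """
    out = predictions.copy()
    usable = out[~out["excluded"].astype(bool)]
    for (_, _), grp in usable.groupby(["species_bin", "grouping_unit"]):
        n = len(grp)
        if n == 0:
            continue
        f_p = (grp["mode"] == "phototrophy").sum() / n
        f_h = (grp["mode"] == "heterotrophy").sum() / n
        if f_p > split_frac and f_h > split_frac:
            out.loc[grp.index, "excluded"] = True
            out.loc[grp.index, "reason"] = "split_P_H"
    return out


def agreement(predictions: pd.DataFrame) -> pd.DataFrame:
    """Proportion of predictions agreeing with the modal mode per group.

    Computed over non-excluded predictions within each
    (species_bin, grouping_unit); ties return the maximal fraction. Groups
    with no usable predictions are omitted.
    """
    usable = predictions[~predictions["excluded"].astype(bool)]
    rows = []
    for (species_bin, unit), grp in usable.groupby(["species_bin", "grouping_unit"]):
        counts = grp["mode"].value_counts()
        rows.append(
            {
                "species_bin": species_bin,
                "grouping_unit": unit,
                "n_predictions": len(grp),
                "modal_mode": counts.idxmax(),
                "agreement": counts.max() / len(grp),
            }
        )
    return pd.DataFrame(rows, columns=["species_bin", "grouping_unit", "n_predictions", "modal_mode", "agreement"])


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    predictions.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"species_bin": str, "sample_id": str}, keep_default_na=False)
    df["excluded"] = df["excluded"].astype(str).str.lower().isin(("true", "1"))
    for m in MODES:
        df[f"p_{m}"] = pd.to_numeric(df[f"p_{m}"], errors="coerce")
    df["ctg_coverage"] = pd.to_numeric(df["ctg_coverage"], errors="coerce")
    return df
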