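"""Species-bin Pfam expression profiles from contig-level tables.

The unit of analysis is the *species bin*: all contigs in a metatranscriptome
sample that share the same closest species-level taxonomic annotation. For
each (species bin, sample) pair a profile maps Pfam accession -> TPM, where
TPM is normalized *within* the bin and sample so that per-contig values sum
to one million. Profiles are carried as long-format pandas DataFrames with
columns (species_bin, sample_id, pfam_acc, tpm) and pivoted to wide matrices
for model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Thresholds

PROFILE_COLUMNS = ["species_bin", "sample_id", "pfam_acc", "tpm"]


class RowErrors(ValueError):
    """Raised when input rows are malformed; carries a per-row error report."""

    def __init__(self, message: str, rows: pd.DataFrame):
        super().__init__(f"{message}\n{rows.to_string()}")
        self.rows = rows


# ---------------------------------------------------------------------------
# Pfam annotation selection
# ---------------------------------------------------------------------------

def select_best_pfam(
    hits: pd.DataFrame,
    evalue_max: float = Thresholds.evalue_max,
) -> dict[str, str | None]:
    """Pick one Pfam annotation per contig from domain-search hits.

    Hits with e-value >= ``evalue_max`` are discarded (the filter is a strict
    ``<``). Among the survivors of each contig the hit with the highest
    bitscore wins; bitscore ties are broken by the lexicographically smallest
    Pfam accession so the choice is deterministic. Contigs whose hits were all
    filtered out map to ``None``.

    Parameters
    ----------
    hits
        DataFrame with columns ``contig_id, pfam_acc, e_value, bitscore``.

    Returns
    -------
    dict mapping contig_id -> pfam accession, or ``None`` if no hit survived.
    """
    required = {"contig_id", "pfam_acc", "e_value", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")

    bad = hits[hits["e_value"] < 0]
    if len(bad):
        raise RowErrors("negative e-value in annotation rows", bad)

    kept = hits[hits["e_value"] < evalue_max]
    result: dict[str, str | None] = {c: None for c in hits["contig_id"].unique()}
    if len(kept):
        best = (
            kept.sort_values(["bitscore", "pfam_acc"], ascending=[False, True], kind="stable")
            .drop_duplicates("contig_id", keep="first")
        )
        result.update(dict(zip(best["contig_id"], best["pfam_acc"])))
    return result


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def compute_tpm(contigs: pd.DataFrame) -> pd.DataFrame:
    """Per-contig TPM, normalized within each (species_bin, sample_id).

    RPK_i = est_count_i / (length_nt_i / 1000); the conversion factor is the
    sum of RPK within the bin and sample divided by one million; TPM_i is
    RPK_i over that factor. A bin+sample whose counts are all zero yields
    all-zero TPM rather than an error (environmental samples legitimately
    lack some bins).

    Parameters
    ----------
    contigs
        DataFrame with columns
        ``contig_id, length_nt, est_count, species_bin, sample_id``.

    Returns
    -------
    Copy of the input with ``rpk`` and ``tpm`` columns appended.
    """
    required = {"contig_id", "length_nt", "est_count", "species_bin", "sample_id"}
    missing = required - set(contigs.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")

    bad = contigs[contigs["length_nt"] < 1]
    if len(bad):
        names = ", ".join(map(str, bad["contig_id"].tolist()))
        raise ValueError(f"contigs with length < 1 nt: {names}")
    if (contigs["est_count"] < 0).any():
        raise RowErrors("negative est_count", contigs[contigs["est_count"] < 0])

    out = contigs.copy()
    out["rpk"] = out["est_count"] / (out["length_nt"] / 1000.0)
    factor = out.groupby(["species_bin", "sample_id"])["rpk"].transform("sum") / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        tpm = out["rpk"] / factor
    out["tpm"] = tpm.where(factor > 0, 0.0)
    return out


def aggregate_by_pfam(
    contig_tpm: pd.DataFrame,
    contig_to_pfam: dict[str, str | None],
    feature_list: list[str] | None = None,
) -> pd.DataFrame:
    """Sum per-contig TPM into (species_bin, sample_id, pfam_acc) profiles.

    Contigs with no Pfam annotation are dropped. When ``feature_list`` is
    given, every listed Pfam is present in every (bin, sample) profile, with
    TPM 0 where no transcript mapped — the zero-fill the classifier relies on.
    """
    df = contig_tpm.copy()
    df["pfam_acc"] = df["contig_id"].map(contig_to_pfam)
    df = df.dropna(subset=["pfam_acc"])
    prof = (
        df.groupby(["species_bin", "sample_id", "pfam_acc"], as_index=False)["tpm"].sum()
        if len(df)
        else pd.DataFrame(columns=PROFILE_COLUMNS)
    )
    if feature_list is not None:
        pairs = contig_tpm[["species_bin", "sample_id"]].drop_duplicates()
        full = pairs.merge(pd.DataFrame({"pfam_acc": list(feature_list)}), how="cross")
        prof = full.merge(prof, on=["species_bin", "sample_id", "pfam_acc"], how="left")
        prof["tpm"] = prof["tpm"].fillna(0.0)
    return prof[PROFILE_COLUMNS].reset_index(drop=True)


def profiles_to_matrix(
    profiles: pd.DataFrame, feature_list: list[str] | None = None
) -> pd.DataFrame:
    """Pivot a long profile table to a wide (bin, sample) x Pfam matrix.

    Missing entries are zero-filled. With ``feature_list`` the columns are
    exactly that list, in order, regardless of what the table contains.
    """
    wide = profiles.pivot_table(
        index=["species_bin", "sample_id"],
        columns="pfam_acc",
        values="tpm",
        aggfunc="sum",
        fill_value=0.0,
    )
    wide.columns.name = None
    if feature_list is not None:
        wide = wide.reindex(columns=list(feature_list), fill_value=0.0)
    return wide.astype(float)


# ---------------------------------------------------------------------------
# Training-set QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: tuple[str, ...] = ()


def qc_training_transcriptome(
    total_sequences: int,
    total_pfam_domains: int,
    contamination_pct: float,
    thresholds: Thresholds | None = None,
) -> QCResult:
    """Quality gate for a training transcriptome.

    Passes iff total sequences >= 1200, assigned Pfam domains >= 500 and
    contamination strictly < 50% (defaults; see :class:`Thresholds`).
    """
    thr = thresholds or Thresholds()
    reasons = []
    if total_sequences < thr.qc_min_sequences:
        reasons.append("sequences")
    if total_pfam_domains < thr.qc_min_pfam_domains:
        reasons.append("pfam_domains")
    if not contamination_pct < thr.qc_max_contamination_pct:
        reasons.append("contamination")
    return QCResult(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Scaling / binarization
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Per-feature min/max fitted on training data (MinMax scaling to [0,1]).

    Transformed values are clipped to [0, 1], so environmental profiles whose
    expression exceeds the training range saturate at 1. Constant features
    (min == max) map to 0.
    """

    features: list[str]
    data_min: np.ndarray
    data_max: np.ndarray

    def __post_init__(self) -> None:
        self.data_min = np.asarray(self.data_min, dtype=float)
        self.data_max = np.asarray(self.data_max, dtype=float)
        if not (len(self.features) == len(self.data_min) == len(self.data_max)):
            raise ValueError("feature/min/max length mismatch")
        if (self.data_min > self.data_max).any():
            raise ValueError("data_min exceeds data_max for some feature")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pfam_acc": self.features, "data_min": self.data_min, "data_max": self.data_max}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScalerParams":
        return cls(
            features=df["pfam_acc"].tolist(),
            data_min=df["data_min"].to_numpy(),
            data_max=df["data_max"].to_numpy(),
        )


def fit_scaler(matrix: pd.DataFrame) -> ScalerParams:
    """Fit per-feature min/max on a training matrix (rows = profiles)."""
    if len(matrix) < 2:
        raise ValueError("scaler fit requires at least 2 profiles")
    return ScalerParams(
        features=list(matrix.columns),
        data_min=matrix.min(axis=0).to_numpy(dtype=float),
        data_max=matrix.max(axis=0).to_numpy(dtype=float),
    )


def apply_scaler(matrix: pd.DataFrame, params: ScalerParams) -> pd.DataFrame:
    """Scale a matrix with fitted params: (x - min)/(max - min), clipped to [0,1]."""
    mat = matrix.reindex(columns=params.features, fill_value=0.0).astype(float)
    span = params.data_max - params.data_min
    span_safe = np.where(span > 0, span, 1.0)  # constant features -> 0 after centering
    scaled = (mat.to_numpy() - params.data_min) / span_safe
    scaled = np.clip(scaled, 0.0, 1.0)
    return pd.DataFrame(scaled, index=mat.index, columns=params.features)


def binarize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence transform: 1 where TPM > 0, else 0. Idempotent."""
    return (matrix > 0).astype(float)


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> pd.DataFrame:
    """TSV of domain-search hits: contig_id, pfam_acc, e_value, bitscore."""
    return pd.read_csv(path, sep="\t", dtype={"contig_id": str, "pfam_acc": str})


def read_abundance_table(path, sample_id: str | None = None) -> pd.DataFrame:
    """Pseudo-alignment abundance TSV (target_id, length, est_counts).

    Column aliases of the common dialect are normalized to
    (contig_id, length_nt, est_count); a ``sample_id`` column is added when
    the argument is given.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns={"target_id": "contig_id", "length": "length_nt", "est_counts": "est_count"}
    )
    if sample_id is not None:
        df["sample_id"] = sample_id
    return df


def read_taxonomy_table(path) -> pd.DataFrame:
    """TSV mapping contig_id -> species_bin with a dinoflagellate flag."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "species_bin": str})
    if "is_dinoflagellate" in df.columns:
        df["is_dinoflagellate"] = df["is_dinoflagellate"].astype(bool)
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"species_bin": str, "sample_id": str, "pfam_acc": str})


def build_profiles(
    annotation: pd.DataFrame,
    abundance: pd.DataFrame,
    taxonomy: pd.DataFrame,
    feature_list: list[str] | None = None,
    evalue_max: float = Thresholds.evalue_max,
) -> pd.DataFrame:
    """End-to-end profile construction from the three contig-level tables.

    Joins abundance with taxonomy on contig_id, computes per-contig TPM within
    each species bin and sample, selects the best Pfam per contig from the
    annotation table and aggregates TPM by Pfam.
    """
    contigs = abundance.merge(taxonomy[["contig_id", "species_bin"]], on="contig_id")
    tpm = compute_tpm(contigs)
    mapping = select_best_pfam(annotation, evalue_max=evalue_max)
    return aggregate_by_pfam(tpm, mapping, feature_list=feature_list)
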