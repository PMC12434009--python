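"""Run configuration: every numeric threshold the pipeline applies, in one place.

Defaults are the values used throughout the analysis; any of them can be
overridden from a YAML config file or programmatically, and every run echoes
the active configuration into its JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Canonical trophic-mode labels, in the fixed order used for class encoding
#: and probability vectors everywhere in the package.
MODES: tuple[str, str, str] = ("phototrophy", "mixotrophy", "heterotrophy")

#: Short single-letter aliases accepted in input tables.
MODE_ALIASES: Mapping[str, str] = {
    "P": "phototrophy",
    "M": "mixotrophy",
    "H": "heterotrophy",
}

#: Sign convention for permutation importance. The importance of a feature is
#: (F1 - F1_after_shuffle) / F1, so a feature whose shuffling *degrades*
#: performance scores positive, and positive-mean features are retained.
IMPORTANCE_RETAIN_SIGN: int = +1

#: Tie-break precedence for the dominant trophic mode of a species bin
#: (first entry wins a tie).
DOMINANT_TIE_PRECEDENCE: tuple[str, str, str] = (
    "heterotrophy",
    "mixotrophy",
    "phototrophy",
)


@dataclass
class Thresholds:
    """Numeric gates applied by the pipeline.

    All fractional thresholds are on [0, 1]; comparisons follow the stated
    strictness exactly (e.g. the e-value filter is strict ``<``, the CTG
    completeness gate is inclusive ``>=``).
    """

    evalue_max: float = 1e-05          # Pfam hit kept iff e-value < this
    qc_min_sequences: int = 1200       # training transcriptome: total sequences >=
    qc_min_pfam_domains: int = 500     # training transcriptome: assigned Pfam domains >=
    qc_max_contamination_pct: float = 50.0  # strict <
    ctg_min_coverage: float = 0.70     # fraction of CTG Pfams expressed, inclusive >=
    exclusion_split_frac: float = 0.25  # both P and H strictly > this within a group
    capability_divergence_frac: float = 0.23  # inclusive >=
    capability_mixotrophy_frac: float = 0.77  # strict >
    dino_correction_factor: float = 6.4  # divide dinoflagellate transcript conc. by this

    def __post_init__(self) -> None:
        for name in (
            "ctg_min_coverage",
            "exclusion_split_frac",
            "capability_divergence_frac",
            "capability_mixotrophy_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")


#: Grouping keys per dataset kind, used by the exclusion rule and agreement
#: summaries. A grouping unit is the tuple of these metadata columns.
DEFAULT_GROUPING_KEYS: Mapping[str, tuple[str, ...]] = {
    "surface": ("cruise", "latitude"),
    "depth": ("latitude", "depth"),
    "incubation": ("latitude", "treatment", "timepoint"),
    "diel": ("date",),
}


@dataclass
class RunConfig:
    """Full configuration for a pipeline run."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    grouping_keys: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_GROUPING_KEYS.items()}
    )
    seed: int = 0
    #: "train" scales environmental profiles with the scaler fitted on the
    #: training dataset (default); "refit" refits min/max per dataset.
    scaler_mode: str = "train"
    binarize: bool = False

    def __post_init__(self) -> None:
        if self.scaler_mode not in ("train", "refit"):
            raise ValueError(f"scaler_mode must be 'train' or 'refit', got {self.scaler_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        gk = {k: tuple(v) for k, v in raw.pop("grouping_keys", DEFAULT_GROUPING_KEYS).items()}
        return cls(thresholds=thr, grouping_keys=gk, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grouping_keys"] = {k: list(v) for k, v in self.grouping_keys.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def canonical_mode(label: str) -> str:
    """Normalize a trophic-mode label to its canonical long form."""
    label = label.strip()
    if label in MODES:
        return label
    if label in MODE_ALIASES:
        return MODE_ALIASES[label]
    low = label.lower()
    if low in MODES:
        return low
    raise ValueError(f"unknown trophic mode label: {label!r}")
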