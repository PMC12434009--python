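"""Synthetic labeled profiles and mock environmental datasets.

The generator emulates the statistical structure the pipeline assumes in
real data: species-level Pfam TPM profiles whose expression depends on
trophic mode through functional archetypes —

* *photosynthesis-like* Pfams, expressed in phototrophs and mixotrophs and
  mostly silent in heterotrophs;
* *motility-like* and *phagocytosis-like* Pfams, expressed in mixotrophs and
  heterotrophs and mostly silent in phototrophs;
* *housekeeping* Pfams expressed in everything (these double as the Core
  Transcribed Gene list for completeness gating);
* *noise* Pfams with mode-independent expression.

Each profile draws a per-sample *activity level* for every archetype —
e.g. a mixotroph may run its photosynthetic machinery anywhere between
barely and fully on — which interpolates both the log-mean expression and
the zero-inflation probability between the archetype's "off" and "on"
levels. This produces the continuum of borderline profiles real
metatranscriptomes show (mixotrophs shading into phototrophs being the
classic confusion) and makes each signal Pfam individually informative
rather than a redundant copy of its archetype. A per-feature log-mean
offset, drawn once, adds expression heterogeneity among the Pfams of an
archetype.

Expression is log-normal, zero-inflated, and renormalized so every profile
sums to one million (TPM). Class imbalance defaults to the 258/85/44
phototrophy/mixotrophy/heterotrophy composition of the culture training
corpus. Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .config import MODES

ARCHETYPES = ("photosynthesis", "motility", "phagocytosis", "housekeeping", "noise")

#: Expression levels per archetype: log-mean TPM and zero-inflation
#: probability at activity 0 ("off") and activity 1 ("on").
DEFAULT_LEVELS: dict[str, dict[str, float]] = {
    "photosynthesis": {"mu_off": 1.0, "mu_on": 6.0, "zp_off": 0.90, "zp_on": 0.10},
    "motility":       {"mu_off": 1.0, "mu_on": 6.0, "zp_off": 0.80, "zp_on": 0.10},
    "phagocytosis":   {"mu_off": 0.5, "mu_on": 5.6, "zp_off": 0.85, "zp_on": 0.10},
    "housekeeping":   {"mu_off": 5.0, "mu_on": 5.0, "zp_off": 0.02, "zp_on": 0.02},
    "noise":          {"mu_off": 3.0, "mu_on": 3.0, "zp_off": 0.50, "zp_on": 0.50},
}

#: Per-sample activity ranges (uniform low/high) per (archetype, mode).
#: Mixotrophs vary widely in how strongly they run either machinery, which is
#: what makes some of their profiles borderline.
DEFAULT_ACTIVITY: dict[str, dict[str, tuple[float, float]]] = {
    "photosynthesis": {
        "phototrophy": (0.70, 1.00),
        "mixotrophy": (0.30, 1.00),
        "heterotrophy": (0.00, 0.15),
    },
    "motility": {
        "phototrophy": (0.00, 0.25),
        "mixotrophy": (0.30, 1.00),
        "heterotrophy": (0.70, 1.00),
    },
    "phagocytosis": {
        "phototrophy": (0.00, 0.20),
        "mixotrophy": (0.30, 1.00),
        "heterotrophy": (0.70, 1.00),
    },
    "housekeeping": {m: (1.0, 1.0) for m in MODES},
    "noise": {m: (1.0, 1.0) for m in MODES},
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic expression model."""

    n_pfams_total: int = 2000
    archetype_counts: dict[str, int] = field(
        default_factory=lambda: {
            "photosynthesis": 15,
            "motility": 21,
            "phagocytosis": 10,
            "housekeeping": 605,
        }
    )
    levels: dict[str, dict[str, float]] = field(
        default_factory=lambda: {a: dict(v) for a, v in DEFAULT_LEVELS.items()}
    )
    activity: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {a: dict(v) for a, v in DEFAULT_ACTIVITY.items()}
    )
    log_sd: float = 0.8
    #: sd of the per-feature offset added to the archetype log-mean, drawn
    #: once per Pfam; breaks exact redundancy within an archetype.
    feature_jitter_sd: float = 0.5
    class_counts: dict[str, int] = field(
        default_factory=lambda: {"phototrophy": 258, "mixotrophy": 85, "heterotrophy": 44}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        named = sum(self.archetype_counts.values())
        if named > self.n_pfams_total:
            raise ValueError("archetype counts exceed n_pfams_total")
        for a, lv in self.levels.items():
            for key in ("zp_off", "zp_on"):
                if not 0.0 <= lv[key] <= 1.0:
                    raise ValueError(f"levels[{a}][{key}]={lv[key]} outside [0,1]")
        for a, per_mode in self.activity.items():
            for m, (lo, hi) in per_mode.items():
                if not (0.0 <= lo <= hi <= 1.0):
                    raise ValueError(f"activity[{a}][{m}]=({lo},{hi}) invalid")
        for m, n in self.class_counts.items():
            if n <= 0:
                raise ValueError(f"class count for {m} must be positive")

    @property
    def n_noise(self) -> int:
        return self.n_pfams_total - sum(self.archetype_counts.values())


def pfam_catalog(spec: GeneratorSpec) -> pd.Series:
    """Pfam accession -> archetype, in a fixed deterministic order."""
    labels = []
    for a in ("photosynthesis", "motility", "phagocytosis", "housekeeping"):
        labels += [a] * spec.archetype_counts.get(a, 0)
    labels += ["noise"] * spec.n_noise
    accs = [f"PF{i:05d}" for i in range(1, len(labels) + 1)]
    return pd.Series(labels, index=pd.Index(accs, name="pfam_acc"), name="archetype")


def signal_pfams(spec: GeneratorSpec) -> list[str]:
    """The planted mode-informative Pfams (non-housekeeping, non-noise)."""
    cat = pfam_catalog(spec)
    return cat.index[cat.isin(["photosynthesis", "motility", "phagocytosis"])].tolist()


def ctg_list(spec: GeneratorSpec) -> list[str]:
    """The housekeeping Pfams, serving as the Core Transcribed Gene list."""
    cat = pfam_catalog(spec)
    return cat.index[cat == "housekeeping"].tolist()


def _feature_offsets(spec: GeneratorSpec) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xFEA7]))
    return rng.normal(0.0, spec.feature_jitter_sd, size=spec.n_pfams_total)


def _draw_profiles(
    spec: GeneratorSpec, modes: list[str], rng: np.random.Generator
) -> np.ndarray:
    """Raw (un-normalized) expression matrix, one row per requested profile."""
    cat = pfam_catalog(spec)
    offsets = _feature_offsets(spec)
    arch = cat.to_numpy()
    n, p = len(modes), len(cat)

    # per-sample activity level per archetype
    act = np.empty((n, len(ARCHETYPES)))
    a_index = {a: k for k, a in enumerate(ARCHETYPES)}
    for i, m in enumerate(modes):
        for a, k in a_index.items():
            lo, hi = spec.activity[a][m]
            act[i, k] = rng.uniform(lo, hi)

    mu = np.empty((n, p))
    zp = np.empty((n, p))
    for j, a in enumerate(arch):
        lv = spec.levels[a]
        alpha = act[:, a_index[a]]
        mu[:, j] = lv["mu_off"] + alpha * (lv["mu_on"] - lv["mu_off"]) + offsets[j]
        zp[:, j] = lv["zp_off"] + alpha * (lv["zp_on"] - lv["zp_off"])
    expr = rng.lognormal(mean=mu, sigma=spec.log_sd)
    keep = rng.random(expr.shape) >= zp
    return expr * keep


def _renormalize(expr: np.ndarray) -> np.ndarray:
    sums = expr.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return expr / sums * 1e6


def generate_training(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Labeled training profiles plus the ground truth of the generator.

    Returns ``(matrix, labels, truth)``: a wide TPM matrix (rows =
    transcriptome ids, columns = Pfams, each row summing to 1e6), the
    trophic-mode label per row, and a truth dict with the planted signal
    Pfam list, the archetype catalog and the CTG list.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7A1]))
    modes: list[str] = []
    ids: list[str] = []
    for m in MODES:
        n = spec.class_counts.get(m, 0)
        modes += [m] * n
        ids += [f"{m[:5]}_{i:03d}" for i in range(n)]
    expr = _renormalize(_draw_profiles(spec, modes, rng))
    cat = pfam_catalog(spec)
    matrix = pd.DataFrame(expr, index=pd.Index(ids, name="transcriptome_id"), columns=cat.index)
    labels = pd.Series(modes, index=matrix.index, name="label")
    truth = {
        "signal_pfams": signal_pfams(spec),
        "archetypes": cat,
        "ctg_list": ctg_list(spec),
    }
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# Environmental scenarios
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentScenario:
    """Layout of a mock environmental dataset.

    ``bin_modes`` maps species_bin -> either one trophic mode (constant along
    the transect) or a mapping station -> mode (e.g. a mode shift along a
    latitudinal gradient). ``ctg_dropout`` zeroes each housekeeping Pfam with
    the given probability, to exercise the completeness gate.
    """

    name: str = "surface"
    kind: str = "surface"
    cruise: str = "C1"
    stations: tuple[str, ...] = ("st01", "st02", "st03")
    replicates: tuple[str, ...] = ("r1", "r2")
    size_fractions: tuple[str, ...] = ("0.2-3um", ">3um")
    bin_modes: dict = field(
        default_factory=lambda: {
            "bin_photo": "phototrophy",
            "bin_hetero": "heterotrophy",
            "bin_mixo": "mixotrophy",
        }
    )
    dinoflagellate_bins: tuple[str, ...] = ()
    #: true transcript concentration (transcripts/L) per species bin.
    concentrations: dict = field(default_factory=dict)
    ctg_dropout: float = 0.0
    standard_copies_added: float = 1e8
    reads_mapped_to_standards: float = 1e5
    volume_filtered_L: float = 2.0


def gradient_shift_scenario() -> EnvironmentScenario:
    """A transect where one bin shifts heterotrophy -> mixotrophy northward."""
    stations = ("st01", "st02", "st03", "st04")
    return EnvironmentScenario(
        name="gradient-shift",
        stations=stations,
        bin_modes={
            "bin_photo": "phototrophy",
            "bin_hetero": "heterotrophy",
            "bin_shifter": {
                "st01": "heterotrophy",
                "st02": "heterotrophy",
                "st03": "mixotrophy",
                "st04": "mixotrophy",
            },
        },
        concentrations={"bin_photo": 5e8, "bin_hetero": 2e8, "bin_shifter": 3e8},
    )


def _mode_at(scenario: EnvironmentScenario, species_bin: str, station: str) -> str:
    spec = scenario.bin_modes[species_bin]
    return spec[station] if isinstance(spec, Mapping) else spec


def generate_environment(
    spec: GeneratorSpec, scenario: EnvironmentScenario
) -> dict:
    """Mock environmental dataset in the TSV dialects the pipeline reads.

    Returns a dict with keys:

    * ``profiles`` — long table (species_bin, sample_id, pfam_acc, tpm);
    * ``sample_metadata`` — sample_id, cruise, station (as latitude proxy),
      replicate, size_fraction, date;
    * ``bin_reads`` — species_bin, sample_id, station, replicate,
      size_fraction, reads (spike-in accounting inputs);
    * ``spike_ins`` — per-sample standard records;
    * ``truth`` — generating mode per (species_bin, station) and true
      concentrations per bin.

    Bin reads are derived by inverting the internal-standard estimator from
    the scenario's true concentrations split evenly across size fractions,
    so transcripts-per-liter recovery is exact up to floating point.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE27]))
    cat = pfam_catalog(spec)
    hk = cat == "housekeeping"
    profile_rows = []
    meta_rows = []
    read_rows = []
    spike_rows = []
    truth_modes = []

    n_frac = len(scenario.size_fractions)
    for station in scenario.stations:
        for rep in scenario.replicates:
            for frac in scenario.size_fractions:
                sample_id = f"{scenario.cruise}_{station}_{rep}_{frac}"
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "cruise": scenario.cruise,
                        "station": station,
                        "latitude": station,
                        "replicate": rep,
                        "size_fraction": frac,
                        "date": station,  # one station per day in diel-style runs
                    }
                )
                spike_rows.append(
                    {
                        "sample_id": sample_id,
                        "standard_copies_added": scenario.standard_copies_added,
                        "reads_mapped_to_standards": scenario.reads_mapped_to_standards,
                        "volume_filtered_L": scenario.volume_filtered_L,
                    }
                )
                for species_bin in scenario.bin_modes:
                    mode = _mode_at(scenario, species_bin, station)
                    expr = _draw_profiles(spec, [mode], rng)[0]
                    if scenario.ctg_dropout > 0:
                        drop = rng.random(int(hk.sum())) < scenario.ctg_dropout
                        idx = np.flatnonzero(hk.to_numpy())[drop]
                        expr[idx] = 0.0
                    tpm = _renormalize(expr[None, :])[0]
                    nz = tpm > 0
                    profile_rows.append(
                        pd.DataFrame(
                            {
                                "species_bin": species_bin,
                                "sample_id": sample_id,
                                "pfam_acc": cat.index[nz],
                                "tpm": tpm[nz],
                            }
                        )
                    )
                    conc = scenario.concentrations.get(species_bin, 1e8)
                    reads = (
                        conc / n_frac * scenario.volume_filtered_L
                        / scenario.standard_copies_added
                        * scenario.reads_mapped_to_standards
                    )
                    read_rows.append(
                        {
                            "species_bin": species_bin,
                            "sample_id": sample_id,
                            "station": station,
                            "replicate": rep,
                            "size_fraction": frac,
                            "reads": reads,
                        }
                    )
        for species_bin in scenario.bin_modes:
            truth_modes.append(
                {
                    "species_bin": species_bin,
                    "station": station,
                    "mode": _mode_at(scenario, species_bin, station),
                }
            )

    return {
        "profiles": pd.concat(profile_rows, ignore_index=True),
        "sample_metadata": pd.DataFrame(meta_rows),
        "bin_reads": pd.DataFrame(read_rows),
        "spike_ins": pd.DataFrame(spike_rows),
        "truth": {
            "modes": pd.DataFrame(truth_modes),
            "concentrations": dict(scenario.concentrations),
            "dinoflagellate_bins": list(scenario.dinoflagellate_bins),
        },
    }


def summarize(matrix: pd.DataFrame, labels: pd.Series, archetypes: pd.Series) -> pd.DataFrame:
    """Median TPM per (archetype, mode): a check of the generator's structure.

    For each trophic mode, the median TPM of every Pfam across that mode's
    profiles is computed, then averaged (median) within archetypes.
    """
    rows = []
    for mode in MODES:
        sub = matrix.loc[labels == mode]
        med = sub.median(axis=0)
        for a in ARCHETYPES:
            cols = archetypes.index[archetypes == a]
            if len(cols):
                rows.append({"archetype": a, "mode": mode, "median_tpm": float(med[cols].median())})
    return pd.DataFrame(rows)


def scaled_down(spec: GeneratorSpec, factor: int = 4) -> GeneratorSpec:
    """A smaller copy of a spec (classes and Pfam counts divided by factor)."""
    return replace(
        spec,
        n_pfams_total=max(50, spec.n_pfams_total // factor),
        archetype_counts={
            a: max(2, n // factor) if a != "housekeeping" else max(10, n // factor)
            for a, n in spec.archetype_counts.items()
        },
        class_counts={m: max(8, n // factor) for m, n in spec.class_counts.items()},
    )
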