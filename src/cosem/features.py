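"""The ten candidate predictors of the protein expression score.

For a coding sequence j with elongation-rate profile omega_i and accuracy
profile a_i the features are

==  ==================  =============================================
x1  current             steady-state protein synthesis rate per mRNA
                        from the traffic simulation [protein/(s*mRNA)]
x2  avg_rate            arithmetic mean elongation rate [codon/s]
x3  bottleneck          minimum 10-codon sliding-window mean rate [codon/s]
x4  accuracy            product of per-codon accuracies, prod_i a_i
x5  folding_energy      5' MFE of the first 30 codons [kcal/mol]
x6  log10_transcript    log10 transcript abundance (optional)
x7  gc3                 G+C fraction at third codon positions
x8  ramp                mean elongation rate over the first 30 codons [codon/s]
x9  hairpins            hairpin count in the 5' structure
x10 length              sequence length in codons
==  ==================  =============================================

The arithmetic mean is used for x2 (it correlates less with the current
than the harmonic mean and therefore adds more independent information);
the harmonic mean is available from :func:`cosem.simulator.mean_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .folding import FoldingEngine, count_hairpins, default_engine
from .rate_model import CodonRateTable, clean_cds, sequence_profiles
from .simulator import TranslationSystem, simulate

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "gc3",
    "bottleneck_index",
    "ramp_index",
    "accuracy_product",
    "folding_features_5prime",
    "compute_features",
    "features_frame",
]

FEATURE_NAMES = (
    "current",
    "avg_rate",
    "bottleneck",
    "accuracy",
    "folding_energy",
    "log10_transcript",
    "gc3",
    "ramp",
    "hairpins",
    "length",
)

RAMP_WINDOW = 30  # codons
BOTTLENECK_WINDOW = 10  # codons
FOLD_WINDOW_NT = 90  # first 30 codons


@dataclass(frozen=True)
class FeatureVector:
    """One sequence's predictor values; ``log10_transcript`` is None when the
    transcript abundance is undetermined (the situation at sequence-design
    time)."""

    current: float
    avg_rate: float
    bottleneck: float
    accuracy: float
    folding_energy: float
    log10_transcript: float | None
    gc3: float
    ramp: float
    hairpins: int
    length: int

    def as_dict(self) -> dict:
        return asdict(self)

    def as_series(self) -> pd.Series:
        d = self.as_dict()
        if d["log10_transcript"] is None:
            d["log10_transcript"] = np.nan
        return pd.Series(d, index=list(FEATURE_NAMES), dtype=float)


def gc3(seq: str) -> float:
    """Fraction of G or C at third codon positions (stop codon included if
    present; gc3 is a plain nucleotide statistic)."""
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    if len(s) % 3 != 0:
        raise ValueError(f"length {len(s)} not divisible by 3")
    thirds = s[2::3]
    return sum(c in "GC" for c in thirds) / len(thirds)


def bottleneck_index(profile: np.ndarray, window: int = BOTTLENECK_WINDOW) -> float:
    """Minimum over all contiguous windows of the window-mean elongation rate."""
    p = np.asarray(profile, dtype=float)
    if p.size < window:
        raise ValueError(f"profile length {p.size} shorter than window {window}")
    csum = np.concatenate([[0.0], np.cumsum(p)])
    means = (csum[window:] - csum[:-window]) / window
    return float(means.min())


def ramp_index(profile: np.ndarray, window: int = RAMP_WINDOW) -> float:
    """Arithmetic mean elongation rate over the first ``window`` codons."""
    p = np.asarray(profile, dtype=float)
    if p.size < window:
        raise ValueError(f"profile length {p.size} shorter than ramp window {window}")
    return float(p[:window].mean())


def accuracy_product(acc_profile: np.ndarray) -> float:
    """prod_i a_i, computed in the log domain (underflow-safe)."""
    a = np.asarray(acc_profile, dtype=float)
    if np.any(a <= 0) or np.any(a > 1):
        raise ValueError("accuracies must lie in (0, 1]")
    return float(math.exp(np.log(a).sum()))


def folding_features_5prime(
    seq: str,
    engine: FoldingEngine | None = None,
    *,
    window_nt: int = FOLD_WINDOW_NT,
    min_stem: int = 3,
) -> tuple[float, int]:
    """MFE (kcal/mol) and hairpin count of the first ``window_nt`` nucleotides.

    Sequences shorter than the window are folded whole.
    """
    if engine is None:
        engine = default_engine()
    s = str(seq).strip().upper().replace("U", "T")
    structure, energy = engine.fold(s[:window_nt])
    return float(energy), count_hairpins(structure, min_stem=min_stem)


def compute_features(
    seq: str,
    table: CodonRateTable,
    *,
    init_rate: float,
    dropoff_rate: float = 0.0,
    term_rate: float | None = None,
    footprint: int = 10,
    transcript_abundance: float | None = None,
    seed: int = 0,
    engine: FoldingEngine | None = None,
    simulate_kwargs: dict | None = None,
) -> FeatureVector:
    """Compute the full feature vector for one coding sequence.

    The current (x1) comes from the traffic simulation and is reproducible
    bit-for-bit given ``seed``; all other features are deterministic
    functions of the sequence and the rate table.  ``simulate_kwargs`` tunes
    the simulation (e.g. ``target_completions`` for faster, noisier
    estimates).
    """
    s = clean_cds(seq)
    rates, accs = sequence_profiles(s, table)
    sys = TranslationSystem(
        rates=rates,
        init_rate=init_rate,
        term_rate=term_rate,
        dropoff_rate=dropoff_rate,
        footprint=footprint,
    )
    res = simulate(
        sys, seed=seed, collect_profile=False, **(simulate_kwargs or {})
    )
    energy, hairpins = folding_features_5prime(s, engine)
    return FeatureVector(
        current=res.current,
        avg_rate=float(rates.mean()),
        bottleneck=bottleneck_index(rates),
        accuracy=accuracy_product(accs),
        folding_energy=energy,
        log10_transcript=(
            math.log10(transcript_abundance)
            if transcript_abundance is not None
            else None
        ),
        gc3=gc3(s),
        ramp=ramp_index(rates),
        hairpins=hairpins,
        length=int(rates.size),
    )


def features_frame(
    records: list[tuple[str, str]],
    table: CodonRateTable,
    *,
    init_rate: float,
    transcript_abundances: dict[str, float] | None = None,
    seed: int = 0,
    engine: FoldingEngine | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature table (one row per (id, sequence) record), indexed by id.

    Each record gets an independent simulation seed derived from ``seed``.
    """
    if engine is None:
        engine = default_engine()
    rows = {}
    for k, (rid, seq) in enumerate(records):
        ta = (transcript_abundances or {}).get(rid)
        fv = compute_features(
            seq,
            table,
            init_rate=init_rate,
            transcript_abundance=ta,
            seed=seed + k,
            engine=engine,
            **kwargs,
        )
        rows[rid] = fv.as_series()
    return pd.DataFrame(rows).T.rename_axis("id")
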