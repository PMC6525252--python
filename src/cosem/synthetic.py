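"""Deterministic generators for rate tables, tRNA pools, toy genes and
benchmark datasets with known additive ground truth.

Everything regenerates bit-identically from its seed.  Default rate ranges
bracket the organism-wide average elongation rates of common expression
hosts (roughly 6 to 33 per second between slow mammalian and fast yeast
translation), so slow-bottleneck and fast-traffic regimes are both
exercised; the generated codon usage makes no attempt to mimic any real
organism's codon bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import features_frame
from .rate_model import (
    GENETIC_CODE,
    SENSE_CODONS,
    SYNONYMS,
    CodonRateTable,
    TRNAPool,
)

__all__ = [
    "make_rate_table",
    "make_trna_pool",
    "make_genes",
    "EffectSpec",
    "GenerativeSpec",
    "SyntheticBenchmark",
    "make_benchmark",
]


def make_rate_table(
    seed: int,
    rate_range: tuple[float, float] = (4.0, 40.0),
    accuracy_range: tuple[float, float] = (0.90, 0.9999),
    *,
    organism_label: str = "synthetic",
) -> CodonRateTable:
    """Random valid rate table; synonyms are drawn independently so every
    codon family has rate and accuracy spread (needed by the optimizer)."""
    lo, hi = rate_range
    alo, ahi = accuracy_range
    if lo <= 0 or hi < lo or not (0 < alo <= ahi <= 1):
        raise ValueError("invalid rate or accuracy range")
    rng = np.random.default_rng(seed)
    rates = {c: float(rng.uniform(lo, hi)) for c in SENSE_CODONS}
    accs = {c: float(rng.uniform(alo, ahi)) for c in SENSE_CODONS}
    return CodonRateTable(organism_label=organism_label, rates=rates, accuracies=accs)


def make_trna_pool(seed: int, *, conc_range: tuple[float, float] = (1.0, 20.0)) -> TRNAPool:
    """One tRNA species per sense codon with a random concentration.

    Near-cognates of a codon are the other codons of the same family plus
    same-first-two-nucleotide codons of other amino acids (a wobble-like
    convention); everything else is non-cognate.
    """
    rng = np.random.default_rng(seed)
    conc = {f"tRNA-{c}": float(rng.uniform(*conc_range)) for c in SENSE_CODONS}
    cognate, near, non = {}, {}, {}
    for c in SENSE_CODONS:
        fam = set(SYNONYMS[GENETIC_CODE[c]])
        wobble = {o for o in SENSE_CODONS if o[:2] == c[:2]}
        near_set = (fam | wobble) - {c}
        cognate[c] = frozenset({f"tRNA-{c}"})
        near[c] = frozenset(f"tRNA-{o}" for o in near_set)
        non[c] = frozenset(
            f"tRNA-{o}" for o in SENSE_CODONS if o != c and o not in near_set
        )
    return TRNAPool(
        concentrations=conc, cognate=cognate, near_cognate=near, non_cognate=non
    )


def make_genes(
    seed: int,
    n: int,
    length_range: tuple[int, int] = (40, 90),
    *,
    with_stop: bool = True,
) -> list[tuple[str, str]]:
    """Random coding sequences: ATG start, random sense codons, optional
    terminal TAA; lengths (in codons, excluding the stop) drawn uniformly."""
    lo, hi = length_range
    if lo < 30:
        raise ValueError("genes must be at least 30 codons for the ramp window")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    out = []
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(codons, size=length - 1))
        seq = "ATG" + body + ("TAA" if with_stop else "")
        out.append((f"gene{k:04d}", seq))
    return out


@dataclass(frozen=True)
class EffectSpec:
    """One additive generative effect g_k acting on a z-scored feature.

    shapes: 'linear' a*z; 'monotone' a*tanh(z) (smooth, saturating,
    increasing); 'quadratic' a*(z**2 - 1) (centred, symmetric).
    """

    shape: str
    amplitude: float = 1.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            return self.amplitude * z
        if self.shape == "monotone":
            return self.amplitude * np.tanh(z)
        if self.shape == "quadratic":
            return self.amplitude * (z**2 - 1.0)
        raise ValueError(f"unknown effect shape {self.shape!r}")


@dataclass(frozen=True)
class GenerativeSpec:
    """Which features carry signal, their shapes, and the noise level."""

    effects: dict = field(
        default_factory=lambda: {
            "current": EffectSpec("monotone", 1.0),
            "gc3": EffectSpec("quadratic", 0.6),
            "log10_transcript": EffectSpec("linear", 0.8),
        }
    )
    noise_sd: float = 1.4  # puts the default explainable fraction near 0.5
    offset: float = 2.0


@dataclass
class SyntheticBenchmark:
    """Genes + rate table + features + outcomes with recorded ground truth.

    ``generative_r2`` is the exact explainable variance fraction
    var(signal) / (var(signal) + noise_sd**2) computed from the recorded
    signal values, i.e. the R^2 an oracle regression function would reach on
    fresh noise draws.
    """

    seed: int
    genes: list[tuple[str, str]]
    table: CodonRateTable
    transcript_abundance: dict[str, float]
    features: "object"  # pandas DataFrame, id-indexed
    signal: np.ndarray
    y: np.ndarray
    spec: GenerativeSpec
    generative_r2: float
    feature_stats: dict


def make_benchmark(
    seed: int,
    n: int = 300,
    spec: GenerativeSpec | None = None,
    *,
    init_rate: float = 0.5,
    dropoff_rate: float = 0.0066,
    length_range: tuple[int, int] = (40, 90),
    target_completions: int = 60,
) -> SyntheticBenchmark:
    """Benchmark dataset: features through the real pipeline (fast simulator
    settings), outcomes y = offset + sum_k g_k(z_k) + N(0, sd).

    ``init_rate`` 0.5/s and a drop-off rate of 0.0066/s (a 3e-4 per-codon
    drop-off probability at a 22/s average elongation rate) put the traffic
    in the initiation-limited regime typical of cellular translation.
    """
    spec = spec or GenerativeSpec()
    rng = np.random.default_rng(seed)
    table = make_rate_table(seed + 1)
    genes = make_genes(seed + 2, n, length_range)
    transcript = {
        gid: float(10 ** rng.normal(1.5, 0.8)) for gid, _ in genes
    }
    feats = features_frame(
        genes,
        table,
        init_rate=init_rate,
        dropoff_rate=dropoff_rate,
        transcript_abundances=transcript,
        seed=seed + 3,
        simulate_kwargs={"target_completions": target_completions},
    )
    signal = np.zeros(len(feats))
    stats = {}
    for name, effect in spec.effects.items():
        x = feats[name].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std())
        if sd == 0:
            raise ValueError(f"feature {name} is constant; cannot carry signal")
        stats[name] = {"mean": mu, "sd": sd, "shape": effect.shape,
                       "amplitude": effect.amplitude}
        signal = signal + effect((x - mu) / sd)
    y = spec.offset + signal + rng.normal(0.0, spec.noise_sd, size=len(feats))
    var_sig = float(np.var(signal))
    gen_r2 = var_sig / (var_sig + spec.noise_sd**2)
    return SyntheticBenchmark(
        seed=seed,
        genes=genes,
        table=table,
        transcript_abundance=transcript,
        features=feats,
        signal=signal,
        y=y,
        spec=spec,
        generative_r2=gen_r2,
        feature_stats=stats,
    )
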