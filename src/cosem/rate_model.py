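"""Codon-level kinetic parameters.

A :class:`CodonRateTable` assigns every sense codon an elongation rate
``omega`` (1/s) and an accuracy ``a`` (the probability that the ribosome
incorporates a tRNA cognate to the codon).  Tables are either loaded from a
TSV file or synthesized from a simplified ternary-complex competition scheme
in which each codon's rate and accuracy follow from the concentrations of
its cognate, near-cognate and non-cognate tRNA species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "GENETIC_CODE",
    "SYNONYMS",
    "CodonRateTable",
    "TRNAPool",
    "RateTableError",
    "load_rate_table",
    "write_rate_table",
    "synthesize_rate_table",
    "sequence_profiles",
    "clean_cds",
    "translate",
    "dropoff_rate_from_probability",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
GENETIC_CODE: Mapping[str, str] = dict(_STANDARD.forward_table)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

# amino acid -> codons, alphabetical within each family
SYNONYMS: Mapping[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in GENETIC_CODE.items() if a == aa))
    for aa in sorted(set(GENETIC_CODE.values()))
}


class RateTableError(ValueError):
    """Raised when a rate table or coding sequence violates an invariant."""


def clean_cds(seq: str, *, name: str = "sequence") -> str:
    """Normalize a coding sequence: uppercase, U->T, strip one terminal stop.

    Internal stop codons and non-ACGT characters are hard errors; the length
    must be divisible by 3.  Returns the sense-codon part of the CDS.
    """
    s = str(seq).strip().upper().replace("U", "T")
    if not s:
        raise RateTableError(f"{name}: empty sequence")
    bad = set(s) - set("ACGT")
    if bad:
        raise RateTableError(f"{name}: non-ACGT characters {sorted(bad)}")
    if len(s) % 3 != 0:
        raise RateTableError(f"{name}: length {len(s)} not divisible by 3")
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise RateTableError(f"{name}: internal stop codon {c} at codon {i + 1}")
    if not codons:
        raise RateTableError(f"{name}: no sense codons")
    return "".join(codons)


def translate(seq: str) -> str:
    """Translate a (cleaned or raw) CDS to its amino-acid sequence."""
    s = clean_cds(seq)
    return "".join(GENETIC_CODE[s[i : i + 3]] for i in range(0, len(s), 3))


@dataclass(frozen=True)
class CodonRateTable:
    """Per-codon elongation rates (1/s) and accuracies for one organism/context.

    Invariants: all 61 sense codons present, rates > 0, accuracies in (0, 1].
    """

    organism_label: str
    rates: Mapping[str, float]
    accuracies: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, mapping in (("rate", self.rates), ("accuracy", self.accuracies)):
            extra = set(mapping) - set(SENSE_CODONS)
            stops = extra & STOP_CODONS
            if stops:
                raise RateTableError(f"stop codons not allowed in table: {sorted(stops)}")
            if extra:
                raise RateTableError(f"invalid codons in table: {sorted(extra)}")
            missing = set(SENSE_CODONS) - set(mapping)
            if missing:
                raise RateTableError(
                    f"missing {name} for codon(s): {', '.join(sorted(missing))}"
                )
        for c in SENSE_CODONS:
            r = float(self.rates[c])
            a = float(self.accuracies[c])
            if not r > 0.0 or not np.isfinite(r):
                raise RateTableError(f"nonpositive elongation rate for {c}: {r}")
            if not 0.0 < a <= 1.0:
                raise RateTableError(f"accuracy for {c} outside (0, 1]: {a}")

    def rate(self, codon: str) -> float:
        return float(self.rates[codon])

    def accuracy(self, codon: str) -> float:
        return float(self.accuracies[codon])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": list(SENSE_CODONS),
                "elongation_rate": [self.rates[c] for c in SENSE_CODONS],
                "accuracy": [self.accuracies[c] for c in SENSE_CODONS],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, organism_label: str = "") -> "CodonRateTable":
        required = {"codon", "elongation_rate", "accuracy"}
        if not required <= set(frame.columns):
            raise RateTableError(
                f"rate table needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        codons = frame["codon"].astype(str).str.upper().str.replace("U", "T")
        return cls(
            organism_label=organism_label,
            rates=dict(zip(codons, frame["elongation_rate"].astype(float))),
            accuracies=dict(zip(codons, frame["accuracy"].astype(float))),
        )


def load_rate_table(path: str | Path, organism_label: str | None = None) -> CodonRateTable:
    """Load a validated rate table from TSV (columns codon / elongation_rate /
    accuracy, ``#`` comment lines allowed)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return CodonRateTable.from_frame(frame, organism_label or path.stem)


def write_rate_table(table: CodonRateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TRNAPool:
    """tRNA species concentrations and a codon-wise cognate partition.

    ``cognate``/``near_cognate``/``non_cognate`` map each sense codon to a
    disjoint set of species names; every codon needs at least one cognate
    species.  Species concentrations are in arbitrary (relative) units:
    the competition formula below is scale invariant.
    """

    concentrations: Mapping[str, float]
    cognate: Mapping[str, frozenset[str]] = field(default_factory=dict)
    near_cognate: Mapping[str, frozenset[str]] = field(default_factory=dict)
    non_cognate: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, conc in self.concentrations.items():
            if conc < 0:
                raise RateTableError(f"negative concentration for species {sp}")
        for codon in SENSE_CODONS:
            cog = self.cognate.get(codon, frozenset())
            near = self.near_cognate.get(codon, frozenset())
            non = self.non_cognate.get(codon, frozenset())
            if cog & near or cog & non or near & non:
                raise RateTableError(f"overlapping tRNA partition for codon {codon}")
            if not cog:
                raise RateTableError(f"codon {codon} has no cognate tRNA species")

    def concentration_of(self, species: frozenset[str]) -> float:
        return float(sum(self.concentrations.get(sp, 0.0) for sp in species))


def synthesize_rate_table(
    pool: TRNAPool,
    base_rate: float = 22.0,
    *,
    w_near: float = 0.1,
    w_non: float = 0.01,
    organism_label: str = "synthetic",
) -> CodonRateTable:
    """Generate a rate table from ternary-complex competition.

    For each codon ``c`` with aggregate cognate / near-cognate / non-cognate
    concentrations ``C``, ``N``, ``X``::

        omega_c = base_rate * C / (C + w_near * N + w_non * X)
        a_c     = C / (C + w_near * N)

    ``w_near`` and ``w_non`` are fixed discrimination weights for the reduced
    binding of near- and non-cognate ternary complexes.  The map is
    deterministic and invariant under a common rescaling of concentrations.
    """
    if base_rate <= 0:
        raise RateTableError("base_rate must be positive")
    rates: dict[str, float] = {}
    accs: dict[str, float] = {}
    for codon in SENSE_CODONS:
        cog = pool.concentration_of(pool.cognate.get(codon, frozenset()))
        near = pool.concentration_of(pool.near_cognate.get(codon, frozenset()))
        non = pool.concentration_of(pool.non_cognate.get(codon, frozenset()))
        if cog <= 0:
            raise RateTableError(f"codon {codon}: zero total cognate concentration")
        rates[codon] = base_rate * cog / (cog + w_near * near + w_non * non)
        accs[codon] = cog / (cog + w_near * near)
    return CodonRateTable(organism_label=organism_label, rates=rates, accuracies=accs)


def sequence_profiles(
    seq: str, table: CodonRateTable
) -> tuple[np.ndarray, np.ndarray]:
    """Map a CDS to its per-codon elongation-rate and accuracy profiles.

    A terminal stop codon is stripped; internal stops raise.  Position ``i``
    of the returned arrays is the table entry for codon ``i`` of the sequence.
    """
    s = clean_cds(seq)
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    rates = np.array([table.rates[c] for c in codons], dtype=float)
    accs = np.array([table.accuracies[c] for c in codons], dtype=float)
    return rates, accs


def dropoff_rate_from_probability(per_codon_probability: float, elongation_rate: float) -> float:
    """Convert a per-codon drop-off probability into a rate gamma (1/s).

    A ribosome spends on average 1/omega at a codon, so a per-codon drop-off
    probability p corresponds to gamma = p * omega.
    """
    if per_codon_probability < 0 or elongation_rate <= 0:
        raise ValueError("need probability >= 0 and elongation rate > 0")
    return per_codon_probability * elongation_rate
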