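"""Score-driven synonymous codon sequence design.

Candidate sequences are sampled codon by codon: at each position the
synonymous codon l is proposed with probability

    pi_l = (s1 * (w_l - w_min)/(w_max - w_min)
            + s2 * (a_l - a_min)/(a_max - a_min) + eps) / W

where w/a are the codon's elongation rate and accuracy, s1 and s2 weight
speed against accuracy, and eps regularizes so the slowest/least accurate
synonym keeps a nonzero proposal probability.  The search starts from the
locally optimal sequence (per-position argmax of the combined normalized
criterion), evaluates the weighted protein expression score of every
proposal, keeps the best, and terminates when the coefficient of variation
among the running top-m scores falls below a threshold (default m = 100,
5%).  Deoptimization minimizes instead of maximizes; frozen regions (e.g. a
ramp of slow codons in the first 50 codons) are copied from the wildtype.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .boosting import ExpressionBooster
from .features import compute_features
from .folding import default_engine
from .rate_model import (
    GENETIC_CODE,
    SYNONYMS,
    CodonRateTable,
    clean_cds,
    translate,
)

__all__ = [
    "ProposalWeights",
    "OptimizerConfig",
    "OptimizationResult",
    "proposal_probabilities",
    "initial_sequence",
    "optimize",
    "relative_score",
    "cai",
]

#: feature weights used at sequence-design time: transcript abundance is
#: undetermined for a synthetic sequence, so its weight is zero.
DESIGN_WEIGHTS = {"log10_transcript": 0.0}


@dataclass(frozen=True)
class ProposalWeights:
    """s1 (rate), s2 (accuracy) and the regularization eps of the proposal
    distribution."""

    s1: float = 1.0
    s2: float = 1.0
    eps: float = 0.05

    def __post_init__(self) -> None:
        if self.s1 < 0 or self.s2 < 0:
            raise ValueError("s1 and s2 must be nonnegative")
        if self.s1 == 0 and self.s2 == 0 and self.eps <= 0:
            raise ValueError("s1 = s2 = 0 requires eps > 0")


@dataclass
class OptimizerConfig:
    """Search configuration.

    ``frozen`` holds 0-based codon indices copied from the wildtype.
    ``stop_window`` (m) and ``cv_threshold`` define termination: the run
    stops once the coefficient of variation among the tracked m scores
    drops below the threshold.  ``score_buffer`` chooses what those m
    scores are: the global top-m distinct scores seen so far (``"top"``,
    default) or the last m record-breaking scores (``"recent"``).
    """

    objective: str = "maximize"
    weights: dict = field(default_factory=lambda: dict(DESIGN_WEIGHTS))
    frozen: frozenset = frozenset()
    stop_window: int = 100
    cv_threshold: float = 0.05
    max_proposals: int = 2000
    score_buffer: str = "top"
    seed: int = 0
    proposal: ProposalWeights = ProposalWeights()

    def __post_init__(self) -> None:
        if self.objective not in ("maximize", "minimize"):
            raise ValueError("objective must be 'maximize' or 'minimize'")
        if self.stop_window < 2:
            raise ValueError("stop_window must be >= 2")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")
        if self.score_buffer not in ("top", "recent"):
            raise ValueError("score_buffer must be 'top' or 'recent'")


@dataclass
class OptimizationResult:
    best_sequence: str
    best_score: float
    wildtype_score: float
    relative_score: float
    proposals_evaluated: int
    converged: bool
    trajectory: list


def _sequence_seed(seq: str, base_seed: int) -> int:
    """Deterministic per-sequence simulation seed: identical sequences always
    receive identical scores (so a flat synonym landscape really scores
    flat), while distinct sequences get effectively independent streams."""
    return (int(base_seed) + zlib.crc32(seq.encode())) % (2**31 - 1)


def _normalized(values: np.ndarray) -> np.ndarray:
    """(v - min)/(max - min); all-equal values normalize to 0 (the
    continuity limit, leaving only the eps term)."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def proposal_probabilities(
    codons: list[str],
    table: CodonRateTable,
    weights: ProposalWeights = ProposalWeights(),
) -> np.ndarray:
    """Proposal probability for each synonymous codon in ``codons``.

    ``codons`` must be one synonym family (all encoding the same amino
    acid).  Returns a probability vector summing to one; when every synonym
    has identical rate and accuracy, the distribution is uniform.
    """
    if not codons:
        raise ValueError("empty synonym family")
    aas = {GENETIC_CODE[c] for c in codons}
    if len(aas) != 1:
        raise ValueError(f"codons encode different amino acids: {sorted(aas)}")
    if len(codons) == 1:
        return np.array([1.0])
    w = np.array([table.rate(c) for c in codons])
    a = np.array([table.accuracy(c) for c in codons])
    raw = weights.s1 * _normalized(w) + weights.s2 * _normalized(a) + weights.eps
    total = raw.sum()
    if total <= 0:
        return np.full(len(codons), 1.0 / len(codons))
    return raw / total


def _combined_criterion(codons: list[str], table: CodonRateTable,
                        weights: ProposalWeights) -> np.ndarray:
    w = np.array([table.rate(c) for c in codons])
    a = np.array([table.accuracy(c) for c in codons])
    return weights.s1 * _normalized(w) + weights.s2 * _normalized(a)


def initial_sequence(
    protein_or_cds: str,
    table: CodonRateTable,
    weights: ProposalWeights = ProposalWeights(),
) -> str:
    """Locally optimal seed: per position, the synonym maximizing the
    combined normalized rate + accuracy criterion (ties break to the
    alphabetically first codon)."""
    s = protein_or_cds.strip().upper()
    # nucleotide input is detected by alphabet + translatability; an
    # all-A/C/G/T peptide that is also a valid CDS is read as DNA
    protein = s
    if set(s) <= set("ACGTU") and len(s) % 3 == 0:
        try:
            protein = translate(s)
        except Exception:
            protein = s
    out = []
    for aa in protein:
        if aa not in SYNONYMS:
            raise ValueError(f"unknown amino acid {aa!r}")
        fam = list(SYNONYMS[aa])  # alphabetical; argmax takes the first max
        crit = _combined_criterion(fam, table, weights)
        out.append(fam[int(np.argmax(crit))])
    return "".join(out)


def _cv(scores: np.ndarray) -> float:
    mean = scores.mean()
    if mean == 0:
        return math.inf
    return float(scores.std(ddof=1) / abs(mean))


def optimize(
    wildtype: str,
    table: CodonRateTable,
    model: ExpressionBooster,
    config: OptimizerConfig | None = None,
    *,
    init_rate: float,
    dropoff_rate: float = 0.0,
    footprint: int = 10,
    engine=None,
    simulate_kwargs: dict | None = None,
) -> OptimizationResult:
    """Search synonymous sequence space for the best weighted score.

    The candidate set always contains the wildtype and the locally optimal
    seed, so when maximizing the best score is >= the wildtype score (and
    <= when minimizing).  Every candidate is checked to translate to the
    wildtype protein.  The result is flagged non-converged when
    ``max_proposals`` is reached before the CV criterion fires.
    """
    config = config or OptimizerConfig()
    wt = clean_cds(wildtype)
    protein = translate(wt)
    wt_codons = [wt[i : i + 3] for i in range(0, len(wt), 3)]
    engine = engine or default_engine()
    sign = 1.0 if config.objective == "maximize" else -1.0
    rng = np.random.default_rng(config.seed)

    # per-position synonym families and proposal distributions
    families: list[list[str]] = []
    probs: list[np.ndarray] = []
    for i, aa in enumerate(protein):
        if i in config.frozen:
            families.append([wt_codons[i]])
            probs.append(np.array([1.0]))
        else:
            fam = list(SYNONYMS[aa])
            families.append(fam)
            probs.append(proposal_probabilities(fam, table, config.proposal))

    def evaluate(seq: str) -> float:
        assert translate(seq) == protein, "proposal changed the protein"
        fv = compute_features(
            seq,
            table,
            init_rate=init_rate,
            dropoff_rate=dropoff_rate,
            footprint=footprint,
            seed=_sequence_seed(seq, config.seed),
            engine=engine,
            simulate_kwargs=simulate_kwargs,
        )
        return model.score_weighted(fv, config.weights)

    wt_score = evaluate(wt)
    ini = initial_sequence(protein, table, config.proposal)
    seed_seq = "".join(
        wt_codons[i] if i in config.frozen else ini[3 * i : 3 * i + 3]
        for i in range(len(protein))
    )

    best_seq, best_score = wt, wt_score
    buffer: list[float] = [wt_score]
    trajectory: list[float] = [wt_score]
    converged = False
    evaluated = 1

    def admit(score_val: float, seq: str) -> None:
        nonlocal best_seq, best_score
        if sign * score_val > sign * best_score:
            best_seq, best_score = seq, score_val
            if config.score_buffer == "recent":
                buffer.append(score_val)
                del buffer[: -config.stop_window]
        if config.score_buffer == "top":
            buffer.append(score_val)
            buffer.sort(key=lambda s: sign * s, reverse=True)
            del buffer[config.stop_window :]

    proposals = [seed_seq]
    while evaluated <= config.max_proposals:
        if proposals:
            seq = proposals.pop()
        else:
            codons = [
                fam[rng.choice(len(fam), p=p)] if len(fam) > 1 else fam[0]
                for fam, p in zip(families, probs)
            ]
            seq = "".join(codons)
        sc = evaluate(seq)
        evaluated += 1
        admit(sc, seq)
        trajectory.append(best_score)
        if len(buffer) >= config.stop_window and _cv(np.asarray(buffer)) < config.cv_threshold:
            converged = True
            break

    return OptimizationResult(
        best_sequence=best_seq,
        best_score=best_score,
        wildtype_score=wt_score,
        relative_score=_relative(best_score, wt_score),
        proposals_evaluated=evaluated,
        converged=converged,
        trajectory=trajectory,
    )


def _relative(variant_score: float, wildtype_score: float) -> float:
    """score ratio; when the wildtype score is <= 0 both scores are shifted
    by (1 - wildtype score) so the ratio stays defined (shift documented,
    raw scores are always reported alongside)."""
    if wildtype_score > 0:
        return variant_score / wildtype_score
    shift = 1.0 - wildtype_score
    return (variant_score + shift) / (wildtype_score + shift)


def relative_score(
    variant: str,
    wildtype: str,
    table: CodonRateTable,
    model: ExpressionBooster,
    weights: dict | None = None,
    *,
    init_rate: float,
    seed: int = 0,
    **feature_kwargs,
) -> tuple[float, float, float]:
    """(relative, variant score, wildtype score) for one synonymous variant.

    Raises when the two sequences translate to different proteins.
    """
    v, w = clean_cds(variant), clean_cds(wildtype)
    if translate(v) != translate(w):
        raise ValueError("variant and wildtype encode different proteins")
    weights = dict(DESIGN_WEIGHTS) if weights is None else weights
    fv = compute_features(
        v, table, init_rate=init_rate, seed=_sequence_seed(v, seed), **feature_kwargs
    )
    fw = compute_features(
        w, table, init_rate=init_rate, seed=_sequence_seed(w, seed), **feature_kwargs
    )
    sv = model.score_weighted(fv, weights)
    sw = model.score_weighted(fw, weights)
    return _relative(sv, sw), sv, sw


def cai(seq: str, usage: dict) -> float:
    """Codon adaptation index (auxiliary comparison baseline, not part of
    the expression score): geometric mean of relative adaptiveness
    w_c = f_c / max(f over the codon's synonym family)."""
    s = clean_cds(seq)
    wmax = {
        aa: max(usage.get(c, 0.0) for c in fam) for aa, fam in SYNONYMS.items()
    }
    logs = []
    for i in range(0, len(s), 3):
        c = s[i : i + 3]
        aa = GENETIC_CODE[c]
        denom = wmax[aa]
        if denom <= 0:
            continue
        w = max(usage.get(c, 0.0), 1e-12) / denom
        logs.append(math.log(w))
    if not logs:
        raise ValueError("no informative codons for CAI")
    return math.exp(sum(logs) / len(logs))
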