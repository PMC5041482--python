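"""Codon-usage models for motif encoding in coding sequences.

A 4 bp motif, or a 5 bp motif straddling one codon boundary, is carried by
an adjacent codon *pair*; a 5 bp motif can also span *three* codons (last
base of the first, all of the second, first base of the third), which pins
the middle codon to the motif centre — GTA (Val) or CTT (Leu) for sense
motifs, TAC (Tyr) or AAG (Lys) for antisense. The symbol alphabet is the
20 amino acids plus a STOP symbol; ordered pairs with at most one STOP
give a 440-member universe, and the four admissible middle residues give
4 x 440 = 1760 triplets.

For an ORF class, the usage model records how often each synonymous codon
combination realises each amino-acid pair/triplet; the expected number of
predicted sites in an ORF is the sum, over its pairs and eligible
triplets, of the class-level probability that the realised combination
carries a motif.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .catalog import Genome, Transcript, reverse_complement
from .motifs import ALL_MOTIFS, scan, scan_antisense, MotifSet, DEFAULT_MOTIF_SETS

logger = logging.getLogger(__name__)

STOP = "*"

CODONS_BY_SYM: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_SYM.setdefault(_aa, [])
    CODONS_BY_SYM[_aa].append(_codon)
CODONS_BY_SYM[STOP] = list(standard_dna_table.stop_codons)
CODONS_BY_SYM = {aa: tuple(sorted(cs)) for aa, cs in sorted(CODONS_BY_SYM.items())}

SYM_OF_CODON: dict[str, str] = {c: aa for aa, cs in CODONS_BY_SYM.items() for c in cs}

AMINO_ACIDS: tuple[str, ...] = tuple(s for s in CODONS_BY_SYM if s != STOP)

#: Middle residues whose codons can sit under a three-codon-spanning 5-mer.
SENSE_MIDDLE = ("L", "V")       # CTT (Leu), GTA (Val)
ANTISENSE_MIDDLE = ("K", "Y")   # AAG (Lys), TAC (Tyr)
TRIPLET_MIDDLE = tuple(sorted(set(SENSE_MIDDLE + ANTISENSE_MIDDLE)))

FIVE_MERS = tuple(m for m in ALL_MOTIFS if len(m) == 5)

PairKey = tuple[str, str]
TripletKey = tuple[str, str, str]


def pair_universe() -> list[PairKey]:
    """All ordered symbol pairs with at most one STOP (400 aa-aa + 40 with STOP)."""
    syms = tuple(CODONS_BY_SYM)
    return [(a, b) for a in syms for b in syms if not (a == STOP and b == STOP)]


def triplet_universe() -> list[TripletKey]:
    """All (sym, middle, sym) keys with an admissible middle residue (1760)."""
    return [(a, m, b) for (a, b) in pair_universe() for m in TRIPLET_MIDDLE]


def pair_combinations(key: PairKey) -> list[tuple[str, str]]:
    a, b = key
    return list(product(CODONS_BY_SYM[a], CODONS_BY_SYM[b]))


def triplet_combinations(key: TripletKey) -> list[tuple[str, str, str]]:
    a, m, b = key
    return list(product(CODONS_BY_SYM[a], CODONS_BY_SYM[m], CODONS_BY_SYM[b]))


def _pair_has_motif(combo: tuple[str, str], direction: str,
                    motifs: Sequence[str] = ALL_MOTIFS) -> bool:
    hexamer = combo[0] + combo[1]
    if direction == "antisense":
        hexamer = reverse_complement(hexamer)
    return any(m in hexamer for m in motifs)


def _triplet_has_spanning_motif(combo: tuple[str, str, str], direction: str,
                                five_mers: Sequence[str] = FIVE_MERS) -> bool:
    """True when the 9-mer's core (last base of codon 1 through first base of
    codon 3) is a 5 bp motif in the requested direction."""
    core = (combo[0] + combo[1] + combo[2])[2:7]
    if direction == "antisense":
        core = reverse_complement(core)
    return core in five_mers


@lru_cache(maxsize=None)
def motif_encoding_pairs(direction: str) -> dict[PairKey, frozenset[tuple[str, str]]]:
    """Pairs able to host a motif in ``direction``, with their motif-bearing combinations."""
    if direction not in ("sense", "antisense"):
        raise ValueError(f"unknown direction {direction!r}")
    table: dict[PairKey, frozenset] = {}
    for key in pair_universe():
        hits = frozenset(c for c in pair_combinations(key)
                         if _pair_has_motif(c, direction))
        if hits:
            table[key] = hits
    return table


@lru_cache(maxsize=None)
def motif_encoding_triplets(direction: str) -> dict[TripletKey, frozenset[tuple[str, str, str]]]:
    """Triplets able to host a three-codon-spanning 5-mer in ``direction``."""
    if direction not in ("sense", "antisense"):
        raise ValueError(f"unknown direction {direction!r}")
    table: dict[TripletKey, frozenset] = {}
    for key in triplet_universe():
        hits = frozenset(c for c in triplet_combinations(key)
                         if _triplet_has_spanning_motif(c, direction))
        if hits:
            table[key] = hits
    return table


def enumeration_summary() -> dict[str, int]:
    """Universe sizes and motif-encoding counts.

    Pair counts are reported as the sense-only / antisense-only / both
    partition; triplet sense and antisense sets are disjoint.
    """
    sense = set(motif_encoding_pairs("sense"))
    anti = set(motif_encoding_pairs("antisense"))
    t_sense = set(motif_encoding_triplets("sense"))
    t_anti = set(motif_encoding_triplets("antisense"))
    return {
        "pair_universe": len(pair_universe()),
        "pairs_sense_only": len(sense - anti),
        "pairs_antisense_only": len(anti - sense),
        "pairs_both": len(sense & anti),
        "pairs_sense_capable": len(sense),
        "pairs_antisense_capable": len(anti),
        "triplet_universe": len(triplet_universe()),
        "triplets_sense": len(t_sense),
        "triplets_antisense": len(t_anti),
        "triplets_both": len(t_sense & t_anti),
    }


def spanning_middle_codons(direction: str) -> set[str]:
    """Middle codons observed across all motif-bearing triplet combinations."""
    return {c2 for combos in motif_encoding_triplets(direction).values()
            for (_, c2, _) in combos}


# ---------------------------------------------------------------------------
# usage models


def cds_codons(cds: str) -> list[str]:
    """Split a CDS (start codon through stop codon) into codons; validates frame."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def cds_symbols(codons: Sequence[str]) -> list[str]:
    return [SYM_OF_CODON[c] for c in codons]


@dataclass
class CodonUsageModel:
    """Class-conditional codon-combination usage for pairs and eligible triplets.

    ``pair_counts[key]`` maps each observed codon pair to its count in the
    class; triplets are restricted to admissible middle residues. Motif
    probabilities are usage-weighted fractions of motif-bearing
    combinations; a key never observed in the class falls back to the
    uniform-over-combinations prior (logged).
    """

    name: str = "usage"
    pair_counts: dict[PairKey, Counter] = field(default_factory=dict)
    triplet_counts: dict[TripletKey, Counter] = field(default_factory=dict)
    n_orfs: int = 0

    def add_cds(self, cds: str) -> None:
        codons = cds_codons(cds)
        syms = cds_symbols(codons)
        if STOP in syms[:-1]:
            raise ValueError("internal STOP codon")
        for i in range(len(codons) - 1):
            key = (syms[i], syms[i + 1])
            self.pair_counts.setdefault(key, Counter())[(codons[i], codons[i + 1])] += 1
        for i in range(len(codons) - 2):
            if syms[i + 1] in TRIPLET_MIDDLE:
                key = (syms[i], syms[i + 1], syms[i + 2])
                self.triplet_counts.setdefault(key, Counter())[
                    (codons[i], codons[i + 1], codons[i + 2])] += 1
        self.n_orfs += 1

    def pair_frequencies(self, key: PairKey) -> dict[tuple[str, str], float]:
        counts = self.pair_counts.get(key)
        if not counts:
            combos = pair_combinations(key)
            return {c: 1.0 / len(combos) for c in combos}
        total = sum(counts.values())
        return {c: n / total for c, n in counts.items()}

    def p_motif_pair(self, key: PairKey, direction: str,
                     prior: "CodonUsageModel | None" = None) -> float:
        motif_combos = motif_encoding_pairs(direction).get(key)
        if not motif_combos:
            return 0.0
        counts = self.pair_counts.get(key)
        if not counts:
            if prior is not None and key in prior.pair_counts:
                logger.debug("%s: pair %s unseen; using pooled prior", self.name, key)
                return prior.p_motif_pair(key, direction)
            logger.debug("%s: pair %s unseen; using uniform prior", self.name, key)
            combos = pair_combinations(key)
            return len(motif_combos) / len(combos)
        total = sum(counts.values())
        return sum(n for c, n in counts.items() if c in motif_combos) / total

    def p_motif_triplet(self, key: TripletKey, direction: str,
                        prior: "CodonUsageModel | None" = None) -> float:
        motif_combos = motif_encoding_triplets(direction).get(key)
        if not motif_combos:
            return 0.0
        counts = self.triplet_counts.get(key)
        if not counts:
            if prior is not None and key in prior.triplet_counts:
                logger.debug("%s: triplet %s unseen; using pooled prior", self.name, key)
                return prior.p_motif_triplet(key, direction)
            logger.debug("%s: triplet %s unseen; using uniform prior", self.name, key)
            combos = triplet_combinations(key)
            return len(motif_combos) / len(combos)
        total = sum(counts.values())
        return sum(n for c, n in counts.items() if c in motif_combos) / total

    def merged_with(self, *others: "CodonUsageModel",
                    name: str = "pooled") -> "CodonUsageModel":
        """Pool counts with other class models (the shared fallback prior)."""
        pooled = CodonUsageModel(name=name)
        for model in (self, *others):
            for key, counts in model.pair_counts.items():
                pooled.pair_counts.setdefault(key, Counter()).update(counts)
            for key, counts in model.triplet_counts.items():
                pooled.triplet_counts.setdefault(key, Counter()).update(counts)
            pooled.n_orfs += model.n_orfs
        return pooled

    def marginal_codon_frequencies(self) -> dict[str, dict[str, float]]:
        """Per-symbol marginal codon frequencies (first slot of each pair,
        plus the second slot of terminal pairs so STOP codons are covered)."""
        counts: dict[str, Counter] = defaultdict(Counter)
        for (a, b), combos in self.pair_counts.items():
            for (c1, c2), n in combos.items():
                counts[a][c1] += n
                if b == STOP:
                    counts[b][c2] += n
        freqs: dict[str, dict[str, float]] = {}
        for sym, codons in CODONS_BY_SYM.items():
            c = counts.get(sym)
            if not c:
                freqs[sym] = {codon: 1.0 / len(codons) for codon in codons}
            else:
                total = sum(c.values())
                freqs[sym] = {codon: c[codon] / total for codon in codons}
        return freqs


def fit_usage(orfs: Iterable[Transcript], genome: Genome,
              name: str = "usage") -> CodonUsageModel:
    """Fit the codon-combination usage of one ORF class from its CDSs.

    ORFs with an internal stop codon, an out-of-frame CDS or a missing
    start codon are excluded with a logged reason.
    """
    model = CodonUsageModel(name=name)
    for orf in orfs:
        cds = orf.cds_sequence(genome) if isinstance(orf, Transcript) else str(orf)
        try:
            if not cds.startswith("ATG"):
                raise ValueError("CDS does not begin with ATG")
            model.add_cds(cds)
        except ValueError as exc:
            oid = orf.id if isinstance(orf, Transcript) else "<cds>"
            logger.warning("%s excluded from usage fit: %s", oid, exc)
    if model.n_orfs == 0:
        raise ValueError(f"{name}: no valid CDS to fit")
    return model


def _resolve_cds(orf, genome: Genome | None) -> str:
    if isinstance(orf, Transcript):
        if genome is None:
            raise ValueError("genome required when passing a Transcript")
        return orf.cds_sequence(genome)
    return str(orf).upper()


def expected_sites(orf, usage: CodonUsageModel, direction: str,
                   genome: Genome | None = None,
                   prior: CodonUsageModel | None = None) -> float:
    """Expected number of motif-bearing frames in a CDS under a class usage model.

    Sums, over the ORF's adjacent amino-acid pairs, the probability that
    the realised codon pair carries a motif within its 6-mer, plus, over
    eligible triplets, the probability of a three-codon-spanning 5-mer.
    This is the expectation of the frame count returned by
    :func:`observed_sites` with ``method="frame"``. ``prior`` (typically
    the classes pooled) supplies probabilities for keys the class never
    realised.
    """
    cds = _resolve_cds(orf, genome)
    syms = cds_symbols(cds_codons(cds))
    pair_keys = motif_encoding_pairs(direction)
    trip_keys = motif_encoding_triplets(direction)
    total = 0.0
    for i in range(len(syms) - 1):
        key = (syms[i], syms[i + 1])
        if key in pair_keys:
            total += usage.p_motif_pair(key, direction, prior)
    for i in range(len(syms) - 2):
        key = (syms[i], syms[i + 1], syms[i + 2])
        if key in trip_keys:
            total += usage.p_motif_triplet(key, direction, prior)
    return total


def observed_sites(orf, direction: str, genome: Genome | None = None,
                   msets: Sequence[MotifSet] = DEFAULT_MOTIF_SETS,
                   method: str = "frame") -> int:
    """Observed motif content of a CDS in one direction.

    ``method="frame"`` counts motif-bearing codon frames — adjacent codon
    pairs whose 6-mer contains a motif, plus eligible triplets whose core
    is a three-codon-spanning 5-mer. This is the observable whose
    expectation :func:`expected_sites` computes (a spanning 5-mer also
    leaves 4-mer fragments in both flanking 6-mers, so per-frame counting
    is the internally consistent convention for residuals).
    ``method="scan"`` counts longest-match scanner sites, the convention
    used for window counts and density profiles; it runs slightly below
    the frame count whenever spanning 5-mers occur.
    """
    cds = _resolve_cds(orf, genome)
    if method == "scan":
        scanner = scan if direction == "sense" else scan_antisense
        return sum(len(scanner(cds, mset)) for mset in msets)
    if method != "frame":
        raise ValueError(f"unknown method {method!r}")
    motifs = tuple(m for mset in msets for m in mset.motifs)
    fives = tuple(m for m in motifs if len(m) == 5)
    codons = cds_codons(cds)
    total = 0
    for i in range(len(codons) - 1):
        if _pair_has_motif((codons[i], codons[i + 1]), direction, motifs):
            total += 1
    for i in range(len(codons) - 2):
        if SYM_OF_CODON[codons[i + 1]] in TRIPLET_MIDDLE:
            if _triplet_has_spanning_motif(
                    (codons[i], codons[i + 1], codons[i + 2]), direction, fives):
                total += 1
    return total


def delta_expected(orf, usage_own: CodonUsageModel, usage_clear: CodonUsageModel,
                   direction: str, genome: Genome | None = None,
                   prior: CodonUsageModel | None = None) -> float:
    """Expected sites under the ORF's own class usage minus under the
    background (ORF_CLEAR) usage; positive values mean the class's codon
    choices favour motif creation relative to background. Both
    expectations share the same pooled ``prior`` for unseen keys."""
    if prior is None:
        prior = usage_own.merged_with(usage_clear)
    return (expected_sites(orf, usage_own, direction, genome, prior)
            - expected_sites(orf, usage_clear, direction, genome, prior))


def class_residuals(orfs: Iterable, usage: CodonUsageModel, direction: str,
                    genome: Genome | None = None,
                    prior: CodonUsageModel | None = None) -> pd.DataFrame:
    """Observed, expected and residual (observed - expected) per ORF."""
    rows = []
    for orf in orfs:
        oid = orf.id if isinstance(orf, Transcript) else f"cds{len(rows)}"
        exp = expected_sites(orf, usage, direction, genome, prior)
        obs = observed_sites(orf, direction, genome)
        rows.append((oid, direction, obs, exp, obs - exp))
    return pd.DataFrame(rows, columns=["orf_id", "direction", "observed",
                                       "expected", "residual"])


def single_codon_expected(orf, usage: CodonUsageModel, direction: str,
                          genome: Genome | None = None) -> float:
    """Expectation under the independent per-codon (marginal) usage model.

    Replaces each pair/triplet combination probability with the product of
    the marginal codon frequencies; kept as the comparator the pairwise
    model is judged against (it ignores coupling between adjacent codons).
    """
    cds = _resolve_cds(orf, genome)
    syms = cds_symbols(cds_codons(cds))
    marg = usage.marginal_codon_frequencies()
    pair_keys = motif_encoding_pairs(direction)
    trip_keys = motif_encoding_triplets(direction)
    total = 0.0
    for i in range(len(syms) - 1):
        key = (syms[i], syms[i + 1])
        combos = pair_keys.get(key)
        if combos:
            total += sum(marg[key[0]][c1] * marg[key[1]][c2] for c1, c2 in combos)
    for i in range(len(syms) - 2):
        key = (syms[i], syms[i + 1], syms[i + 2])
        combos = trip_keys.get(key)
        if combos:
            total += sum(marg[key[0]][c1] * marg[key[1]][c2] * marg[key[2]][c3]
                         for c1, c2, c3 in combos)
    return total


def model_sse(orfs: Iterable, usage: CodonUsageModel, direction: str,
              genome: Genome | None = None) -> dict[str, float]:
    """Sum of squared residuals of the pairwise and single-codon models."""
    sse_pair = sse_single = 0.0
    for orf in orfs:
        obs = observed_sites(orf, direction, genome)
        sse_pair += (obs - expected_sites(orf, usage, direction, genome)) ** 2
        sse_single += (obs - single_codon_expected(orf, usage, direction, genome)) ** 2
    return {"pair_model_sse": sse_pair, "single_codon_sse": sse_single}


# ---------------------------------------------------------------------------
# codon adaptation index


def load_cai_weights(path=None) -> dict[str, float]:
    """Relative-adaptiveness weights (codon -> w); defaults to the packaged
    Sharp & Li S. cerevisiae table. Weights must be positive and, within
    each amino-acid family, reach 1 for the optimal codon."""
    if path is None:
        path = resources.files("codonmask.data") / "cai_weights_sharp_li_1987.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    weights = dict(zip(df["codon"], df["weight"].astype(float)))
    for codon, w in weights.items():
        if w <= 0:
            raise ValueError(f"non-positive CAI weight for {codon}")
    return weights


#: Codons excluded from the CAI geometric mean: stop codons and the
#: single-codon families Met/Trp, which carry no synonymous choice
#: (the Sharp & Li convention).
CAI_EXCLUDED = frozenset({"ATG", "TGG"} | set(CODONS_BY_SYM[STOP]))


def cai(cds: str, weights: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of weights over the CDS codons.

    Stop codons and the single-codon families (ATG, TGG) are excluded
    from the mean, following the Sharp & Li convention — they offer no
    synonymous choice and would only dilute the index.
    """
    codons = cds_codons(cds)
    log_sum, n = 0.0, 0
    for codon in codons:
        if codon in CAI_EXCLUDED:
            continue
        if codon not in weights:
            raise ValueError(f"no CAI weight for codon {codon}")
        w = weights[codon]
        if w <= 0:
            raise ValueError(f"non-positive CAI weight for {codon}")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError("CDS contains no weighted codons")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# residual normality


def residual_normality(residuals: Sequence[float]) -> tuple[float, float]:
    """Anderson-Darling test of normality on expected-vs-observed residuals.

    Returns the size-adjusted A^2* statistic and its approximate p-value
    (Stephens' formula for the composite-normal case). Requires n >= 8 and
    a non-constant sample.
    """
    x = np.asarray(residuals, float)
    if x.size < 8:
        raise ValueError("need at least 8 residuals")
    if np.all(x == x[0]):
        raise ValueError("constant residual sample")
    a2 = float(stats.anderson(x, dist="norm", method="interpolate").statistic)
    n = x.size
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n ** 2)
    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star ** 2)
    elif a2_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star ** 2)
    elif a2_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star ** 2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star ** 2)
    return a2_star, min(max(p, 0.0), 1.0)
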