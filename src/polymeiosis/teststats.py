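"""Replicated-meiosis statistics ("test mode").

Runs many independent meioses of a single founder, samples one random
gamete per meiosis, and records the founder allele of every chromatid at a
set of test loci. From the accumulated observations it estimates
recombination fractions between locus pairs, double-reduction frequencies
per locus, and configuration frequencies, and compares them with the
closed-form references (Haldane/Kosambi map functions, the
quadrivalent-fraction formula).

A chromatid is scored recombinant between two loci when its founder
alleles differ there; a double crossover restoring the same founder allele
scores non-recombinant, matching the observational definition behind map
functions. Double reduction is scored per gamete: both chromatids carrying
the same founder allele at the locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from random import Random

import numpy as np
import pandas as pd

from .chiasma import ChiasmaProcessConfig
from .genome import ChromosomeSpec, founder_genome
from .meiosis import do_meiosis, pair_telomere, sample_gamete
from .theory import expected_quadrivalent_fraction, map_function_r

__all__ = [
    "GameteStats",
    "run_test_meioses",
    "estimate_recombination",
    "estimate_double_reduction",
    "count_quadrivalent_draws",
    "map_function_r",
    "summarize",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given ploidy."""


@dataclass
class GameteStats:
    """Accumulated per-locus founder-allele observations.

    ``alleles`` has shape (n_meioses, ploidy/2, n_loci): the founder allele
    of each chromatid of the sampled gamete at each test locus.
    """

    spec: ChromosomeSpec
    ploidy: int
    loci: list[float]
    n_meioses: int
    alleles: np.ndarray
    config_counts: dict[str, int]
    exchange_points: list[float] = field(default_factory=list)

    @property
    def n_chromatids(self) -> int:
        return self.n_meioses * (self.ploidy // 2)

    def locus_index(self, position: float) -> int:
        try:
            return self.loci.index(position)
        except ValueError:
            raise KeyError(f"locus at {position} cM was not recorded") from None


def run_test_meioses(
    spec: ChromosomeSpec,
    cfg: ChiasmaProcessConfig,
    n: int,
    loci: list[float],
    seed: int | Random,
    ploidy: int = 4,
) -> GameteStats:
    """Simulate ``n`` meioses of one founder; sample one gamete from each."""
    if n < 1:
        raise ValueError("need at least one meiosis")
    for pos in loci:
        if not 0.0 <= pos <= spec.length:
            raise ValueError(f"test locus {pos} outside chromosome {spec.name!r}")
    rng = Random(seed) if isinstance(seed, int) else seed
    parent = founder_genome(0, ploidy, [spec])
    half = ploidy // 2
    alleles = np.empty((n, half, len(loci)), dtype=np.int32)
    config_counts: dict[str, int] = {}
    exchange_points: list[float] = []
    specs = [spec]
    configs: dict = {}
    for m in range(n):
        configs.clear()
        gametes = do_meiosis(parent, specs, cfg, rng, configs_out=configs)
        config = configs[spec.name]
        config_counts[config.kind] = config_counts.get(config.kind, 0) + 1
        if config.kind == "cross":
            exchange_points.append(config.exchange_point)
        gamete = sample_gamete(gametes, rng)
        chromatids = gamete.chromatids[spec.name]
        for c in range(half):
            h = chromatids[c]
            for k, pos in enumerate(loci):
                alleles[m, c, k] = h.allele_at(pos)
    return GameteStats(
        spec=spec,
        ploidy=ploidy,
        loci=list(loci),
        n_meioses=n,
        alleles=alleles,
        config_counts=config_counts,
        exchange_points=exchange_points,
    )


def estimate_recombination(
    stats: GameteStats, locus_a: float, locus_b: float
) -> tuple[float, float]:
    """Recombination fraction between two recorded loci, with binomial SE."""
    ia = stats.locus_index(locus_a)
    ib = stats.locus_index(locus_b)
    if ia == ib:
        return 0.0, 0.0
    diff = stats.alleles[:, :, ia] != stats.alleles[:, :, ib]
    n = diff.size
    r = float(np.count_nonzero(diff)) / n
    return r, math.sqrt(r * (1.0 - r) / n)


def estimate_double_reduction(stats: GameteStats, locus: float) -> tuple[float, float]:
    """Double-reduction frequency at a locus, with binomial SE.

    The fraction of sampled gametes whose two chromatids carry the same
    founder allele at the locus. Only defined for tetraploids.
    """
    if stats.ploidy != 4:
        raise UndefinedStatisticError("double reduction is undefined for diploids")
    i = stats.locus_index(locus)
    same = stats.alleles[:, 0, i] == stats.alleles[:, 1, i]
    n = same.size
    dr = float(np.count_nonzero(same)) / n
    return dr, math.sqrt(dr * (1.0 - dr) / n)


def count_quadrivalent_draws(p: float, n: int, rng: Random) -> int:
    """Count quadrivalent outcomes among ``n`` natural pairing decisions.

    Draws top and bottom telomere pairings independently at preferential
    pairing ``p``; a quadrivalent results when the two pairings differ.
    """
    count = 0
    for _ in range(n):
        if pair_telomere(p, rng) != pair_telomere(p, rng):
            count += 1
    return count


def summarize(
    stats: GameteStats,
    intervals: list[tuple[float, float]] | None = None,
    map_kind: str | None = None,
) -> pd.DataFrame:
    """Report table: estimates, standard errors, references and z-scores.

    One row per locus interval (recombination; the map-function reference
    applies to bivalent-only runs), per locus (double reduction, tetraploid
    only), and one row per configuration kind, with the closed-form
    quadrivalent fraction as reference for natural-pairing runs.
    """
    if intervals is None:
        intervals = [(a, b) for a, b in zip(stats.loci, stats.loci[1:])]
    rows = []
    for a, b in intervals:
        r, se = estimate_recombination(stats, a, b)
        expected = (
            map_function_r(abs(b - a) / 100.0, map_kind) if map_kind is not None else np.nan
        )
        z = (r - expected) / se if se > 0 and not np.isnan(expected) else np.nan
        rows.append(
            {"statistic": "recombination", "from": a, "to": b,
             "estimate": r, "se": se, "expected": expected, "z": z}
        )
    if stats.ploidy == 4:
        for pos in stats.loci:
            dr, se = estimate_double_reduction(stats, pos)
            rows.append(
                {"statistic": "double_reduction", "from": pos, "to": pos,
                 "estimate": dr, "se": se, "expected": np.nan, "z": np.nan}
            )
        quad_expected = (
            expected_quadrivalent_fraction(stats.spec.pref_pairing)
            if stats.spec.natural_quadrivalents
            else np.nan
        )
        for kind, count in sorted(stats.config_counts.items()):
            freq = count / stats.n_meioses
            expected = np.nan
            if kind in ("cross", "parallel") and not np.isnan(quad_expected):
                pass  # per-kind split depends on parallel_fraction; report raw
            if kind == "bivalents" and not np.isnan(quad_expected):
                expected = 1.0 - quad_expected
            se = math.sqrt(freq * (1.0 - freq) / stats.n_meioses)
            z = (freq - expected) / se if se > 0 and not np.isnan(expected) else np.nan
            rows.append(
                {"statistic": f"config_{kind}", "from": np.nan, "to": np.nan,
                 "estimate": freq, "se": se, "expected": expected, "z": z}
            )
    return pd.DataFrame(rows)
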