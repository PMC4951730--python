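"""Monte Carlo simulation of backcross/DH mapping populations.

Genotypes follow a two-state Markov chain along each chromosome: the first
locus is a fair coin mapped to +/-1 and adjacent loci flip with the
Haldane recombination probability of their map distance. Phenotypes add
QTL effects (back-calculated from target r-squared fractions), an optional
multivariate-normal polygenic background with marker-inferred covariance,
optional epistatic pair effects on product codes, and Gaussian residual
noise.

Four experiment presets mirror a standard evaluation design on one 2400 cM
chromosome with 481 markers at 5 cM and n = 400: (I) twenty additive QTL
spanning r-squared 0.5%..20%, including four small-effect QTL (< 1%) and
four closely linked groups; (II) the same plus a polygenic background;
(III) the same plus three epistatic pairs; (IV) pure residual noise, for
false-positive calibration. Separate random streams drive genotypes,
polygene and residual, so experiments share genotypes at equal seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GeneticMap, GenotypeData, haldane_recomb
from .genome import _both_flank_expectation

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "experiment_config",
    "effects_from_r2",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate",
    "DEFAULT_QTL",
    "DEFAULT_EPISTATIC_PAIRS",
]

# Default 20-QTL configuration (position cM, r^2 fraction). Structure:
# largest r^2 = 0.20 (QTL 1), smallest = 0.005 (QTL 20); QTL 9, 14, 19, 20
# have r^2 < 1% (the small-effect group); adjacent spacing <= 20 cM within
# the linked groups {5,6}, {7,8}, {10,11,12} and {16,17,18}.
DEFAULT_QTL = (
    (50.0, 0.20),
    (220.0, 0.06),
    (400.0, 0.05),
    (560.0, 0.04),
    (700.0, 0.03),
    (715.0, 0.03),
    (880.0, 0.03),
    (898.0, 0.02),
    (1020.0, 0.008),
    (1150.0, 0.03),
    (1165.0, 0.02),
    (1182.0, 0.02),
    (1350.0, 0.04),
    (1480.0, 0.007),
    (1650.0, 0.03),
    (1800.0, 0.02),
    (1815.0, 0.02),
    (1832.0, 0.015),
    (2000.0, 0.006),
    (2200.0, 0.005),
)

# Epistatic pairs (posA, posB, r^2): the pairs sit inside the stated
# windows 800-1800, 1210-1860 and 275-740 cM.
DEFAULT_EPISTATIC_PAIRS = (
    (900.0, 1700.0, 0.05),
    (1300.0, 1800.0, 0.05),
    (300.0, 700.0, 0.05),
)

SMALL_QTL_INDICES = (9, 14, 19, 20)          # 1-based, r^2 < 1%
LINKED_QTL_GROUPS = ((5, 6), (7, 8), (10, 11, 12), (16, 17, 18))


@dataclass
class SimulationConfig:
    """Parameters of one simulated mapping population."""

    n: int = 400
    chrom_length: float = 2400.0
    marker_spacing: float = 5.0
    qtl: tuple = ()                      # (position cM, r^2 fraction)
    residual_var: float = 10.0
    mean: float = 100.0
    polygenic_h2: float = 0.0
    epistatic_pairs: tuple = ()          # (posA, posB, r^2 fraction)
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least two individuals")
        if self.residual_var <= 0:
            raise ValueError("residual variance must be positive")
        total = (
            sum(r2 for _, r2 in self.qtl)
            + self.polygenic_h2
            + sum(r2 for *_, r2 in self.epistatic_pairs)
        )
        if total >= 1.0:
            raise ValueError(
                f"variance fractions sum to {total:.3f}; must be < 1"
            )
        for pos, _ in self.qtl:
            if not 0.0 <= pos <= self.chrom_length:
                raise ValueError(f"QTL position {pos} outside the chromosome")
        for pa, pb, _ in self.epistatic_pairs:
            if not (0.0 <= pa <= self.chrom_length and 0.0 <= pb <= self.chrom_length):
                raise ValueError("epistatic QTL position outside the chromosome")


@dataclass
class SimulatedDataset:
    """Simulator output: map, genotypes, phenotype and the truth table."""

    gmap: GeneticMap
    geno: GenotypeData
    y: np.ndarray
    truth: pd.DataFrame       # per-QTL position, effect, r2
    config: SimulationConfig


def experiment_config(experiment, n: int = 400, seed: int = 0) -> SimulationConfig:
    """Preset configuration for experiments I-IV (1-4)."""
    label = str(experiment).upper()
    base = SimulationConfig(n=n, qtl=DEFAULT_QTL, seed=seed)
    if label in ("1", "I"):
        return base
    if label in ("2", "II"):
        return replace(base, polygenic_h2=0.1)
    if label in ("3", "III"):
        return replace(base, epistatic_pairs=DEFAULT_EPISTATIC_PAIRS)
    if label in ("4", "IV"):
        return replace(base, qtl=())
    raise ValueError(f"unknown experiment {experiment!r}")


def effects_from_r2(qtl, polygenic_h2=0.0, epistatic_pairs=(), residual_var=10.0):
    """Back-calculate effect sizes and variance components from r^2 targets.

    With +/-1 coding each locus code has unit variance in an idealized
    BC/DH, so the total phenotypic variance is
    sigma_P^2 = residual_var / (1 - sum r^2 - h2_pg - sum r^2_epi) and each
    additive effect is gamma_k = sqrt(r_k^2 * sigma_P^2); epistatic effects
    apply to the product code of a pair, polygenic variance is
    phi^2 = h2_pg * sigma_P^2.
    """
    r2_qtl = np.array([r2 for _, r2 in qtl], dtype=float)
    r2_epi = np.array([r2 for *_, r2 in epistatic_pairs], dtype=float)
    frac = float(r2_qtl.sum() + r2_epi.sum() + polygenic_h2)
    if frac >= 1.0:
        raise ValueError("variance fractions must sum to less than 1")
    sigma_p2 = residual_var / (1.0 - frac)
    return {
        "sigma_p2": sigma_p2,
        "qtl_effects": np.sqrt(r2_qtl * sigma_p2),
        "epistatic_effects": np.sqrt(r2_epi * sigma_p2),
        "polygenic_var": polygenic_h2 * sigma_p2,
    }


def _streams(seed):
    ss = np.random.SeedSequence(seed)
    geno_s, poly_s, resid_s = ss.spawn(3)
    return (
        np.random.default_rng(geno_s),
        np.random.default_rng(poly_s),
        np.random.default_rng(resid_s),
    )


def _conditional_mean_code(left, right, d_left, d_right):
    """Vectorized conditional expectation of a +/-1 code given flank codes."""
    if left is None and right is None:
        return np.zeros(1)
    if right is None:
        return left * (1.0 - 2.0 * haldane_recomb(d_left))
    if left is None:
        return right * (1.0 - 2.0 * haldane_recomb(d_right))
    r1 = haldane_recomb(d_left)
    r2 = haldane_recomb(d_right)
    return _both_flank_expectation(left, right, r1, r2)


def _markov_codes(rng, n, positions):
    first = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if positions.size == 1:
        return first[:, None]
    r = haldane_recomb(np.diff(positions))
    flips = rng.random((n, positions.size - 1)) < r[None, :]
    steps = np.where(flips, -1.0, 1.0)
    path = np.cumprod(np.hstack([np.ones((n, 1)), steps]), axis=1)
    return first[:, None] * path


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Simulate the marker map and genotype codes for one population.

    Returns ``(geno, gmap, qtl_codes, epi_codes)``: the emitted marker
    panel, its map, and the +/-1 codes at the (possibly off-grid, hidden)
    QTL and epistatic positions used for the phenotype.

    The marker-grid chain is drawn first; off-grid loci are then sampled
    from their exact conditional distribution given the flanking markers
    (valid by the Markov property of the no-interference model). Marker
    genotypes therefore do not depend on which QTL are configured, so
    experiments with different genetic architectures share genotypes when
    seeded identically.
    """
    if rng is None:
        rng = _streams(config.seed)[0]
    n_markers = int(round(config.chrom_length / config.marker_spacing)) + 1
    marker_pos = np.arange(n_markers) * config.marker_spacing
    marker_codes = _markov_codes(rng, config.n, marker_pos)

    qtl_pos = np.array([p for p, _ in config.qtl], dtype=float)
    epi_pos = np.array(
        [p for pair in config.epistatic_pairs for p in pair[:2]], dtype=float
    )
    extra_pos = np.concatenate([qtl_pos, epi_pos])
    extra_codes = np.empty((config.n, extra_pos.size))
    # sorted draw order keeps the stream independent of QTL list ordering
    for j in np.argsort(extra_pos, kind="stable"):
        pos = extra_pos[j]
        i = np.searchsorted(marker_pos, pos)
        if i < marker_pos.size and marker_pos[i] == pos:
            extra_codes[:, j] = marker_codes[:, i]
            continue
        left, right = i - 1, i
        e = _conditional_mean_code(
            marker_codes[:, left] if left >= 0 else None,
            marker_codes[:, right] if right < marker_pos.size else None,
            pos - marker_pos[left] if left >= 0 else None,
            marker_pos[right] - pos if right < marker_pos.size else None,
        )
        p_plus = 0.5 * (1.0 + e)
        extra_codes[:, j] = np.where(rng.random(config.n) < p_plus, 1.0, -1.0)
    qtl_codes = extra_codes[:, : qtl_pos.size]
    epi_codes = extra_codes[:, qtl_pos.size:]

    names = np.array([f"m{j:04d}" for j in range(n_markers)], dtype=object)
    gmap = GeneticMap(
        chromosome=np.array(["1"] * n_markers, dtype=object),
        position=marker_pos.astype(float),
        name=names,
        is_pseudo=np.zeros(n_markers, dtype=bool),
    )
    geno = GenotypeData(
        codes=marker_codes,
        ids=np.array([f"ind{j:04d}" for j in range(config.n)], dtype=object),
        names=names,
    )
    return geno, gmap, qtl_codes, epi_codes


def simulate_phenotype(qtl_codes, config: SimulationConfig, marker_codes=None,
                       epi_codes=None, rng_poly=None, rng_resid=None):
    """Phenotype y = mean + Z gamma + epistasis + polygene + residual."""
    if rng_poly is None or rng_resid is None:
        _, p_s, r_s = _streams(config.seed)
        rng_poly = rng_poly or p_s
        rng_resid = rng_resid or r_s
    comp = effects_from_r2(
        config.qtl, config.polygenic_h2, config.epistatic_pairs, config.residual_var
    )
    n = config.n
    y = np.full(n, config.mean, dtype=float)
    if qtl_codes is not None and qtl_codes.size:
        y += qtl_codes @ comp["qtl_effects"]
    if epi_codes is not None and epi_codes.size:
        prod = epi_codes[:, 0::2] * epi_codes[:, 1::2]
        y += prod @ comp["epistatic_effects"]
    if comp["polygenic_var"] > 0:
        if marker_codes is None:
            raise ValueError("polygenic background needs the simulated marker codes")
        K = marker_codes @ marker_codes.T / marker_codes.shape[1]
        vals, vecs = np.linalg.eigh(K)
        vals = np.clip(vals, 0.0, None)
        xi = vecs @ (np.sqrt(vals * comp["polygenic_var"]) * rng_poly.standard_normal(n))
        y += xi
    y += rng_resid.normal(0.0, np.sqrt(config.residual_var), size=n)
    return y


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Full reproducible simulation of one replicate from ``config.seed``."""
    rng_geno, rng_poly, rng_resid = _streams(config.seed)
    geno, gmap, qtl_codes, epi_codes = simulate_genotypes(config, rng=rng_geno)
    y = simulate_phenotype(
        qtl_codes,
        config,
        marker_codes=geno.codes,
        epi_codes=epi_codes,
        rng_poly=rng_poly,
        rng_resid=rng_resid,
    )
    comp = effects_from_r2(
        config.qtl, config.polygenic_h2, config.epistatic_pairs, config.residual_var
    )
    truth = pd.DataFrame(
        {
            "chromosome": ["1"] * len(config.qtl),
            "position_cM": [p for p, _ in config.qtl],
            "effect": comp["qtl_effects"],
            "r2": [r2 for _, r2 in config.qtl],
        }
    )
    return SimulatedDataset(gmap=gmap, geno=geno, y=y, truth=truth, config=config)
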