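"""Genetic maps, genotype coding, pseudo-marker insertion and kinship.

Backcross (BC) and doubled-haploid (DH) populations carry two genotype
classes per locus, coded +1/-1 (AA/Aa in BC; the two homozygotes in DH).
Scan positions between markers ("pseudo markers") and missing entries are
represented by the conditional expectation of the +/-1 code given the
nearest observed flanking markers, computed under a no-interference
(Haldane) recombination model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "GenotypeData",
    "Kinship",
    "haldane_recomb",
    "kosambi_recomb",
    "insert_pseudo_markers",
    "conditional_expectation",
    "fill_expected",
    "build_kinship",
    "collapse_duplicate_positions",
]

#: numeric code used for a missing genotype observation
MISSING = np.nan


def haldane_recomb(d_cm):
    """Recombination fraction for a map distance in cM (Haldane, no interference).

    r = (1 - exp(-2 d / 100)) / 2, strictly increasing, -> 0.5 as d -> inf.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-0.02 * d))
    return float(r) if np.isscalar(d_cm) else r


def kosambi_recomb(d_cm):
    """Kosambi recombination fraction, r = tanh(2d/100)/2 (interference-adjusted)."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(0.02 * d)
    return float(r) if np.isscalar(d_cm) else r


MAP_FUNCTIONS = {"haldane": haldane_recomb, "kosambi": kosambi_recomb}


@dataclass
class GeneticMap:
    """Ordered loci (true markers and inserted pseudo markers) on a linkage map.

    Positions are in centimorgan, nondecreasing within each chromosome;
    duplicate positions must be collapsed before construction (see
    :func:`collapse_duplicate_positions`).
    """

    chromosome: np.ndarray
    position: np.ndarray
    name: np.ndarray
    is_pseudo: np.ndarray

    def __post_init__(self):
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=float)
        self.name = np.asarray(self.name, dtype=object)
        if self.is_pseudo is None:
            self.is_pseudo = np.zeros(self.position.size, dtype=bool)
        self.is_pseudo = np.asarray(self.is_pseudo, dtype=bool)
        n = self.position.size
        if not (self.chromosome.size == self.name.size == self.is_pseudo.size == n):
            raise ValueError("map fields must have equal length")
        if n and np.any(self.position < 0):
            raise ValueError("positions must be nonnegative")
        if len(set(self.name)) != n:
            raise ValueError("locus names must be unique")
        for chrom in self.chromosomes:
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions on chromosome {chrom!r} must be strictly "
                    "increasing (collapse duplicate positions first)"
                )

    @property
    def chromosomes(self):
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.chromosome))

    @property
    def n_loci(self) -> int:
        return self.position.size

    def chrom_indices(self, chrom) -> np.ndarray:
        return np.flatnonzero(self.chromosome == chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.name,
                "chromosome": self.chromosome,
                "position_cM": self.position,
                "is_pseudo": self.is_pseudo,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        is_pseudo = df["is_pseudo"].to_numpy() if "is_pseudo" in df else None
        return cls(
            chromosome=df["chromosome"].to_numpy(),
            position=df["position_cM"].to_numpy(),
            name=df["name"].to_numpy(),
            is_pseudo=is_pseudo,
        )


def collapse_duplicate_positions(df: pd.DataFrame):
    """Keep one marker per (chromosome, position), first by input order.

    Returns ``(collapsed_frame, n_dropped)``.
    """
    keep = ~df.duplicated(subset=["chromosome", "position_cM"], keep="first")
    return df.loc[keep].reset_index(drop=True), int((~keep).sum())


@dataclass
class GenotypeData:
    """Genotype codes for n individuals at m mapped loci.

    ``codes`` holds observed +1/-1 codes with NaN for missing entries and for
    pseudo loci; ``expected`` equals ``codes`` where observed and the
    conditional expectation given flanking markers elsewhere (filled by
    :func:`fill_expected`).
    """

    codes: np.ndarray
    ids: np.ndarray
    names: np.ndarray
    is_pseudo: np.ndarray = None
    expected: np.ndarray = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x loci)")
        self.ids = np.asarray(self.ids, dtype=object)
        self.names = np.asarray(self.names, dtype=object)
        if self.is_pseudo is None:
            self.is_pseudo = np.zeros(self.codes.shape[1], dtype=bool)
        self.is_pseudo = np.asarray(self.is_pseudo, dtype=bool)
        if self.expected is None:
            self.expected = self.codes.copy()
        self.expected = np.asarray(self.expected, dtype=float)
        n, m = self.codes.shape
        if self.ids.size != n or self.names.size != m or self.is_pseudo.size != m:
            raise ValueError("inconsistent genotype dimensions")
        obs = np.isfinite(self.codes)
        if not np.all(np.isin(self.codes[obs], (-1.0, 1.0))):
            raise ValueError("observed genotype codes must be +1 or -1")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]


@dataclass
class Kinship:
    """Marker-inferred relatedness matrix K = (1/m) sum_k z_k z_k'."""

    matrix: np.ndarray
    marker_names: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("kinship must be square")


def insert_pseudo_markers(gmap: GeneticMap, d: float) -> GeneticMap:
    """Insert pseudo markers so no inter-locus gap exceeds ``d`` cM.

    Each interval of length L > d receives ceil(L/d) - 1 equally spaced
    pseudo loci; intervals already <= d are untouched, so the operation is
    idempotent at fixed ``d``.
    """
    if d <= 0:
        raise ValueError("pseudo-marker spacing d must be positive")
    chroms, positions, names, pseudo = [], [], [], []
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_indices(chrom)
        pos = gmap.position[idx]
        for j, i in enumerate(idx):
            chroms.append(chrom)
            positions.append(gmap.position[i])
            names.append(gmap.name[i])
            pseudo.append(gmap.is_pseudo[i])
            if j == len(idx) - 1:
                continue
            gap = pos[j + 1] - pos[j]
            if gap <= d + 1e-9:
                continue
            k = int(np.ceil(gap / d - 1e-9)) - 1
            step = gap / (k + 1)
            for t in range(1, k + 1):
                p = pos[j] + t * step
                chroms.append(chrom)
                positions.append(p)
                names.append(f"pseudo_{chrom}_{p:.6g}")
                pseudo.append(True)
    return GeneticMap(
        chromosome=np.array(chroms, dtype=object),
        position=np.array(positions, dtype=float),
        name=np.array(names, dtype=object),
        is_pseudo=np.array(pseudo, dtype=bool),
    )


def _both_flank_expectation(left, right, r1, r2):
    # P(+1 | flanks) via the two paths through the middle locus; the
    # normalizer is P(left -> right) so Haldane additivity is implicit.
    up1 = np.where(left > 0, 1.0 - r1, r1)
    up2 = np.where(right > 0, 1.0 - r2, r2)
    dn1 = np.where(left > 0, r1, 1.0 - r1)
    dn2 = np.where(right > 0, r2, 1.0 - r2)
    num = up1 * up2 - dn1 * dn2
    den = up1 * up2 + dn1 * dn2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def conditional_expectation(
    left_code, right_code, d_left, d_right, map_function=haldane_recomb
):
    """Expected +/-1 code at a locus given flanking marker codes and distances.

    Either flank may be missing (``None`` or NaN): with one observed flank
    the single-flank conditional ``code * (1 - 2 r(d))`` applies, with none
    the prior expectation 0 is returned.
    """
    left_missing = left_code is None or not np.isfinite(left_code)
    right_missing = right_code is None or not np.isfinite(right_code)
    if d_left is not None and d_left < 0 or d_right is not None and d_right < 0:
        raise ValueError("flank distances must be nonnegative")
    if left_missing and right_missing:
        return 0.0
    if right_missing:
        return float(left_code) * (1.0 - 2.0 * map_function(d_left))
    if left_missing:
        return float(right_code) * (1.0 - 2.0 * map_function(d_right))
    r1 = map_function(d_left)
    r2 = map_function(d_right)
    return float(
        _both_flank_expectation(
            np.asarray(float(left_code)), np.asarray(float(right_code)),
            np.asarray(r1), np.asarray(r2),
        )
    )


def fill_expected(
    geno: GenotypeData, gmap: GeneticMap, map_function=haldane_recomb
) -> GenotypeData:
    """Expand genotypes onto the scan grid of ``gmap`` and fill expectations.

    Every pseudo locus and every missing observation is replaced by the
    conditional expectation given the nearest non-missing observed true
    markers on the same chromosome (exact multipoint value for fully
    observed flanks under no interference). An individual with no observed
    marker on a chromosome gets expectation 0 there, with a warning.
    """
    name_to_col = {nm: j for j, nm in enumerate(geno.names)}
    n = geno.n_individuals
    m_out = gmap.n_loci
    codes_out = np.full((n, m_out), np.nan)
    expected_out = np.zeros((n, m_out))
    n_empty = 0

    for chrom in gmap.chromosomes:
        idx = gmap.chrom_indices(chrom)
        true_idx = idx[~gmap.is_pseudo[idx]]
        true_pos = gmap.position[true_idx]
        cols = []
        for i in true_idx:
            nm = gmap.name[i]
            if nm not in name_to_col:
                raise KeyError(f"map marker {nm!r} absent from genotype data")
            cols.append(name_to_col[nm])
        cols = np.asarray(cols, dtype=int)
        obs_codes = geno.codes[:, cols]  # n x mt
        mt = cols.size
        if mt == 0:
            n_empty += n
            continue
        mask = np.isfinite(obs_codes)
        col_range = np.arange(mt)
        left_idx = np.where(mask, col_range[None, :], -1)
        np.maximum.accumulate(left_idx, axis=1, out=left_idx)
        right_idx = np.where(mask, col_range[None, :], mt)
        right_idx = np.flip(
            np.minimum.accumulate(np.flip(right_idx, axis=1), axis=1), axis=1
        )
        n_empty += int(np.sum(~mask.any(axis=1)))

        # bracketing true-marker local indices for every scan locus
        pos = gmap.position[idx]
        tl = np.searchsorted(true_pos, pos + 1e-12) - 1  # last true <= pos
        tr = np.searchsorted(true_pos, pos - 1e-12)      # first true >= pos
        tl_c = np.clip(tl, 0, mt - 1)
        tr_c = np.clip(tr, 0, mt - 1)
        li = np.where(tl[None, :] >= 0, left_idx[:, tl_c], -1)
        ri = np.where(tr[None, :] <= mt - 1, right_idx[:, tr_c], mt)

        li_valid = li >= 0
        ri_valid = ri <= mt - 1
        li_c = np.clip(li, 0, mt - 1)
        ri_c = np.clip(ri, 0, mt - 1)
        lcode = np.take_along_axis(obs_codes, li_c, axis=1)
        rcode = np.take_along_axis(obs_codes, ri_c, axis=1)
        d_l = pos[None, :] - true_pos[li_c]
        d_r = true_pos[ri_c] - pos[None, :]
        r1 = map_function(np.maximum(d_l, 0.0))
        r2 = map_function(np.maximum(d_r, 0.0))

        exp_both = _both_flank_expectation(lcode, rcode, r1, r2)
        exp_left = lcode * (1.0 - 2.0 * r1)
        exp_right = rcode * (1.0 - 2.0 * r2)
        expected = np.where(
            li_valid & ri_valid,
            exp_both,
            np.where(li_valid, exp_left, np.where(ri_valid, exp_right, 0.0)),
        )

        # true loci carry their observed codes exactly
        true_local = ~gmap.is_pseudo[idx]
        codes_out[:, idx[true_local]] = obs_codes
        expected[:, true_local] = np.where(mask, obs_codes, expected[:, true_local])
        expected_out[:, idx] = expected

    if n_empty:
        warnings.warn(
            f"{n_empty} individual-chromosome combinations have no observed "
            "marker; their expectations default to 0",
            stacklevel=2,
        )
    return GenotypeData(
        codes=codes_out,
        ids=geno.ids,
        names=gmap.name,
        is_pseudo=gmap.is_pseudo,
        expected=expected_out,
    )


def build_kinship(geno: GenotypeData, exclude=None) -> Kinship:
    """Kinship K = (1/m) Z Z' over the expected codes of true markers.

    Pseudo loci never enter K. ``exclude`` names true markers to drop —
    used by the part-marker mode, which removes the two markers flanking
    the scanned interval.
    """
    exclude = set(exclude) if exclude is not None else set()
    use = ~geno.is_pseudo & ~np.isin(geno.names, list(exclude))
    m = int(use.sum())
    if m == 0:
        raise ValueError("no markers left for kinship after exclusion")
    Z = geno.expected[:, use]
    if not np.all(np.isfinite(Z)):
        raise ValueError(
            "expected codes contain missing values; run fill_expected first"
        )
    K = (Z @ Z.T) / m
    return Kinship(matrix=K, marker_names=geno.names[use])
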